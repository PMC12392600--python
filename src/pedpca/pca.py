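"""Leading principal components of the (centred) relationship matrix.

Two matrix-free backends over :class:`~pedpca.operators.ImplicitOperator`:

* :func:`rsvd_pca` — randomised SVD.  A Gaussian test matrix is pushed
  through the operator, QR of the image gives an orthonormal range basis Q
  (optionally refined by extra passes), and a small SVD of ``Z = L^T Q``
  recovers singular values of L and the component scores.
* :func:`lanczos_pca` — a Lanczos/implicitly-restarted symmetric eigensolver
  (ARPACK via ``scipy.sparse.linalg.eigsh``) driven by the same operator.

Both return the covariance-of-individuals PCA convention: if
``A = W diag(lambda) W^T`` then scores are ``W diag(lambda)`` and the
per-component standard deviation ("sdev") is ``sqrt(lambda)`` — the singular
value of L.  Variance proportions are ``sdev^2 / total_variance`` when the
total variance (trace) is supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse.linalg import eigsh

from .operators import ImplicitOperator, TraceEstimate

__all__ = ["RsvdConfig", "PCAResult", "rsvd_pca", "lanczos_pca", "summarise", "align_signs"]


@dataclass
class RsvdConfig:
    """Randomised-SVD tuning knobs.

    ``k`` components are reported from an ``l``-column sketch (``l >= k``;
    going beyond 2k buys little).  ``power_iterations`` extra operator passes
    re-orthonormalised each time sharpen the range basis for slowly decaying
    spectra.
    """

    k: int = 10
    l: int | None = None
    power_iterations: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.l is None:
            self.l = max(15, int(np.ceil(1.5 * self.k)))
            self.l = min(self.l, max(self.k, 2 * self.k))
        if self.l < self.k:
            raise ValueError(f"sketch size l={self.l} must be >= k={self.k}")
        if self.l > 2 * self.k:
            warnings.warn(
                f"sketch size l={self.l} exceeds 2k={2 * self.k}; larger sketches "
                "rarely improve accuracy",
                stacklevel=2,
            )


@dataclass
class PCAResult:
    """Scores (n x k), per-component sdev, and optional variance accounting."""

    scores: np.ndarray
    sdev: np.ndarray
    centred: bool
    method: str
    total_variance: TraceEstimate | None = None
    labels: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    @property
    def proportion(self) -> np.ndarray | None:
        """Fraction of total variance per component (None without a trace)."""
        if self.total_variance is None:
            return None
        return self.sdev**2 / self.total_variance.value


def _orth(Y: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(Y)
    return Q


def rsvd_pca(
    op: ImplicitOperator,
    cfg: RsvdConfig | None = None,
    total_variance: TraceEstimate | None = None,
) -> PCAResult:
    """Approximate PCA of the implicit relationship matrix by randomised SVD.

    Steps: draw a Gaussian test matrix Omega (n x l); Y = op @ Omega; QR of Y
    gives the range basis Q, refined by ``power_iterations`` further
    ``orth(op @ Q)`` passes; Z = L^T Q (mean-subtracted first when centred)
    carries all the spectral information of the sketch, and its thin SVD
    Z = W diag(d) V^T yields sdev = d (singular values of L) and scores
    Q V diag(d^2), truncated to the leading k.  Deterministic given the seed.
    """
    cfg = cfg or RsvdConfig()
    n = op.shape[0]
    if cfg.l > n:
        raise ValueError(f"sketch size l={cfg.l} exceeds pedigree size n={n}")
    rng = np.random.default_rng(cfg.seed)
    # column-major generation order fixes the stream layout for a given seed
    Omega = rng.standard_normal((cfg.l, n)).T
    Q = _orth(op.matmat(Omega))
    for _ in range(cfg.power_iterations):
        Q = _orth(op.matmat(Q))
    Z = op.lt_mat(Q)  # n x l; Z^T Z = Q^T A Q
    _, d, Vt = np.linalg.svd(Z, full_matrices=False)
    order = np.argsort(d)[::-1]
    d = d[order[: cfg.k]]
    U_B = Vt[order[: cfg.k]].T  # right singular vectors of Z = left of B = Q^T L
    scores = Q @ (U_B * d**2)
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite values encountered in PCA (bad input?)")
    return PCAResult(
        scores=scores,
        sdev=d,
        centred=op.centred,
        method="rsvd",
        total_variance=total_variance,
        labels=getattr(op.chol, "labels", None),
    )


def lanczos_pca(
    op: ImplicitOperator,
    k: int = 10,
    tol: float = 0.0,
    total_variance: TraceEstimate | None = None,
    seed: int = 0,
) -> PCAResult:
    """Leading-k PCA via a Lanczos-type symmetric eigensolver on the implicit
    operator; same score convention as :func:`rsvd_pca` so the two backends
    agree to solver tolerance."""
    n = op.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"need 1 <= k < n, got k={k}, n={n}")
    v0 = np.random.default_rng(seed).standard_normal(n)  # fixed start vector
    try:
        lam, W = eigsh(op, k=k, which="LA", tol=tol, v0=v0)
    except Exception as exc:  # ArpackNoConvergence and friends
        raise RuntimeError(
            "Lanczos eigensolver did not converge; try a larger tol or smaller k"
        ) from exc
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    W = W[:, order]
    return PCAResult(
        scores=W * lam,
        sdev=np.sqrt(lam),
        centred=op.centred,
        method="lanczos",
        total_variance=total_variance,
        labels=getattr(op.chol, "labels", None),
    )


def align_signs(res: PCAResult) -> PCAResult:
    """Fix the sign indeterminacy of each component: flip any score column
    whose largest-magnitude entry is negative. Idempotent; sdev unchanged."""
    scores = res.scores.copy()
    for j in range(scores.shape[1]):
        col = scores[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            scores[:, j] = -col
    return replace(res, scores=scores)


def summarise(res: PCAResult) -> str:
    """Per-component table: sdev, variance proportion, cumulative proportion.

    Proportions are shown as NA when no total variance is attached (truncated
    decompositions cannot recover the trace on their own).
    """
    lines = [f"Pedigree PCA ({res.method}, {'centred' if res.centred else 'non-centred'})"]
    prop = res.proportion
    if res.total_variance is not None:
        kind = "exact" if res.total_variance.exact else "Hutch++ estimate"
        lines.append(f"Total variance: {res.total_variance.value:.6g} ({kind})")
    else:
        lines.append("Total variance unknown: proportions reported as NA")
    lines.append(f"{'PC':>4} {'sdev':>12} {'prop.var':>10} {'cum.prop':>10}")
    cum = 0.0
    for j in range(res.k):
        if prop is None:
            p = c = "NA"
        else:
            cum += prop[j]
            p, c = f"{100 * prop[j]:9.3f}%", f"{100 * cum:9.3f}%"
        lines.append(f"{j + 1:>4} {res.sdev[j]:>12.6g} {p:>10} {c:>10}")
    return "\n".join(lines)
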