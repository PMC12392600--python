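"""Pedigree parsing, cleaning, sorting and sparse precision-factor construction.

A pedigree is a directed acyclic graph of parent-offspring links. Under the
standard additive-genetic model it implies a dense covariance matrix between
individuals, the numerator relationship matrix ``A`` with ``A[i, i] = 1 + F_i``
(``F`` the inbreeding coefficient).  ``A`` itself is never needed: its inverse
is extremely sparse and factorises as ``A^-1 = (L^-1)^T (L^-1)`` where the
lower-triangular factor ``L^-1`` has at most three non-zero entries per row
(the individual itself plus its known parents).  Everything downstream
(matrix-vector products, PCA, traces) works through that factor.

Conventions used throughout:

* individuals are stored in file order until :func:`sort_pedigree` renumbers
  them 1..n with parents preceding offspring;
* parent index 0 means "unknown"; unknown parents are treated as draws from a
  non-inbred, unrelated base population;
* founders (both parents unknown) are generation 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from numba import njit

__all__ = [
    "Pedigree",
    "PedigreeError",
    "CycleError",
    "PrecisionCholesky",
    "read_pedigree",
    "write_pedigree",
    "add_missing_parents",
    "sort_pedigree",
    "assign_generations",
    "inbreeding",
    "mendelian_variance",
    "build_precision_cholesky",
    "dense_A_oracle",
]

#: strings accepted as "parent unknown" in input files
UNKNOWN_CODES = {"0", "", "na", "nan", "none", "."}


class PedigreeError(ValueError):
    """Invalid pedigree structure or file contents."""


class CycleError(PedigreeError):
    """An individual was found to be its own ancestor."""

    def __init__(self, individuals: Sequence[str]):
        self.individuals = list(individuals)
        super().__init__(
            "pedigree contains a loop (individual(s) found to be their own "
            f"ancestor): {', '.join(map(str, self.individuals))}"
        )


def _as_label(value) -> str | None:
    """Normalise a raw parent field to a label string or None (unknown)."""
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    s = str(value).strip()
    if s.lower() in UNKNOWN_CODES:
        return None
    return s


@dataclass
class Pedigree:
    """A pedigree table: one record per individual with parent references.

    Parents are stored by label; the integer index views :attr:`sire` and
    :attr:`dam` (1-based, 0 = unknown) are derived on demand and raise
    :class:`PedigreeError` while parent labels dangle (use
    :func:`add_missing_parents` first).
    """

    labels: np.ndarray                   # object array of unique id strings
    sire_label: np.ndarray               # object array, None = unknown
    dam_label: np.ndarray
    generation: np.ndarray | None = None  # int array, founders = 1
    metadata: pd.DataFrame | None = None  # extra columns, aligned by row
    sorted: bool = False
    #: permutation mapping sorted rows back to the pre-sort input order,
    #: i.e. ``input_row = perm_to_input[sorted_row]`` (set by sort_pedigree)
    perm_to_input: np.ndarray | None = None
    _sire_idx: np.ndarray | None = field(default=None, repr=False)
    _dam_idx: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        self.sire_label = np.asarray(self.sire_label, dtype=object)
        self.dam_label = np.asarray(self.dam_label, dtype=object)
        if not (len(self.labels) == len(self.sire_label) == len(self.dam_label)):
            raise PedigreeError("id/sire/dam columns differ in length")
        dup = pd.Index(self.labels)[pd.Index(self.labels).duplicated()]
        if len(dup):
            raise PedigreeError(
                f"duplicate individual ids: {', '.join(map(str, dup.unique()))}"
            )

    @property
    def n(self) -> int:
        return len(self.labels)

    # -- index views ------------------------------------------------------
    def _resolve(self) -> tuple[np.ndarray, np.ndarray]:
        if self._sire_idx is None:
            pos = {lab: i + 1 for i, lab in enumerate(self.labels)}
            missing: list[str] = []

            def idx(parents):
                out = np.zeros(self.n, dtype=np.int64)
                for i, lab in enumerate(parents):
                    if lab is None:
                        continue
                    j = pos.get(lab, 0)
                    if j == 0:
                        missing.append(lab)
                    out[i] = j
                return out

            s, d = idx(self.sire_label), idx(self.dam_label)
            if missing:
                uniq = sorted(set(missing))
                raise PedigreeError(
                    "parents referenced but not recorded as individuals: "
                    f"{', '.join(uniq)} (use add_missing_parents to insert them)"
                )
            self._sire_idx, self._dam_idx = s, d
        return self._sire_idx, self._dam_idx

    @property
    def sire(self) -> np.ndarray:
        """1-based sire indices, 0 = unknown."""
        return self._resolve()[0]

    @property
    def dam(self) -> np.ndarray:
        """1-based dam indices, 0 = unknown."""
        return self._resolve()[1]

    def is_complete(self) -> bool:
        """True when every referenced parent exists as an individual."""
        try:
            self._resolve()
        except PedigreeError:
            return False
        return True

    def require_sorted(self, op: str) -> None:
        if not self.sorted:
            raise PedigreeError(f"{op} requires a sorted pedigree; call sort_pedigree first")

    @classmethod
    def from_indices(
        cls,
        sire: Sequence[int],
        dam: Sequence[int],
        labels: Sequence[str] | None = None,
        **kwargs,
    ) -> "Pedigree":
        """Build a pedigree from 1-based parent index arrays (0 = unknown).

        If the arrays are already parents-first the result is marked sorted.
        """
        sire = np.asarray(sire, dtype=np.int64)
        dam = np.asarray(dam, dtype=np.int64)
        n = len(sire)
        if labels is None:
            labels = np.asarray([str(i + 1) for i in range(n)], dtype=object)
        else:
            labels = np.asarray(labels, dtype=object)
        for name, arr in (("sire", sire), ("dam", dam)):
            if np.any((arr < 0) | (arr > n)):
                raise PedigreeError(f"{name} indices must be in 0..{n}")
        is_sorted = bool(
            np.all(sire <= np.arange(n)) and np.all(dam <= np.arange(n))
        )
        ped = cls(
            labels,
            np.asarray([labels[s - 1] if s else None for s in sire], dtype=object),
            np.asarray([labels[d - 1] if d else None for d in dam], dtype=object),
            sorted=kwargs.pop("sorted", is_sorted),
            **kwargs,
        )
        ped._sire_idx, ped._dam_idx = sire, dam
        return ped

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": self.labels,
                "sire": [s if s is not None else "0" for s in self.sire_label],
                "dam": [d if d is not None else "0" for d in self.dam_label],
            }
        )
        if self.generation is not None:
            df["generation"] = self.generation
        if self.metadata is not None:
            for col in self.metadata.columns:
                df[col] = np.asarray(self.metadata[col])
        return df


def read_pedigree(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    sep: str | None = None,
    on_missing_parent: str = "error",
) -> Pedigree:
    """Read a delimited pedigree file (id, sire, dam, optional metadata).

    The delimiter is auto-detected (comma or tab) unless ``sep`` is given, and
    a header row is detected by looking for id/sire/dam-like column names.
    Unknown parents may be coded ``0``, ``NA``, ``.`` or left empty.

    Parameters
    ----------
    column_map:
        optional mapping from the roles ``id``/``sire``/``dam`` to the actual
        column names in the file.
    on_missing_parent:
        ``"error"`` (default) raises when a parent id is never declared as an
        individual; ``"insert"`` appends founder records for them, like
        :func:`add_missing_parents`.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if sep is None:
        sep = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","
    name_hints = {"id", "sire", "dam", "ind", "animal", "father", "mother"}
    tokens = [t.strip().lower() for t in first.rstrip("\n").split(sep)]
    has_header = bool(name_hints.intersection(tokens)) or (
        column_map is not None and set(column_map.values()).intersection(first.split(sep))
    )
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None, dtype=str,
                     keep_default_na=False)
    if not has_header:
        base = ["id", "sire", "dam"]
        extra = [f"meta{j}" for j in range(1, df.shape[1] - 2)]
        if df.shape[1] < 3:
            raise PedigreeError("pedigree file needs at least id, sire, dam columns")
        df.columns = base + extra
    cmap = {"id": "id", "sire": "sire", "dam": "dam"}
    if column_map:
        cmap.update(column_map)
    for role, col in cmap.items():
        if col not in df.columns:
            raise PedigreeError(f"column {col!r} (role {role}) not found in {path.name}")
    labels = df[cmap["id"]].map(lambda v: _as_label(v)).to_numpy(dtype=object)
    if any(lab is None for lab in labels):
        raise PedigreeError("individual id column contains empty/unknown codes")
    sire = df[cmap["sire"]].map(_as_label).to_numpy(dtype=object)
    dam = df[cmap["dam"]].map(_as_label).to_numpy(dtype=object)
    meta_cols = [c for c in df.columns if c not in {cmap["id"], cmap["sire"], cmap["dam"]}]
    meta = df[meta_cols].reset_index(drop=True) if meta_cols else None
    ped = Pedigree(labels, sire, dam, metadata=meta)
    if not ped.is_complete():
        if on_missing_parent == "insert":
            ped = add_missing_parents(ped)
        else:
            ped._resolve()  # raises with the offending labels
    return ped


def write_pedigree(ped: Pedigree, path: str | Path, sep: str = ",") -> None:
    """Write id/sire/dam (+ generation and metadata) as delimited text."""
    ped.to_frame().to_csv(path, sep=sep, index=False)


def add_missing_parents(ped: Pedigree) -> Pedigree:
    """Append founder records for parents that are referenced but not listed.

    Inserted parents get unknown parents themselves and keep their referenced
    label; they are appended after the existing records. A complete pedigree
    is returned unchanged.
    """
    known = set(ped.labels)
    new: list[str] = []
    seen: set[str] = set()
    for lab in list(ped.sire_label) + list(ped.dam_label):
        if lab is not None and lab not in known and lab not in seen:
            seen.add(lab)
            new.append(lab)
    if not new:
        return ped
    labels = np.concatenate([ped.labels, np.asarray(new, dtype=object)])
    nones = np.asarray([None] * len(new), dtype=object)
    meta = ped.metadata
    if meta is not None:
        pad = pd.DataFrame({c: [""] * len(new) for c in meta.columns})
        meta = pd.concat([meta, pad], ignore_index=True)
    return Pedigree(
        labels,
        np.concatenate([ped.sire_label, nones]),
        np.concatenate([ped.dam_label, nones]),
        metadata=meta,
    )


def sort_pedigree(ped: Pedigree) -> Pedigree:
    """Topologically sort a complete pedigree so parents precede offspring.

    The sort is stable: among individuals whose order is not constrained by
    parent-offspring links, the input order is preserved.  Rows are renumbered
    1..n and the permutation back to input order is retained in
    ``perm_to_input``.  Raises :class:`CycleError` naming at least one
    individual that is its own ancestor.
    """
    import heapq

    n = ped.n
    sire, dam = ped.sire, ped.dam
    indeg = np.zeros(n, dtype=np.int64)
    children: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p > 0:
                if p == i + 1:
                    raise CycleError([ped.labels[i]])
                indeg[i] += 1
                children[p - 1].append(i)
    ready = [i for i in range(n) if indeg[i] == 0]
    heapq.heapify(ready)
    order: list[int] = []
    while ready:
        i = heapq.heappop(ready)
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(ready, c)
    if len(order) < n:
        # walk parent links among the leftover rows until one repeats
        left = set(range(n)) - set(order)
        i = min(left)
        seen: dict[int, int] = {}
        path = [i]
        while i not in seen:
            seen[i] = len(path) - 1
            i = (sire[i] if sire[i] > 0 and sire[i] - 1 in left else dam[i]) - 1
            path.append(i)
        cycle = path[seen[i]:]
        raise CycleError([ped.labels[j] for j in set(cycle)])
    order_arr = np.asarray(order, dtype=np.int64)
    newpos = np.empty(n, dtype=np.int64)
    newpos[order_arr] = np.arange(n)
    meta = ped.metadata.iloc[order_arr].reset_index(drop=True) if ped.metadata is not None else None
    gen = ped.generation[order_arr] if ped.generation is not None else None
    out = Pedigree(
        ped.labels[order_arr],
        ped.sire_label[order_arr],
        ped.dam_label[order_arr],
        generation=gen,
        metadata=meta,
        sorted=True,
        perm_to_input=order_arr,
    )
    # renumbered index arrays follow directly from the permutation
    out._sire_idx = np.where(sire[order_arr] > 0, newpos[sire[order_arr] - 1] + 1, 0)
    out._dam_idx = np.where(dam[order_arr] > 0, newpos[dam[order_arr] - 1] + 1, 0)
    return out


def assign_generations(ped: Pedigree) -> Pedigree:
    """Count generations forward in time: founders are generation 1, every
    other individual is one more than its highest-generation known parent."""
    ped.require_sorted("assign_generations")
    sire, dam = ped.sire, ped.dam
    gen = np.zeros(ped.n + 1, dtype=np.int64)
    for i in range(1, ped.n + 1):
        g = max(gen[sire[i - 1]], gen[dam[i - 1]])
        gen[i] = g + 1
    out = replace(ped, generation=gen[1:])
    out._sire_idx, out._dam_idx = ped._sire_idx, ped._dam_idx
    return out


@njit(cache=True)
def _ml_inbreeding(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Meuwissen & Luo ancestor-tracing inbreeding kernel.

    ``sire``/``dam`` are length n+1 int64 arrays (entry 0 unused) holding
    1-based parent indices of a sorted pedigree, 0 = unknown. Returns F of
    length n+1 with the F[0] = -1 sentinel for unknown parents, which folds
    the one-parent/no-parent Mendelian variance cases into a single formula
    d_j = 0.5 - 0.25 (F[s_j] + F[d_j]).
    """
    n = sire.shape[0] - 1
    F = np.zeros(n + 1)
    F[0] = -1.0
    L = np.zeros(n + 1)
    inset = np.zeros(n + 1, dtype=np.uint8)
    anc = np.empty(n + 1, dtype=np.int64)
    for i in range(1, n + 1):
        if sire[i] == 0 and dam[i] == 0:
            continue  # founder: F = 0
        # gather the ancestor set of i (including i) by worklist expansion
        top = 0
        anc[top] = i
        top += 1
        inset[i] = 1
        head = 0
        while head < top:
            j = anc[head]
            head += 1
            for p in (sire[j], dam[j]):
                if p > 0 and inset[p] == 0:
                    inset[p] = 1
                    anc[top] = p
                    top += 1
        ids = np.sort(anc[:top])[::-1]  # descending: contributors first
        L[i] = 1.0
        f = -1.0
        for t in range(top):
            j = ids[t]
            lj = L[j]
            dj = 0.5 - 0.25 * (F[sire[j]] + F[dam[j]])
            f += lj * lj * dj
            if sire[j] > 0:
                L[sire[j]] += 0.5 * lj
            if dam[j] > 0:
                L[dam[j]] += 0.5 * lj
        F[i] = f
        for t in range(top):
            L[ids[t]] = 0.0
            inset[ids[t]] = 0
    return F


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Pedigree inbreeding coefficients F (Meuwissen–Luo algorithm).

    F_i is half the additive relationship between i's parents; individuals
    with an unknown parent get F = 0 (unrelated base population). No dense
    matrix is formed; cost is proportional to the summed ancestor-set sizes.
    """
    ped.require_sorted("inbreeding")
    s = np.concatenate([[0], ped.sire]).astype(np.int64)
    d = np.concatenate([[0], ped.dam]).astype(np.int64)
    return _ml_inbreeding(s, d)[1:]


def mendelian_variance(ped: Pedigree, F: np.ndarray) -> np.ndarray:
    """Mendelian sampling variances d_i from parental inbreeding.

    d = 0.5 - 0.25 (F_s + F_d) with both parents known, 0.75 - 0.25 F_p with
    one parent p known, and 1 for founders.
    """
    ped.require_sorted("mendelian_variance")
    F = np.asarray(F, dtype=float)
    Fpad = np.concatenate([[-1.0], F])  # F[0] = -1 folds the unknown cases
    return 0.5 - 0.25 * (Fpad[ped.sire] + Fpad[ped.dam])


@dataclass
class PrecisionCholesky:
    """Sparse lower-triangular Cholesky factor L^-1 of the pedigree precision
    matrix A^-1 = (L^-1)^T (L^-1); at most 3 non-zeros per row."""

    linv: sp.csc_matrix
    labels: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.linv.shape[0]

    @property
    def nnz(self) -> int:
        return self.linv.nnz

    def to_matrix_market(self, path: str | Path) -> None:
        """Write L^-1 in 1-based MatrixMarket coordinate format."""
        scipy.io.mmwrite(str(path), sp.coo_matrix(self.linv))

    @classmethod
    def from_matrix_market(cls, path: str | Path) -> "PrecisionCholesky":
        m = scipy.io.mmread(str(path)).tocsc()
        coo = m.tocoo()
        if np.any(coo.row < coo.col):
            raise PedigreeError("L^-1 must be lower triangular")
        return cls(m)


def build_precision_cholesky(ped: Pedigree, F: np.ndarray | None = None) -> PrecisionCholesky:
    """Build L^-1 directly from a sorted pedigree; A is never formed.

    Row i carries 1/sqrt(d_i) on the diagonal and -0.5/sqrt(d_i) in each known
    parent's column, so nnz = n + 2p + q for p individuals with both and q
    with one known parent.
    """
    ped.require_sorted("build_precision_cholesky")
    if F is None:
        F = inbreeding(ped)
    d = mendelian_variance(ped, F)
    w = 1.0 / np.sqrt(d)
    n = ped.n
    sire, dam = ped.sire, ped.dam
    rows = [np.arange(n)]
    cols = [np.arange(n)]
    vals = [w]
    for par in (sire, dam):
        mask = par > 0
        rows.append(np.nonzero(mask)[0])
        cols.append(par[mask] - 1)
        vals.append(-0.5 * w[mask])
    linv = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsc()
    return PrecisionCholesky(linv, labels=ped.labels)


def dense_A_oracle(ped: Pedigree, max_n: int = 2000) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method (test oracle).

    A_ii = 1 + A(s_i, d_i)/2 and A_ij = (A(j, s_i) + A(j, d_i))/2 for j < i.
    Quadratic in n, so guarded by ``max_n``.
    """
    ped.require_sorted("dense_A_oracle")
    n = ped.n
    if n > max_n:
        raise PedigreeError(f"dense oracle limited to n <= {max_n}, got {n}")
    sire, dam = ped.sire, ped.dam
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i] - 1, dam[i] - 1  # -1 = unknown
        row = np.zeros(i)
        if s >= 0:
            row += A[s, :i]
        if d >= 0:
            row += A[d, :i]
        row *= 0.5
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return A
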