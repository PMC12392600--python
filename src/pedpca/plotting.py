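"""Score plotting with reproducible down-sampling.

Large pedigrees produce millions of score points; plots down-sample to a
seeded random subset (default 10,000) so figures stay fast and reproducible.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .pca import PCAResult

__all__ = ["downsample_indices", "plot_scores"]


def downsample_indices(n: int, limit: int = 10_000, seed: int = 0) -> np.ndarray:
    """Indices of at most ``limit`` individuals out of ``n``.

    The identity when n <= limit; otherwise a uniform random subset without
    replacement, sorted, reproducible from the seed (store it to reuse across
    plots).
    """
    if limit < 1:
        raise ValueError("limit must be >= 1")
    if n <= limit:
        return np.arange(n)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n, size=limit, replace=False))


def _axis_label(res: PCAResult, comp: int) -> str:
    prop = res.proportion
    if prop is not None:
        return f"PC{comp + 1} ({100 * prop[comp]:.1f}%)"
    return f"PC{comp + 1}"


def plot_scores(
    res: PCAResult,
    path: str | Path,
    colour_by: str | None = None,
    metadata=None,
    dims: tuple[int, ...] = (1, 2),
    indices: np.ndarray | None = None,
) -> Path:
    """Scatter the requested score components to a PNG/SVG file.

    ``dims`` are 1-based component indices: two for a single panel, three for
    a 2x2 figure showing the 3D scatter's three pairwise coordinate-plane
    projections plus a legend panel.  ``colour_by`` names a metadata column
    (a pandas DataFrame aligned with the scores).
    """
    dims0 = tuple(d - 1 for d in dims)
    if len(dims0) not in (2, 3):
        raise ValueError("dims must name 2 or 3 components")
    if max(dims0) >= res.k:
        raise ValueError(f"component {max(dims0) + 1} not available (k={res.k})")
    idx = np.arange(res.scores.shape[0]) if indices is None else np.asarray(indices)
    colours, groups = None, None
    if colour_by is not None:
        if metadata is None or colour_by not in metadata.columns:
            avail = [] if metadata is None else list(metadata.columns)
            raise ValueError(
                f"metadata column {colour_by!r} not found; available: {avail}"
            )
        groups = np.asarray(metadata[colour_by])[idx]

    def panel(ax, a, b):
        if groups is None:
            ax.scatter(res.scores[idx, a], res.scores[idx, b], s=4, alpha=0.6)
        else:
            for g in pd_unique(groups):
                m = groups == g
                ax.scatter(res.scores[idx][m, a], res.scores[idx][m, b],
                           s=4, alpha=0.6, label=str(g))
        ax.set_xlabel(_axis_label(res, a))
        ax.set_ylabel(_axis_label(res, b))

    if len(dims0) == 2:
        fig, ax = plt.subplots(figsize=(6, 5))
        panel(ax, *dims0)
        if groups is not None:
            ax.legend(markerscale=3, fontsize=8)
    else:
        a, b, c = dims0
        fig, axes = plt.subplots(2, 2, figsize=(9, 8))
        for ax, (u, v) in zip(axes.flat, [(a, b), (a, c), (b, c)]):
            panel(ax, u, v)
        axes.flat[3].axis("off")
        if groups is not None:
            handles, labels = axes.flat[0].get_legend_handles_labels()
            axes.flat[3].legend(handles, labels, loc="center", markerscale=3)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def pd_unique(values):
    """Unique values in order of first appearance."""
    seen, out = set(), []
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out
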