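"""Cross-sample normalization, transforms, clustering and figures.

Comparisons across samples use within-pathway normalization: each pathway's
abundance in a sample is divided by that pathway's total over all samples, so
rows become fractions summing to 1 and pathway rows of very different
magnitude are displayed on a common scale. Bubble plots use log10 of the
abundance scaled by 10^3, with zeros masked (undetected pathways are drawn as
absent rather than pseudo-counted).
"""

from __future__ import annotations

import logging
import os
import tempfile
import warnings
from pathlib import Path
from typing import Mapping, Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)


def normalize_across_samples(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each pathway row by its sum over samples.

    Nonzero rows become fractions summing to 1; all-zero rows stay all-zero.
    Idempotent on already-normalized rows.
    """
    out = table.astype(float).copy()
    sums = out.sum(axis=1)
    nonzero = sums != 0
    out.loc[nonzero] = out.loc[nonzero].div(sums[nonzero], axis=0)
    return out


def bubble_transform(x) -> np.ma.MaskedArray:
    """log10(x * 10^3) with zeros masked; negative input is an error.

    Strictly increasing on x > 0: 0.001 -> 0.0, 1 -> 3.0.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("abundance must be >= 0")
    masked = np.ma.masked_equal(arr, 0.0)
    with np.errstate(divide="ignore"):
        return np.ma.log10(masked * 1e3)


def cluster_samples(
    table: pd.DataFrame, metric: str = "braycurtis", linkage: str = "average"
) -> tuple[list[str], np.ndarray, list[str]]:
    """Hierarchically cluster samples by their pathway composition.

    Samples (columns) are clustered on Bray–Curtis dissimilarity of their
    pathway vectors with average linkage by default. Input columns are sorted
    by sample id before clustering so the result is independent of input
    order (deterministic tie-break).

    Returns ``(leaf_order, linkage_matrix, labels)`` where ``labels`` is the
    sorted sample list that linkage row indices refer to.
    """
    if table.shape[1] < 2:
        raise ValueError("clustering requires at least 2 samples")
    labels = sorted(table.columns)
    mat = table[labels].to_numpy(dtype=float).T
    dist = pdist(mat, metric=metric)
    if np.any(~np.isfinite(dist)):
        # Bray-Curtis between two all-zero vectors is NaN; identical samples.
        dist = np.nan_to_num(dist, nan=0.0)
    z = hierarchy.linkage(dist, method=linkage)
    order = hierarchy.leaves_list(z)
    return [labels[i] for i in order], z, labels


def _atomic_savefig(fig: plt.Figure, path: Path) -> None:
    """Write the figure to a temp file in the target directory, then rename."""
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=path.suffix)
    os.close(fd)
    try:
        fig.savefig(tmp, format=path.suffix.lstrip("."), bbox_inches="tight")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _figure_paths(path) -> list[Path]:
    """Resolve an output stem or file path into [svg, png] targets."""
    p = Path(path)
    if p.suffix.lower() in {".svg", ".png"}:
        other = ".png" if p.suffix.lower() == ".svg" else ".svg"
        return [p, p.with_suffix(other)]
    return [p.with_suffix(".svg"), p.with_suffix(".png")]


def render_heatmap(table: pd.DataFrame, path) -> list[Path]:
    """Render a pathway × sample heatmap; writes both SVG and PNG.

    Returns the written paths. The input table is not modified.
    """
    if table.empty:
        raise ValueError("cannot render a heatmap of an empty table")
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.6 * table.shape[1] + 3), max(3.0, 0.3 * table.shape[0] + 2))
    )
    sns.heatmap(table, ax=ax, cmap="viridis", cbar_kws={"label": "relative abundance"})
    ax.set_xlabel("sample")
    ax.set_ylabel("pathway")
    targets = _figure_paths(path)
    for t in targets:
        _atomic_savefig(fig, t)
    plt.close(fig)
    return targets


def render_cycle_sketch(
    normalized: pd.DataFrame,
    cycle: str,
    path,
    pathway_cycles: Optional[Mapping[str, str]] = None,
) -> dict[tuple[str, str], float]:
    """Draw per-pathway, per-sample markers whose *area* scales linearly with
    the cross-sample normalized fraction, for one biogeochemical cycle.

    ``pathway_cycles`` maps pathway id → cycle name and selects which rows
    belong to the requested cycle; if omitted, all rows are drawn. Writes SVG
    and PNG; returns the marker geometry as {(pathway, sample): area} in
    point² units so area ratios can be checked without rasterizing.
    """
    if pathway_cycles is not None:
        rows = [p for p in normalized.index if pathway_cycles.get(p) == cycle]
    else:
        rows = list(normalized.index)
    sub = normalized.loc[rows]

    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.6 * normalized.shape[1] + 3), max(2.5, 0.4 * max(len(rows), 1) + 2))
    )
    geometry: dict[tuple[str, str], float] = {}
    if sub.empty:
        warnings.warn(f"no pathways for cycle {cycle!r}; writing an empty figure")
    else:
        max_area = 600.0  # pt^2 for a fraction of 1
        xs, ys, sizes = [], [], []
        for yi, pid in enumerate(sub.index):
            for xi, sample in enumerate(sub.columns):
                frac = float(sub.at[pid, sample])
                area = max_area * frac
                geometry[(pid, sample)] = area
                if frac > 0:
                    xs.append(xi)
                    ys.append(yi)
                    sizes.append(area)
        if xs:
            ax.scatter(xs, ys, s=sizes, alpha=0.8, color="#1f77b4")
        ax.set_xticks(range(len(sub.columns)), sub.columns)
        ax.set_yticks(range(len(sub.index)), sub.index)
        ax.invert_yaxis()
    ax.set_title(f"{cycle} cycle — normalized relative abundance")
    for t in _figure_paths(path):
        _atomic_savefig(fig, t)
    plt.close(fig)
    return geometry
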