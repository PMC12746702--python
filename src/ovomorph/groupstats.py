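"""Group-level comparison of morphological profiles.

A group's *morphological enrichment* is summarized either as its fractional
abundance over the k-means clusters or as a kernel-density map on the 2D
embedding; enrichment similarity between two groups is the Pearson
correlation of those summaries. Centroid-shift analysis measures how far
each reference cell sits from the mean embedding position of a comparison
group (e.g., untreated cells vs the centroid of drug-treated cells).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GroupProfile",
    "CentroidShiftResult",
    "fractional_abundance",
    "enrichment_correlation",
    "kde_enrichment_map",
    "shared_grid",
    "centroid_shift",
    "compare_groups",
]


@dataclass
class GroupProfile:
    """One group's distribution over morphological space."""

    group: str
    fractions: np.ndarray  # length-k abundance over clusters, sums to 1
    n_cells: int
    kde: np.ndarray | None = None  # G x G density grid, integrates to 1
    kde_extent: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.n_cells > 0 and abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {self.fractions.sum()}, not 1")


@dataclass
class CentroidShiftResult:
    """Distances from each reference cell to the target group's centroid."""

    reference: str
    target: str
    target_centroid: np.ndarray
    distances: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.distances.mean())

    @property
    def sd(self) -> float:
        return float(self.distances.std(ddof=1)) if len(self.distances) > 1 else float("nan")


def fractional_abundance(labels: np.ndarray, groups: np.ndarray, k: int | None = None) -> dict[str, GroupProfile]:
    """Per-group fractional abundance over the k clusters (labels in 1..k)."""
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    if len(labels) != len(groups):
        raise ValueError("labels and groups differ in length")
    if len(labels) == 0:
        raise ValueError("empty input: no cells")
    if k is None:
        k = int(labels.max())
    out: dict[str, GroupProfile] = {}
    for g in pd.unique(groups):
        sel = groups == g
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"group '{g}' is empty")
        counts = np.bincount(labels[sel] - 1, minlength=k)[:k]
        out[str(g)] = GroupProfile(group=str(g), fractions=counts / n, n_cells=n)
    return out


def enrichment_correlation(
    profile_a: GroupProfile,
    profile_b: GroupProfile,
    method: str = "cluster_fraction",
) -> float:
    """Pearson correlation of two groups' enrichment summaries.

    ``method="cluster_fraction"`` correlates the abundance vectors;
    ``"kde_grid"`` correlates the flattened density maps (which must share a
    grid). A zero-variance profile yields NaN with a warning.
    """
    if method == "cluster_fraction":
        a, b = profile_a.fractions, profile_b.fractions
        if len(a) != len(b):
            raise ValueError(f"profiles have different k: {len(a)} vs {len(b)}")
    elif method == "kde_grid":
        if profile_a.kde is None or profile_b.kde is None:
            raise ValueError("kde_grid method requires profiles with KDE maps")
        if profile_a.kde.shape != profile_b.kde.shape or profile_a.kde_extent != profile_b.kde_extent:
            raise ValueError("KDE maps are not on a common grid")
        a, b = profile_a.kde.ravel(), profile_b.kde.ravel()
    else:
        raise ValueError(f"unknown enrichment method '{method}'")
    if np.std(a) < 1e-15 or np.std(b) < 1e-15:
        logger.warning("zero-variance enrichment profile: correlation undefined")
        return float("nan")
    if np.array_equal(a, b):
        return 1.0
    return float(stats.pearsonr(a, b)[0])


def shared_grid(points: np.ndarray, grid_size: int = 100, margin: float = 0.05):
    """Common evaluation grid spanning the pooled embedding extent + margin."""
    points = np.asarray(points, dtype=float)
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    pad = margin * (hi - lo)
    lo, hi = lo - pad, hi + pad
    xs = np.linspace(lo[0], hi[0], grid_size)
    ys = np.linspace(lo[1], hi[1], grid_size)
    return xs, ys


def kde_enrichment_map(
    points: np.ndarray,
    grid_size: int = 100,
    bandwidth: str | float = "scott",
    extent: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Gaussian KDE of one group's embedding positions on a fixed grid.

    Returns ``(density, (xs, ys))`` with the density normalized to integrate
    to 1 over the grid (trapezoidal rule), so maps of groups with different
    cell counts are directly comparable. Duplicate positions are collapsed to
    weighted points, so exact duplication of the data leaves the map
    unchanged.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 10:
        raise ValueError("need at least 10 cells for a KDE map")
    if np.allclose(points.std(axis=0), 0.0):
        raise ValueError("degenerate group: all cells at the same position")
    xs, ys = extent if extent is not None else shared_grid(points, grid_size)
    uniq, counts = np.unique(points, axis=0, return_counts=True)
    kde = stats.gaussian_kde(uniq.T, bw_method=bandwidth, weights=counts.astype(float))
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    dens = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(len(xs), len(ys))
    total = np.trapezoid(np.trapezoid(dens, ys, axis=1), xs)
    if total <= 0:
        raise ValueError("KDE normalization failed")
    return dens / total, (xs, ys)


def centroid_shift(
    embedding: np.ndarray,
    reference_idx: np.ndarray,
    target_idx: np.ndarray,
    reference_name: str = "reference",
    target_name: str = "target",
) -> CentroidShiftResult:
    """Distance of each reference cell to the target group's mean position."""
    emb = np.asarray(embedding, dtype=float)
    reference_idx = np.asarray(reference_idx)
    target_idx = np.asarray(target_idx)
    if reference_idx.size == 0:
        raise ValueError("reference set is empty")
    if target_idx.size == 0:
        raise ValueError("target set is empty")
    ref = emb[reference_idx]
    tgt = emb[target_idx]
    centroid = tgt.mean(axis=0)
    d = np.linalg.norm(ref - centroid, axis=1)
    return CentroidShiftResult(
        reference=reference_name, target=target_name, target_centroid=centroid, distances=d
    )


def compare_groups(values_a, values_b, test: str = "welch_t") -> tuple[float, float]:
    """Welch two-sample t-test; returns (statistic, two-sided p).

    Zero variance in both groups with equal means returns (0.0, 1.0) by
    convention.
    """
    if test != "welch_t":
        raise ValueError(f"unknown test '{test}'")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if a.std() < 1e-15 and b.std() < 1e-15:
        if abs(a.mean() - b.mean()) < 1e-15:
            return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
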