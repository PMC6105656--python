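"""Area-scan imaging analytics: sum-filter chemical images, L1 (Manhattan)
k-medians segmentation, cluster spectra, and line-vs-area equivalence.

Segmentation follows the "Manhattan analysis with derivative pre-mode"
approach: each pixel spectrum is converted to a smoothed first derivative
and vector-normalized, then clustered by L1 distance with coordinate-wise
median centroid updates (the L1-optimal centroid).  Cluster labels are
1-based and renumbered by descending cluster size, so the largest cluster
(typically the off-cell background) is always cluster 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .preprocess import PreprocessRecipe, Step, apply_recipe
from .spectral_data import (
    HyperspectralMap,
    RangeError,
    SpectralDataError,
    SpectralDataset,
    Spectrum,
    StructuralError,
)
from .preprocess import normalize_area

__all__ = [
    "ClusterResult",
    "SumFilterImage",
    "DEFAULT_PREMODE",
    "sum_filter",
    "kmeans_manhattan",
    "subtract_background_cluster",
    "line_scan_average",
    "compare_line_vs_area",
    "adjusted_rand_index",
]

#: Default clustering pre-mode: smoothed first derivative (suppresses the
#: slowly varying baseline while keeping band intensities comparable
#: across pixels; no per-pixel normalization, which would inflate the
#: noise of empty background pixels to unit scale).
DEFAULT_PREMODE = PreprocessRecipe(
    (Step("derivative", {"order": 1, "width": 9, "polyorder": 3}),)
)


@dataclass(frozen=True)
class SumFilterImage:
    """Per-pixel band integral over [lo, hi] cm^-1."""

    grid_shape: tuple[int, int]
    values: np.ndarray  # flattened, one per pixel
    band: tuple[float, float]

    def image(self) -> np.ndarray:
        return self.values.reshape(self.grid_shape)


@dataclass(frozen=True)
class ClusterResult:
    """K-medians segmentation of a hyperspectral map.

    ``pixel_labels`` are 1-based, renumbered by descending cluster size;
    ``cluster_spectra`` holds each cluster's mean raw spectrum on the map
    axis; ``objective`` is the total within-cluster L1 distance in the
    preprocessed feature space.
    """

    k: int
    pixel_labels: np.ndarray
    cluster_spectra: np.ndarray
    objective: float


def sum_filter(m: HyperspectralMap, lo: float, hi: float) -> SumFilterImage:
    """Trapezoidal band integral per pixel (a chemical image).

    Integration runs over the grid points with lo <= nu <= hi, so filters
    over adjacent bands sharing a grid-point endpoint add up to the filter
    over the union.
    """
    if lo >= hi:
        raise RangeError(f"invalid band: lo={lo} >= hi={hi}")
    mask = m.axis.window_mask(lo, hi)
    if mask.sum() < 2:
        raise RangeError(f"band [{lo}, {hi}] covers fewer than 2 grid points")
    vals = np.trapezoid(m.cube[:, mask], m.axis.values[mask], axis=1)
    return SumFilterImage(m.grid_shape, vals, (float(lo), float(hi)))


def _l1_seed(
    X: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Squared-distance-weighted (k-means++-style) seeding under L1 distance.

    Squared weighting strongly favours small, chemically distinct regions
    (e.g. a few lipid-droplet pixels) that linear weighting rarely seeds.
    """
    n = X.shape[0]
    centers = [X[rng.integers(n)]]
    for _ in range(1, k):
        d = cdist(X, np.vstack(centers), metric="cityblock").min(axis=1) ** 2
        total = d.sum()
        if total == 0:
            centers.append(X[rng.integers(n)])
            continue
        centers.append(X[rng.choice(n, p=d / total)])
    return np.vstack(centers)


def _kmedians_once(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, float]:
    centers = _l1_seed(X, k, rng)
    labels = np.zeros(X.shape[0], dtype=int)
    prev_obj = np.inf
    for _ in range(max_iter):
        d = cdist(X, centers, metric="cityblock")
        labels = np.argmin(d, axis=1)  # ties -> lowest cluster index
        obj = float(d[np.arange(X.shape[0]), labels].sum())
        # median update can only lower the within-cluster L1 cost
        assert obj <= prev_obj + 1e-9 * max(1.0, abs(prev_obj)), "objective increased"
        for j in range(k):
            members = X[labels == j]
            if members.size == 0:
                # re-seed empty cluster at the worst-served point
                worst = int(np.argmax(d[np.arange(X.shape[0]), labels]))
                centers[j] = X[worst]
            else:
                centers[j] = np.median(members, axis=0)
        if prev_obj - obj < 1e-12 * max(1.0, abs(prev_obj)):
            prev_obj = obj
            break
        prev_obj = obj
    d = cdist(X, centers, metric="cityblock")
    labels = np.argmin(d, axis=1)
    # every cluster must be non-empty: hand each empty cluster the point
    # currently worst-served (never raises the total objective)
    for j in range(k):
        if not np.any(labels == j):
            dist_own = d[np.arange(X.shape[0]), labels]
            movable = np.flatnonzero(np.bincount(labels, minlength=k)[labels] > 1)
            donor = movable[np.argmax(dist_own[movable])]
            labels[donor] = j
            centers[j] = X[donor]
            d[:, j] = cdist(X, centers[j : j + 1], metric="cityblock")[:, 0]
    obj = float(d[np.arange(X.shape[0]), labels].sum())
    return labels, centers, obj


def kmeans_manhattan(
    m: HyperspectralMap,
    k: int,
    premode: PreprocessRecipe | None = None,
    n_restarts: int = 10,
    seed: int = 0,
) -> ClusterResult:
    """L1-distance k-medians segmentation of an area scan.

    Pixels are preprocessed by ``premode`` (default: smoothed first
    derivative + vector normalization), clustered by Manhattan distance
    with median centroid updates, and the best of ``n_restarts`` seeded
    initializations is kept.
    """
    if k < 1:
        raise SpectralDataError("k must be >= 1")
    if k > m.n_pixels:
        raise SpectralDataError(f"k={k} exceeds pixel count {m.n_pixels}")
    if premode is None:
        premode = DEFAULT_PREMODE
    import pandas as pd

    d = SpectralDataset(m.axis, m.cube, pd.DataFrame(index=range(m.n_pixels)))
    X = apply_recipe(d, premode).matrix

    best: tuple[np.ndarray, float] | None = None
    streams = np.random.SeedSequence(seed).spawn(n_restarts)
    for ss in streams:
        labels, _, obj = _kmedians_once(X, k, np.random.default_rng(ss))
        if best is None or obj < best[1]:
            best = (labels, obj)
    labels, obj = best

    # renumber by descending cluster size, 1-based
    sizes = np.bincount(labels, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    labels = remap[labels]
    spectra = np.vstack(
        [m.cube[labels == j].mean(axis=0) for j in range(1, k + 1)]
    )
    return ClusterResult(k, labels, spectra, obj)


def subtract_background_cluster(
    c: ClusterResult, m: HyperspectralMap, bg_label: int = 1
) -> dict[int, np.ndarray]:
    """Each non-background cluster's mean raw spectrum minus the background's.

    Removes the substrate/media contribution from cell-region cluster
    spectra, assuming the background cluster sees substrate only.
    """
    if bg_label not in range(1, c.k + 1) or not np.any(c.pixel_labels == bg_label):
        raise SpectralDataError(f"background label {bg_label} not present")
    bg = c.cluster_spectra[bg_label - 1]
    return {
        j: c.cluster_spectra[j - 1] - bg
        for j in range(1, c.k + 1)
        if j != bg_label
    }


def line_scan_average(d: SpectralDataset, cell_id: str) -> Spectrum:
    """Pointwise mean of one cell's line-scan point spectra."""
    mask = (d.meta["cell_id"] == cell_id).to_numpy()
    if not mask.any():
        raise SpectralDataError(f"unknown cell_id {cell_id!r}")
    row = d.meta.loc[mask].iloc[0]
    from .spectral_data import SpectrumMeta

    return Spectrum(
        d.axis,
        d.matrix[mask].mean(axis=0),
        SpectrumMeta(cell_line=str(row["cell_line"]), cell_id=str(cell_id)),
    )


def compare_line_vs_area(
    line_avg: Spectrum, area_avg: Spectrum
) -> tuple[Spectrum, float]:
    """Difference of area-normalized line and area average spectra.

    Both inputs are normalized to unit area under the curve before
    differencing, so a pure intensity scale difference vanishes.  Returns
    the difference spectrum and its maximum absolute value.
    """
    if line_avg.axis != area_avg.axis:
        raise StructuralError("line and area spectra are on different axes")
    a = normalize_area(line_avg)
    b = normalize_area(area_avg)
    diff = a.intensities - b.intensities
    return Spectrum(line_avg.axis, diff), float(np.max(np.abs(diff)))


def adjusted_rand_index(a: np.ndarray, b: np.ndarray) -> float:
    """Chance-adjusted agreement between two labelings of the same items.

    Closed form over the contingency table; 1 for identical partitions
    (up to relabeling), ~0 for independent ones.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("labelings must have equal length")
    n = a.size
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(table, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
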