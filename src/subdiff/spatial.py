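"""Point-pattern analyses for super-resolution localization data.

Box-counting fractal dimension of the occupied membrane structure,
distance-threshold (single-linkage) clustering of localized molecules with a
matched Poisson null, radial density of mobility-state subpopulations, montage
alignment of many cells, and segment fluorescence intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = [
    "FractalFit", "ClusterSet", "box_counting_dimension", "cluster_localizations",
    "cluster_size_distribution", "radial_density", "align_montage",
    "segment_intensity", "default_box_scales",
]


@dataclass
class FractalFit:
    d_f: float
    scales: np.ndarray          # box side lengths used for the fit
    counts: np.ndarray          # occupied boxes per scale
    fit_range: tuple[float, float]
    residual: float
    stderr: float


@dataclass
class ClusterSet:
    labels: np.ndarray          # cluster index per point
    sizes: np.ndarray           # points per cluster
    threshold: float

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def default_box_scales(lo: float = 10.0, hi: float = 1000.0) -> np.ndarray:
    """Geometric ladder of box sizes, factor sqrt(2), spanning [lo, hi] nm."""
    n = int(np.floor(np.log(hi / lo) / np.log(np.sqrt(2.0))))
    return lo * np.sqrt(2.0) ** np.arange(n + 1)


def box_counting_dimension(points: np.ndarray,
                           scales: np.ndarray | None = None,
                           fit_range: tuple[float, float] = (10.0, 1000.0),
                           n_origins: int = 1) -> FractalFit:
    """Box-counting (Minkowski) dimension of a planar point set.

    Boxes of side s on a grid anchored at the data bounding-box corner are
    counted when occupied; d_f is the slope of log(count) vs log(1/s) over
    ``fit_range``.  ``n_origins`` > 1 averages counts over shifted grid
    origins to reduce grid artifacts.  A degenerate (single-location) set
    returns d_f = 0 with a warning.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if len(pts) < 2 or np.allclose(pts, pts[0]):
        warnings.warn("degenerate point set; d_f = 0")
        return FractalFit(0.0, np.empty(0), np.empty(0), fit_range, np.nan, np.nan)
    if scales is None:
        scales = default_box_scales(*fit_range)
    origin = pts.min(axis=0)
    counts = np.empty(len(scales))
    for i, s in enumerate(scales):
        c = 0.0
        for j in range(n_origins):
            shift = origin - (j / max(n_origins, 1)) * s
            idx = np.floor((pts - shift) / s).astype(np.int64)
            c += len(np.unique(idx, axis=0))
        counts[i] = c / max(n_origins, 1)
    lo, hi = fit_range
    sel = (scales >= lo) & (scales <= hi) & (counts > 0)
    if sel.sum() < 2:
        raise ValueError("need at least 2 scales inside fit_range")
    x = np.log(1.0 / scales[sel])
    y = np.log(counts[sel])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    dof = max(sel.sum() - 2, 1)
    sxx = ((x - x.mean()) ** 2).sum()
    stderr = float(np.sqrt((resid ** 2).sum() / dof / sxx))
    return FractalFit(d_f=float(slope), scales=scales[sel], counts=counts[sel],
                      fit_range=fit_range, residual=float(np.sqrt((resid ** 2).mean())),
                      stderr=stderr)


def cluster_localizations(points: np.ndarray, threshold: float = 40.0) -> ClusterSet:
    """Single-linkage clustering: points closer than ``threshold`` share a cluster.

    The assignment is the transitive closure of the <=-threshold neighbour
    relation (order-independent); every point belongs to exactly one cluster.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n == 0:
        return ClusterSet(np.empty(0, int), np.empty(0, int), threshold)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=threshold, output_type="ndarray")
    if len(pairs):
        graph = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                           shape=(n, n))
    else:
        graph = coo_matrix((n, n))
    n_comp, labels = connected_components(graph, directed=False)
    # renumber clusters by first occurrence for a deterministic, order-stable labelling
    first = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in first:
            first[lab] = len(first)
        out[i] = first[lab]
    sizes = np.bincount(out, minlength=len(first))
    return ClusterSet(labels=out, sizes=sizes, threshold=threshold)


def cluster_size_distribution(clusters: ClusterSet, null_points: np.ndarray,
                              bins: np.ndarray | None = None):
    """Cluster-size histograms of the data and of a matched Poisson null.

    ``null_points`` is a random scatter with the same point count and area;
    it is clustered with the same threshold.  Returns (bins, data_counts,
    null_counts) with logarithmic size bins.
    """
    null = cluster_localizations(np.asarray(null_points, float), clusters.threshold)
    top = max(clusters.sizes.max(initial=1), null.sizes.max(initial=1))
    if bins is None:
        edges = np.unique(np.round(np.geomspace(1, top + 1, 20)).astype(int))
        bins = np.concatenate([edges, [top + 1]]) - 0.5
        bins = np.unique(bins)
    data_h, _ = np.histogram(clusters.sizes, bins=bins)
    null_h, _ = np.histogram(null.sizes, bins=bins)
    return bins, data_h, null_h


def radial_density(points_by_state: dict[int, np.ndarray],
                   center: np.ndarray | None = None,
                   bin_width: float = 250.0):
    """Annulus-corrected radial density per mobility state.

    ``points_by_state`` maps state label to an (n, 2) array of segment
    localizations.  The center defaults to the center of mass of all points.
    Each state's density is normalised to integrate to 1 over radius
    (sum density * bin_width = 1); empty states yield empty curves.
    """
    all_pts = [p for p in points_by_state.values() if len(p)]
    if not all_pts:
        raise ValueError("no points given")
    pooled = np.concatenate(all_pts)
    if center is None:
        center = pooled.mean(axis=0)
    rmax = np.hypot(*(pooled - center).T).max()
    nbin = max(int(np.ceil(rmax / bin_width)), 1)
    edges = np.arange(nbin + 1) * bin_width
    area = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    out = {}
    for state, pts in points_by_state.items():
        if len(pts) == 0:
            out[state] = (edges, np.empty(0))
            continue
        r = np.hypot(*(np.asarray(pts, float) - center).T)
        counts, _ = np.histogram(r, bins=edges)
        dens = counts / area
        total = (dens * bin_width).sum()
        if total > 0:
            dens = dens / total
        out[state] = (edges, dens)
    return out


def align_montage(cells: list[np.ndarray]) -> np.ndarray:
    """Pool point sets from many cells after centering each at its center of mass."""
    if not cells:
        raise ValueError("need at least one cell")
    shifted = []
    for pts in cells:
        pts = np.asarray(pts, dtype=float)
        if len(pts) == 0:
            continue
        shifted.append(pts - pts.mean(axis=0))
    return np.concatenate(shifted) if shifted else np.empty((0, 2))


def segment_intensity(segment) -> float:
    """Mean fluorescence intensity over the first min(10, length) points.

    Uses the earliest points of the segment to minimise photobleaching bias.
    """
    traj = segment.trajectory if hasattr(segment, "trajectory") else segment
    vals = traj.intensity[:10]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("segment has no intensity values")
    return float(vals.mean())
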