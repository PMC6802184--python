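"""Intrinsic dimension and radius-stable topology of the embedded cloud.

The dimension estimate is the classical correlation-dimension slope: the
average number of neighbors within a sphere grows as r^d on a manifold of
dimension d, so the log-log slope of mean cumulative neighbor count against
radius estimates d.  Topology is estimated by Vietoris-Rips persistence on a
representative landmark set (K-means centroids, sparse clusters discarded),
reading off the Betti vector (components, holes, enclosed voids) that stays
constant over the widest range of filtration radii.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from ._rips import betti_curves, rips_persistence
from ._utils import pairwise_distances
from .containers import BettiResult, DimensionEstimate, Embedding


def _coords(points) -> np.ndarray:
    if isinstance(points, Embedding):
        return points.coords
    return np.asarray(points, dtype=float)


def estimate_intrinsic_dimension(coords, n_radii: int = 32,
                                 count_window: tuple = (10.0, 0.5),
                                 fit_points: int = 10,
                                 max_centers: int = 2000, seed: int = 0) -> DimensionEstimate:
    """Correlation-dimension slope of the point cloud.

    Cumulative neighbor counts are averaged over up to ``max_centers``
    reference points.  Candidate radii are restricted to mean counts between
    ``count_window[0]`` (above the noise floor) and ``count_window[1] * n``
    (below saturation); within those bounds the slope is read from the most
    linear window of ``fit_points`` consecutive grid points on the log-log
    curve — the scaling regime of the manifold, between the small-radius
    noise thickness and the large-radius curvature/saturation roll-offs.
    The radius grid derives from the data's own distance scales, so the
    slope is invariant to global rescaling.
    """
    pts = _coords(coords)
    n = pts.shape[0]
    if n < 50:
        raise ValueError("need at least 50 points for a dimension estimate")
    if n > max_centers:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        centers = pts[rng.choice(n, max_centers, replace=False)]
    else:
        centers = pts
    tree = cKDTree(pts)
    d_nn, _ = tree.query(centers, k=2)
    r_lo = np.median(d_nn[:, 1])
    if not np.isfinite(r_lo) or r_lo == 0:
        # degenerate cloud: all points identical (or nearly so)
        return DimensionEstimate(radii=np.empty(0), mean_counts=np.empty(0),
                                 slope=np.nan, fit_window=(np.nan, np.nan), degenerate=True)
    spread = pts.max(axis=0) - pts.min(axis=0)
    r_hi = float(np.linalg.norm(spread))
    radii = np.geomspace(0.5 * r_lo, r_hi, n_radii)
    counts = np.empty((len(radii), len(centers)))
    for i, r in enumerate(radii):
        counts[i] = tree.query_ball_point(centers, r, return_length=True) - 1  # exclude self
    mean_counts = counts.mean(axis=1)

    lo, hi_frac = count_window
    idx = np.flatnonzero((mean_counts >= lo) & (mean_counts <= hi_frac * n))
    if idx.size < 3:  # fall back to the middle of the grid
        idx = np.arange(n_radii // 4, 3 * n_radii // 4)
    x = np.log(radii[idx])
    y = np.log(np.maximum(mean_counts[idx], 1e-12))
    w = min(fit_points, len(idx))
    best = None
    for start in range(len(idx) - w + 1):
        xs, ys = x[start:start + w], y[start:start + w]
        coef = np.polyfit(xs, ys, 1)
        resid = float(np.sqrt(np.mean((ys - np.polyval(coef, xs)) ** 2)))
        if best is None or resid < best[0]:
            best = (resid, float(coef[0]), start)
    _, slope, start = best
    fit_window = (float(radii[idx[start]]), float(radii[idx[start + w - 1]]))
    return DimensionEstimate(radii=radii, mean_counts=mean_counts, slope=slope,
                             fit_window=fit_window)


def _widest_plateau(bc: np.ndarray, radii: np.ndarray, stable_frac: float):
    """Widest run of a constant Betti vector; must span >= stable_frac of the range."""
    n = bc.shape[1]
    runs = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and np.array_equal(bc[:, j + 1], bc[:, i]):
            j += 1
        runs.append((radii[j] - radii[i], i, j))
        i = j + 1
    span = radii[-1] - radii[0]
    eligible = [r for r in runs if r[0] >= stable_frac * span]
    pool = eligible if eligible else runs
    width, i, j = max(pool, key=lambda r: (r[0], -r[1]))
    return tuple(int(v) for v in bc[:, i]), (float(radii[i]), float(radii[j]))


def persistent_betti(coords, k_landmarks: int = 70, min_cluster: int = 50,
                     n_radii: int = 128, stable_frac: float = 0.25,
                     r_max: float | None = None, seed: int = 0) -> BettiResult:
    """Radius-stable Betti numbers (beta_0, beta_1, beta_2) of the point cloud.

    Landmarks are the centroids of a seeded K-means (default K = 70, 10
    restarts, best inertia) after discarding clusters with fewer than
    ``min_cluster`` members — sparse clusters are dominated by noise.  A
    result computed from fewer than 50 surviving landmarks is flagged
    ``low_confidence``.  ``r_max`` defaults to the 99th percentile of
    pairwise landmark distances; a Betti vector must persist over at least
    ``stable_frac`` of [0, r_max] to qualify as a plateau, and the widest
    plateau wins.
    """
    pts = _coords(coords)
    n = pts.shape[0]
    if n < k_landmarks:
        raise ValueError(f"need at least k_landmarks={k_landmarks} points, got {n}")
    km = KMeans(n_clusters=k_landmarks, n_init=10, random_state=seed)
    labels = km.fit_predict(pts)
    sizes = np.bincount(labels, minlength=k_landmarks)
    landmarks = km.cluster_centers_[sizes >= min_cluster]
    low_confidence = len(landmarks) < 50
    if len(landmarks) < 2:
        raise ValueError("fewer than 2 surviving landmarks; decrease min_cluster")

    dist = pairwise_distances(landmarks)
    if r_max is None:
        r_max = float(np.percentile(dist[np.triu_indices(len(landmarks), 1)], 99))
    intervals = rips_persistence(dist, r_max)
    radii = np.linspace(0.0, r_max, n_radii)
    bc = betti_curves(intervals, radii)
    stable, plateau = _widest_plateau(bc, radii, stable_frac)
    return BettiResult(radii=radii, betti_curves=bc, stable_betti=stable, plateau=plateau,
                       landmarks=landmarks, low_confidence=low_confidence,
                       intervals=intervals)
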