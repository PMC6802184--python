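"""Shared numerical helpers: seeding, kernels, circular statistics."""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Split one session seed into ``n`` independent generators.

    All randomness in the package flows from a single integer seed through
    ``numpy.random.SeedSequence.spawn``, so any sub-stream can be reproduced
    from the session seed alone.
    """
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def truncated_gaussian_kernel(sigma: float, size: int) -> np.ndarray:
    """Truncated Gaussian kernel of odd ``size`` taps, normalized to sum 1."""
    if size % 2 != 1:
        raise ValueError("kernel size must be odd")
    half = size // 2
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def smooth_1d(values: np.ndarray, sigma: float, size: int, circular: bool = False) -> np.ndarray:
    """Convolve with a truncated Gaussian; edges are renormalized (linear mode)."""
    k = truncated_gaussian_kernel(sigma, size)
    v = np.asarray(values, dtype=float)
    if circular:
        pad = size // 2
        vp = np.concatenate([v[-pad:], v, v[:pad]])
        return np.convolve(vp, k, mode="valid")
    # renormalize by the kernel mass actually inside the support
    ones = np.ones_like(v)
    num = np.convolve(v, k, mode="same")
    den = np.convolve(ones, k, mode="same")
    return num / den


def smooth_angle_series(theta: np.ndarray, sigma: float, size: int) -> np.ndarray:
    """Temporally smooth an angle series via its unit vectors (avoids wrap artifacts)."""
    c = smooth_1d(np.cos(theta), sigma, size)
    s = smooth_1d(np.sin(theta), sigma, size)
    return np.mod(np.arctan2(s, c), TWO_PI)


def circ_diff(a: np.ndarray | float, b: np.ndarray | float) -> np.ndarray:
    """Signed circular difference a - b mapped to (-pi, pi]."""
    return np.pi - np.mod(np.pi - (np.asarray(a) - np.asarray(b)), TWO_PI)


def circ_corr(a: np.ndarray, b: np.ndarray, max_points: int = 2000) -> float:
    """Fisher-Lee circular correlation (pairwise T-linear form).

    rho = sum_{i<j} sin(a_i - a_j) sin(b_i - b_j), normalized — well defined
    even for uniformly distributed angles, where mean-centered variants
    degenerate.  Long series are deterministically strided down to bound the
    O(n^2) pair sums.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) > max_points:
        step = int(np.ceil(len(a) / max_points))
        a, b = a[::step], b[::step]
    sa = np.sin(a[:, None] - a[None, :])
    sb = np.sin(b[:, None] - b[None, :])
    denom = np.sqrt((sa**2).sum() * (sb**2).sum())
    if denom == 0:
        return 0.0
    return float((sa * sb).sum() / denom)


def stable_knn(points: np.ndarray, k: int, chunk: int = 512) -> np.ndarray:
    """Indices of the k nearest neighbors (self excluded) per point.

    Brute force Euclidean with a stable argsort, so distance ties are always
    broken by the lowest point index — required for deterministic graphs on
    binary data where ties are common.  Chunked over query points to bound
    memory at large n.
    """
    pts = np.asarray(points, dtype=np.float32)
    n = pts.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < n={n}")
    sq = (pts**2).sum(axis=1)
    out = np.empty((n, k), dtype=np.int64)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * (pts[start:stop] @ pts.T)
        rows = np.arange(start, stop)
        d2[np.arange(stop - start), rows] = np.inf  # exclude self
        # round-off can make exact ties differ in the last ulp; snap tiny
        # differences so the stable sort sees true ties
        np.maximum(d2, 0.0, out=d2)
        order = np.argsort(d2, axis=1, kind="stable")
        out[start:stop] = order[:, :k]
    return out


def pairwise_distances(points: np.ndarray) -> np.ndarray:
    """Dense Euclidean distance matrix (float64) for small point sets."""
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(np.asarray(points, dtype=float)))


def weighted_std(values: np.ndarray, weights: np.ndarray) -> float:
    w = np.asarray(weights, float)
    v = np.asarray(values, float)
    tot = w.sum()
    if tot <= 0:
        return 0.0
    mu = (w * v).sum() / tot
    return float(np.sqrt((w * (v - mu) ** 2).sum() / tot))
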