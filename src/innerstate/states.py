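"""Network states: clustering, temporal segmentation, subtypes, ordering.

A network state is a dense cluster of population activity vectors in the
embedded space.  Topological clustering treats dense clusters as components
of the neighborhood graph: the radius that captures the maximal number of
stable large components defines the clusters, and stragglers are attached to
the cluster of their nearest assigned neighbor.  Temporal segmentation turns
per-frame labels into contiguous visits; per-state PCA of segment-averaged
activity exposes hidden subtypes (e.g. the two running directions sharing
one cluster); the empirical transition matrix and the permutation search of
Eq.-style ordering recover the linear or cyclic arrangement of states.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .containers import ActivityMatrix, Embedding, Segment, StateModel

MAX_ORDERABLE_STATES = 10


# ---------------------------------------------------------------------------
# single-linkage scaffold
# ---------------------------------------------------------------------------

def _mst_edges(points: np.ndarray, k: int = 15) -> np.ndarray:
    """(i, j, dist) rows of a Euclidean MST, ascending by length.

    Built from a kNN graph (bridged between components if needed), which is
    exact whenever the kNN graph is connected and a tight approximation
    otherwise; single-linkage merges are read directly off the sorted edges.
    """
    from ._utils import stable_knn

    n = len(points)
    k = min(k, n - 1)
    nbrs = stable_knn(points, k)
    rows = np.repeat(np.arange(n), k)
    cols = nbrs.ravel()
    d = np.linalg.norm(points[rows] - points[cols], axis=1)
    g = sp.coo_matrix((d + 1e-300, (rows, cols)), shape=(n, n)).tocsr()
    g = g.maximum(g.T)
    n_comp, comp = connected_components(g, directed=False)
    bridges = []
    while n_comp > 1:
        # bridge the smallest component to its nearest outside neighbor
        sizes = np.bincount(comp).astype(float)
        sizes[sizes == 0] = np.inf  # ids emptied by earlier relabeling
        c = np.argmin(sizes)
        inside = np.flatnonzero(comp == c)
        outside = np.flatnonzero(comp != c)
        tree = cKDTree(points[outside])
        dd, jj = tree.query(points[inside])
        a = np.argmin(dd)
        i, j = inside[a], outside[jj[a]]
        bridges.append((i, j, dd[a]))
        comp[comp == c] = comp[j]
        n_comp -= 1
    mst = minimum_spanning_tree(g).tocoo()
    ii = np.concatenate([mst.row, [b[0] for b in bridges]]).astype(np.int64)
    jj = np.concatenate([mst.col, [b[1] for b in bridges]]).astype(np.int64)
    dd = np.concatenate([mst.data, [b[2] for b in bridges]])
    order = np.argsort(dd, kind="stable")
    return np.c_[ii[order], jj[order], dd[order]]


class _SizedUnionFind:
    def __init__(self, n):
        self.parent = np.arange(n)
        self.size = np.ones(n, dtype=np.int64)

    def find(self, x):
        root = x
        p = self.parent
        while p[root] != root:
            root = p[root]
        while p[x] != root:
            p[x], x = root, p[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return None
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]
        return ra


def _large_component_curve(edges, n, min_points, radii):
    """Count of components with >= min_points members (and their total
    membership) at each radius."""
    uf = _SizedUnionFind(n)
    large = int(n) if min_points <= 1 else 0
    members = int(n) if min_points <= 1 else 0
    counts = np.empty(len(radii), dtype=np.int64)
    mem = np.empty(len(radii), dtype=np.int64)
    e = 0
    for gi, r in enumerate(radii):
        while e < len(edges) and edges[e, 2] <= r:
            i, j = int(edges[e, 0]), int(edges[e, 1])
            sa, sb = int(uf.size[uf.find(i)]), int(uf.size[uf.find(j)])
            root = uf.union(i, j)
            if root is not None:
                la, lb, lab = sa >= min_points, sb >= min_points, sa + sb >= min_points
                large += int(lab) - int(la) - int(lb)
                members += (sa + sb if lab else 0) - (sa if la else 0) - (sb if lb else 0)
            e += 1
        counts[gi] = large
        mem[gi] = members
    return counts, mem


def _pick_stable_radius(curve, radii, stable_frac, membership=None, mem_tol=1.0):
    """Radius capturing the maximal number of stable large components.

    A run of constant component count qualifies as stable when it spans at
    least ``stable_frac`` of the radius range and, if ``membership`` is
    given, the points held by large components grow by less than ``mem_tol``
    (relative; default: membership may at most double) across it — a cloud
    whose "clusters" keep swallowing points as the radius grows has no
    genuine multi-cluster structure.  Returns
    ``(radius, count)``; count 0 signals that no stable clustering exists.
    """
    runs = []
    i = 0
    n = len(radii)
    while i < n:
        j = i
        while j + 1 < n and curve[j + 1] == curve[i]:
            j += 1
        runs.append((curve[i], radii[j] - radii[i], i, j))
        i = j + 1
    span = radii[-1] - radii[0]
    eligible = [r for r in runs if r[1] >= stable_frac * span and r[0] > 0]
    if membership is not None:
        # the growth gate applies to multi-cluster plateaus only: a single
        # component legitimately swells from min_points to the whole cloud
        # when the data is one dense blob
        eligible = [r for r in eligible
                    if r[0] == 1 or membership[r[3]] <= (1.0 + mem_tol) * max(membership[r[2]], 1)]
    if not eligible:
        return float(radii[0]), 0
    count, _, i, j = max(eligible, key=lambda r: (r[0], r[1], -r[2]))
    return float(0.5 * (radii[i] + radii[j])), int(count)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_states(e, mode: str = "topological", min_points: int = 250, k: int = 8,
                   seed: int = 0, stable_frac: float = 0.05, n_radii: int = 1024) -> StateModel:
    """Cluster embedded frames into network states.

    ``topological`` mode picks the neighborhood radius that captures the
    maximal stable number of components with at least ``min_points``
    members (250 for clustering, 50 for sub-clustering by convention); the
    remaining points are attached to the cluster of their nearest assigned
    neighbor.  A component count qualifies as stable when it persists over
    at least ``stable_frac`` of the radius range; among stable counts the
    maximum wins — the count is the objective, the stability requirement
    only guards against split/merge noise.  ``kmeans`` mode runs a seeded
    K-means with fixed K (default 8, the ephys convention).  Cluster ids are
    ordered by first frame of occurrence for determinism.
    """
    if isinstance(e, Embedding):
        pts, frame_index = e.coords, e.frame_index
    else:
        pts = np.asarray(e, dtype=float)
        frame_index = np.arange(len(pts))
    if len(pts) == 0:
        raise ValueError("empty embedding")

    if mode == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        raw = km.fit_predict(pts)
        labels = _relabel_by_first_occurrence(raw)
        return StateModel(labels=labels, frame_index=frame_index,
                          n_states=int(labels.max()) + 1,
                          centroids=_centroids(pts, labels))
    if mode != "topological":
        raise ValueError(f"unknown clustering mode {mode!r}")

    edges = _mst_edges(pts)
    positive = edges[edges[:, 2] > 0, 2]
    if positive.size == 0:
        return StateModel(labels=np.zeros(len(pts), dtype=np.int64), frame_index=frame_index,
                          n_states=1, centroids=_centroids(pts, np.zeros(len(pts), int)))
    # geometric radius grid: plateau stability is judged on a log scale, so
    # a few outlying long MST edges cannot drown the cluster-scale plateaus
    radii = np.geomspace(np.percentile(positive, 1), edges[-1, 2], n_radii)
    curve, membership = _large_component_curve(edges, len(pts), min_points, radii)
    if curve.max() == 0:
        return StateModel(labels=np.full(len(pts), -1), frame_index=frame_index, n_states=0)
    log_radius, count = _pick_stable_radius(curve, np.log(radii), stable_frac,
                                            membership=membership)
    if count == 0:
        return StateModel(labels=np.full(len(pts), -1), frame_index=frame_index, n_states=0)
    radius = float(np.exp(log_radius))

    uf = _SizedUnionFind(len(pts))
    for i, j, d in edges:
        if d > radius:
            break
        uf.union(int(i), int(j))
    roots = np.array([uf.find(i) for i in range(len(pts))])
    labels = np.full(len(pts), -1, dtype=np.int64)
    for r in np.unique(roots):
        members = np.flatnonzero(roots == r)
        if len(members) >= min_points:
            labels[members] = r  # temporary id, relabeled below
    assigned = labels >= 0
    if assigned.any() and (~assigned).any():
        # attach stragglers to the cluster of their nearest assigned neighbor
        tree = cKDTree(pts[assigned])
        _, nearest = tree.query(pts[~assigned])
        labels[~assigned] = labels[assigned][nearest]
    labels = _relabel_by_first_occurrence(labels)
    return StateModel(labels=labels, frame_index=frame_index,
                      n_states=int(labels.max()) + 1 if assigned.any() else 0,
                      centroids=_centroids(pts, labels))


def _relabel_by_first_occurrence(labels: np.ndarray) -> np.ndarray:
    out = np.full(len(labels), -1, dtype=np.int64)
    nxt = 0
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab < 0:
            continue
        if lab not in mapping:
            mapping[lab] = nxt
            nxt += 1
        out[i] = mapping[lab]
    return out


def _centroids(pts: np.ndarray, labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels[labels >= 0])
    return np.vstack([pts[labels == s].mean(axis=0) for s in ids]) if len(ids) else \
        np.empty((0, pts.shape[1]))


class StateClusterer(BaseEstimator, ClusterMixin):
    """sklearn-style wrapper over :func:`cluster_states`.

    Attributes after ``fit``: ``labels_`` (per-point state id, -1 for none
    when no component is large enough), ``model_`` (the full
    :class:`StateModel`).
    """

    def __init__(self, mode: str = "topological", min_points: int = 250, k: int = 8,
                 seed: int = 0, stable_frac: float = 0.05):
        self.mode = mode
        self.min_points = min_points
        self.k = k
        self.seed = seed
        self.stable_frac = stable_frac

    def fit(self, X, y=None):
        self.model_ = cluster_states(X, mode=self.mode, min_points=self.min_points,
                                     k=self.k, seed=self.seed, stable_frac=self.stable_frac)
        self.labels_ = self.model_.labels
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


# ---------------------------------------------------------------------------
# temporal segmentation
# ---------------------------------------------------------------------------

def temporal_segments(labels: np.ndarray, max_gap: int = 2, min_length: int = 5,
                      states=None) -> list[Segment]:
    """Merge per-state label runs into temporal segments.

    ``max_gap`` is the maximal number of intervening frames allowed between
    consecutive member points of a segment; candidate segments with fewer
    than ``min_length`` member points are dropped.  Segmentation is performed
    independently per state, so a frame may end up inside segments of one,
    several, or no states.
    """
    if max_gap < 0 or min_length < 1:
        raise ValueError("max_gap must be >= 0 and min_length >= 1")
    labels = np.asarray(labels)
    out: list[Segment] = []
    state_ids = states if states is not None else np.unique(labels[labels >= 0])
    for s in state_ids:
        idx = np.flatnonzero(labels == s)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > max_gap + 1)
        for chunk in np.split(idx, breaks + 1):
            if chunk.size >= min_length:
                seg = Segment(state=int(s), start=int(chunk[0]), stop=int(chunk[-1]))
                seg.members = chunk
                out.append(seg)
    out.sort(key=lambda g: (g.start, g.state))
    return out


def choose_max_gap(labels: np.ndarray, candidates=range(1, 16), tol: float = 0.05) -> int:
    """Smallest gap threshold at which the segment count is robust.

    The segment-length distribution should not be sensitive to small changes
    of the threshold; the first candidate whose total segment count changes
    by less than ``tol`` under a +/-1 perturbation is returned.
    """
    counts = {g: len(temporal_segments(labels, max_gap=g, min_length=1))
              for g in range(min(candidates) - 1, max(candidates) + 2)}
    for g in candidates:
        n = counts[g]
        if n == 0:
            continue
        if abs(counts[g - 1] - n) / n < tol and abs(counts[g + 1] - n) / n < tol:
            return g
    return 2


def choose_min_length(labels: np.ndarray, max_gap: int = 2, fallback: int = 5) -> int:
    """Antimode of the (bimodal) candidate-segment-length histogram.

    Valid visits to a state hold many data points; noise-driven excursions
    hold few, making the distribution of member counts bimodal.  The valley
    of a kernel density estimate between the two dominant modes separates
    them; if no clear bimodality is found, ``fallback`` is returned.
    """
    from scipy.stats import gaussian_kde

    lengths = np.array([s.members.size for s in
                        temporal_segments(labels, max_gap=max_gap, min_length=1)])
    if lengths.size < 10 or np.unique(lengths).size < 3:
        return fallback
    grid = np.arange(1, lengths.max() + 1, dtype=float)
    try:
        dens = gaussian_kde(np.log(lengths))(np.log(grid))
    except np.linalg.LinAlgError:
        return fallback
    n = len(grid)
    maxima = [i for i in range(n)
              if (i == 0 or dens[i] >= dens[i - 1]) and (i == n - 1 or dens[i] >= dens[i + 1])]
    if len(maxima) < 2:
        return fallback
    top2 = sorted(sorted(maxima, key=lambda i: -dens[i])[:2])
    if top2[1] - top2[0] < 2:
        return fallback
    valley = top2[0] + int(np.argmin(dens[top2[0]:top2[1] + 1]))
    return int(grid[valley])


# ---------------------------------------------------------------------------
# subtypes
# ---------------------------------------------------------------------------

def segment_subtypes(m: ActivityMatrix, segments: list[Segment],
                     frame_index: np.ndarray) -> np.ndarray:
    """Split one state's segments into subtypes by PCA of mean activity.

    Each segment is summarized by its average activity vector; the vectors
    are projected on their first principal component, and two subtypes are
    declared iff the 1-d projection histogram (Freedman-Diaconis bins) shows
    two modes separated by at least one empty bin, with each mode holding a
    non-trivial share of the segments (at least 2 and 10%) — a lone outlier
    segment is not a separate cluster.  Returns a per-segment subtype label
    array (all zeros when no split is warranted; fewer than 4 segments never
    split).
    """
    n_seg = len(segments)
    if n_seg < 4:
        return np.zeros(n_seg, dtype=np.int64)
    means = np.vstack([m.values[:, frame_index[s.members]].mean(axis=1) for s in segments])
    if np.allclose(means, means[0]):
        return np.zeros(n_seg, dtype=np.int64)
    pca = PCA(n_components=1)
    proj = pca.fit_transform(means)[:, 0]
    comp = pca.components_[0]
    if comp[np.argmax(np.abs(comp))] < 0:  # canonical sign
        proj = -proj
    iqr = np.subtract(*np.percentile(proj, [75, 25]))
    if iqr == 0:
        return np.zeros(n_seg, dtype=np.int64)
    width = 2 * iqr / n_seg ** (1 / 3)
    # Freedman-Diaconis underbins exactly in the strongly bimodal case this
    # test must detect (the IQR then spans both modes), so enforce a floor of
    # 10 bins; the per-side population guard below prevents spurious splits
    nbins = max(2, min(n_seg // 2, max(10, int(np.ceil((proj.max() - proj.min()) / width)))))
    hist, edges = np.histogram(proj, bins=nbins)
    occupied = np.flatnonzero(hist > 0)
    min_side = max(2, int(np.ceil(0.1 * n_seg)))
    # widest run of empty bins strictly between occupied ones, with enough
    # segments on both sides
    best = None
    for a, b in zip(occupied[:-1], occupied[1:]):
        if b - a <= 1:
            continue
        cut = 0.5 * (edges[a + 1] + edges[b])
        hi = int((proj > cut).sum())
        if min(hi, n_seg - hi) < min_side:
            continue
        if best is None or b - a > best[0]:
            best = (b - a, cut)
    if best is None:
        return np.zeros(n_seg, dtype=np.int64)
    return (proj > best[1]).astype(np.int64)


# ---------------------------------------------------------------------------
# transitions and ordering
# ---------------------------------------------------------------------------

def transition_matrix(labels_or_segments, n_states: int, level: str = "frame") -> np.ndarray:
    """Empirical row-stochastic transition matrix between states.

    Frame level counts consecutive data points; segment level counts
    consecutive segments in time order.  A state with no outgoing transition
    keeps a zero row.
    """
    if level == "frame":
        seq = np.asarray(labels_or_segments)
        a, b = seq[:-1], seq[1:]
        ok = (a >= 0) & (b >= 0)
        a, b = a[ok], b[ok]
    elif level == "segment":
        segs = sorted(labels_or_segments, key=lambda s: s.start)
        seq = np.array([s.state for s in segs])
        a, b = seq[:-1], seq[1:]
    else:
        raise ValueError(f"unknown level {level!r}")
    if len(a) < 1:
        raise ValueError("need at least 2 labeled items")
    counts = np.zeros((n_states, n_states))
    np.add.at(counts, (a, b), 1.0)
    rows = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(rows > 0, counts / rows, 0.0)
    return p


def traversal_end_states(labels: np.ndarray, frame_index: np.ndarray, n_states: int,
                         gap_threshold: int = 10):
    """Sub-clusters most frequent at the beginning and end of each visit.

    A visit (e.g. one track traversal) is a temporally contiguous stretch of
    the parent state's frames — a jump of more than ``gap_threshold``
    original bins starts a new one.  The sub-cluster of the first and last
    labeled frame of each visit is tallied; one sub-cluster dominating the
    starts and another the ends pins the directionality of the ordering.
    """
    starts = np.zeros(n_states)
    ends = np.zeros(n_states)
    prev_frame = None
    first_lab = last_lab = None
    for lab, frame in zip(labels, frame_index):
        if lab < 0:
            continue
        if prev_frame is None or frame - prev_frame > gap_threshold:
            if first_lab is not None:
                starts[first_lab] += 1
                ends[last_lab] += 1
            first_lab = lab
        last_lab = lab
        prev_frame = frame
    if first_lab is not None:
        starts[first_lab] += 1
        ends[last_lab] += 1
    first = int(np.argmax(starts))
    last = int(np.argmax(ends))
    if last == first:
        order = np.argsort(-ends, kind="stable")
        last = int(order[1]) if n_states > 1 else first
    return first, last


def _linear_end_states(segments: list[Segment], n_states: int):
    """End constraints from a segment sequence (fallback when no frame map)."""
    segs = sorted(segments, key=lambda s: s.start)
    starts = np.zeros(n_states)
    ends = np.zeros(n_states)
    prev_stop = None
    for seg in segs:
        if prev_stop is None or seg.start > prev_stop + 1:
            starts[seg.state] += 1
        ends[seg.state] += 1
        prev_stop = seg.stop
    first = int(np.argmax(starts))
    last = int(np.argmax(ends))
    if last == first:
        order = np.argsort(-ends, kind="stable")
        last = int(order[1]) if n_states > 1 else first
    return first, last


def order_states(t: np.ndarray, mode: str = "linear", segments: list[Segment] | None = None,
                 ends: tuple | None = None) -> np.ndarray:
    """Permutation of states maximizing the summed transition probability.

    Linear mode fixes the first and last states (those most frequent at
    segment starts and ends) and exhausts the (M-2)! interior permutations of
    the objective sum P[I_i, I_{i+1}].  Cyclic mode maximizes the sum over
    both neighbors around the ring across the (M-1)!/2 orders that are
    distinct up to rotation and reflection.  Ties resolve to the
    lexicographically smallest permutation.
    """
    t = np.asarray(t, dtype=float)
    m = t.shape[0]
    if m < 3:
        raise ValueError("need at least 3 states to order")
    if m > MAX_ORDERABLE_STATES:
        raise ValueError(
            f"M={m} states makes the factorial ordering search intractable; "
            "coarsen the clustering (M <= 10)")

    if mode == "linear":
        if ends is not None:
            first, last = ends
        elif segments is not None:
            first, last = _linear_end_states(segments, m)
        else:
            raise ValueError("linear ordering needs segments or explicit ends")
        interior = [s for s in range(m) if s not in (first, last)]
        best, best_val = None, -np.inf
        for perm in permutations(interior):
            order = (first, *perm, last)
            val = sum(t[order[i], order[i + 1]] for i in range(m - 1))
            if val > best_val:
                best, best_val = order, val
        return np.asarray(best)

    if mode == "cyclic":
        best, best_val = None, -np.inf
        for perm in permutations(range(1, m)):
            if m > 2 and perm[0] > perm[-1]:
                continue  # reflection symmetry: keep one representative
            order = (0, *perm)
            val = sum(t[order[i], order[(i + 1) % m]] + t[order[(i + 1) % m], order[i]]
                      for i in range(m))
            if val > best_val:
                best, best_val = order, val
        return np.asarray(best)

    raise ValueError(f"unknown ordering mode {mode!r}")
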