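"""Two-stage Laplacian-Eigenmaps embedding of population activity vectors.

Stage 1 embeds the binary activity vectors into 10 dimensions using a sparse
kNN graph (neighbor fraction p1 in [0.25%, 0.5%] of the number of points);
stage 2 re-embeds the 10-d coordinates into 3 dimensions with a denser graph
(p2 in [7.5%, 15%]).  Both stages solve the generalized eigenproblem
L f = lambda D f with L = D - W on the OR-symmetrized binary ("simple
minded") neighborhood graph and keep the eigenvectors after the leading
constant one, ordered by ascending eigenvalue.

Numerically the generalized problem is solved through the normalized
adjacency D^{-1/2} W D^{-1/2}: its largest eigenpairs correspond one-to-one
to the smallest generalized eigenpairs (lambda = 1 - mu), which lets a plain
Lanczos iteration with deterministic start vectors handle the dense stage-2
graphs without factorizations.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import stable_knn
from .containers import ActivityMatrix, Embedding, NeighborGraph

P1_RANGE = (0.0025, 0.005)
P2_RANGE = (0.075, 0.15)
P1_DEFAULT = 0.00375   # midpoint of the stage-1 range
P2_DEFAULT = 0.1125    # midpoint of the stage-2 range


def knn_graph(points: np.ndarray, p: float) -> NeighborGraph:
    """OR-symmetrized kNN graph with k = max(1, round(p * n)), binary weights.

    Nodes i, j are connected if i is among the k nearest neighbors of j or
    vice versa; W_ij = 1 on edges, 0 otherwise, zero diagonal.  Distance ties
    are broken by the lowest point index, making the graph deterministic.
    """
    points = np.asarray(points)
    n = points.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    if not (0 < p < 1):
        raise ValueError("p must be in (0, 1)")
    k = max(1, int(round(p * n)))
    k = min(k, n - 1)
    nbrs = stable_knn(points, k)
    rows = np.repeat(np.arange(n), k)
    cols = nbrs.ravel()
    w = sp.coo_matrix((np.ones(rows.size, dtype=np.int8), (rows, cols)), shape=(n, n)).tocsr()
    w = ((w + w.T) > 0).astype(np.float64)  # OR-symmetrization
    w.setdiag(0)
    w.eliminate_zeros()
    return NeighborGraph(adjacency=w, neighbor_fraction=p, k=k)


def _canonical_signs(vecs: np.ndarray) -> np.ndarray:
    """Make each eigenvector's largest-magnitude entry positive."""
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def spectral_embed(g: NeighborGraph, n_dims: int, frame_index: np.ndarray | None = None,
                   stage: int = 1, seed: int = 0) -> Embedding:
    """Solve L f = lambda D f and return eigenvectors 2..(n_dims+1).

    A disconnected graph is restricted to its largest connected component and
    the dropped nodes are reported on the result — components are never
    silently mixed.  Per-axis signs are canonicalized (largest-magnitude
    entry positive).
    """
    w = g.adjacency
    n = w.shape[0]
    if frame_index is None:
        frame_index = np.arange(n)
    frame_index = np.asarray(frame_index)

    n_comp, comp = connected_components(w, directed=False)
    dropped = np.empty(0, dtype=np.int64)
    if n_comp > 1:
        sizes = np.bincount(comp)
        keep = np.flatnonzero(comp == np.argmax(sizes))
        dropped = frame_index[np.flatnonzero(comp != np.argmax(sizes))]
        w = w[keep][:, keep]
        frame_index = frame_index[keep]
        n = w.shape[0]

    deg = np.asarray(w.sum(axis=0)).ravel()
    d_isqrt = 1.0 / np.sqrt(deg)
    norm_adj = sp.diags(d_isqrt) @ w @ sp.diags(d_isqrt)
    k_eigs = n_dims + 1
    if k_eigs >= n:
        raise ValueError(f"graph too small ({n} nodes) for {n_dims} embedding dims")
    if n <= 1500:
        # dense solve: exact multiplicities (a Lanczos iteration started from a
        # single vector cannot split the degenerate eigenpairs of symmetric
        # graphs such as rings)
        mu_all, vec_all = np.linalg.eigh(norm_adj.toarray())
        order = np.argsort(-mu_all, kind="stable")[:k_eigs]
        mu, g_vecs = mu_all[order], vec_all[:, order]
    else:
        # large graphs: Lanczos with a deterministic start vector; ask for a
        # few extra pairs so near-degenerate multiplets resolve
        k_ask = min(k_eigs + 3, n - 1)
        v0 = np.random.default_rng(np.random.SeedSequence(seed)).normal(size=n)
        mu, g_vecs = eigsh(norm_adj, k=k_ask, which="LA", tol=1e-10, v0=v0)
        order = np.argsort(-mu, kind="stable")[:k_eigs]  # descending mu == ascending lambda
        mu = mu[order]
        g_vecs = g_vecs[:, order]
    lam = 1.0 - mu
    f = g_vecs * d_isqrt[:, None]  # back to generalized eigenvectors of (L, D)
    # D-normalize: f^T D f = 1
    scale = np.sqrt(np.einsum("ij,i,ij->j", f, deg, f))
    f = f / scale
    coords = _canonical_signs(f[:, 1:])  # leave out the leading constant eigenvector
    return Embedding(coords=coords, frame_index=frame_index, stage=stage,
                     eigenvalues=lam, dropped_frames=dropped)


def embed_two_stage(m: ActivityMatrix, p1: float = P1_DEFAULT, p2: float = P2_DEFAULT,
                    seed: int = 0) -> Embedding:
    """Stage-1 (10-d) then stage-2 (3-d) spectral embedding of retained frames."""
    if m.retained_frames.size == 0:
        raise ValueError("no retained frames to embed")
    est = TwoStageSpectralEmbedding(p1=p1, p2=p2, seed=seed)
    est.fit(m)
    return est.embedding_


class TwoStageSpectralEmbedding(BaseEstimator, TransformerMixin):
    """sklearn-style estimator for the two-stage Laplacian-Eigenmaps embedding.

    Parameters
    ----------
    p1, p2 : float
        Neighbor fractions of the two stages (defaults are the midpoints of
        the 0.25-0.5% and 7.5-15% working ranges).
    stage1_dims, stage2_dims : int
        Embedding dimensions (10 then 3 by convention).
    seed : int
        Seeds the deterministic eigensolver start vectors, so per-axis signs
        are reproducible.

    Attributes
    ----------
    embedding_ : Embedding
        Final (stage-2) coordinates with frame bookkeeping.
    stage1_ : Embedding
        Intermediate 10-d embedding.
    """

    def __init__(self, p1: float = P1_DEFAULT, p2: float = P2_DEFAULT,
                 stage1_dims: int = 10, stage2_dims: int = 3, seed: int = 0):
        self.p1 = p1
        self.p2 = p2
        self.stage1_dims = stage1_dims
        self.stage2_dims = stage2_dims
        self.seed = seed

    def fit(self, X, y=None):
        if isinstance(X, ActivityMatrix):
            frames = X.retained()
            frame_index = X.retained_frames
        else:
            frames = np.asarray(X)
            frame_index = np.arange(frames.shape[0])
        if frames.shape[0] == 0:
            raise ValueError("no retained frames to embed")
        try:
            g1 = knn_graph(frames, self.p1)
            self.stage1_ = spectral_embed(g1, self.stage1_dims, frame_index=frame_index,
                                          stage=1, seed=self.seed)
        except ValueError as err:
            raise ValueError(f"stage 1: {err}") from err
        try:
            g2 = knn_graph(self.stage1_.coords, self.p2)
            self.embedding_ = spectral_embed(
                g2, self.stage2_dims, frame_index=self.stage1_.frame_index,
                stage=2, seed=self.seed)
        except ValueError as err:
            raise ValueError(f"stage 2: {err}") from err
        self.embedding_.dropped_frames = np.union1d(self.stage1_.dropped_frames,
                                                    self.embedding_.dropped_frames)
        return self

    def transform(self, X=None):
        return self.embedding_.coords

    def fit_transform(self, X, y=None):
        return self.fit(X).transform()
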