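"""Vietoris-Rips persistent homology (dims 0-2) for small landmark sets.

Designed for the ~50-70 K-means landmarks the topology stage works on.  The
filtration value of a simplex is its diameter (longest edge).  Dimension 0 is
handled by a union-find sweep over edges; dimensions 1-2 use the standard
GF(2) boundary-matrix reduction with columns stored as Python integers
(bitmasks over the sorted lower-dimensional simplices), accelerated by

- the apparent-pairs shortcut: a simplex pair (sigma youngest facet of tau,
  tau oldest cofacet of sigma) is a persistence pair of zero persistence and
  needs no reduction, which disposes of the vast majority of columns;
- clearing: triangles paired during the tetrahedron reduction are known
  cycle-creators, so their own columns are skipped in the triangle reduction.

Intervals of zero persistence are never recorded — they cannot affect Betti
curves read on a radius grid.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _simplex_array(n: int, dim: int) -> np.ndarray:
    combos = np.fromiter(
        (v for c in combinations(range(n), dim + 1) for v in c), dtype=np.int32)
    return combos.reshape(-1, dim + 1)


def _diameters(simplices: np.ndarray, dist: np.ndarray) -> np.ndarray:
    d = np.zeros(len(simplices))
    k = simplices.shape[1]
    for a in range(k):
        for b in range(a + 1, k):
            np.maximum(d, dist[simplices[:, a], simplices[:, b]], out=d)
    return d


def _sort_ranks(simplices: np.ndarray, diam: np.ndarray):
    """Filtration order: by diameter, ties by vertex lexicographic order."""
    keys = tuple(simplices[:, c] for c in range(simplices.shape[1] - 1, -1, -1))
    order = np.lexsort(keys + (diam,))
    rank = np.empty(len(order), dtype=np.int64)
    rank[order] = np.arange(len(order))
    return order, rank


def _reduce_columns(order, col_facet_ranks, apparent_col):
    """GF(2) reduction of one boundary matrix in filtration column order.

    ``col_facet_ranks[pos]`` gives the row (facet) ranks of column ``pos``;
    ``apparent_col`` maps a row rank that is an apparent pivot to a
    lazily-materialized column bitmask factory.  Returns (pairs, zero_cols):
    pairs as (row_rank, column_pos), zero_cols as positions whose column
    reduced to zero.
    """
    pivot_col: dict[int, int] = {}
    pairs = []
    zero_cols = []
    get = pivot_col.get
    app_pop = apparent_col.pop
    for pos in order:
        col = 0
        for r in col_facet_ranks[pos]:
            col ^= 1 << int(r)
        while col:
            piv = col.bit_length() - 1
            other = get(piv)
            if other is None:
                factory = app_pop(piv, None)
                if factory is not None:
                    other = factory()
                    pivot_col[piv] = other
                    col ^= other
                    continue
                pivot_col[piv] = col
                pairs.append((piv, pos))
                break
            col ^= other
        else:
            zero_cols.append(pos)
    return pairs, zero_cols


def rips_persistence(dist: np.ndarray, r_max: float) -> dict[int, np.ndarray]:
    """Persistence intervals (birth, death) per homology dimension 0..2.

    ``dist`` is a dense symmetric distance matrix; simplices with diameter
    above ``r_max`` are excluded, and features still alive there are reported
    with death ``inf``.  Zero-persistence intervals are omitted.
    """
    n = dist.shape[0]
    intervals: dict[int, list] = {0: [], 1: [], 2: []}
    if n == 0:
        return {d: np.empty((0, 2)) for d in range(3)}

    # --- edges and dimension 0 (union-find) ---
    edges = _simplex_array(n, 1)
    e_diam = _diameters(edges, dist)
    keep = e_diam <= r_max
    edges, e_diam = edges[keep], e_diam[keep]
    e_order, e_rank = _sort_ranks(edges, e_diam)
    uf = _UnionFind(n)
    merge_edge = np.zeros(len(edges), dtype=bool)
    for pos in e_order:
        if uf.union(int(edges[pos, 0]), int(edges[pos, 1])):
            merge_edge[pos] = True
            if e_diam[pos] > 0:
                intervals[0].append((0.0, e_diam[pos]))
    n_components = len({uf.find(v) for v in range(n)})
    intervals[0].extend([(0.0, np.inf)] * n_components)

    # edge id -> rank lookup
    eid = np.full(n * n, -1, dtype=np.int64)
    eid[edges[:, 0] * n + edges[:, 1]] = e_rank

    # --- triangles ---
    tris = _simplex_array(n, 2) if n >= 3 else np.empty((0, 3), np.int32)
    t_diam = _diameters(tris, dist) if len(tris) else np.empty(0)
    keep = t_diam <= r_max
    tris, t_diam = tris[keep], t_diam[keep]
    t_order, t_rank = _sort_ranks(tris, t_diam) if len(tris) else (np.empty(0, np.int64),) * 2
    tid = np.full(n * n * n, -1, dtype=np.int64)
    if len(tris):
        tid[(tris[:, 0].astype(np.int64) * n + tris[:, 1]) * n + tris[:, 2]] = \
            np.arange(len(tris))

    tri_facets = np.stack([
        eid[tris[:, 0] * n + tris[:, 1]],
        eid[tris[:, 0] * n + tris[:, 2]],
        eid[tris[:, 1] * n + tris[:, 2]],
    ], axis=1) if len(tris) else np.empty((0, 3), np.int64)

    # --- tetrahedra: reduce first (clearing) ---
    tri_paired = np.zeros(len(tris), dtype=bool)  # triangles killed in dim-2 pairs
    tri_death = np.full(len(tris), np.inf)
    if n >= 4 and len(tris):
        tets = _simplex_array(n, 3)
        q_diam = _diameters(tets, dist)
        keep = q_diam <= r_max
        tets, q_diam = tets[keep], q_diam[keep]
        if len(tets):
            q_order, q_rank = _sort_ranks(tets, q_diam)
            # facet triangle indices per tet
            fac = np.empty((len(tets), 4), dtype=np.int64)
            combs = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
            for f, (a, b, c) in enumerate(combs):
                key = (tets[:, a].astype(np.int64) * n + tets[:, b]) * n + tets[:, c]
                fac[:, f] = tid[key]
            fac_rank = t_rank[fac]
            youngest = fac[np.arange(len(tets)), np.argmax(fac_rank, axis=1)]
            # oldest cofacet (by tet rank) of every triangle
            oldest = np.full(len(tris), np.iinfo(np.int64).max, dtype=np.int64)
            for f in range(4):
                np.minimum.at(oldest, fac[:, f], q_rank)
            apparent = oldest[youngest] == q_rank
            # apparent (triangle, tet) pairs: zero persistence, triangle cleared
            tri_paired[youngest[apparent]] = True
            app_col_of_trirank = {}
            for t_idx in np.flatnonzero(apparent):
                ranks = fac_rank[t_idx]

                def _make(ranks=ranks):
                    col = 0
                    for r in ranks:
                        col ^= 1 << int(r)
                    return col

                app_col_of_trirank[int(np.max(ranks))] = _make
            rest = q_order[~apparent[q_order]]
            pairs, _ = _reduce_columns(rest, fac_rank, app_col_of_trirank)
            tri_by_rank = np.empty(len(tris), dtype=np.int64)
            tri_by_rank[t_rank] = np.arange(len(tris))
            for row_rank, col_pos in pairs:
                tri_idx = tri_by_rank[row_rank]
                tri_paired[tri_idx] = True
                if q_diam[col_pos] > t_diam[tri_idx]:
                    intervals[2].append((t_diam[tri_idx], q_diam[col_pos]))

    # --- triangle reduction (dim-1 deaths), with clearing and apparent pairs ---
    edge_killed = np.zeros(len(edges), dtype=bool)  # creator edges destroyed by a triangle
    if len(tris):
        tri_fac_rank = tri_facets  # already edge ranks
        youngest_e = np.argmax(tri_fac_rank, axis=1)
        youngest_rank = tri_fac_rank[np.arange(len(tris)), youngest_e]
        oldest_cof = np.full(len(edges), np.iinfo(np.int64).max, dtype=np.int64)
        for f in range(3):
            np.minimum.at(oldest_cof, tri_fac_rank[:, f], t_rank)
        apparent_t = (oldest_cof[youngest_rank] == t_rank) & ~tri_paired
        edge_by_rank = np.empty(len(edges), dtype=np.int64)
        edge_by_rank[e_rank] = np.arange(len(edges))
        edge_killed[edge_by_rank[youngest_rank[apparent_t]]] = True
        app_col = {}
        for t_idx in np.flatnonzero(apparent_t):
            ranks = tri_fac_rank[t_idx]

            def _make(ranks=ranks):
                col = 0
                for r in ranks:
                    col ^= 1 << int(r)
                return col

            app_col[int(np.max(ranks))] = _make
        todo = t_order[(~tri_paired[t_order]) & (~apparent_t[t_order])]
        pairs, zero_cols = _reduce_columns(todo, tri_fac_rank, app_col)
        for row_rank, col_pos in pairs:
            e_idx = edge_by_rank[row_rank]
            edge_killed[e_idx] = True
            if t_diam[col_pos] > e_diam[e_idx]:
                intervals[1].append((e_diam[e_idx], t_diam[col_pos]))
        # unpaired cycle-creating triangles not cleared by any tet: essential 2-cycles
        for col_pos in zero_cols:
            if not tri_paired[col_pos]:
                intervals[2].append((t_diam[col_pos], np.inf))

    # creator edges never killed: essential 1-cycles
    for idx in range(len(edges)):
        if not merge_edge[idx] and not edge_killed[idx]:
            intervals[1].append((e_diam[idx], np.inf))

    return {d: (np.asarray(intervals[d]).reshape(-1, 2) if intervals[d]
                else np.empty((0, 2))) for d in range(3)}


def betti_curves(intervals: dict[int, np.ndarray], radii: np.ndarray) -> np.ndarray:
    """Betti numbers beta_0..beta_2 evaluated on a radius grid.

    A feature with interval [b, d) counts at radius r when b <= r < d.
    """
    radii = np.asarray(radii, dtype=float)
    out = np.zeros((3, len(radii)), dtype=np.int64)
    for dim in range(3):
        iv = intervals.get(dim)
        if iv is None or len(iv) == 0:
            continue
        for b, d in iv:
            out[dim] += (radii >= b) & (radii < d)
    return out
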