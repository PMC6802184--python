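"""Conservation of the neural code and of the internal structure across days.

Code stability: Spearman correlation between same-state ensemble rate
vectors (mean event rate per registered neuron within a behavioral state) on
two days, averaged over states weighted by time in state.  Structure
stability: Spearman correlation between the upper triangles of the
state-centroid distance matrices of the two days' embeddings — a
registration-free comparison, invariant to any rotation or scaling of either
day's embedding.  The track's reflection symmetry is handled by taking the
maximal correlation over the two orientations; significance comes from
shuffling state identities in one day of each pair.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy.stats import spearmanr, t as t_dist

from .containers import ActivityMatrix, BehaviorTrack, Embedding, StabilityResult

# behavioral states on the track: drink_L, turn_L, run, turn_R, drink_R
STATE_NAMES = ("drink_L", "turn_L", "run", "turn_R", "drink_R")
FLIP = np.array([4, 3, 2, 1, 0])  # state permutation under track reflection


def behavioral_state_labels(b: BehaviorTrack) -> np.ndarray:
    """Per-frame behavioral state id (0..4), -1 for unlabeled frames.

    Rearing is merged with turning at the same position (the codes are
    alike), using the track half to decide the side.
    """
    lab = b.behavior_label
    out = np.full(b.n_frames, -1, dtype=np.int64)
    for i, name in enumerate(STATE_NAMES):
        out[lab == name] = i
    rear = lab == "rear"
    left = rear & (b.position < b.track_length / 2)
    out[left] = 1
    out[rear & ~left] = 3
    return out


def _ensemble_vectors(m: ActivityMatrix, states: np.ndarray, n_states: int) -> np.ndarray:
    """Mean event rate per neuron per state (n_states x n_neurons)."""
    out = np.zeros((n_states, m.n_neurons))
    for s in range(n_states):
        sel = states == s
        if sel.any():
            out[s] = m.values[:, sel].mean(axis=1) / m.bin_width
        else:
            out[s] = np.nan
    return out


def _state_centroids(emb: Embedding, states: np.ndarray, n_states: int) -> np.ndarray:
    """Center of mass per behavioral state in the embedding (NaN if absent)."""
    cm = np.full((n_states, emb.n_dims), np.nan)
    st = states[emb.frame_index]
    for s in range(n_states):
        sel = st == s
        if sel.any():
            cm[s] = emb.coords[sel].mean(axis=0)
    return cm


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], 1)
    return mat[iu]


def _dist_matrix(cm: np.ndarray) -> np.ndarray:
    return np.linalg.norm(cm[:, None, :] - cm[None, :, :], axis=-1)


def _structure_corr(d1: np.ndarray, d2: np.ndarray, perm: np.ndarray) -> float:
    a = _upper(d1)
    bmat = d2[np.ix_(perm, perm)]
    b = _upper(bmat)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return np.nan
    return float(spearmanr(a[ok], b[ok]).statistic)


def _code_corr(v1: np.ndarray, v2: np.ndarray, weights: np.ndarray,
               perm: np.ndarray) -> float:
    """Time-weighted average Spearman correlation over matched states."""
    cors, ws = [], []
    for s in range(v1.shape[0]):
        a, b = v1[s], v2[perm[s]]
        if np.isnan(a).any() or np.isnan(b).any() or weights[s] <= 0:
            continue
        if np.std(a) == 0 or np.std(b) == 0:
            continue
        cors.append(spearmanr(a, b).statistic)
        ws.append(weights[s])
    if not ws:
        return np.nan
    return float(np.average(cors, weights=ws))


def stability_analysis(activities: list[ActivityMatrix], behaviors: list[BehaviorTrack],
                       embeddings: list[Embedding], day_times: np.ndarray | None = None,
                       shared_neurons: np.ndarray | None = None) -> StabilityResult:
    """Across-day code and structure stability with shuffle significance.

    ``day_times`` gives the recording day of each session (defaults to 0, 2,
    4, ... — sessions every other day); normalized correlation curves anchor
    the minimal elapsed time to 1 and are fit linearly with 95% confidence
    intervals.  ``shared_neurons`` restricts code stability to registered
    cells (defaults to neurons active on every day).
    """
    n_days = len(activities)
    if n_days < 2:
        raise ValueError("need at least 2 days")
    if day_times is None:
        day_times = 2.0 * np.arange(n_days)
    day_times = np.asarray(day_times, float)
    ns = len(STATE_NAMES)

    states = [behavioral_state_labels(b) for b in behaviors]
    if shared_neurons is None:
        active = np.vstack([m.values.sum(axis=1) > 0 for m in activities])
        shared_neurons = np.flatnonzero(active.all(axis=0))
    vecs = [_ensemble_vectors(m, st, ns)[:, shared_neurons]
            for m, st in zip(activities, states)]
    dists = [_dist_matrix(_state_centroids(e, st, ns))
             for e, st in zip(embeddings, states)]
    occ = [np.array([(st == s).sum() for s in range(ns)], float) for st in states]

    pairs, code, struct, elapsed, pvals = [], [], [], [], []
    identity = np.arange(ns)
    all_perms = [np.asarray(p) for p in permutations(range(ns))]
    for i in range(n_days):
        for j in range(i + 1, n_days):
            w = occ[i] + occ[j]
            c = max(_code_corr(vecs[i], vecs[j], w, identity),
                    _code_corr(vecs[i], vecs[j], w, FLIP))
            s = max(_structure_corr(dists[i], dists[j], identity),
                    _structure_corr(dists[i], dists[j], FLIP))
            null = np.array([_structure_corr(dists[i], dists[j], p) for p in all_perms])
            null = null[np.isfinite(null)]
            p = float((1 + np.sum(null >= s)) / (len(null) + 1))
            pairs.append((i, j))
            code.append(c)
            struct.append(s)
            elapsed.append(day_times[j] - day_times[i])
            pvals.append(p)

    code = np.asarray(code)
    struct = np.asarray(struct)
    elapsed = np.asarray(elapsed)
    result = StabilityResult(day_pairs=pairs, code_corr=code, structure_corr=struct,
                             elapsed=elapsed, shuffle_p=np.asarray(pvals))
    result.code_slope = _normalized_slope(elapsed, code)
    result.structure_slope = _normalized_slope(elapsed, struct)
    return result


def _normalized_slope(elapsed: np.ndarray, corr: np.ndarray):
    """Linear slope (with 95% CI) of correlation normalized at minimal elapsed time."""
    ok = np.isfinite(corr)
    if ok.sum() < 2:
        return None
    e, c = elapsed[ok], corr[ok]
    ref = c[e == e.min()].mean()
    if ref == 0:
        return None
    y = c / ref
    if np.unique(e).size < 2:
        return None
    x = np.c_[np.ones(len(e)), e]
    beta, res, *_ = np.linalg.lstsq(x, y, rcond=None)
    dof = len(e) - 2
    if dof <= 0:
        return (float(beta[1]), np.nan, np.nan)
    resid = y - x @ beta
    s2 = (resid**2).sum() / dof
    se = np.sqrt(s2 * np.linalg.inv(x.T @ x)[1, 1])
    tcrit = t_dist.ppf(0.975, dof)
    return (float(beta[1]), float(beta[1] - tcrit * se), float(beta[1] + tcrit * se))
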