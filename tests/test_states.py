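"""State clustering, segmentation, subtypes, transitions and ordering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from innerstate.containers import ActivityMatrix
from innerstate.states import (
    cluster_states,
    order_states,
    segment_subtypes,
    temporal_segments,
    transition_matrix,
    traversal_end_states,
)


def test_single_blob_is_one_cluster_with_all_points():
    rng = np.random.default_rng(0)
    model = cluster_states(rng.normal(0, 1, (1000, 3)), min_points=250)
    assert model.n_states == 1
    assert (model.labels == 0).all()


def test_three_blobs_recovered():
    rng = np.random.default_rng(1)
    blobs = [rng.normal(0, 0.3, (400, 3)) + c
             for c in (np.zeros(3), np.array([10.0, 0, 0]), np.array([0, 10.0, 0]))]
    pts = np.vstack(blobs)
    model = cluster_states(pts, min_points=250)
    assert model.n_states == 3
    for lo in (0, 400, 800):
        block = model.labels[lo:lo + 400]
        assert np.all(block == block[0])


def test_kmeans_mode_fixed_k():
    rng = np.random.default_rng(2)
    model = cluster_states(rng.normal(0, 1, (500, 3)), mode="kmeans", k=8, seed=0)
    assert model.n_states == 8


def test_straggler_assignment_matches_bruteforce_nearest_assigned():
    """Post-hoc assignment of unassigned points equals a brute-force
    nearest-assigned-neighbor search."""
    rng = np.random.default_rng(3)
    a = rng.normal(0, 0.2, (260, 3))
    b = rng.normal(0, 0.2, (260, 3)) + np.array([5.0, 0, 0])
    stragglers = rng.uniform(-1, 6, (60, 3))
    pts = np.vstack([a, b, stragglers])
    model = cluster_states(pts, min_points=250)
    assert model.n_states == 2
    core = np.r_[np.arange(520)]
    for i in range(520, 580):
        d = np.linalg.norm(pts[core] - pts[i], axis=1)
        assert model.labels[i] == model.labels[core[np.argmin(d)]]


def test_unbroken_run_single_segment():
    labels = np.array([0] * 30)
    segs = temporal_segments(labels, max_gap=2, min_length=5)
    assert len(segs) == 1
    assert (segs[0].start, segs[0].stop) == (0, 29)


def test_short_run_dropped_by_min_length():
    labels = np.array([-1] * 5 + [1] * 3 + [-1] * 5)
    assert temporal_segments(labels, max_gap=1, min_length=5) == []


@settings(deadline=None, max_examples=30)
@given(st.lists(st.tuples(st.integers(5, 20), st.integers(0, 3)), min_size=1, max_size=6),
       st.integers(1, 4))
def test_planted_segments_recovered_exactly(spans, gap):
    """A label sequence built from known intervals separated by wide gaps is
    segmented back into exactly those intervals."""
    labels = []
    expected = []
    for length, _ in spans:
        start = len(labels)
        labels.extend([0] * length)
        expected.append((start, start + length - 1))
        labels.extend([-1] * (gap + 2))  # gap wider than max_gap: always splits
    segs = temporal_segments(np.asarray(labels), max_gap=gap, min_length=1)
    assert [(s.start, s.stop) for s in segs] == expected


def test_gaps_within_threshold_are_merged():
    labels = np.array([0, 0, -1, -1, 0, 0, 0])
    segs = temporal_segments(labels, max_gap=2, min_length=1)
    assert len(segs) == 1 and segs[0].stop == 6
    segs = temporal_segments(labels, max_gap=1, min_length=1)
    assert len(segs) == 2


def test_identical_segments_single_subtype():
    vals = np.tile(np.array([1, 0, 1, 0], np.uint8)[:, None], (1, 40))
    m = ActivityMatrix(values=vals, bin_width=0.1, modality="imaging",
                       retained_frames=np.arange(40))
    # carve into 8 five-frame segments of one state
    segs = []
    for s in range(8):
        seg_labels = np.full(40, -1)
        seg_labels[s * 5:(s + 1) * 5] = 0
        segs.extend(temporal_segments(seg_labels, max_gap=0, min_length=1))
    labs = segment_subtypes(m, segs, np.arange(40))
    assert np.all(labs == 0)


def test_two_mean_population_recovers_planted_split():
    """Segment means drawn 4 SD apart split into the planted subtypes."""
    rng = np.random.default_rng(4)
    n_seg, n_neurons, seg_len = 30, 60, 10
    planted = rng.integers(0, 2, n_seg)
    base = np.zeros((2, n_neurons))
    base[0, :20] = 0.8
    base[1, 20:40] = 0.8
    k = n_seg * seg_len
    vals = np.zeros((n_neurons, k), np.uint8)
    segs = []
    labels = np.zeros(k, np.int64)
    for i in range(n_seg):
        cols = slice(i * seg_len, (i + 1) * seg_len)
        p = base[planted[i]][:, None] + 0.1
        vals[:, cols] = rng.random((n_neurons, seg_len)) < p
    m = ActivityMatrix(values=vals, bin_width=0.1, modality="imaging",
                       retained_frames=np.arange(k))
    for i in range(n_seg):
        lab = np.full(k, -1)
        lab[i * seg_len:(i + 1) * seg_len] = 0
        segs.extend(temporal_segments(lab, max_gap=0, min_length=1))
    labs = segment_subtypes(m, segs, np.arange(k))
    assert len(np.unique(labs)) == 2
    agree = (labs == planted).mean()
    assert max(agree, 1 - agree) == 1.0


def test_fewer_than_four_segments_never_split():
    m = ActivityMatrix(values=np.zeros((4, 30), np.uint8), bin_width=0.1,
                       modality="imaging", retained_frames=np.arange(30))
    segs = temporal_segments(np.r_[np.zeros(10, np.int64), np.full(20, -1)],
                             max_gap=0, min_length=1)
    assert np.all(segment_subtypes(m, segs, np.arange(30)) == 0)


def test_transition_rows_sum_to_one():
    rng = np.random.default_rng(5)
    seq = rng.integers(0, 4, 500)
    t = transition_matrix(seq, 4, level="frame")
    rows = t.sum(axis=1)
    assert np.allclose(rows[rows > 0], 1.0)


def test_transition_matches_bruteforce_pair_counting():
    rng = np.random.default_rng(6)
    seq = rng.integers(0, 5, 1000)
    t = transition_matrix(seq, 5, level="frame")
    counts = np.zeros((5, 5))
    for a, b in zip(seq[:-1], seq[1:]):
        counts[a, b] += 1
    expect = counts / counts.sum(axis=1, keepdims=True)
    assert np.allclose(t, expect)


def test_segment_level_counts_successions_not_frames():
    segs = temporal_segments(np.array([0] * 10 + [1] * 10 + [0] * 10), max_gap=0,
                             min_length=1)
    t = transition_matrix(segs, 2, level="segment")
    assert t[0, 1] == 1.0 and t[1, 0] == 1.0


def test_linear_ordering_three_states_unique():
    t = np.array([[0, 1.0, 0], [0, 0, 1.0], [0.2, 0, 0]])
    order = order_states(t, mode="linear", ends=(0, 2))
    assert list(order) == [0, 1, 2]


def test_ordering_matches_exhaustive_search():
    """The returned permutation attains the exhaustive-search maximum of the
    summed transition probability for M <= 8 (both modes)."""
    from itertools import permutations

    rng = np.random.default_rng(7)
    for m in (5, 6, 7):
        t = rng.random((m, m))
        np.fill_diagonal(t, 0)
        order = order_states(t, mode="linear", ends=(0, m - 1))
        val = sum(t[order[i], order[i + 1]] for i in range(m - 1))
        best = max(sum(t[p[i], p[i + 1]] for i in range(m - 1))
                   for p in permutations(range(m)) if p[0] == 0 and p[-1] == m - 1)
        assert val == pytest.approx(best)
        order = order_states(t, mode="cyclic")
        val = sum(t[order[i], order[(i + 1) % m]] + t[order[(i + 1) % m], order[i]]
                  for i in range(m))
        best = max(sum(t[p[i], p[(i + 1) % m]] + t[p[(i + 1) % m], p[i]] for i in range(m))
                   for p in permutations(range(m)))
        assert val == pytest.approx(best)


def test_cyclic_ordering_recovers_planted_ring():
    """Ring Markov chain (stay 0.8, step +-1 0.1 each): the recovered cyclic
    order equals the planted ring up to rotation and reflection."""
    m = 7
    rng = np.random.default_rng(8)
    seq = [0]
    for _ in range(4000):
        r = rng.random()
        step = 0 if r < 0.8 else (1 if r < 0.9 else -1)
        seq.append((seq[-1] + step) % m)
    t = transition_matrix(np.asarray(seq), m, level="frame")
    order = order_states(t, mode="cyclic")
    pos = np.empty(m, int)
    pos[order] = np.arange(m)
    steps = np.mod(np.diff(pos[np.arange(m)]), m)
    assert np.all(steps == steps[0]) and steps[0] in (1, m - 1)


def test_ordering_objective_reflection_invariant():
    rng = np.random.default_rng(9)
    m = 6
    t = rng.random((m, m))
    order = order_states(t, mode="cyclic")
    fwd = sum(t[order[i], order[(i + 1) % m]] + t[order[(i + 1) % m], order[i]]
              for i in range(m))
    rev = order[::-1]
    bwd = sum(t[rev[i], rev[(i + 1) % m]] + t[rev[(i + 1) % m], rev[i]]
              for i in range(m))
    assert fwd == pytest.approx(bwd)


def test_factorial_guard():
    t = np.eye(11)
    with pytest.raises(ValueError, match="coarsen"):
        order_states(t, mode="cyclic")


def test_traversal_end_states():
    # three visits, each starting in state 0 and ending in state 2
    labels = np.array([0, 1, 2, 0, 1, 2, 0, 1, 1, 2])
    frames = np.array([0, 1, 2, 50, 51, 52, 100, 101, 102, 103])
    assert traversal_end_states(labels, frames, 3) == (0, 2)
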