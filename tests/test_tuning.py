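"""Internal/external tuning curves, information, field and overlap statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from innerstate._utils import TWO_PI
from innerstate.containers import ActivityMatrix, BehaviorTrack, StateModel, TuningCurve
from innerstate.tuning import (
    InsufficientEvents,
    bidirectionality,
    external_tuning_curve,
    field_stats,
    information_from_counts,
    information_per_event,
    internal_tuning_curve,
    reconstruct_internal_variable,
)


def _model(labels, ordering, mode="linear"):
    return StateModel(labels=np.asarray(labels), frame_index=np.arange(len(labels)),
                      n_states=len(ordering), ordering=np.asarray(ordering),
                      ordering_mode=mode)


def _curve(rate, mode="circular", occupancy=None, counts=None):
    rate = np.asarray(rate, float)
    n = len(rate)
    centers = (np.arange(n) + 0.5) * TWO_PI / n if mode == "circular" else np.arange(n) + 0.5
    occ = np.ones(n) if occupancy is None else np.asarray(occupancy, float)
    cnt = rate * occ if counts is None else np.asarray(counts, float)
    return TuningCurve(bin_centers=centers, occupancy=occ, event_counts=cnt, rate=rate,
                       mode=mode, source="external", raw_occupancy=occ, raw_counts=cnt)


# ---------------------------------------------------------------------------
# internal variable reconstruction
# ---------------------------------------------------------------------------

def test_ordered_subclusters_get_evenly_spaced_positions():
    m = 5
    labels = np.arange(m)
    traj = reconstruct_internal_variable(_model(labels, np.arange(m)), "linear")
    assert np.allclose(sorted(traj.value), np.linspace(0, 1, m))


def test_circular_assignment_and_zero_error():
    m = 8
    labels = np.repeat(np.tile(np.arange(m), 20), 10)  # slow sweep around the ring
    model = _model(labels, np.arange(m), mode="cyclic")
    ext = TWO_PI * labels / m
    traj = reconstruct_internal_variable(model, "circular", external=ext)
    # exact between transitions; residuals at state steps are smoothing-scale
    assert np.nanmedian(np.abs(traj.error_series)) == pytest.approx(0.0, abs=1e-12)
    assert np.nanmax(np.abs(traj.error_series)) < 0.4 * TWO_PI / 8


def test_circular_error_uses_wrapped_difference():
    """theta_hat = 0.05 vs theta = 2*pi - 0.05 gives error 0.1 through the
    mod(theta_hat - theta + pi, 2*pi) - pi formula."""
    est, act = 0.05, TWO_PI - 0.05
    err = np.mod(est - act + np.pi, TWO_PI) - np.pi
    assert err == pytest.approx(0.1)
    from innerstate._utils import circ_diff

    assert circ_diff(est, act) == pytest.approx(0.1)


def test_reflection_gauge_fixed_by_mse():
    m = 6
    labels = np.tile(np.arange(m), 30)
    ext = 96.0 * (1.0 - labels / (m - 1))  # reversed mapping: needs reflection
    traj = reconstruct_internal_variable(_model(labels, np.arange(m)), "linear",
                                         external=ext)
    assert traj.gauge["reflect"]
    assert np.nanmax(np.abs(traj.error_series)) < 1e-9


def test_missing_ordering_rejected():
    model = StateModel(labels=np.zeros(10, np.int64), frame_index=np.arange(10),
                       n_states=1)
    with pytest.raises(ValueError):
        reconstruct_internal_variable(model, "linear")


def test_gauge_preserves_error_magnitudes():
    """Gauge fixing changes the frame, not the size, of the mismatches."""
    m = 6
    rng = np.random.default_rng(0)
    labels = rng.integers(0, m, 300)
    ext = TWO_PI * labels / m
    model = _model(labels, np.arange(m), mode="cyclic")
    t1 = reconstruct_internal_variable(model, "circular", external=ext)
    t2 = reconstruct_internal_variable(model, "circular",
                                       external=np.mod(ext + 1.3, TWO_PI))
    assert np.nanmedian(np.abs(t1.error_series)) == pytest.approx(
        np.nanmedian(np.abs(t2.error_series)), abs=0.15)


# ---------------------------------------------------------------------------
# tuning curves
# ---------------------------------------------------------------------------

def test_neuron_with_too_few_events_excluded():
    m = 6
    labels = np.tile(np.arange(m), 20)
    traj = reconstruct_internal_variable(_model(labels, np.arange(m)), "linear")
    vals = np.zeros((1, len(labels)), np.uint8)
    vals[0, :4] = 1  # 4 events only
    act = ActivityMatrix(values=vals, bin_width=0.05, modality="imaging",
                         retained_frames=np.arange(len(labels)))
    with pytest.raises(InsufficientEvents):
        internal_tuning_curve(act, traj, 0)


def test_constant_rate_uniform_occupancy_flat_curve():
    m = 5
    labels = np.tile(np.arange(m), 100)
    traj = reconstruct_internal_variable(_model(labels, np.arange(m)), "linear")
    rng = np.random.default_rng(1)
    vals = (rng.random((1, len(labels))) < 0.3).astype(np.uint8)
    act = ActivityMatrix(values=vals, bin_width=0.05, modality="imaging",
                         retained_frames=np.arange(len(labels)))
    curve = internal_tuning_curve(act, traj, 0, n_bins=20)
    rate = curve.rate[np.isfinite(curve.rate)]
    assert rate.std() / rate.mean() < 0.25


def test_angle_curve_has_forty_bins():
    beh = BehaviorTrack(time=np.arange(100) * 0.1,
                        head_direction=np.mod(np.linspace(0, 12, 100), TWO_PI))
    vals = np.zeros((1, 100), np.uint8)
    vals[0, ::3] = 1
    act = ActivityMatrix(values=vals, bin_width=0.1, modality="ephys",
                         retained_frames=np.arange(100))
    curve = external_tuning_curve(act, beh, 0, variable="angle")
    assert curve.n_bins == 40
    assert curve.mode == "circular"


def test_positional_curve_excludes_track_ends_and_stationary_frames():
    n = 400
    beh = BehaviorTrack(time=np.arange(n) * 0.05,
                        position=np.linspace(0, 96, n),
                        running_direction=np.full(n, 1, np.int8),
                        speed=np.full(n, 20.0), track_length=96.0)
    beh.speed[:50] = 0.0  # stationary frames must not contribute
    vals = np.ones((1, n), np.uint8)
    act = ActivityMatrix(values=vals, bin_width=0.05, modality="imaging",
                         retained_frames=np.arange(n))
    curve = external_tuning_curve(act, beh, 0, variable="position", direction=1)
    assert curve.n_bins == 20  # 24 four-cm bins minus 2 at each end
    stationary_occ = curve.raw_occupancy[0]
    assert stationary_occ < 0.05 * 50  # the zeroed-speed stretch is filtered out


def test_no_running_gives_flagged_empty_curve():
    n = 50
    beh = BehaviorTrack(time=np.arange(n) * 0.05, position=np.zeros(n),
                        running_direction=np.zeros(n, np.int8), speed=np.zeros(n),
                        track_length=96.0)
    act = ActivityMatrix(values=np.ones((1, n), np.uint8), bin_width=0.05,
                         modality="imaging", retained_frames=np.arange(n))
    curve = external_tuning_curve(act, beh, 0, variable="position", direction=1)
    assert np.all(np.isnan(curve.rate))


def test_smoothed_rate_matches_bruteforce_kernel_sum():
    """Smoothed positional rate equals a direct truncated-Gaussian kernel sum
    over the raw occupancy and count maps."""
    rng = np.random.default_rng(2)
    n = 2400  # 2 min at 20 Hz
    pos = np.mod(np.linspace(0, 4 * 96, n), 2 * 96)
    pos = np.where(pos > 96, 2 * 96 - pos, pos)
    beh = BehaviorTrack(time=np.arange(n) * 0.05, position=pos,
                        running_direction=np.full(n, 1, np.int8),
                        speed=np.full(n, 20.0), track_length=96.0)
    vals = (rng.random((5, n)) < 0.1).astype(np.uint8)
    act = ActivityMatrix(values=vals, bin_width=0.05, modality="imaging",
                         retained_frames=np.arange(n))
    kern = np.exp(-0.5 * (np.arange(-2, 3) / 1.5) ** 2)
    kern /= kern.sum()
    for neuron in range(5):
        curve = external_tuning_curve(act, beh, neuron, variable="position", direction=1)
        occ, cnt = curve.raw_occupancy, curve.raw_counts
        for b in range(curve.n_bins):
            num = den = 0.0
            wsum = 0.0
            for o, tap in enumerate(kern):
                j = b + o - 2
                if 0 <= j < curve.n_bins:
                    num += tap * cnt[j]
                    den += tap * occ[j]
                    wsum += tap
            expect = (num / wsum) / (den / wsum)
            assert curve.rate[b] == pytest.approx(expect, rel=1e-9)


# ---------------------------------------------------------------------------
# information
# ---------------------------------------------------------------------------

def test_uniform_rate_zero_information():
    occ = np.ones(8)
    cnt = np.full(8, 3.0)
    assert information_from_counts(occ, cnt) == pytest.approx(0.0, abs=1e-12)


def test_concentrated_events_give_log2_nbins():
    """All events in 1 of 8 equal-occupancy bins: 3 bits/event."""
    occ = np.ones(8)
    cnt = np.zeros(8)
    cnt[3] = 24
    assert information_from_counts(occ, cnt) == pytest.approx(3.0)


def test_information_matches_direct_summation():
    rng = np.random.default_rng(3)
    occ = rng.uniform(0.5, 2.0, 20)
    cnt = rng.poisson(3.0, 20).astype(float)
    p = occ / occ.sum()
    r = cnt / occ
    rbar = (p * r).sum()
    expect = sum(pi * (ri / rbar) * np.log2(ri / rbar)
                 for pi, ri in zip(p, r) if ri > 0)
    assert information_from_counts(occ, cnt) == pytest.approx(expect, abs=1e-12)


@settings(deadline=None, max_examples=30)
@given(st.lists(st.integers(0, 20), min_size=4, max_size=30))
def test_information_non_negative(counts):
    occ = np.ones(len(counts))
    cnt = np.asarray(counts, float)
    if cnt.sum() == 0:
        return
    assert information_from_counts(occ, cnt) >= -1e-12


def test_information_invariant_to_bin_relabeling():
    rng = np.random.default_rng(4)
    occ = rng.uniform(0.5, 2.0, 12)
    cnt = rng.poisson(2.0, 12).astype(float)
    perm = rng.permutation(12)
    assert information_from_counts(occ, cnt) == pytest.approx(
        information_from_counts(occ[perm], cnt[perm]), abs=1e-12)


def test_information_shuffle_significance():
    rng = np.random.default_rng(5)
    occ = np.ones(20)
    cnt = np.zeros(20)
    cnt[7] = 50  # sharply tuned
    info, p, sig = information_per_event(_curve(cnt, "linear", occupancy=occ),
                                         n_shuffles=200, seed=0)
    assert sig and p < 0.05
    flat = rng.multinomial(60, np.ones(20) / 20).astype(float)
    info2, p2, sig2 = information_per_event(_curve(flat, "linear", occupancy=occ),
                                            n_shuffles=200, seed=0)
    assert not sig2


def test_information_requires_five_events():
    occ = np.ones(8)
    cnt = np.zeros(8)
    cnt[0] = 4
    with pytest.raises(InsufficientEvents):
        information_per_event(_curve(cnt, "linear", occupancy=occ), n_shuffles=10)


# ---------------------------------------------------------------------------
# field statistics
# ---------------------------------------------------------------------------

def test_delta_curve_width_one_rayleigh_one():
    rate = np.zeros(40)
    rate[13] = 5.0
    stats = field_stats(_curve(rate))
    assert stats["width"] == 1
    assert stats["rayleigh_length"] == pytest.approx(1.0)


def test_uniform_circular_curve_zero_rayleigh():
    stats = field_stats(_curve(np.ones(40)))
    assert stats["rayleigh_length"] == pytest.approx(0.0, abs=1e-12)


def test_von_mises_rayleigh_length_matches_bessel_ratio():
    """Rayleigh length of a von-Mises-shaped curve equals I1(kappa)/I0(kappa)."""
    from scipy.special import i0, i1

    n = 3600
    centers = (np.arange(n) + 0.5) * TWO_PI / n
    for kappa in (0.5, 2.0, 5.0):
        rate = np.exp(kappa * np.cos(centers - 1.0))
        stats = field_stats(_curve(rate))
        assert stats["rayleigh_length"] == pytest.approx(i1(kappa) / i0(kappa), abs=1e-3)
        assert stats["rayleigh_angle"] == pytest.approx(1.0, abs=1e-6)


def test_all_zero_curve_undefined_stats():
    stats = field_stats(_curve(np.zeros(20)))
    assert np.isnan(stats["width"]) and np.isnan(stats["rayleigh_length"])


# ---------------------------------------------------------------------------
# bidirectionality
# ---------------------------------------------------------------------------

def test_identical_maps_full_overlap():
    r = _curve(np.array([1.0, 3.0, 2.0, 0.5, 1.5]), "linear")
    assert bidirectionality(r, r).value == pytest.approx(1.0)


def test_disjoint_supports_zero_overlap():
    a = _curve(np.array([2.0, 3.0, 0.0, 0.0, 0.0, 0.0]), "linear", counts=np.array([3., 3, 0, 0, 0, 0]))
    b = _curve(np.array([0.0, 0.0, 0.0, 0.0, 3.0, 2.0]), "linear", counts=np.array([0., 0, 0, 0, 3, 3]))
    assert bidirectionality(a, b).value == pytest.approx(0.0)


def test_bidirectionality_matches_direct_formula():
    rng = np.random.default_rng(6)
    for variant in ("position", "phase-flipped"):
        r = rng.uniform(0, 2, 20)
        l = rng.uniform(0, 2, 20)
        res = bidirectionality(_curve(r, "linear"), _curve(l, "linear"), variant=variant)
        lv = l[::-1] if variant == "phase-flipped" else l
        pr = 20 * r / r.sum()
        pl = 20 * lv / lv.sum()
        expect = 2 * np.minimum(pr, pl).sum() / (pr + pl).sum()
        assert res.value == pytest.approx(expect, abs=1e-12)


@settings(deadline=None, max_examples=25)
@given(st.lists(st.floats(0.0, 10.0), min_size=5, max_size=20),
       st.lists(st.floats(0.0, 10.0), min_size=5, max_size=20))
def test_bidirectionality_bounded(r, l):
    n = min(len(r), len(l))
    r, l = np.asarray(r[:n]) + 0.01, np.asarray(l[:n]) + 0.01
    cnt = np.full(n, 2.0)  # enough events for the >=5 gate
    value = bidirectionality(_curve(r, "linear", counts=cnt),
                             _curve(l, "linear", counts=cnt)).value
    assert -1e-12 <= value <= 1 + 1e-12
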