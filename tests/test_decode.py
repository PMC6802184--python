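"""Decoder suite: likelihood decoding, templates, gauges and shuffle tests."""

import numpy as np
import pytest

import innerstate as ins
from innerstate._utils import TWO_PI, circ_diff
from innerstate.containers import ActivityMatrix, DecodeResult, TuningCurve
from innerstate.decode import (
    MLDecoder,
    across_structure_decode,
    explained_variance,
    fix_gauge,
    ml_decode,
    nn_phase_decode,
    phase_time_variability,
    shuffle_test_decoding,
    template_bins,
    template_decode,
)
from innerstate.tuning import reconstruct_internal_variable


def _circ_curves(n_neurons=20, n_bins=40, kappa=4.0, peak=20.0, seed=0):
    rng = np.random.default_rng(seed)
    centers = (np.arange(n_bins) + 0.5) * TWO_PI / n_bins
    pref = rng.uniform(0, TWO_PI, n_neurons)
    rates = 0.5 + peak * np.exp(kappa * (np.cos(centers[None, :] - pref[:, None]) - 1))
    return [TuningCurve(bin_centers=centers, occupancy=np.ones(n_bins),
                        event_counts=rates[i], rate=rates[i], mode="circular",
                        source="external") for i in range(n_neurons)], rates, centers


def test_ml_decodes_matching_pattern():
    """A frame exactly matching one bin's expected pattern, with the other
    bins orthogonal, decodes to that bin."""
    n_bins = 4
    centers = np.arange(n_bins, dtype=float)
    rates = np.full((8, n_bins), 1e-3)
    for b in range(n_bins):
        rates[2 * b:2 * b + 2, b] = 10.0
    dec = MLDecoder(mode="linear").fit(rates, bin_centers=centers)
    frame = np.zeros((1, 8))
    frame[0, 4:6] = 1  # the bin-2 pattern
    assert dec.predict(frame, bin_width=0.1)[0] == 2.0


def test_ml_equals_bruteforce_likelihood_maximization():
    """Vectorized decoding equals direct per-frame evaluation of the
    independent-Poisson log-likelihood on a frame-by-bin grid."""
    rng = np.random.default_rng(1)
    curves, rates, centers = _circ_curves(15, 30, seed=1)
    frames = (rng.random((100, 15)) < 0.3).astype(float)
    dt = 0.1
    dec = MLDecoder().fit(curves)
    got = dec.predict(frames, bin_width=dt)
    lam = np.maximum(rates, 1e-3)
    for t in range(100):
        if frames[t].sum() == 0:
            assert np.isnan(got[t])
            continue
        ll = [np.sum(frames[t] * np.log(lam[:, b]) - dt * lam[:, b])
              for b in range(30)]
        assert got[t] == centers[int(np.argmax(ll))]


def test_ml_all_zero_frame_undefined():
    curves, _, _ = _circ_curves(10, 20)
    dec = MLDecoder().fit(curves)
    out = dec.predict(np.zeros((3, 10)), bin_width=0.1)
    assert np.all(np.isnan(out))


def test_ml_decode_recovers_planted_heading():
    rng = np.random.default_rng(2)
    curves, rates, centers = _circ_curves(40, 40, seed=2)
    true = rng.uniform(0, TWO_PI, 400)
    which = np.clip((true / TWO_PI * 40).astype(int), 0, 39)
    p = 1 - np.exp(-rates[:, which].T * 0.1)
    frames = (rng.random(p.shape) < p).astype(float)
    r = ml_decode(frames, curves, mode="circular", actual=true, bin_width=0.1)
    assert np.nanmedian(np.abs(r.error_series)) < np.deg2rad(15)


def test_gauge_search_never_hurts():
    rng = np.random.default_rng(3)
    decoded = rng.uniform(0, TWO_PI, 200)
    actual = np.mod(decoded + 2.0, TWO_PI)  # pure rotation offset
    _, gauge, _, mse = fix_gauge(decoded, actual, "circular", n_offsets=40)
    ident_mse = float(np.mean(circ_diff(decoded, actual) ** 2))
    assert mse <= ident_mse + 1e-12
    assert mse < 0.05  # the rotation is found on the offset grid


def test_across_structure_self_decode_zero_error():
    from innerstate.containers import StateModel

    m = 8
    labels = np.repeat(np.tile(np.arange(m), 10), 5)
    model = StateModel(labels=labels, frame_index=np.arange(len(labels)), n_states=m,
                       ordering=np.arange(m), ordering_mode="linear")
    traj = reconstruct_internal_variable(model, "linear")
    ext = 96.0 * labels / (m - 1)
    r = across_structure_decode(traj, traj, ext, test_actual=ext)
    assert np.nanmax(np.abs(r.error_series)) < 1e-9


def test_across_structure_rejects_mode_mismatch():
    from innerstate.containers import InternalTrajectory

    a = InternalTrajectory(value=np.zeros(5), frame_index=np.arange(5), mode="linear")
    b = InternalTrajectory(value=np.zeros(5), frame_index=np.arange(5), mode="circular")
    with pytest.raises(ValueError):
        across_structure_decode(a, b, np.zeros(5))


def test_nn_phase_ties_resolve_to_earliest_frame():
    train = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 0.0]])  # duplicate points
    phase = np.array([10.0, 20.0, 30.0])
    r = nn_phase_decode(np.array([[0.0, 0.0]]), train, phase)
    assert r.decoded[0] == 10.0  # first (earliest) of the tied neighbors


def test_nn_phase_exact_match_returns_training_phase():
    rng = np.random.default_rng(4)
    train = rng.normal(0, 1, (50, 3))
    phase = rng.uniform(0, 96, 50)
    r = nn_phase_decode(train[[7]], train, phase)
    assert r.decoded[0] == phase[7]


def test_explained_variance_trivial_cases():
    rng = np.random.default_rng(5)
    actual = rng.integers(0, 20, 500).astype(float)
    assert explained_variance(actual, actual, seed=0) == pytest.approx(1.0)
    # decoded = an independent shuffle of actual: EV ~ 0
    ev = explained_variance(rng.permutation(actual), actual, n_shuffles=400, seed=0)
    assert abs(ev) < 0.1


def test_explained_variance_affine_invariant():
    rng = np.random.default_rng(6)
    actual = rng.integers(0, 20, 400).astype(float)
    decoded = actual + rng.normal(0, 2, 400)
    ev1 = explained_variance(decoded, actual, n_shuffles=200, seed=1)
    ev2 = explained_variance(4.0 * decoded - 7.0, 4.0 * actual - 7.0,
                             n_shuffles=200, seed=1)
    assert ev1 == pytest.approx(ev2, abs=1e-9)


def test_template_bins_conventions():
    beh, act, _ = ins.gen_linear_track_session("acc", n_neurons=30, duration=300.0,
                                               frame_rate=10.0, seed=6)
    for var in ("phase", "time", "speed_by_accel"):
        labels = template_bins(beh, var)
        used = labels[labels >= 0]
        assert used.min() >= 0 and used.max() <= 19
    # speed axis: slowing-down frames map to the upper half
    labels = template_bins(beh, "speed_by_accel")
    accel = np.gradient(beh.speed, beh.time)
    running = beh.running_direction != 0
    slowing = running & (accel < 0) & (labels >= 0)
    assert np.all(labels[slowing] >= 10)


def test_template_requires_two_minutes():
    beh, act, _ = ins.gen_linear_track_session("acc", n_neurons=20, duration=60.0,
                                               frame_rate=10.0, seed=6)
    with pytest.raises(ValueError):
        template_decode(act, beh)


def test_perfect_decode_gives_minimal_p():
    rng = np.random.default_rng(7)
    actual = rng.uniform(0, 96, 300)
    r = DecodeResult(decoded=actual.copy(), actual=actual, mse=0.0, mode="linear")
    p = shuffle_test_decoding(r, n_shuffles=100, seed=0)
    assert p == pytest.approx(1.0 / 101.0)


def test_shuffle_p_calibrated_under_null():
    """A random decoded series yields approximately uniform p-values
    (Kolmogorov-Smirnov vs uniform at alpha = 0.01 over 200 replicates)."""
    from scipy.stats import kstest

    rng = np.random.default_rng(8)
    pvals = []
    for rep in range(200):
        actual = rng.uniform(0, 96, 60)
        decoded = rng.uniform(0, 96, 60)
        mse = float(np.mean((decoded - actual) ** 2))
        # observed gauge-fixed mse, as the decoders report
        _, _, _, mse = fix_gauge(decoded, actual, "linear")
        r = DecodeResult(decoded=decoded, actual=actual, mse=mse, mode="linear")
        pvals.append(shuffle_test_decoding(r, n_shuffles=120, seed=rep))
    assert kstest(pvals, "uniform").pvalue > 0.01


def test_shuffle_test_requires_enough_shuffles():
    r = DecodeResult(decoded=np.arange(10.0), actual=np.arange(10.0), mse=0.0)
    with pytest.raises(ValueError):
        shuffle_test_decoding(r, n_shuffles=10)


def test_variability_separates_phase_from_time_coding():
    """Planted phase cells show SD_P > SD_T; hand-built time-tuned cells (rate
    a function of time-in-traversal) show the opposite sign, and at least 90%
    of the combined population is correctly classified by the sign."""
    rng = np.random.default_rng(10)
    beh, act, truth = ins.gen_linear_track_session("acc", n_neurons=150, duration=600.0,
                                                   frame_rate=10.0, seed=9)
    correct = total = 0
    for n in np.flatnonzero(truth.tuning_class == "phase"):
        if act.values[n].sum() < 30:  # SDs of near-silent cells are noise
            continue
        try:
            v = phase_time_variability(act, beh, n)
        except ValueError:
            continue
        assert v.joint_rate_map.shape == (20, 20)
        total += 1
        correct += v.sd_p > v.sd_t
    tbins = template_bins(beh, "time")
    for pref in (3, 6, 9, 12, 15, 18):
        rate = np.where(np.abs(tbins - pref) <= 1, 3.0, 0.05)
        rate[tbins < 0] = 0.0
        vals = (rng.random(beh.n_frames) < rate * 0.1).astype(np.uint8)
        m = ActivityMatrix(values=vals[None, :], bin_width=0.1, modality="imaging",
                           retained_frames=np.arange(beh.n_frames))
        try:
            v = phase_time_variability(m, beh, 0)
        except ValueError:  # late-time cells may never fire often enough
            continue
        total += 1
        correct += v.sd_t > v.sd_p
    assert total >= 30
    assert correct / total >= 0.9
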