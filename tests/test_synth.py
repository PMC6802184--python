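"""Generator correctness: determinism, planted-tuning recovery, roster overlap."""

import numpy as np
import pytest

import innerstate as ins
from innerstate.containers import DIR_LEFT, DIR_RIGHT, ActivityMatrix
from innerstate.synth import TRACK_LENGTH, roster_of


def test_positions_stay_on_track():
    beh, act, truth = ins.gen_linear_track_session("ca1", n_neurons=50, duration=120.0,
                                                   frame_rate=20.0, seed=7)
    assert beh.position.min() >= 0.0
    assert beh.position.max() <= TRACK_LENGTH
    assert beh.n_frames == act.n_bins == 2400


def test_same_seed_bit_identical():
    a = ins.gen_linear_track_session("acc", n_neurons=40, duration=60.0, frame_rate=10.0,
                                     seed=5)
    b = ins.gen_linear_track_session("acc", n_neurons=40, duration=60.0, frame_rate=10.0,
                                     seed=5)
    assert np.array_equal(a[1].values, b[1].values)
    assert np.array_equal(a[0].position, b[0].position)
    assert np.array_equal(a[2].preferred, b[2].preferred)


def test_rejects_bad_arguments():
    with pytest.raises(ValueError):
        ins.gen_linear_track_session("ca1", duration=-5.0)
    with pytest.raises(ValueError):
        ins.gen_linear_track_session("ca1", frame_rate=0.0, duration=10.0)
    with pytest.raises(ValueError):
        ins.gen_hd_session(rem_fraction=1.5)
    with pytest.raises(ValueError):
        ins.gen_multiday_sessions(n_days=1)


def test_acc_phase_cells_recover_planted_phase_by_binning():
    """Direct binning of generated events against planted phase: the empirical
    rate-map peak lands within one bin of the planted preferred phase for at
    least 90% of phase cells."""
    beh, act, truth = ins.gen_linear_track_session("acc", n_neurons=300, duration=900.0,
                                                   frame_rate=10.0, seed=3)
    phase = beh.phase()
    running = np.isfinite(phase)
    n_bins = 20
    edges = np.linspace(0, TRACK_LENGTH, n_bins + 1)
    which = np.clip(np.digitize(phase[running], edges) - 1, 0, n_bins - 1)
    occ = np.bincount(which, minlength=n_bins)
    hits = 0
    cells = np.flatnonzero(truth.tuning_class == "phase")
    for i in cells:
        cnt = np.bincount(which, weights=act.values[i, running].astype(float),
                          minlength=n_bins)
        peak = np.argmax(cnt / occ)
        planted = min(int(truth.preferred[i] / (TRACK_LENGTH / n_bins)), n_bins - 1)
        hits += abs(peak - planted) <= 1
    assert hits / len(cells) >= 0.9


def test_hd_preferred_directions_recovered_by_binning():
    """Empirical preferred directions from wake spikes match the planted ones
    (circular correlation > 0.95)."""
    from innerstate._utils import circ_corr

    beh, act, truth = ins.gen_hd_session(n_neurons=50, duration=900.0, seed=4)
    edges = np.linspace(0, 2 * np.pi, 41)
    which = np.clip(np.digitize(beh.head_direction, edges) - 1, 0, 39)
    occ = np.bincount(which, minlength=40)
    centers = 0.5 * (edges[:-1] + edges[1:])
    empirical = np.empty(50)
    for i in range(50):
        cnt = np.bincount(which, weights=act.values[i].astype(float), minlength=40)
        rate = cnt / occ
        z = np.sum(rate * np.exp(1j * centers))
        empirical[i] = np.mod(np.angle(z), 2 * np.pi)
    assert circ_corr(empirical, truth.preferred) > 0.95


def test_hd_session_binning_conventions():
    beh, act, _ = ins.gen_hd_session(n_neurons=20, duration=30.0, seed=0)
    assert act.bin_width == 0.1
    assert set(np.unique(act.values)) <= {0, 1}
    beh0, act0, _ = ins.gen_hd_session(n_neurons=20, duration=0.0, seed=0)
    assert act0.n_bins == 0


def test_acc_maps_more_bidirectional_than_ca1():
    """ACC rate maps are symmetric under the direction flip that maps position
    to trajectory phase; CA1 direction-selective place maps are not."""
    from innerstate.tuning import InsufficientEvents, bidirectionality, external_tuning_curve

    values = {}
    for mode in ("ca1", "acc"):
        beh, act, truth = ins.gen_linear_track_session(
            mode, n_neurons=200, duration=600.0, frame_rate=10.0, seed=9)
        cells = np.flatnonzero(np.isin(truth.tuning_class, ("place", "phase")))
        vals = []
        for i in cells:
            try:
                r = external_tuning_curve(act, beh, i, "position", direction=DIR_RIGHT)
                l = external_tuning_curve(act, beh, i, "position", direction=DIR_LEFT)
                vals.append(bidirectionality(r, l, variant="phase-flipped").value)
            except (InsufficientEvents, ValueError):
                continue
        values[mode] = np.mean(vals)
    assert values["acc"] > values["ca1"]


def test_multiday_overlap_statistics():
    sessions = ins.gen_multiday_sessions(
        dict(mode="ca1", n_neurons=600, duration=10.0), n_days=4, overlap=0.5, seed=2)
    rosters = [roster_of(t) for _, _, t in sessions]
    # participation probability s = 2o/(1+o); Jaccard overlap concentrates
    # around o with binomial-scale fluctuations
    s = 2 * 0.5 / 1.5
    for i in range(4):
        for j in range(i + 1, 4):
            inter = (rosters[i] & rosters[j]).sum()
            union = (rosters[i] | rosters[j]).sum()
            jac = inter / union
            sd = np.sqrt(0.5 * (1 - 0.5) / union)  # binomial-scale spread
            assert abs(jac - 0.5) < 3 * sd + 0.05
    # full overlap -> identical rosters
    full = ins.gen_multiday_sessions(dict(mode="ca1", n_neurons=50, duration=10.0),
                                     n_days=2, overlap=1.0, seed=2)
    assert np.array_equal(roster_of(full[0][2]), roster_of(full[1][2]))


def test_multiday_preserves_tuning_of_retained_neurons():
    sessions = ins.gen_multiday_sessions(dict(mode="ca1", n_neurons=100, duration=10.0),
                                         n_days=2, overlap=0.6, seed=8)
    t0, t1 = sessions[0][2], sessions[1][2]
    both = roster_of(t0) & roster_of(t1)
    assert np.array_equal(t0.preferred[both], t1.preferred[both])
    assert np.array_equal(t0.tuning_class[both], t1.tuning_class[both])


def test_fluorescence_kernel_decay_defaults():
    from innerstate.synth import _INDICATOR_KERNELS

    assert _INDICATOR_KERNELS["GCaMP6s"][1] == 0.6
    assert _INDICATOR_KERNELS["GCaMP6f"][1] == 0.2
    with pytest.raises(ValueError):
        ins.gen_fluorescence_traces(
            ActivityMatrix(values=np.zeros((1, 10), np.uint8), bin_width=0.05,
                           modality="imaging"), indicator="GCaMP7")


def test_zero_events_give_baseline_only_traces():
    ev = ActivityMatrix(values=np.zeros((3, 400), np.uint8), bin_width=0.05,
                        modality="imaging")
    tr = ins.gen_fluorescence_traces(ev, "GCaMP6s", noise_sd=0.01, seed=1, drift_sd=0.02)
    # no transients: traces are zero-mean drift + noise
    assert abs(tr.traces.mean()) < 0.05
    assert tr.traces.std() < 0.06
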