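"""End-to-end synthetic validation studies.

Each study generates a session with planted ground truth, runs the full
unsupervised pipeline on the activity alone, and scores the result against
the planted structure.  The reproduction script and the validation tests
both run these; intermediate products are cached per study object so the
expensive stages (embedding, clustering) run once.

Problem sizes: linear-track sessions use 400 neurons and seven 3-minute trials
(21 min) at 20 Hz (CA1-like) or 10 Hz (ACC-like); head-direction sessions
use 50 cells for 30 min at 100-ms bins.  Track sessions embed with the
stage-2 neighbor fraction at the bottom of its working range because their
state clusters hold only one to two thousand frames.
"""

from __future__ import annotations

from functools import cached_property

import numpy as np

from .containers import DIR_LEFT, DIR_RIGHT, REM, WAKE
from .decode import (
    across_structure_decode,
    ml_decode,
    nn_phase_decode,
    shuffle_test_decoding,
    template_decode,
)
from .embedding import embed_two_stage
from .geometry import estimate_intrinsic_dimension, persistent_betti
from .pipelines import (
    analyze_states,
    linear_reconstruction,
    restrict_frames,
    ring_reconstruction,
    running_frames,
    winding_numbers,
)
from .preprocess import shuffle_control
from .states import cluster_states, segment_subtypes
from .synth import TRACK_LENGTH, gen_hd_session, gen_linear_track_session
from .tuning import (
    InsufficientEvents,
    external_tuning_curve,
    internal_information_loo,
    internal_tuning_curve,
    information_from_counts,
)

TRACK_KW = dict(n_neurons=400, duration=1260.0)  # seven 3-min trials
TRACK_P2 = 0.075
HD_KW = dict(n_neurons=50, duration=1800.0, bin_width=0.1)
TRACK_BIN_CM = TRACK_LENGTH / 20.0  # 20-bin convention of the positional curves


class TrackStudy:
    """Full pipeline on one synthetic linear-track session."""

    def __init__(self, mode: str, seed: int):
        self.mode = mode
        self.seed = int(seed)
        frame_rate = 20.0 if mode == "ca1" else 10.0
        self.behavior, self.activity, self.truth = gen_linear_track_session(
            mode, frame_rate=frame_rate, seed=self.seed, **TRACK_KW)

    @cached_property
    def embedding(self):
        return embed_two_stage(self.activity, p2=TRACK_P2, seed=self.seed)

    @cached_property
    def states(self):
        return analyze_states(self.embedding, self.activity, min_points=250,
                              seed=self.seed)

    # -- cycle motif --------------------------------------------------------

    def winding_median(self) -> float:
        w = winding_numbers(self.behavior, self.states)
        return float(np.median(w)) if len(w) else np.nan

    # -- running-state subtypes ---------------------------------------------

    def _running_states(self):
        lab = self.behavior.behavior_label[self.embedding.frame_index]
        out = []
        for s in range(self.states.model.n_states):
            sel = self.states.model.labels == s
            if sel.any() and (lab[sel] == "run").mean() > 0.5:
                out.append(s)
        return out

    def running_subtype_split(self):
        """Subtype split of the pooled running-state segments vs planted direction.

        Returns (n_subtypes, fraction of segments whose subtype matches the
        planted running direction).
        """
        run_states = self._running_states()
        segs = [g for g in self.states.segments if g.state in run_states]
        labs = segment_subtypes(self.activity, segs, self.embedding.frame_index)
        n_subtypes = int(len(np.unique(labs)))
        agree = tot = 0
        for g, sub in zip(segs, labs):
            d = self.behavior.running_direction[self.embedding.frame_index[g.members]]
            d = d[d != 0]
            if d.size == 0:
                continue
            major = 1 if (d == DIR_RIGHT).mean() >= 0.5 else -1
            tot += 1
            agree += int(major == (1 if sub == 1 else -1))
        frac = max(agree, tot - agree) / tot if tot else np.nan
        return n_subtypes, float(frac)

    # -- within-running-state fine structure --------------------------------

    @cached_property
    def recon_right(self):
        return linear_reconstruction(self.activity, self.behavior,
                                     running_frames(self.behavior, self.activity,
                                                    DIR_RIGHT), seed=self.seed)

    @cached_property
    def recon_left(self):
        return linear_reconstruction(self.activity, self.behavior,
                                     running_frames(self.behavior, self.activity,
                                                    DIR_LEFT), seed=self.seed)

    def dimension_slopes(self):
        """Correlation-dimension slope of each running-direction sub-embedding."""
        return (estimate_intrinsic_dimension(self.recon_right.embedding,
                                             seed=self.seed).slope,
                estimate_intrinsic_dimension(self.recon_left.embedding,
                                             seed=self.seed).slope)

    def running_betti(self):
        """Radius-stable Betti vector of the running-state sub-embedding.

        The sparse-cluster discard threshold scales with the sub-cloud size
        (about half the mean K-means cluster membership, floored at 10): the
        fixed 50-point cutoff assumes full-session cluster sizes and would
        discard most landmarks of a ~3k-frame sub-population, leaving
        coverage gaps that fragment beta_0.
        """
        n = self.recon_right.embedding.n_points
        return persistent_betti(self.recon_right.embedding,
                                min_cluster=max(10, n // 200), seed=self.seed)

    def tuning_recovery(self):
        """Internal tuning curves vs planted fields (rightward place cells).

        Returns (median peak mismatch in track bins, fraction of tuned cells
        whose internal curve correlates > 0.7 with the external curve,
        median |reconstructed - actual| position in cm).
        """
        rec = self.recon_right
        lo, hi = rec.trajectory.gauge["scale"]
        cells = np.flatnonzero((self.truth.tuning_class == "place")
                               & (self.truth.direction == DIR_RIGHT))
        mismatches, cors = [], []
        for n in cells:
            try:
                ic = internal_tuning_curve(self.activity, rec.trajectory, n, n_bins=20)
            except InsufficientEvents:
                continue
            ec = external_tuning_curve(self.activity, self.behavior, n, "position",
                                       direction=DIR_RIGHT)
            cm = lo + ic.bin_centers * (hi - lo)
            mismatches.append(abs(cm[np.nanargmax(ic.rate)] - self.truth.preferred[n]))
            on_ext = np.interp(ec.bin_centers, cm, np.nan_to_num(ic.rate))
            ok = np.isfinite(ec.rate)
            if ok.sum() > 3:
                cors.append(np.corrcoef(on_ext[ok], ec.rate[ok])[0, 1])
        err = float(np.nanmedian(np.abs(rec.trajectory.error_series)))
        return (float(np.median(mismatches) / TRACK_BIN_CM),
                float(np.mean(np.asarray(cors) > 0.7)), err)

    # -- opposite-direction phase decoding ----------------------------------

    def nn_phase(self, n_shuffles: int = 200):
        """Train on one running direction, test on the other.

        Returns (median |error| as a fraction of the track span, shuffle p).
        """
        phase = self.behavior.phase()[self.embedding.frame_index]
        rdir = self.behavior.running_direction[self.embedding.frame_index]
        train, test = rdir == DIR_RIGHT, rdir == DIR_LEFT
        r = nn_phase_decode(self.embedding.coords[test], self.embedding.coords[train],
                            phase[train], test_actual=phase[test])
        p = shuffle_test_decoding(r, n_shuffles=max(100, n_shuffles), seed=self.seed)
        med = float(np.nanmedian(np.abs(r.error_series))) / TRACK_LENGTH
        return med, p

    def template_explained_variance(self):
        return {var: template_decode(self.activity, self.behavior, variable=var,
                                     seed=self.seed).explained_variance
                for var in ("phase", "time", "speed_by_accel")}

    # -- shuffle controls ----------------------------------------------------

    def shuffle_state_count(self, mode: str) -> int:
        sh = shuffle_control(self.activity, mode, seed=self.seed)
        emb = embed_two_stage(sh, p2=TRACK_P2, seed=self.seed)
        return cluster_states(emb, min_points=250, seed=self.seed).n_states


class HDStudy:
    """Full pipeline on one synthetic head-direction session."""

    def __init__(self, seed: int, rem_fraction: float = 0.0):
        self.seed = int(seed)
        self.rem_fraction = rem_fraction
        self.behavior, self.activity, self.truth = gen_hd_session(
            seed=self.seed, rem_fraction=rem_fraction, **HD_KW)

    @cached_property
    def embedding(self):
        wake = np.flatnonzero(self.behavior.episode == WAKE)
        sub = restrict_frames(self.activity, wake)
        return embed_two_stage(sub, seed=self.seed)

    def betti(self):
        return persistent_betti(self.embedding, seed=self.seed)

    def sleep_to_wake_error_deg(self) -> float:
        """Train internal curves exclusively on REM, decode wake heading.

        Returns the median absolute circular error (degrees) after fixing the
        ring's rotation/reflection gauge.
        """
        if self.rem_fraction <= 0:
            raise ValueError("study was generated without REM sleep")
        rem = np.flatnonzero(self.behavior.episode == REM)
        rec = ring_reconstruction(self.activity, self.behavior, frames=rem,
                                  seed=self.seed)
        neurons = sorted(rec.curves)
        curves = [rec.curves[n] for n in neurons]
        wake = restrict_frames(self.activity,
                               np.flatnonzero(self.behavior.episode == WAKE))
        frames = wake.retained_frames
        test = self.activity.values[np.ix_(neurons, frames)].T
        r = ml_decode(test, curves, mode="circular",
                      actual=self.behavior.head_direction[frames],
                      bin_width=self.activity.bin_width)
        return float(np.degrees(np.nanmedian(np.abs(r.error_series))))


def disc_control_slope(seed: int = 0) -> float:
    """Correlation-dimension slope of a uniform 2-d disc (analytic area law)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    r = np.sqrt(rng.uniform(0, 1, 2000))
    th = rng.uniform(0, 2 * np.pi, 2000)
    return estimate_intrinsic_dimension(np.c_[r * np.cos(th), r * np.sin(th)],
                                        seed=seed).slope


def across_session_position_error(study_a: TrackStudy, study_b: TrackStudy) -> float:
    """Decode session B's position from session A's state-position map (cm)."""
    rec_a, rec_b = study_a.recon_right, study_b.recon_right
    r = across_structure_decode(
        rec_b.trajectory, rec_a.trajectory,
        study_a.behavior.position[rec_a.frames],
        test_actual=study_b.behavior.position[rec_b.frames])
    return float(np.nanmedian(np.abs(r.error_series)))


def loo_information_rank_corr(seed: int = 11, n_cells: int = 40) -> float:
    """Leave-one-out internal information vs external spatial information.

    A compact, dense linear-track session (120 neurons, 15 min at 10 Hz,
    elevated rates so the frame filter keeps enough running frames) is
    analyzed per cell: the cell is excluded, the rest embedded and clustered
    into 8 states, and its shuffle-corrected state information computed;
    external information uses 8 position bins over the same frames.  Returns
    the Spearman rank correlation across cells.
    """
    from scipy.stats import spearmanr

    params = dict(peak_rate=(2.0, 4.0), pause_peak_rate=(2.0, 4.0),
                  baseline_rate=(0.08, 0.15))
    beh, act, truth = gen_linear_track_session(
        "ca1", n_neurons=120, duration=900.0, frame_rate=10.0, seed=seed,
        params=params)
    frames = np.intersect1d(running_frames(beh, act, DIR_RIGHT), act.retained_frames)
    internal, external = [], []
    for n in range(0, act.n_neurons, max(1, act.n_neurons // n_cells)):
        try:
            r = internal_information_loo(act, n, frames=frames, seed=seed)
        except (ValueError, InsufficientEvents):
            continue
        which = np.clip((beh.position[frames] / (TRACK_LENGTH / 8)).astype(int), 0, 7)
        occ = np.bincount(which, minlength=8).astype(float)
        cnt = np.bincount(which, weights=act.values[n, frames].astype(float),
                          minlength=8)
        try:
            ext = information_from_counts(occ, cnt)
        except InsufficientEvents:
            continue
        internal.append(r["corrected"])
        external.append(ext)
    return float(spearmanr(internal, external).statistic)
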