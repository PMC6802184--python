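"""Population decoders with explained variance and shuffle statistics.

Four decoder families: a maximum-likelihood decoder assuming independent
Poisson events given the tuning curves (used e.g. to decode wake behavior
from sleep-derived internal curves); an across-structure decoder that maps
internal coordinates between two sessions under the structure's symmetry
group; a nearest-neighbor trajectory-phase decoder trained on one running
direction and tested on the other; and correlation-template decoders for
trajectory phase, time-in-traversal and speed-by-acceleration.  Decoding
error is compared against label-shuffled nulls, with the residual gauge
degrees of freedom re-fit per shuffle.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from ._utils import TWO_PI, circ_diff
from .containers import (
    ActivityMatrix,
    BehaviorTrack,
    DecodeResult,
    InternalTrajectory,
    TuningCurve,
    VariabilityResult,
)

RATE_FLOOR = 1e-3  # events/s floor of the Poisson likelihood
N_TEMPLATE_BINS = 20
TEMPLATE_SPEED_MAX = 40.0  # cm/s, top of the speed-by-acceleration axis


# ---------------------------------------------------------------------------
# gauge handling
# ---------------------------------------------------------------------------

def _apply_gauge_circ(theta, reflect, rot):
    base = np.mod(-theta, TWO_PI) if reflect else theta
    return np.mod(base + rot, TWO_PI)


def fix_gauge(decoded: np.ndarray, actual: np.ndarray, mode: str,
              n_offsets: int = 40):
    """Best reflection (linear) or rotation+reflection (circular) vs actual.

    Returns (adjusted decoded, gauge dict, error series, mse).  The search
    never increases MSE relative to identity, which is always a candidate.
    """
    ok = np.isfinite(decoded) & np.isfinite(actual)
    if mode == "circular":
        best = None
        for reflect in (False, True):
            for k in range(n_offsets):
                rot = TWO_PI * k / n_offsets
                cand = _apply_gauge_circ(decoded, reflect, rot)
                mse = float(np.mean(circ_diff(cand[ok], actual[ok]) ** 2))
                if best is None or mse < best[0]:
                    best = (mse, reflect, rot, cand)
        mse, reflect, rot, cand = best
        err = np.full(len(decoded), np.nan)
        err[ok] = circ_diff(cand[ok], actual[ok])
        return cand, {"reflect": reflect, "rotation": rot}, err, mse
    if mode == "linear":
        lo = np.nanmin(actual[ok])
        hi = np.nanmax(actual[ok])
        best = None
        for reflect in (False, True):
            cand = (lo + hi) - decoded if reflect else decoded
            mse = float(np.mean((cand[ok] - actual[ok]) ** 2))
            if best is None or mse < best[0]:
                best = (mse, reflect, cand)
        mse, reflect, cand = best
        err = np.full(len(decoded), np.nan)
        err[ok] = cand[ok] - actual[ok]
        return cand, {"reflect": reflect}, err, mse
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# maximum-likelihood decoder
# ---------------------------------------------------------------------------

class MLDecoder(BaseEstimator):
    """Independent-Poisson maximum-likelihood decoder over tuning-curve bins.

    ``fit`` takes the training tuning curves (one per neuron, shared bin
    grid) — internal or external, wake or sleep; ``predict`` maximizes, per
    test frame, sum_i [n_i log(lambda_i(b)) - lambda_i(b) dt] over bins b,
    with rates floored at ``rate_floor``.  All-zero frames decode as NaN and
    are excluded from error statistics.
    """

    def __init__(self, mode: str = "circular", rate_floor: float = RATE_FLOOR):
        self.mode = mode
        self.rate_floor = rate_floor

    def fit(self, curves: list[TuningCurve] | np.ndarray, y=None,
            bin_centers: np.ndarray | None = None):
        if isinstance(curves, np.ndarray):
            rates = np.asarray(curves, dtype=float)
            if bin_centers is None:
                raise ValueError("bin_centers required with a raw rate matrix")
            centers = np.asarray(bin_centers, dtype=float)
        else:
            rates = np.vstack([np.nan_to_num(c.rate, nan=0.0) for c in curves])
            centers = curves[0].bin_centers
        self.rates_ = np.maximum(rates, self.rate_floor)
        self.bin_centers_ = centers
        self.log_rates_ = np.log(self.rates_)
        return self

    def predict(self, X, bin_width: float | None = None) -> np.ndarray:
        if isinstance(X, ActivityMatrix):
            frames = X.values.T.astype(float)
            bin_width = X.bin_width
        else:
            frames = np.asarray(X, dtype=float)
            if bin_width is None:
                raise ValueError("bin_width required with a raw frame matrix")
        loglik = frames @ self.log_rates_ - bin_width * self.rates_.sum(axis=0)[None, :]
        decoded_bin = np.argmax(loglik, axis=1)
        decoded = self.bin_centers_[decoded_bin].astype(float)
        decoded[frames.sum(axis=1) == 0] = np.nan
        return decoded


def ml_decode(test, curves, mode: str = "circular", actual: np.ndarray | None = None,
              bin_width: float | None = None, bin_centers: np.ndarray | None = None,
              ) -> DecodeResult:
    """Decode each test frame by Poisson maximum likelihood over the curves."""
    dec = MLDecoder(mode=mode).fit(curves, bin_centers=bin_centers)
    decoded = dec.predict(test, bin_width=bin_width)
    result = DecodeResult(decoded=decoded, actual=actual, mode=mode,
                          valid=np.isfinite(decoded))
    if actual is not None:
        adj, gauge, err, mse = fix_gauge(decoded, np.asarray(actual, float), mode,
                                         n_offsets=len(dec.bin_centers_))
        result.decoded, result.gauge, result.error_series, result.mse = adj, gauge, err, mse
    return result


# ---------------------------------------------------------------------------
# across-structure decoder
# ---------------------------------------------------------------------------

def _reference_association(ref_internal: InternalTrajectory, ref_external: np.ndarray,
                           n_bins: int = 40):
    """Map each internal level/bin of the reference session to its external value."""
    v = ref_internal.value
    ok = np.isfinite(v) & np.isfinite(ref_external)
    if ref_internal.mode == "linear":
        levels = np.unique(v[ok])
        assoc = np.array([np.mean(ref_external[ok & (v == lvl)]) for lvl in levels])
        return levels, assoc
    edges = np.linspace(0.0, TWO_PI, n_bins + 1)
    which = np.clip(np.digitize(v[ok], edges) - 1, 0, n_bins - 1)
    assoc = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            z = np.exp(1j * ref_external[ok][sel]).mean()
            assoc[b] = np.mod(np.angle(z), TWO_PI)
    # fill empty bins from the nearest occupied one around the ring
    occ = np.flatnonzero(np.isfinite(assoc))
    for b in np.flatnonzero(~np.isfinite(assoc)):
        d = np.minimum(np.abs(occ - b), n_bins - np.abs(occ - b))
        assoc[b] = assoc[occ[np.argmin(d)]]
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, assoc


def across_structure_decode(test_internal: InternalTrajectory,
                            ref_internal: InternalTrajectory,
                            ref_external: np.ndarray,
                            test_actual: np.ndarray | None = None,
                            n_offsets: int = 40) -> DecodeResult:
    """Decode one session's behavior from another session's state-behavior map.

    Each test frame's internal coordinate is matched to the reference state
    with the nearest internal coordinate under the best symmetry element
    (reflection for a line, rotation+reflection for a ring, searched on the
    coordinate grid); the decoded value is that reference state's associated
    external value.  The symmetry is fixed by minimizing the decoding MSE
    when ``test_actual`` is available, identity otherwise.
    """
    if test_internal.mode != ref_internal.mode:
        raise ValueError("sessions have incompatible internal modes "
                         f"({test_internal.mode} vs {ref_internal.mode})")
    mode = test_internal.mode
    levels, assoc = _reference_association(ref_internal, ref_external)
    v = test_internal.value

    def decode_with(vv):
        ok = np.isfinite(vv)
        out = np.full(len(vv), np.nan)
        if mode == "linear":
            idx = np.argmin(np.abs(vv[ok, None] - levels[None, :]), axis=1)
        else:
            d = np.abs(circ_diff(vv[ok, None], levels[None, :]))
            idx = np.argmin(d, axis=1)
        out[ok] = assoc[idx]
        return out

    candidates = []
    if mode == "linear":
        for reflect in (False, True):
            candidates.append(({"reflect": reflect}, (1.0 - v) if reflect else v))
    else:
        for reflect in (False, True):
            for k in range(n_offsets):
                rot = TWO_PI * k / n_offsets
                candidates.append(({"reflect": reflect, "rotation": rot},
                                   _apply_gauge_circ(v, reflect, rot)))
    best = None
    for gauge, vv in candidates:
        decoded = decode_with(vv)
        if test_actual is None:
            best = (np.nan, gauge, decoded)
            break
        act = np.asarray(test_actual, float)
        ok = np.isfinite(decoded) & np.isfinite(act)
        err = circ_diff(decoded[ok], act[ok]) if mode == "circular" else decoded[ok] - act[ok]
        mse = float(np.mean(err**2))
        if best is None or mse < best[0]:
            best = (mse, gauge, decoded)
    mse, gauge, decoded = best
    result = DecodeResult(decoded=decoded, actual=test_actual, mode=mode, gauge=gauge,
                          valid=np.isfinite(decoded))
    if test_actual is not None:
        act = np.asarray(test_actual, float)
        err = np.full(len(decoded), np.nan)
        ok = np.isfinite(decoded) & np.isfinite(act)
        err[ok] = circ_diff(decoded[ok], act[ok]) if mode == "circular" \
            else decoded[ok] - act[ok]
        result.error_series, result.mse = err, mse
    return result


class AcrossStructureDecoder(BaseEstimator):
    """Estimator form of :func:`across_structure_decode`.

    ``fit`` stores the reference session's internal-to-external association;
    ``predict`` maps a test session's internal trajectory to decoded external
    values under the best symmetry element.
    """

    def __init__(self, n_offsets: int = 40):
        self.n_offsets = n_offsets

    def fit(self, ref_internal: InternalTrajectory, ref_external: np.ndarray):
        self.ref_internal_ = ref_internal
        self.ref_external_ = np.asarray(ref_external, float)
        return self

    def predict(self, test_internal: InternalTrajectory,
                test_actual: np.ndarray | None = None) -> DecodeResult:
        return across_structure_decode(test_internal, self.ref_internal_,
                                       self.ref_external_, test_actual,
                                       n_offsets=self.n_offsets)


# ---------------------------------------------------------------------------
# nearest-neighbor phase decoder
# ---------------------------------------------------------------------------

def nn_phase_decode(test_coords: np.ndarray, train_coords: np.ndarray,
                    train_phase: np.ndarray,
                    test_actual: np.ndarray | None = None) -> DecodeResult:
    """Decode trajectory phase from the opposite running direction.

    Each test point's nearest neighbor among the training points (the other
    direction's frames in the reduced space) supplies the decoded phase.
    Distance ties resolve to the earliest training frame.
    """
    test_coords = np.asarray(test_coords, float)
    train_coords = np.asarray(train_coords, float)
    if len(train_coords) == 0 or len(test_coords) == 0:
        raise ValueError("both running directions must be non-empty")
    decoded = np.empty(len(test_coords))
    chunk = 2048
    for start in range(0, len(test_coords), chunk):
        stop = min(start + chunk, len(test_coords))
        d2 = ((test_coords[start:stop, None, :] - train_coords[None, :, :]) ** 2).sum(-1)
        nn = np.argmin(d2, axis=1)  # np.argmin returns the first (earliest) minimum
        decoded[start:stop] = train_phase[nn]
    result = DecodeResult(decoded=decoded, actual=test_actual, mode="linear",
                          valid=np.ones(len(decoded), bool))
    if test_actual is not None:
        act = np.asarray(test_actual, float)
        result.error_series = decoded - act
        result.mse = float(np.nanmean(result.error_series**2))
    return result


class NNPhaseDecoder(BaseEstimator):
    """Estimator form of :func:`nn_phase_decode` (fit on one direction,
    predict on the other)."""

    def fit(self, train_coords: np.ndarray, train_phase: np.ndarray):
        self.train_coords_ = np.asarray(train_coords, float)
        self.train_phase_ = np.asarray(train_phase, float)
        return self

    def predict(self, test_coords: np.ndarray) -> np.ndarray:
        return nn_phase_decode(test_coords, self.train_coords_, self.train_phase_).decoded


# ---------------------------------------------------------------------------
# template decoders (phase / time / speed-by-acceleration)
# ---------------------------------------------------------------------------

def _traversal_ids(b: BehaviorTrack) -> np.ndarray:
    """Integer id per frame of the current track traversal (-1 off-run)."""
    running = b.running_direction != 0
    ids = np.full(b.n_frames, -1, dtype=np.int64)
    current = -1
    prev = False
    for i in range(b.n_frames):
        if running[i] and not prev:
            current += 1
        if running[i]:
            ids[i] = current
        prev = running[i]
    return ids


def template_bins(b: BehaviorTrack, variable: str) -> np.ndarray:
    """20-bin label per frame for phase, time or speed-by-acceleration (-1 invalid).

    Phase: 8 cm excluded at each side, 20 evenly spaced bins, directions
    pooled by flipping the indexing.  Time: from traversal start to the
    maximal traversal length, 20 bins.  Speed-by-acceleration: 10 bins
    0->40 cm/s while speeding up, then 10 bins 40->0 while slowing down,
    ordered along the typical traversal.
    """
    nb = N_TEMPLATE_BINS
    running = b.running_direction != 0
    labels = np.full(b.n_frames, -1, dtype=np.int64)
    if variable == "phase":
        ph = b.phase()
        lo, hi = 8.0, b.track_length - 8.0
        ok = running & (ph >= lo) & (ph <= hi)
        labels[ok] = np.clip(((ph[ok] - lo) / (hi - lo) * nb).astype(int), 0, nb - 1)
        return labels
    trav = _traversal_ids(b)
    if variable == "time":
        t_rel = np.full(b.n_frames, np.nan)
        for tid in np.unique(trav[trav >= 0]):
            sel = trav == tid
            t_rel[sel] = b.time[sel] - b.time[sel][0]
        t_max = np.nanmax(t_rel)
        ok = running & np.isfinite(t_rel)
        labels[ok] = np.clip((t_rel[ok] / t_max * nb).astype(int), 0, nb - 1)
        return labels
    if variable == "speed_by_accel":
        accel = np.gradient(b.speed, b.time)
        half = nb // 2
        ok = running
        idx = np.clip((b.speed / TEMPLATE_SPEED_MAX * half).astype(int), 0, half - 1)
        labels[ok] = np.where(accel[ok] >= 0, idx[ok], nb - 1 - idx[ok])
        return labels
    raise ValueError(f"unknown variable {variable!r}")


def explained_variance(decoded: np.ndarray, actual: np.ndarray, n_shuffles: int = 100,
                       seed: int = 0) -> float:
    """1 - MSE(data) / MSE(label shuffle preserving label probabilities)."""
    ok = np.isfinite(decoded) & np.isfinite(actual)
    d, a = decoded[ok], actual[ok]
    mse = float(np.mean((d - a) ** 2))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        null[s] = np.mean((d - rng.permutation(a)) ** 2)
    return 1.0 - mse / float(null.mean())


class TemplateDecoder(BaseEstimator):
    """Per-bin mean-activity templates decoded by maximal Pearson correlation.

    ``fit`` averages the training activity vectors within each of the 20
    bins of the chosen variable; ``predict`` assigns each test frame the bin
    whose template correlates best with it (ties to the lowest bin).
    """

    def __init__(self, variable: str = "phase"):
        self.variable = variable

    def fit(self, frames: np.ndarray, labels: np.ndarray):
        nb = N_TEMPLATE_BINS
        self.templates_ = np.full((nb, frames.shape[1]), np.nan)
        self.bins_ = []
        for b in range(nb):
            sel = labels == b
            if sel.any():
                self.templates_[b] = frames[sel].mean(axis=0)
                self.bins_.append(b)
        self.bins_ = np.asarray(self.bins_)
        return self

    def predict(self, frames: np.ndarray) -> np.ndarray:
        temp = self.templates_[self.bins_]
        tc = temp - temp.mean(axis=1, keepdims=True)
        tn = np.linalg.norm(tc, axis=1)
        fc = frames - frames.mean(axis=1, keepdims=True)
        fn = np.linalg.norm(fc, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (fc @ tc.T) / (fn[:, None] * tn[None, :])
        corr = np.nan_to_num(corr, nan=-np.inf)
        decoded = self.bins_[np.argmax(corr, axis=1)].astype(float)
        decoded[~np.isfinite(corr).any(axis=1)] = np.nan
        decoded[fn == 0] = np.nan
        return decoded


def template_decode(m: ActivityMatrix, b: BehaviorTrack, variable: str = "phase",
                    n_shuffles: int = 100, seed: int = 0) -> DecodeResult:
    """Odd/even-minute split template decoding with Eq.-style explained variance.

    The session's even minutes train the per-bin templates and the odd
    minutes are decoded; the shuffle MSE preserves the label probabilities
    of the test set.
    """
    if b.time[-1] < 120:
        raise ValueError("session must be at least 2 minutes for the odd/even split")
    labels = template_bins(b, variable)
    minute = (b.time // 60).astype(int)
    train = (minute % 2 == 0) & (labels >= 0)
    test = (minute % 2 == 1) & (labels >= 0)
    frames = m.values.T.astype(float)
    dec = TemplateDecoder(variable=variable).fit(frames[train], labels[train])
    decoded = dec.predict(frames[test])
    actual = labels[test].astype(float)
    ok = np.isfinite(decoded)
    mse = float(np.mean((decoded[ok] - actual[ok]) ** 2))
    ev = explained_variance(decoded, actual, n_shuffles=n_shuffles, seed=seed)
    return DecodeResult(decoded=decoded, actual=actual, error_series=decoded - actual,
                        mse=mse, explained_variance=ev, mode="linear", valid=ok)


# ---------------------------------------------------------------------------
# shuffle test
# ---------------------------------------------------------------------------

def shuffle_test_decoding(r: DecodeResult, n_shuffles: int = 1000, seed: int = 0) -> float:
    """Permutation p-value of the decoding MSE.

    Decoded values are shuffled across time bins; the gauge degrees of
    freedom (rotation and reflection for angles, reflection for positions)
    are re-fit separately for each shuffle, exactly as for the observed
    decoding.  p = (1 + #{null <= observed}) / (n_shuffles + 1).
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    if r.actual is None or r.mse is None:
        raise ValueError("result needs actual values and an observed mse")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ok = np.isfinite(r.decoded) & np.isfinite(np.asarray(r.actual, float))
    decoded = r.decoded[ok]
    actual = np.asarray(r.actual, float)[ok]
    if np.allclose(decoded, decoded[0]):
        import warnings

        warnings.warn("constant decoded series: degenerate shuffle null")
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(decoded)
        _, _, _, null[s] = fix_gauge(perm, actual, r.mode)
    return float((1 + np.sum(null <= r.mse)) / (n_shuffles + 1))


# ---------------------------------------------------------------------------
# phase/time variability
# ---------------------------------------------------------------------------

def phase_time_variability(m: ActivityMatrix, b: BehaviorTrack, neuron: int) -> VariabilityResult:
    """Joint 20x20 phase-by-time rate map and its marginal variabilities.

    SD_T is the occupancy-weighted average (over phases) of the standard
    deviation of event rates across time bins — variability in *when* the
    cell is active; SD_P is the symmetric quantity across phases.  A
    phase-coding cell has SD_P > SD_T.  Requires >= 10 events during running.
    """
    from ._utils import weighted_std

    phase_bins = template_bins(b, "phase")
    time_bins = template_bins(b, "time")
    ok = (phase_bins >= 0) & (time_bins >= 0)
    spikes = m.values[neuron].astype(float)
    if spikes[ok].sum() < 10:
        raise ValueError(f"neuron {neuron}: fewer than 10 events during running")
    nb = N_TEMPLATE_BINS
    occ = np.zeros((nb, nb))
    cnt = np.zeros((nb, nb))
    np.add.at(occ, (phase_bins[ok], time_bins[ok]), 1.0)
    np.add.at(cnt, (phase_bins[ok], time_bins[ok]), spikes[ok])
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occ > 0, cnt / occ, np.nan)

    from ._utils import weighted_std

    # inner SDs weight each bin by its occupancy, so thinly sampled bins with
    # noise-dominated rate estimates do not drive the comparison
    sd_across_time = np.array([
        weighted_std(rate[p][occ[p] > 0], occ[p][occ[p] > 0])
        if (occ[p] > 0).sum() > 1 else 0.0 for p in range(nb)])
    sd_t = weighted_std_like(sd_across_time, occ.sum(axis=1))
    sd_across_phase = np.array([
        weighted_std(rate[:, t][occ[:, t] > 0], occ[:, t][occ[:, t] > 0])
        if (occ[:, t] > 0).sum() > 1 else 0.0 for t in range(nb)])
    sd_p = weighted_std_like(sd_across_phase, occ.sum(axis=0))
    return VariabilityResult(joint_rate_map=rate, sd_t=sd_t, sd_p=sd_p)


def weighted_std_like(values: np.ndarray, weights: np.ndarray) -> float:
    """Occupancy-weighted mean of per-slice standard deviations."""
    w = weights.astype(float)
    tot = w.sum()
    if tot == 0:
        return 0.0
    return float((values * w).sum() / tot)
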