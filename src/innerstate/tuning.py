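"""Reconstructed internal variables, tuning curves, and tuning statistics.

The ordered network states parameterize the encoded variable: ordered
sub-clusters get evenly spaced internal positions on [0, 1] (linear mode) or
angles 2*pi*k/M (circular mode, temporally smoothed through unit vectors).
A neuron's internal tuning curve is its event rate as a function of that
internal coordinate — occupancy and event counts per ordered state,
interpolated to the spatial-bin grid and kernel-smoothed (linear) or binned
into 40 bins of 9 degrees (circular).  External curves use the measured
behavior with the same binning conventions.  Information per event, field
width, Rayleigh vectors and bidirectionality quantify and compare the two.
"""

from __future__ import annotations

import numpy as np

from ._utils import TWO_PI, circ_diff, smooth_1d, smooth_angle_series
from .containers import (
    DIR_LEFT,
    DIR_RIGHT,
    ActivityMatrix,
    BehaviorTrack,
    BidirectionalityResult,
    InternalTrajectory,
    StateModel,
    TuningCurve,
)

N_TRACK_BINS = 24          # 4-cm bins on the 96-cm track
N_EDGE_EXCLUDED = 2        # bins dropped at each end (mouse mostly stationary)
N_ANGLE_BINS = 40          # 9-degree bins
SPEED_THRESHOLD = 1.0      # cm/s, running filter for positional curves
MIN_EVENTS_CURVE = 6       # internal curves need > 5 events in the relevant states
MIN_EVENTS_INFO = 5        # information/bidirectionality need >= 5 events


class InsufficientEvents(ValueError):
    """Raised when a neuron has too few events for a tuning statistic."""


# ---------------------------------------------------------------------------
# internal variable
# ---------------------------------------------------------------------------

def reconstruct_internal_variable(s: StateModel, mode: str,
                                  external: np.ndarray | None = None,
                                  smooth_sigma: float = 2.0, smooth_size: int = 5,
                                  ) -> InternalTrajectory:
    """Per-frame internal coordinate from ordered states.

    Linear mode assigns ordered sub-cluster k of M the position k/(M-1);
    circular mode assigns cluster k the angle 2*pi*k/M and then smooths the
    angle series temporally (sigma = 2 frames, 5-frame support, through unit
    vectors).  If ``external`` (aligned with the label rows) is given, the
    residual gauge freedom — reflection for a line, rotation+reflection for a
    ring — is fixed by minimizing the global mean squared error, and the
    per-frame mismatch series is attached (circular errors in (-pi, pi]).
    """
    if s.ordering is None:
        raise ValueError("state model has no ordering; run order_states first")
    m = len(s.ordering)
    pos_of_state = np.full(s.n_states, np.nan)
    for rank, state in enumerate(s.ordering):
        pos_of_state[state] = rank
    labels = s.labels
    valid = labels >= 0
    value = np.full(len(labels), np.nan)

    if mode == "linear":
        value[valid] = pos_of_state[labels[valid]] / (m - 1)
        gauge = {"reflect": False}
        err = None
        if external is not None:
            ext = np.asarray(external, dtype=float)
            ok = valid & np.isfinite(ext)
            lo, hi = np.nanmin(ext[ok]), np.nanmax(ext[ok])
            best = None
            for reflect in (False, True):
                v = 1.0 - value if reflect else value
                scaled = lo + v * (hi - lo)
                mse = np.nanmean((scaled[ok] - ext[ok]) ** 2)
                if best is None or mse < best[0]:
                    best = (mse, reflect, scaled)
            _, reflect, scaled = best
            if reflect:
                value = 1.0 - value
            gauge = {"reflect": reflect, "scale": (float(lo), float(hi))}
            err = np.full(len(labels), np.nan)
            err[ok] = scaled[ok] - ext[ok]
        return InternalTrajectory(value=value, frame_index=s.frame_index, mode="linear",
                                 gauge=gauge, error_series=err)

    if mode != "circular":
        raise ValueError(f"unknown mode {mode!r}")

    theta = np.full(len(labels), np.nan)
    theta[valid] = TWO_PI * pos_of_state[labels[valid]] / m
    if valid.all():
        theta = smooth_angle_series(theta, smooth_sigma, smooth_size)
    elif valid.any():
        theta[valid] = smooth_angle_series(theta[valid], smooth_sigma, smooth_size)
    gauge = {"reflect": False, "rotation": 0.0}
    err = None
    if external is not None:
        ext = np.asarray(external, dtype=float)
        ok = valid & np.isfinite(ext)
        best = None
        for reflect in (False, True):
            base = np.mod(-theta, TWO_PI) if reflect else theta
            for k in range(m):
                rot = TWO_PI * k / m
                cand = np.mod(base + rot, TWO_PI)
                mse = np.mean(circ_diff(cand[ok], ext[ok]) ** 2)
                if best is None or mse < best[0]:
                    best = (mse, reflect, rot, cand)
        _, reflect, rot, theta = best
        gauge = {"reflect": reflect, "rotation": float(rot)}
        err = np.full(len(labels), np.nan)
        err[ok] = circ_diff(theta[ok], ext[ok])
    return InternalTrajectory(value=theta, frame_index=s.frame_index, mode="circular",
                             gauge=gauge, error_series=err)


# ---------------------------------------------------------------------------
# tuning curves
# ---------------------------------------------------------------------------

def _rate_curve(occ_s: np.ndarray, cnt_s: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(occ_s > 0, cnt_s / occ_s, np.nan)


def internal_tuning_curve(m: ActivityMatrix, traj: InternalTrajectory, neuron: int,
                          n_bins: int = 20) -> TuningCurve:
    """Event rate of one neuron as a function of the internal coordinate.

    Linear mode: occupancy and event counts per ordered state are linearly
    interpolated onto ``n_bins`` evenly spaced internal positions, both maps
    smoothed with a truncated Gaussian (sigma = 1.5 bins, 5-bin support) and
    divided.  Circular mode: the smoothed internal angle is binned into 40
    bins of 9 degrees with no interpolation or kernel smoothing.  Requires
    more than 5 events within the covered states.
    """
    spikes = m.values[neuron, traj.frame_index].astype(float)
    ok = np.isfinite(traj.value)
    n_events = int(spikes[ok].sum())
    if n_events < MIN_EVENTS_CURVE:
        raise InsufficientEvents(
            f"neuron {neuron}: {n_events} events in the relevant states (>5 required)")

    if traj.mode == "linear":
        states, inv = np.unique(traj.value[ok], return_inverse=True)
        occ = np.bincount(inv, minlength=len(states)) * m.bin_width
        cnt = np.bincount(inv, weights=spikes[ok], minlength=len(states))
        grid = np.linspace(0.0, 1.0, n_bins)
        occ_i = np.interp(grid, states, occ)
        cnt_i = np.interp(grid, states, cnt)
        occ_s = smooth_1d(occ_i, 1.5, 5)
        cnt_s = smooth_1d(cnt_i, 1.5, 5)
        return TuningCurve(bin_centers=grid, occupancy=occ_s, event_counts=cnt_s,
                           rate=_rate_curve(occ_s, cnt_s), mode="linear", source="internal",
                           raw_occupancy=occ_i, raw_counts=cnt_i)

    edges = np.linspace(0.0, TWO_PI, N_ANGLE_BINS + 1)
    which = np.clip(np.digitize(traj.value[ok], edges) - 1, 0, N_ANGLE_BINS - 1)
    occ = np.bincount(which, minlength=N_ANGLE_BINS) * m.bin_width
    cnt = np.bincount(which, weights=spikes[ok], minlength=N_ANGLE_BINS)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return TuningCurve(bin_centers=centers, occupancy=occ, event_counts=cnt,
                       rate=_rate_curve(occ, cnt), mode="circular", source="internal",
                       raw_occupancy=occ, raw_counts=cnt)


def external_tuning_curve(m: ActivityMatrix, b: BehaviorTrack, neuron: int,
                          variable: str = "position", direction: int | None = None,
                          frames: np.ndarray | None = None) -> TuningCurve:
    """Event rate against a measured external variable.

    ``position``: single running direction (``direction`` required), 24 bins
    of 4 cm with the outer 2 bins at each end excluded, frames restricted to
    speed > 1 cm/s, occupancy and counts smoothed (sigma = 1.5 bins, 5-bin
    support) before dividing.  ``phase``: both directions pooled after
    flipping the positional indexing of one, same binning.  ``angle``: 40
    bins of 9 degrees, no smoothing or edge exclusion.  Zero-occupancy bins
    come out NaN.
    """
    spikes = m.values[neuron].astype(float)
    sel = np.ones(b.n_frames, dtype=bool) if frames is None else \
        np.isin(np.arange(b.n_frames), frames)

    if variable == "angle":
        sel &= np.isfinite(b.head_direction)
        edges = np.linspace(0.0, TWO_PI, N_ANGLE_BINS + 1)
        which = np.clip(np.digitize(b.head_direction[sel], edges) - 1, 0, N_ANGLE_BINS - 1)
        occ = np.bincount(which, minlength=N_ANGLE_BINS) * m.bin_width
        cnt = np.bincount(which, weights=spikes[sel], minlength=N_ANGLE_BINS)
        centers = 0.5 * (edges[:-1] + edges[1:])
        return TuningCurve(bin_centers=centers, occupancy=occ, event_counts=cnt,
                           rate=_rate_curve(occ, cnt), mode="circular", source="external",
                           raw_occupancy=occ, raw_counts=cnt)

    if variable == "position":
        if direction not in (DIR_LEFT, DIR_RIGHT):
            raise ValueError("positional curve needs direction=DIR_LEFT or DIR_RIGHT")
        sel &= (b.running_direction == direction) & (b.speed > SPEED_THRESHOLD)
        values = b.position
    elif variable == "phase":
        sel &= (b.running_direction != 0) & (b.speed > SPEED_THRESHOLD)
        values = b.phase()
    else:
        raise ValueError(f"unknown variable {variable!r}")

    L = b.track_length
    edges = np.linspace(0.0, L, N_TRACK_BINS + 1)
    lo, hi = N_EDGE_EXCLUDED, N_TRACK_BINS - N_EDGE_EXCLUDED
    if not sel.any():
        nan = np.full(hi - lo, np.nan)
        centers = 0.5 * (edges[lo:hi] + edges[lo + 1:hi + 1])
        return TuningCurve(bin_centers=centers, occupancy=np.zeros(hi - lo),
                           event_counts=np.zeros(hi - lo), rate=nan,
                           mode="linear", source="external",
                           raw_occupancy=np.zeros(hi - lo), raw_counts=np.zeros(hi - lo))
    which = np.clip(np.digitize(values[sel], edges) - 1, 0, N_TRACK_BINS - 1)
    occ_full = np.bincount(which, minlength=N_TRACK_BINS) * m.bin_width
    cnt_full = np.bincount(which, weights=spikes[sel], minlength=N_TRACK_BINS)
    occ, cnt = occ_full[lo:hi], cnt_full[lo:hi]
    occ_s = smooth_1d(occ, 1.5, 5)
    cnt_s = smooth_1d(cnt, 1.5, 5)
    centers = 0.5 * (edges[lo:hi] + edges[lo + 1:hi + 1])
    return TuningCurve(bin_centers=centers, occupancy=occ_s, event_counts=cnt_s,
                       rate=_rate_curve(occ_s, cnt_s), mode="linear", source="external",
                       raw_occupancy=occ, raw_counts=cnt)


# ---------------------------------------------------------------------------
# information and field statistics
# ---------------------------------------------------------------------------

def information_from_counts(occupancy: np.ndarray, counts: np.ndarray) -> float:
    """Information per event (bits) between events and a binned variable.

    sum_i p_i (r_i / rbar) log2(r_i / rbar) with p_i the occupancy
    probability of bin i, r_i the event rate there, rbar the overall mean
    rate; empty-rate bins contribute zero in the limit.
    """
    occ = np.asarray(occupancy, float)
    cnt = np.asarray(counts, float)
    ok = occ > 0
    occ, cnt = occ[ok], cnt[ok]
    tot_occ = occ.sum()
    tot_cnt = cnt.sum()
    if tot_occ <= 0 or tot_cnt <= 0:
        raise InsufficientEvents("no events / no occupancy")
    p = occ / tot_occ
    r = cnt / occ
    rbar = tot_cnt / tot_occ
    ratio = r / rbar
    nz = ratio > 0
    return float(np.sum(p[nz] * ratio[nz] * np.log2(ratio[nz])))


def information_per_event(curve: TuningCurve, n_shuffles: int = 1000, seed: int = 0):
    """Eq.-style information of the unsmoothed map plus a shuffle test.

    The null redraws each event's bin i.i.d. from the occupancy
    distribution (the spatial coverage statistics); the cell is significant
    iff its information is strictly higher than 95% of its shuffles.
    Returns ``(information, p_value, significant)``.
    """
    occ = curve.raw_occupancy
    cnt = curve.raw_counts
    n_events = int(round(np.nansum(cnt)))
    if n_events < MIN_EVENTS_INFO:
        raise InsufficientEvents(f"{n_events} events (>=5 required)")
    info = information_from_counts(occ, cnt)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ok = occ > 0
    p = occ[ok] / occ[ok].sum()
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        shuf = rng.multinomial(n_events, p)
        null[s] = information_from_counts(occ[ok], shuf)
    p_value = float((1 + np.sum(null >= info)) / (n_shuffles + 1))
    significant = bool(np.mean(info > null) >= 0.95)
    return info, p_value, significant


def field_stats(curve: TuningCurve) -> dict:
    """Field width and (for circular curves) the Rayleigh vector.

    Width counts the bins contiguous with the peak whose rate exceeds half
    the maximum; the Rayleigh vector sum_k r(theta_k) e^{-i theta_k} /
    sum_k r(theta_k) gives the preferred direction (its angle) and the
    directionality (its length).
    """
    rate = np.nan_to_num(curve.rate, nan=0.0)
    if curve.n_bins < 2:
        raise ValueError("curve needs at least 2 bins")
    if rate.max() <= 0:
        return {"width": np.nan, "preferred": np.nan,
                "rayleigh_length": np.nan, "rayleigh_angle": np.nan}
    peak = int(np.argmax(rate))
    half = 0.5 * rate.max()
    n = curve.n_bins
    width = 1
    i = peak - 1
    while (curve.mode == "circular" or i >= 0) and rate[i % n] > half and width < n:
        width += 1
        i -= 1
    j = peak + 1
    while (curve.mode == "circular" or j < n) and rate[j % n] > half and width < n:
        width += 1
        j += 1
    out = {"width": int(width), "preferred": float(curve.bin_centers[peak]),
           "rayleigh_length": np.nan, "rayleigh_angle": np.nan}
    if curve.mode == "circular":
        z = np.sum(rate * np.exp(-1j * curve.bin_centers)) / rate.sum()
        out["rayleigh_length"] = float(np.abs(z))
        out["rayleigh_angle"] = float(np.mod(-np.angle(z), TWO_PI))
        out["preferred"] = out["rayleigh_angle"]
    return out


def bidirectionality(map_right: TuningCurve, map_left: TuningCurve,
                     variant: str = "position") -> BidirectionalityResult:
    """Normalized overlap of the two running directions' rate maps, in [0, 1].

    Each map is normalized to N_bins * r(i) / sum_i r(i); the overlap is
    2 * sum_i min(P_right, P_left) / sum_i (P_right + P_left).  The
    ``phase-flipped`` variant reverses the bin order of the leftward map
    first, testing trajectory-phase rather than position coding.  1 means
    identical normalized maps, 0 disjoint supports.
    """
    r = np.nan_to_num(map_right.rate, nan=0.0)
    l = np.nan_to_num(map_left.rate, nan=0.0)
    if map_right.n_bins != map_left.n_bins:
        raise ValueError("maps must share the bin grid")
    if int(round(np.nansum(map_right.raw_counts))) < MIN_EVENTS_INFO or \
            int(round(np.nansum(map_left.raw_counts))) < MIN_EVENTS_INFO:
        raise InsufficientEvents("both directions need >= 5 events")
    if variant == "phase-flipped":
        l = l[::-1]
    elif variant != "position":
        raise ValueError(f"unknown variant {variant!r}")
    if r.sum() == 0 or l.sum() == 0:
        raise ValueError("zero-rate map")
    nb = map_right.n_bins
    pr = nb * r / r.sum()
    pl = nb * l / l.sum()
    value = 2.0 * np.minimum(pr, pl).sum() / (pr + pl).sum()
    return BidirectionalityResult(value=float(value), p_right=pr, p_left=pl,
                                 n_bins=nb, variant=variant)


# ---------------------------------------------------------------------------
# leave-one-out internal information
# ---------------------------------------------------------------------------

def internal_information_loo(m: ActivityMatrix, neuron: int, n_states: int = 8,
                             n_shuffles: int = 100, seed: int = 0,
                             frames: np.ndarray | None = None,
                             p1: float | None = None, p2: float | None = None) -> dict:
    """Shuffle-corrected information between a cell and the network state.

    The cell is excluded from the activity vectors, the remaining population
    is embedded (two-stage) and clustered into ``n_states`` K-means states
    (8, matching the 8 external bins of the comparison), and the held-out
    cell's information across states is computed; the mean information of
    ``n_shuffles`` time-shuffles of that cell is subtracted to remove the
    occupancy-statistics bias.  Returns raw, shuffle-mean and corrected
    information (bits/event).
    """
    from .embedding import P1_DEFAULT, P2_DEFAULT, TwoStageSpectralEmbedding

    keep = np.ones(m.n_neurons, dtype=bool)
    keep[neuron] = False
    frames = m.retained_frames if frames is None else np.asarray(frames)
    reduced = ActivityMatrix(values=m.values[keep], bin_width=m.bin_width,
                             modality=m.modality, retained_frames=frames)
    try:
        est = TwoStageSpectralEmbedding(p1=p1 or P1_DEFAULT, p2=p2 or P2_DEFAULT, seed=seed)
        est.fit(reduced)
    except ValueError as err:
        raise ValueError(f"leave-one-out embedding failed for neuron {neuron}: {err}") from err
    emb = est.embedding_
    from sklearn.cluster import KMeans

    labels = KMeans(n_clusters=n_states, n_init=10, random_state=seed).fit_predict(emb.coords)
    spikes = m.values[neuron, emb.frame_index].astype(float)
    n_events = int(spikes.sum())
    if n_events < MIN_EVENTS_INFO:
        raise InsufficientEvents(f"neuron {neuron}: {n_events} events (>=5 required)")
    occ = np.bincount(labels, minlength=n_states).astype(float)
    cnt = np.bincount(labels, weights=spikes, minlength=n_states)
    raw = information_from_counts(occ, cnt)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        shuf = rng.permutation(spikes)
        null[s] = information_from_counts(occ, np.bincount(labels, weights=shuf,
                                                           minlength=n_states))
    return {"information": raw, "shuffle_mean": float(null.mean()),
            "corrected": raw - float(null.mean()), "shuffle_sd": float(null.std())}
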