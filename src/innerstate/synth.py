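"""Synthetic linear-track and head-direction sessions with planted tuning.

The generators emulate the recording conditions of the experiments the
pipeline is built for: a 96-cm linear track explored back and forth with
drink/turn pauses at both ends (Ca2+ imaging at 10-20 Hz, GCaMP6-like
events), and head-direction populations recorded extracellularly and binned
at 100 ms, including REM episodes in which a faster "virtual" heading sweep
drives the same ring-tuned cells.  Every neuron carries an explicit
:class:`~innerstate.containers.GroundTruthTuning` entry so downstream stages
can be validated against what was planted.

Tuning shapes are Gaussian on position/trajectory-phase and von-Mises-shaped
on angle; events are Bernoulli per frame with probability rate*dt (clipped to
[0, 1]), matching the binarized raster the pipeline consumes.  All randomness
flows from one session seed through a documented splitting scheme
(:func:`innerstate._utils.spawn_rngs`).
"""

from __future__ import annotations

import numpy as np

from ._utils import TWO_PI, spawn_rngs
from .containers import (
    DIR_LEFT,
    DIR_NONE,
    DIR_RIGHT,
    REM,
    WAKE,
    ActivityMatrix,
    BehaviorTrack,
    FluorescenceTraces,
    GroundTruthTuning,
)

TRACK_LENGTH = 96.0  # cm

_LINEAR_DEFAULTS = dict(
    track_length=TRACK_LENGTH,
    peak_speed=40.0,        # cm/s, cruise speed of the trapezoidal run profile
    peak_speed_sd=6.0,      # trial-to-trial speed variability (traversals 2-4 s)
    run_accel=30.0,         # cm/s^2, acceleration of the speed-up/slow-down ramps
    drink_duration=(2.0, 4.0),   # s, uniform range
    turn_duration=(1.5, 2.5),
    rear_duration=(1.0, 2.0),
    rear_prob=0.15,         # probability of a rear bout after a turn
    place_width=6.0,        # cm (sigma of the Gaussian field)
    phase_width=6.0,
    peak_rate=(0.8, 2.0),   # events/s at the field peak (place/phase cells)
    pause_peak_rate=(1.5, 3.0),  # events/s for drink/turn/rear cells during their bout
    baseline_rate=(0.01, 0.03),
    nonpreferred_factor=0.3,  # rate fraction in the non-preferred running direction
    # cell-type composition
    ca1_fractions=dict(place=0.60, drink=0.15, turn=0.15, untuned=0.10),
    acc_fractions=dict(phase=0.50, drink=0.12, turn=0.12, rear=0.06, untuned=0.20),
)

_HD_DEFAULTS = dict(
    kappa=3.0,
    peak_rate=(10.0, 40.0),  # Hz
    baseline_rate=(0.5, 1.5),
    omega_sd=1.25,           # rad/s, stationary SD of angular velocity
    omega_tau=1.0,           # s, velocity correlation time
    omega_max=3.0,           # rad/s, bound on angular speed
    rem_speed_factor=2.0,    # REM virtual sweep runs the same walk law, twice as fast
)


def _config(defaults: dict, params: dict | None) -> dict:
    cfg = dict(defaults)
    if params:
        unknown = set(params) - set(defaults)
        if unknown:
            raise ValueError(f"unknown generator parameters: {sorted(unknown)}")
        cfg.update(params)
    return cfg


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def _gen_track_behavior(duration: float, frame_rate: float, rng: np.random.Generator,
                        cfg: dict) -> BehaviorTrack:
    """Alternating runs with drink/turn (and occasional rear) pauses at both ends.

    Each traversal follows a triangular speed profile peaking near 40 cm/s,
    so every track crossing contains a speeding-up half (positive
    acceleration) and a slowing-down half.
    """
    dt = 1.0 / frame_rate
    n_frames = int(round(duration * frame_rate))
    L = cfg["track_length"]

    pos, spd, rdir, label = [], [], [], []

    def pause(n, p, lab):
        pos.extend([p] * n)
        spd.extend([0.0] * n)
        rdir.extend([DIR_NONE] * n)
        label.extend([lab] * n)

    side = 0  # 0: left end, 1: right end
    while len(pos) < n_frames:
        end_pos = 0.0 if side == 0 else L
        end_tag = "L" if side == 0 else "R"
        n_drink = max(1, int(round(rng.uniform(*cfg["drink_duration"]) * frame_rate)))
        pause(n_drink, end_pos, f"drink_{end_tag}")
        n_turn = max(1, int(round(rng.uniform(*cfg["turn_duration"]) * frame_rate)))
        pause(n_turn, end_pos, f"turn_{end_tag}")
        if rng.random() < cfg["rear_prob"]:
            n_rear = max(1, int(round(rng.uniform(*cfg["rear_duration"]) * frame_rate)))
            pause(n_rear, end_pos, "rear")
        # trapezoidal run profile: speed up, cruise near 40 cm/s, slow down
        v_peak = float(np.clip(rng.normal(cfg["peak_speed"], cfg["peak_speed_sd"]),
                               0.5 * cfg["peak_speed"], 1.5 * cfg["peak_speed"]))
        a = cfg["run_accel"]
        t_ramp = v_peak / a
        d_ramp = 0.5 * v_peak * t_ramp
        if 2 * d_ramp >= L:  # short track relative to ramps: triangular profile
            t_ramp = np.sqrt(L / a)
            v_peak = a * t_ramp
            t_cruise = 0.0
        else:
            t_cruise = (L - 2 * d_ramp) / v_peak
        T = 2 * t_ramp + t_cruise
        n_run = int(round(T * frame_rate))
        t = (np.arange(n_run) + 0.5) * dt
        v = np.where(t < t_ramp, a * t,
                     np.where(t < t_ramp + t_cruise, v_peak, a * np.maximum(T - t, 0.0)))
        x = np.minimum(np.cumsum(v) * dt, L)
        d = DIR_RIGHT if side == 0 else DIR_LEFT
        run_pos = x if side == 0 else L - x
        pos.extend(np.clip(run_pos, 0.0, L).tolist())
        spd.extend(v.tolist())
        rdir.extend([d] * n_run)
        label.extend(["run"] * n_run)
        side = 1 - side

    time = np.arange(n_frames) * dt
    return BehaviorTrack(
        time=time,
        position=np.asarray(pos[:n_frames]),
        running_direction=np.asarray(rdir[:n_frames], dtype=np.int8),
        speed=np.asarray(spd[:n_frames]),
        behavior_label=np.asarray(label[:n_frames], dtype=object),
        episode=np.full(n_frames, WAKE, dtype=np.int8),
        track_length=L,
    )


def _bounded_walk_heading(n: int, dt: float, rng: np.random.Generator, cfg: dict,
                          speed_factor: float = 1.0, theta0: float = 0.0) -> np.ndarray:
    """Bounded-speed random walk on the circle (OU angular velocity)."""
    tau = cfg["omega_tau"]
    sd = cfg["omega_sd"] * speed_factor
    omax = cfg["omega_max"] * speed_factor
    a = np.exp(-dt / tau)
    innov_sd = sd * np.sqrt(1 - a * a)
    omega = rng.normal(0.0, sd)
    theta = np.empty(n)
    th = theta0
    for i in range(n):
        th = np.mod(th + omega * dt, TWO_PI)
        theta[i] = th
        omega = np.clip(a * omega + rng.normal(0.0, innov_sd), -omax, omax)
    return theta


# ---------------------------------------------------------------------------
# tuning and events
# ---------------------------------------------------------------------------

def _draw_linear_tuning(mode: str, n_neurons: int, rng: np.random.Generator,
                        cfg: dict) -> GroundTruthTuning:
    fracs = cfg["ca1_fractions"] if mode == "ca1" else cfg["acc_fractions"]
    classes = list(fracs)
    counts = np.floor(np.asarray([fracs[c] for c in classes]) * n_neurons).astype(int)
    counts[-1] += n_neurons - counts.sum()  # remainder goes to the last class
    tuning_class = np.repeat(classes, counts).astype(object)

    L = cfg["track_length"]
    preferred = np.zeros(n_neurons)
    width = np.full(n_neurons, cfg["place_width"] if mode == "ca1" else cfg["phase_width"])
    peak = rng.uniform(*cfg["peak_rate"], size=n_neurons)
    baseline = rng.uniform(*cfg["baseline_rate"], size=n_neurons)
    direction = np.zeros(n_neurons, dtype=np.int8)

    for i, cls in enumerate(tuning_class):
        if cls in ("place", "phase"):
            preferred[i] = rng.uniform(0.0, L)
            if cls == "place":
                direction[i] = DIR_RIGHT if rng.random() < 0.5 else DIR_LEFT
        elif cls in ("drink", "turn", "rear"):
            peak[i] = rng.uniform(*cfg["pause_peak_rate"])
            if mode == "ca1":
                # one end only; store the end as direction (-1 left, +1 right)
                direction[i] = DIR_RIGHT if rng.random() < 0.5 else DIR_LEFT
                preferred[i] = 0.0 if direction[i] == DIR_LEFT else L
        elif cls == "untuned":
            peak[i] = 0.0
    return GroundTruthTuning(tuning_class=tuning_class, preferred=preferred, width=width,
                             peak_rate=peak, direction=direction, baseline_rate=baseline)


def _linear_rates(behavior: BehaviorTrack, truth: GroundTruthTuning, mode: str,
                  cfg: dict) -> np.ndarray:
    """Per-neuron per-frame event rates (events/s) from the planted tuning."""
    n = truth.n_neurons
    k = behavior.n_frames
    rates = np.tile(truth.baseline_rate[:, None], (1, k))
    x = behavior.position
    running = behavior.running_direction != DIR_NONE
    lab = behavior.behavior_label
    phase = behavior.phase()
    nonpref = cfg["nonpreferred_factor"]

    for i in range(n):
        cls = truth.tuning_class[i]
        pk = truth.peak_rate[i]
        if pk == 0:
            continue
        if cls == "place":
            g = pk * np.exp(-0.5 * ((x - truth.preferred[i]) / truth.width[i]) ** 2)
            sel = np.where(behavior.running_direction == truth.direction[i], 1.0, nonpref)
            rates[i, running] += (g * sel)[running]
        elif cls == "phase":
            g = pk * np.exp(-0.5 * ((phase - truth.preferred[i]) / truth.width[i]) ** 2)
            rates[i, running] += g[running]
        elif cls == "drink":
            if mode == "ca1":
                tag = "drink_L" if truth.direction[i] == DIR_LEFT else "drink_R"
                rates[i, lab == tag] += pk
            else:
                rates[i, (lab == "drink_L") | (lab == "drink_R")] += pk
        elif cls == "turn":
            if mode == "ca1":
                tag = "turn_L" if truth.direction[i] == DIR_LEFT else "turn_R"
                rates[i, lab == tag] += pk
            else:
                rates[i, (lab == "turn_L") | (lab == "turn_R")] += pk
        elif cls == "rear":
            rates[i, lab == "rear"] += pk
    return rates


def _bernoulli_events(rates: np.ndarray, dt: float, rng: np.random.Generator) -> np.ndarray:
    p = np.clip(rates * dt, 0.0, 1.0)
    return (rng.random(p.shape) < p).astype(np.uint8)


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def gen_linear_track_session(mode: str, n_neurons: int = 500, duration: float = 1080.0,
                             frame_rate: float = 20.0, seed: int = 0,
                             params: dict | None = None):
    """Generate a linear-track session with planted tuning.

    ``mode='ca1'`` plants direction-selective place cells plus drink/turn
    cells tuned to one end of the track; ``mode='acc'`` plants
    trajectory-phase cells and behavior-state cells whose tuning is identical
    for both ends and running directions.

    Returns ``(BehaviorTrack, ActivityMatrix, GroundTruthTuning)``.
    """
    if mode not in ("ca1", "acc"):
        raise ValueError(f"mode must be 'ca1' or 'acc', got {mode!r}")
    if duration <= 0 or frame_rate <= 0:
        raise ValueError("duration and frame_rate must be positive")
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    cfg = _config(_LINEAR_DEFAULTS, params)
    rng_beh, rng_tune, rng_ev = spawn_rngs(seed, 3)
    behavior = _gen_track_behavior(duration, frame_rate, rng_beh, cfg)
    truth = _draw_linear_tuning(mode, n_neurons, rng_tune, cfg)
    rates = _linear_rates(behavior, truth, mode, cfg)
    events = _bernoulli_events(rates, 1.0 / frame_rate, rng_ev)
    activity = ActivityMatrix(values=events, bin_width=1.0 / frame_rate, modality="imaging")
    return behavior, activity, truth


def gen_hd_session(n_neurons: int = 50, duration: float = 1800.0, bin_width: float = 0.1,
                   seed: int = 0, rem_fraction: float = 0.0, params: dict | None = None):
    """Generate a head-direction session binned and binarized at ``bin_width``.

    Heading follows a bounded-speed random walk on the circle during wake.
    The final ``rem_fraction`` of the session is a REM episode in which a
    faster "virtual" heading trajectory drives the same von-Mises-shaped
    tuning curves; ``BehaviorTrack.head_direction`` stores the trajectory that
    drove the cells (during REM this is the planted virtual sweep, since no
    physical heading exists for synthetic sleep).

    Returns ``(BehaviorTrack, ActivityMatrix, GroundTruthTuning)``.
    """
    if not (0 <= rem_fraction < 1):
        raise ValueError("rem_fraction must be in [0, 1)")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    cfg = _config(_HD_DEFAULTS, params)
    rng_beh, rng_tune, rng_ev = spawn_rngs(seed, 3)

    n_bins = int(round(duration / bin_width))
    n_rem = int(round(n_bins * rem_fraction))
    n_wake = n_bins - n_rem
    theta_wake = _bounded_walk_heading(n_wake, bin_width, rng_beh, cfg)
    theta0 = theta_wake[-1] if n_wake else 0.0
    theta_rem = _bounded_walk_heading(n_rem, bin_width, rng_beh, cfg,
                                      speed_factor=cfg["rem_speed_factor"], theta0=theta0)
    theta = np.concatenate([theta_wake, theta_rem])
    episode = np.concatenate([np.full(n_wake, WAKE, np.int8), np.full(n_rem, REM, np.int8)])

    preferred = rng_tune.uniform(0.0, TWO_PI, size=n_neurons)
    kappa = np.full(n_neurons, cfg["kappa"])
    peak = rng_tune.uniform(*cfg["peak_rate"], size=n_neurons)
    baseline = rng_tune.uniform(*cfg["baseline_rate"], size=n_neurons)
    truth = GroundTruthTuning(
        tuning_class=np.asarray(["hd"] * n_neurons, dtype=object),
        preferred=preferred, width=kappa, peak_rate=peak,
        direction=np.zeros(n_neurons, dtype=np.int8), baseline_rate=baseline)

    if n_bins:
        rates = baseline[:, None] + peak[:, None] * np.exp(
            kappa[:, None] * (np.cos(theta[None, :] - preferred[:, None]) - 1.0))
        counts = rng_ev.poisson(rates * bin_width)
        values = (counts > 0).astype(np.uint8)
    else:
        values = np.zeros((n_neurons, 0), dtype=np.uint8)

    behavior = BehaviorTrack(time=np.arange(n_bins) * bin_width, head_direction=theta,
                             episode=episode)
    activity = ActivityMatrix(values=values, bin_width=bin_width, modality="ephys")
    return behavior, activity, truth


_INDICATOR_KERNELS = {  # (rise tau s, decay tau s)
    "GCaMP6f": (0.045, 0.2),
    "GCaMP6s": (0.18, 0.6),
}


def gen_fluorescence_traces(events: ActivityMatrix, indicator: str = "GCaMP6f",
                            noise_sd: float = 0.01, seed: int = 0,
                            amplitude: float = 0.1, drift_sd: float = 0.02) -> FluorescenceTraces:
    """Render dF/F0 traces from an event raster.

    Events are convolved with a rise-plus-exponential-decay kernel (decay
    600 ms for GCaMP6s, 200 ms for GCaMP6f), then slow baseline drift and
    white noise are added.  ``amplitude`` is the peak dF/F0 of a unit event
    (per-event amplitudes are log-normally jittered around it).
    """
    if indicator not in _INDICATOR_KERNELS:
        raise ValueError(f"unknown indicator {indicator!r}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    from scipy.ndimage import gaussian_filter1d

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    tau_r, tau_d = _INDICATOR_KERNELS[indicator]
    fr = 1.0 / events.bin_width
    t = np.arange(0, 5 * tau_d, 1.0 / fr)
    kernel = (1.0 - np.exp(-t / tau_r)) * np.exp(-t / tau_d)
    if kernel.max() > 0:
        kernel = kernel / kernel.max()

    n, k = events.values.shape
    traces = np.zeros((n, k))
    for i in range(n):
        idx = np.flatnonzero(events.values[i])
        if idx.size:
            amps = amplitude * rng.lognormal(0.0, 0.3, size=idx.size)
            impulses = np.zeros(k)
            np.add.at(impulses, idx, amps)
            traces[i] = np.convolve(impulses, kernel)[:k]
    if drift_sd > 0 and k > 1:
        drift = gaussian_filter1d(rng.normal(0.0, 1.0, size=(n, k)), sigma=5.0 * fr, axis=1)
        sd = drift.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        traces += drift_sd * drift / sd
    if noise_sd > 0:
        traces += rng.normal(0.0, noise_sd, size=(n, k))
    return FluorescenceTraces(traces=traces, frame_rate=fr, indicator=indicator)


def gen_multiday_sessions(base: dict | None = None, n_days: int = 2,
                          overlap: float = 0.525, seed: int = 0):
    """Generate multiday sessions with partial neuron-roster turnover.

    Each day re-samples which neurons are active while preserving the planted
    tuning of retained neurons.  Neurons participate independently per day
    with probability ``s = 2*overlap/(1+overlap)`` so that the expected
    Jaccard overlap |A∩B|/|A∪B| between any two days equals ``overlap``
    (the recorded across-day overlaps fall in the 41-64% range, hence the
    default midpoint).  Off-roster neurons appear with all rates zeroed in
    that day's :class:`GroundTruthTuning`.
    """
    if n_days < 2:
        raise ValueError("n_days must be >= 2")
    if not (0 < overlap <= 1):
        raise ValueError("overlap must be in (0, 1]")
    base = dict(base or {})
    mode = base.pop("mode", "ca1")
    n_neurons = base.pop("n_neurons", 500)
    duration = base.pop("duration", 1080.0)
    frame_rate = base.pop("frame_rate", 20.0)
    params = base.pop("params", None)
    if base:
        raise ValueError(f"unknown base-config keys: {sorted(base)}")

    cfg = _config(_LINEAR_DEFAULTS, params)
    rngs = spawn_rngs(seed, 2 + 2 * n_days)
    rng_tune, rng_roster = rngs[0], rngs[1]
    truth_master = _draw_linear_tuning(mode, n_neurons, rng_tune, cfg)

    s = 2.0 * overlap / (1.0 + overlap)
    sessions = []
    for day in range(n_days):
        roster = rng_roster.random(n_neurons) < s if s < 1.0 else np.ones(n_neurons, bool)
        rng_beh, rng_ev = rngs[2 + 2 * day], rngs[3 + 2 * day]
        behavior = _gen_track_behavior(duration, frame_rate, rng_beh, cfg)
        truth = GroundTruthTuning(
            tuning_class=truth_master.tuning_class.copy(),
            preferred=truth_master.preferred.copy(),
            width=truth_master.width.copy(),
            peak_rate=np.where(roster, truth_master.peak_rate, 0.0),
            direction=truth_master.direction.copy(),
            baseline_rate=np.where(roster, truth_master.baseline_rate, 0.0),
        )
        rates = _linear_rates(behavior, truth, mode, cfg)
        events = _bernoulli_events(rates, 1.0 / frame_rate, rng_ev)
        activity = ActivityMatrix(values=events, bin_width=1.0 / frame_rate,
                                  modality="imaging")
        sessions.append((behavior, activity, truth))
    return sessions


def roster_of(truth: GroundTruthTuning) -> np.ndarray:
    """Boolean mask of neurons active in a (multiday) session's truth."""
    return (truth.peak_rate > 0) | (truth.baseline_rate > 0)
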