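"""Core data containers shared by the whole pipeline.

The universal input is the binary neurons-by-time :class:`ActivityMatrix`.
Behavioral measurements (:class:`BehaviorTrack`) are carried alongside for
validation only — no analysis stage consumes them except to fix residual
gauge freedoms and to score reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TWO_PI = 2.0 * np.pi

# running_direction codes
DIR_LEFT = -1
DIR_NONE = 0
DIR_RIGHT = 1

# episode codes
WAKE = 0
REM = 1

BEHAVIOR_LABELS = ("drink_L", "turn_L", "run", "turn_R", "drink_R", "rear")


@dataclass
class BehaviorTrack:
    """Per-frame behavioral measurements on the linear track or open arena.

    position is in cm on the track (linear sessions); head_direction in
    radians in [0, 2*pi) (ring sessions); running_direction uses
    {-1 left, 0 none, +1 right}; behavior_label holds one of
    ``BEHAVIOR_LABELS``; episode is 0 (wake) or 1 (REM).
    """

    time: np.ndarray
    position: np.ndarray | None = None
    head_direction: np.ndarray | None = None
    running_direction: np.ndarray | None = None
    speed: np.ndarray | None = None
    behavior_label: np.ndarray | None = None
    episode: np.ndarray | None = None
    track_length: float | None = None

    def __post_init__(self):
        n = len(self.time)
        for name in ("position", "head_direction", "running_direction", "speed",
                     "behavior_label", "episode"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != time length {n}")
        if self.position is not None and self.track_length is not None:
            if np.any(self.position < -1e-9) or np.any(self.position > self.track_length + 1e-9):
                raise ValueError("position outside [0, track_length]")
        if self.head_direction is not None:
            if np.any(self.head_direction < 0) or np.any(self.head_direction >= TWO_PI):
                raise ValueError("head_direction outside [0, 2*pi)")

    @property
    def n_frames(self) -> int:
        return len(self.time)

    def phase(self) -> np.ndarray:
        """Trajectory phase: distance from the start point of the current traversal.

        Distance from the left edge when running rightward and from the right
        edge when running leftward; NaN when not running.
        """
        if self.position is None or self.running_direction is None:
            raise ValueError("phase requires position and running_direction")
        ph = np.full(self.n_frames, np.nan)
        right = self.running_direction == DIR_RIGHT
        left = self.running_direction == DIR_LEFT
        ph[right] = self.position[right]
        ph[left] = self.track_length - self.position[left]
        return ph


@dataclass
class GroundTruthTuning:
    """Planted per-neuron tuning — the oracle for parameter-recovery tests.

    tuning_class is one of {place, phase, hd, drink, turn, rear, untuned};
    preferred is cm (place), cm of phase (phase), or radians (hd); width is in
    the same units (kappa for hd); peak_rate in events/s; direction uses the
    running_direction codes (place cells) or the track side (drink/turn cells).
    """

    tuning_class: np.ndarray
    preferred: np.ndarray
    width: np.ndarray
    peak_rate: np.ndarray
    direction: np.ndarray
    baseline_rate: np.ndarray

    def __post_init__(self):
        if np.any(self.width <= 0):
            raise ValueError("tuning widths must be > 0")
        if np.any(self.peak_rate < 0) or np.any(self.baseline_rate < 0):
            raise ValueError("rates must be >= 0")

    @property
    def n_neurons(self) -> int:
        return len(self.tuning_class)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tuning_class": self.tuning_class,
                "preferred": self.preferred,
                "width": self.width,
                "peak_rate": self.peak_rate,
                "direction": self.direction,
                "baseline_rate": self.baseline_rate,
            }
        )


@dataclass
class FluorescenceTraces:
    """Relative fluorescence (dF/F0) per neuron per frame."""

    traces: np.ndarray
    frame_rate: float
    indicator: str  # GCaMP6f or GCaMP6s

    def __post_init__(self):
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("traces must be finite")
        if self.indicator not in ("GCaMP6f", "GCaMP6s"):
            raise ValueError(f"unknown indicator {self.indicator!r}")


@dataclass
class ActivityMatrix:
    """Binary N x K neurons-by-time raster plus the frame-level activity filter.

    retained_frames indexes the time bins that pass the modality filter
    (imaging: >1 active neuron; ephys: >=15 active neurons) and is what the
    embedding consumes; original indices are preserved so behavior stays
    aligned.
    """

    values: np.ndarray
    bin_width: float
    modality: str  # imaging | ephys
    retained_frames: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-d (neurons x bins)")
        uniq = np.unique(self.values)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("activity matrix must be binary")
        self.values = self.values.astype(np.uint8)
        if self.modality not in ("imaging", "ephys"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.retained_frames is None:
            self.retained_frames = default_frame_filter(self.values, self.modality)
        self.retained_frames = np.asarray(self.retained_frames, dtype=np.int64)

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def retained(self) -> np.ndarray:
        """Activity restricted to retained frames, as (frames x neurons)."""
        return self.values[:, self.retained_frames].T


def default_frame_filter(values: np.ndarray, modality: str) -> np.ndarray:
    """Frame filter: imaging keeps bins with >1 active neuron, ephys >=15."""
    counts = values.sum(axis=0)
    if modality == "imaging":
        return np.flatnonzero(counts > 1)
    return np.flatnonzero(counts >= 15)


@dataclass
class NeighborGraph:
    """OR-symmetrized binary kNN graph over points."""

    adjacency: "object"  # scipy.sparse matrix, binary, symmetric, zero diagonal
    neighbor_fraction: float
    k: int
    nodes: np.ndarray | None = None


@dataclass
class Embedding:
    """Low-dimensional spectral coordinates, rows aligned with frame_index."""

    coords: np.ndarray
    frame_index: np.ndarray
    stage: int
    eigenvalues: np.ndarray
    dropped_frames: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]


@dataclass
class Segment:
    state: int
    start: int  # index into the label array (inclusive)
    stop: int   # inclusive
    subtype: int = 0

    @property
    def length(self) -> int:
        return self.stop - self.start + 1


@dataclass
class StateModel:
    """Per-frame network-state labels plus their temporal organization.

    labels uses -1 for unassigned points; rows align with frame_index (the
    original time-bin indices of the embedded points).  ordering is a
    permutation of state ids; ordering_mode is 'linear' or 'cyclic'.
    """

    labels: np.ndarray
    frame_index: np.ndarray
    n_states: int
    segments: list = field(default_factory=list)
    frame_transitions: np.ndarray | None = None
    segment_transitions: np.ndarray | None = None
    ordering: np.ndarray | None = None
    ordering_mode: str | None = None
    centroids: np.ndarray | None = None

    def state_sizes(self) -> np.ndarray:
        return np.bincount(self.labels[self.labels >= 0], minlength=self.n_states)


@dataclass
class InternalTrajectory:
    """Per-frame reconstructed latent coordinate.

    value is position-like in [0, 1] (linear mode) or an angle in [0, 2*pi)
    (circular mode); rows align with frame_index.  gauge records the
    reflection/rotation chosen when an external reference was supplied;
    error_series is the per-frame mismatch against it (circular errors in
    (-pi, pi]).
    """

    value: np.ndarray
    frame_index: np.ndarray
    mode: str  # linear | circular
    gauge: dict = field(default_factory=dict)
    error_series: np.ndarray | None = None


@dataclass
class TuningCurve:
    """Binned occupancy, event counts and rate over an internal or external variable."""

    bin_centers: np.ndarray
    occupancy: np.ndarray
    event_counts: np.ndarray
    rate: np.ndarray
    mode: str    # linear | circular
    source: str  # internal | external
    raw_occupancy: np.ndarray | None = None
    raw_counts: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers)


@dataclass
class DimensionEstimate:
    radii: np.ndarray
    mean_counts: np.ndarray
    slope: float
    fit_window: tuple
    degenerate: bool = False


@dataclass
class BettiResult:
    radii: np.ndarray
    betti_curves: np.ndarray      # 3 x n_radii
    stable_betti: tuple
    plateau: tuple                # (r_lo, r_hi) of the winning plateau
    landmarks: np.ndarray
    low_confidence: bool = False
    intervals: dict | None = None


@dataclass
class BidirectionalityResult:
    value: float
    p_right: np.ndarray
    p_left: np.ndarray
    n_bins: int
    variant: str


@dataclass
class DecodeResult:
    decoded: np.ndarray
    actual: np.ndarray | None = None
    error_series: np.ndarray | None = None
    mse: float | None = None
    explained_variance: float | None = None
    gauge: dict = field(default_factory=dict)
    shuffle_p: float | None = None
    mode: str = "linear"   # linear | circular
    valid: np.ndarray | None = None


@dataclass
class VariabilityResult:
    joint_rate_map: np.ndarray    # 20 x 20 (phase x time)
    sd_t: float
    sd_p: float


@dataclass
class StabilityResult:
    day_pairs: list
    code_corr: np.ndarray
    structure_corr: np.ndarray
    elapsed: np.ndarray
    code_slope: tuple | None = None       # (slope, lo95, hi95)
    structure_slope: tuple | None = None
    shuffle_p: np.ndarray | None = None
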