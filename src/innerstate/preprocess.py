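"""From fluorescence traces or spike trains to filtered binary activity.

Event detection follows the standard pipeline for GCaMP6 miniscope data:
median-trace subtraction over a 20-s sliding window, 2-Hz low-pass, a
MAD-based amplitude threshold (4 MAD for GCaMP6s, 5 for GCaMP6f), a minimum
indicator decay time (600 / 200 ms), and peak-prominence rules that prevent a
single transient from registering several events.  Each accepted event marks
the neuron active for two consecutive frames at the transient peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.signal import butter, filtfilt, find_peaks
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ActivityMatrix, FluorescenceTraces


@dataclass
class EventDetectionConfig:
    """Thresholds of the Ca2+ event detector.

    mad_threshold is in units of the median absolute deviation of the
    filtered trace (4 for GCaMP6s, 5 for GCaMP6f); the "next peak" prominence
    rule uses half of it.  min_decay is the minimum indicator decay time in
    seconds (0.6 GCaMP6s / 0.2 GCaMP6f), measured from the peak to the first
    crossing of half the peak amplitude.
    """

    mad_threshold: float = 5.0
    min_decay: float = 0.2
    lowpass_cutoff: float = 2.0       # Hz
    median_window: float = 20.0       # s
    min_event_rate: float = 0.01      # Hz, neurons below are discarded
    min_event_amplitude: float = 0.01  # dF/F0 (1%)
    active_frames_per_event: int = 2

    def __post_init__(self):
        for name in ("mad_threshold", "min_decay", "lowpass_cutoff", "median_window",
                     "min_event_rate", "min_event_amplitude", "active_frames_per_event"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def for_indicator(cls, indicator: str) -> "EventDetectionConfig":
        if indicator == "GCaMP6s":
            return cls(mad_threshold=4.0, min_decay=0.6)
        if indicator == "GCaMP6f":
            return cls(mad_threshold=5.0, min_decay=0.2)
        raise ValueError(f"unknown indicator {indicator!r}")


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def _detect_one(trace: np.ndarray, fr: float, cfg: EventDetectionConfig):
    """Return (event_peak_frames, event_amplitudes) for one filtered trace."""
    mad = _mad(trace)
    if mad == 0:
        return np.empty(0, np.int64), np.empty(0)
    thr = cfg.mad_threshold * mad
    above = trace > thr
    if not above.any():
        return np.empty(0, np.int64), np.empty(0)
    # contiguous supra-threshold candidate regions
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1)
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        stops = np.r_[stops, len(trace) - 1]

    min_decay_frames = cfg.min_decay * fr
    peaks_out, amps_out = [], []
    for s, e in zip(starts, stops):
        seg = trace[s:e + 1]
        if len(seg) < 3:
            pk = np.array([int(np.argmax(seg))])
        else:
            pk, _ = find_peaks(seg)
            if pk.size == 0:
                pk = np.array([int(np.argmax(seg))])
        heights = seg[pk]
        # prominence rules within the candidate event: a true peak must rise
        # mad_threshold MADs above the preceding peak and half that above the
        # following one
        keep = np.ones(pk.size, bool)
        for j in range(pk.size):
            if j > 0 and heights[j] - heights[j - 1] < cfg.mad_threshold * mad:
                keep[j] = False
            if j < pk.size - 1 and heights[j] - heights[j + 1] < 0.5 * cfg.mad_threshold * mad:
                keep[j] = False
        pk = pk[keep]
        for p in pk:
            gp = s + p
            amp = trace[gp]
            # decay time: peak to first crossing of half the peak amplitude
            tail = trace[gp:]
            below = np.flatnonzero(tail < 0.5 * amp)
            decay = below[0] if below.size else len(tail)
            if decay >= min_decay_frames:
                peaks_out.append(gp)
                amps_out.append(amp)
    return np.asarray(peaks_out, np.int64), np.asarray(amps_out)


def detect_ca_events(traces: FluorescenceTraces, config: EventDetectionConfig | None = None,
                     neighbor_pairs: list | None = None) -> ActivityMatrix:
    """Detect Ca2+ events in dF/F0 traces and return the binary raster.

    Neurons whose event rate falls below ``min_event_rate`` or whose mean
    event amplitude falls below ``min_event_amplitude`` are zeroed out.
    ``neighbor_pairs`` is an optional list of (i, j) index pairs of cells
    close enough for fluorescence crosstalk: near-simultaneous events
    (within 200 ms) in a pair keep only the higher-amplitude one, and a pair
    with event correlation > 0.9 drops the lower-amplitude cell entirely.
    """
    cfg = config or EventDetectionConfig.for_indicator(traces.indicator)
    fr = traces.frame_rate
    if fr < 2 * cfg.lowpass_cutoff:
        raise ValueError(
            f"frame_rate {fr} Hz too low for a {cfg.lowpass_cutoff} Hz low-pass filter")
    n, k = traces.traces.shape
    win = int(round(cfg.median_window * fr)) | 1  # odd

    b, a = butter(2, cfg.lowpass_cutoff / (fr / 2.0), btype="low")
    values = np.zeros((n, k), dtype=np.uint8)
    ev_frames: list[np.ndarray] = []
    ev_amps: list[np.ndarray] = []
    for i in range(n):
        tr = traces.traces[i].astype(float)
        tr = tr - median_filter(tr, size=min(win, k), mode="nearest")
        if k > 12:  # filtfilt needs padding room
            tr = filtfilt(b, a, tr)
        pk, amp = _detect_one(tr, fr, cfg)
        ev_frames.append(pk)
        ev_amps.append(amp)

    if neighbor_pairs:
        ev_frames, ev_amps = _resolve_crosstalk(ev_frames, ev_amps, neighbor_pairs, fr, k)

    duration = k / fr
    for i in range(n):
        pk, amp = ev_frames[i], ev_amps[i]
        if pk.size == 0:
            continue
        if pk.size / duration < cfg.min_event_rate or amp.mean() < cfg.min_event_amplitude:
            continue
        for p in pk:
            values[i, p:p + cfg.active_frames_per_event] = 1
    return ActivityMatrix(values=values, bin_width=1.0 / fr, modality="imaging")


def _resolve_crosstalk(ev_frames, ev_amps, neighbor_pairs, fr, n_bins):
    ev_frames = [f.copy() for f in ev_frames]
    ev_amps = [a.copy() for a in ev_amps]
    win = int(round(0.2 * fr))
    for i, j in neighbor_pairs:
        # only one of a neighbor pair may register an event in any 200 ms window
        keep_i = np.ones(ev_frames[i].size, bool)
        keep_j = np.ones(ev_frames[j].size, bool)
        for ii, fi in enumerate(ev_frames[i]):
            close = np.abs(ev_frames[j] - fi) <= win
            for jj in np.flatnonzero(close):
                if ev_amps[i][ii] >= ev_amps[j][jj]:
                    keep_j[jj] = False
                else:
                    keep_i[ii] = False
        ev_frames[i], ev_amps[i] = ev_frames[i][keep_i], ev_amps[i][keep_i]
        ev_frames[j], ev_amps[j] = ev_frames[j][keep_j], ev_amps[j][keep_j]
        # highly correlated neighbors: drop the weaker cell outright
        bi = np.zeros(n_bins)
        bj = np.zeros(n_bins)
        bi[ev_frames[i]] = 1
        bj[ev_frames[j]] = 1
        if bi.std() > 0 and bj.std() > 0 and np.corrcoef(bi, bj)[0, 1] > 0.9:
            weaker = i if (np.mean(ev_amps[i]) if ev_amps[i].size else 0) <= \
                (np.mean(ev_amps[j]) if ev_amps[j].size else 0) else j
            ev_frames[weaker] = np.empty(0, np.int64)
            ev_amps[weaker] = np.empty(0)
    return ev_frames, ev_amps


class CalciumEventDetector(BaseEstimator, TransformerMixin):
    """Estimator wrapper around :func:`detect_ca_events`.

    ``transform`` maps :class:`FluorescenceTraces` to an
    :class:`ActivityMatrix`; parameters mirror
    :class:`EventDetectionConfig` and participate in ``get_params`` /
    ``set_params`` so the detector composes with sklearn model selection.
    """

    def __init__(self, mad_threshold=None, min_decay=None, lowpass_cutoff=2.0,
                 median_window=20.0, min_event_rate=0.01, min_event_amplitude=0.01):
        self.mad_threshold = mad_threshold
        self.min_decay = min_decay
        self.lowpass_cutoff = lowpass_cutoff
        self.median_window = median_window
        self.min_event_rate = min_event_rate
        self.min_event_amplitude = min_event_amplitude

    def _config(self, traces: FluorescenceTraces) -> EventDetectionConfig:
        base = EventDetectionConfig.for_indicator(traces.indicator)
        return EventDetectionConfig(
            mad_threshold=self.mad_threshold or base.mad_threshold,
            min_decay=self.min_decay or base.min_decay,
            lowpass_cutoff=self.lowpass_cutoff,
            median_window=self.median_window,
            min_event_rate=self.min_event_rate,
            min_event_amplitude=self.min_event_amplitude,
        )

    def fit(self, X: FluorescenceTraces, y=None):
        self.config_ = self._config(X)
        return self

    def transform(self, X: FluorescenceTraces) -> ActivityMatrix:
        return detect_ca_events(X, self._config(X))


def build_activity_matrix(events, bin_width: float, modality: str,
                          n_neurons: int | None = None,
                          duration: float | None = None) -> ActivityMatrix:
    """Bin and binarize events or spike trains into an :class:`ActivityMatrix`.

    ``events`` may be: a list of per-neuron spike-time arrays (seconds); a
    pandas DataFrame with columns ``(neuron_id, t_s)`` or ``(neuron, frame)``;
    or an already-binned (neurons x bins) array, which is binarized.  The
    modality filter (imaging: >1 active neuron per bin; ephys: >=15) is
    applied to ``retained_frames``; original bin indices are preserved.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if isinstance(events, np.ndarray):
        values = (np.asarray(events) > 0).astype(np.uint8)
        return ActivityMatrix(values=values, bin_width=bin_width, modality=modality)

    if isinstance(events, pd.DataFrame):
        cols = set(events.columns)
        if {"neuron_id", "t_s"} <= cols:
            neuron = events["neuron_id"].to_numpy(np.int64)
            b = np.floor(events["t_s"].to_numpy(float) / bin_width).astype(np.int64)
        elif {"neuron", "frame"} <= cols:
            neuron = events["neuron"].to_numpy(np.int64)
            b = events["frame"].to_numpy(np.int64)
        else:
            raise ValueError("event table needs (neuron_id, t_s) or (neuron, frame) columns")
        n = n_neurons if n_neurons is not None else (int(neuron.max()) + 1 if len(neuron) else 0)
        k = int(np.ceil(duration / bin_width)) if duration is not None else \
            (int(b.max()) + 1 if len(b) else 0)
        values = np.zeros((n, k), dtype=np.uint8)
        ok = (b >= 0) & (b < k)
        values[neuron[ok], b[ok]] = 1
        return ActivityMatrix(values=values, bin_width=bin_width, modality=modality)

    # list of spike-time arrays
    trains = [np.asarray(t, float) for t in events]
    n = n_neurons if n_neurons is not None else len(trains)
    if duration is None:
        duration = max((t.max() for t in trains if t.size), default=0.0) + bin_width
    k = int(np.ceil(duration / bin_width))
    values = np.zeros((n, k), dtype=np.uint8)
    for i, t in enumerate(trains):
        if t.size:
            b = np.floor(t / bin_width).astype(np.int64)
            b = b[(b >= 0) & (b < k)]
            values[i, b] = 1
    return ActivityMatrix(values=values, bin_width=bin_width, modality=modality)


def shuffle_control(m: ActivityMatrix, mode: str, seed: int = 0) -> ActivityMatrix:
    """Time- or cell-shuffled control raster.

    ``mode='time'`` shuffles activity times independently per cell, preserving
    every row sum; ``mode='cell'`` shuffles the identity of active cells per
    time bin, preserving every column sum.  Both destroy the population's
    correlational structure while keeping the marginals; the frame filter is
    re-applied to the shuffled matrix.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    v = m.values
    if mode == "time":
        perm = np.argsort(rng.random(v.shape), axis=1)
        out = np.take_along_axis(v, perm, axis=1)
    elif mode == "cell":
        perm = np.argsort(rng.random(v.shape), axis=0)
        out = np.take_along_axis(v, perm, axis=0)
    else:
        raise ValueError(f"unknown shuffle mode {mode!r}")
    return ActivityMatrix(values=out, bin_width=m.bin_width, modality=m.modality)
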