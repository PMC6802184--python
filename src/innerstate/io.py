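"""Readers and writers for sessions, rasters, embeddings and results.

Column conventions (version 1):

- event CSV: long format with columns ``neuron`` (0-based id) and ``frame``
  (0-based time bin);
- spike table CSV: columns ``neuron_id``, ``t_s`` (seconds);
- embedding table: ``frame_index, x1..xd`` plus a JSON sidecar holding the
  neighbor fractions, eigenvalues and dropped frames;
- session container: HDF5 with groups ``activity`` (raster, bin width,
  modality, retained frames), ``behavior`` and ``truth``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import ActivityMatrix, BehaviorTrack, Embedding, GroundTruthTuning

IO_VERSION = 1


def events_to_csv(m: ActivityMatrix, path):
    neuron, frame = np.nonzero(m.values)
    pd.DataFrame({"neuron": neuron, "frame": frame}).to_csv(path, index=False)


def events_from_csv(path, bin_width: float, modality: str, n_neurons: int | None = None,
                    n_bins: int | None = None) -> ActivityMatrix:
    from .preprocess import build_activity_matrix

    df = pd.read_csv(path)
    duration = None if n_bins is None else n_bins * bin_width
    return build_activity_matrix(df, bin_width=bin_width, modality=modality,
                                 n_neurons=n_neurons, duration=duration)


def spike_table_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"neuron_id", "t_s"} <= set(df.columns):
        raise ValueError("spike table needs columns neuron_id, t_s")
    return df


def _write_optional(group, name, arr):
    if arr is not None:
        if arr.dtype == object:
            group.create_dataset(name, data=np.asarray(arr, dtype="S"))
        else:
            group.create_dataset(name, data=arr)


def save_session(path, behavior: BehaviorTrack, activity: ActivityMatrix,
                 truth: GroundTruthTuning | None = None):
    with h5py.File(path, "w") as f:
        f.attrs["io_version"] = IO_VERSION
        g = f.create_group("activity")
        g.create_dataset("values", data=activity.values, compression="gzip")
        g.create_dataset("retained_frames", data=activity.retained_frames)
        g.attrs["bin_width"] = activity.bin_width
        g.attrs["modality"] = activity.modality
        g = f.create_group("behavior")
        g.create_dataset("time", data=behavior.time)
        for name in ("position", "head_direction", "running_direction", "speed",
                     "episode"):
            _write_optional(g, name, getattr(behavior, name))
        _write_optional(g, "behavior_label", behavior.behavior_label)
        if behavior.track_length is not None:
            g.attrs["track_length"] = behavior.track_length
        if truth is not None:
            g = f.create_group("truth")
            _write_optional(g, "tuning_class", truth.tuning_class)
            for name in ("preferred", "width", "peak_rate", "direction", "baseline_rate"):
                g.create_dataset(name, data=getattr(truth, name))


def load_session(path):
    with h5py.File(path, "r") as f:
        g = f["activity"]
        activity = ActivityMatrix(values=g["values"][...], bin_width=float(g.attrs["bin_width"]),
                                  modality=str(g.attrs["modality"]),
                                  retained_frames=g["retained_frames"][...])
        g = f["behavior"]

        def opt(name):
            return g[name][...] if name in g else None

        label = opt("behavior_label")
        if label is not None:
            label = label.astype(str).astype(object)
        behavior = BehaviorTrack(
            time=g["time"][...], position=opt("position"),
            head_direction=opt("head_direction"), running_direction=opt("running_direction"),
            speed=opt("speed"), behavior_label=label, episode=opt("episode"),
            track_length=float(g.attrs["track_length"]) if "track_length" in g.attrs else None)
        truth = None
        if "truth" in f:
            g = f["truth"]
            truth = GroundTruthTuning(
                tuning_class=g["tuning_class"][...].astype(str).astype(object),
                preferred=g["preferred"][...], width=g["width"][...],
                peak_rate=g["peak_rate"][...], direction=g["direction"][...],
                baseline_rate=g["baseline_rate"][...])
    return behavior, activity, truth


def save_embedding(prefix, emb: Embedding, p1: float | None = None, p2: float | None = None):
    prefix = Path(prefix)
    cols = {"frame_index": emb.frame_index}
    for d in range(emb.n_dims):
        cols[f"x{d + 1}"] = emb.coords[:, d]
    pd.DataFrame(cols).to_csv(prefix.with_suffix(".csv"), index=False)
    sidecar = {"io_version": IO_VERSION, "stage": emb.stage, "p1": p1, "p2": p2,
               "eigenvalues": [float(v) for v in emb.eigenvalues],
               "dropped_frames": [int(v) for v in emb.dropped_frames]}
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_embedding(prefix) -> Embedding:
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".csv"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    coords = df[[c for c in df.columns if c.startswith("x")]].to_numpy()
    return Embedding(coords=coords, frame_index=df["frame_index"].to_numpy(np.int64),
                     stage=meta["stage"], eigenvalues=np.asarray(meta["eigenvalues"]),
                     dropped_frames=np.asarray(meta["dropped_frames"], dtype=np.int64))


def curve_table(curves: dict) -> pd.DataFrame:
    """Long-format table (neuron, bin, occupancy, count, rate) of tuning curves."""
    rows = []
    for neuron, c in curves.items():
        for i in range(c.n_bins):
            rows.append((neuron, float(c.bin_centers[i]), float(c.occupancy[i]),
                         float(c.event_counts[i]), float(c.rate[i])))
    return pd.DataFrame(rows, columns=["neuron", "bin", "occupancy", "count", "rate"])


def load_traces(path, frame_rate: float, indicator: str) -> "FluorescenceTraces":
    """Read a neurons-by-frames dF/F0 trace matrix from CSV or NPZ."""
    from .containers import FluorescenceTraces

    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as f:
            traces = f[f.files[0]]
    else:
        traces = pd.read_csv(path, header=None).to_numpy(float)
    return FluorescenceTraces(traces=traces, frame_rate=frame_rate, indicator=indicator)


def save_betti(prefix, result):
    """Betti curves and persistence intervals as tables, plateau report as JSON."""
    prefix = Path(prefix)
    pd.DataFrame({"radius": result.radii, "b0": result.betti_curves[0],
                  "b1": result.betti_curves[1], "b2": result.betti_curves[2]}
                 ).to_csv(prefix.with_suffix(".curves.csv"), index=False)
    rows = [(dim, float(b), float(d)) for dim, iv in (result.intervals or {}).items()
            for b, d in iv]
    pd.DataFrame(rows, columns=["dim", "birth", "death"]).to_csv(
        prefix.with_suffix(".intervals.csv"), index=False)
    report = {"stable_betti": list(result.stable_betti),
              "plateau": list(result.plateau),
              "low_confidence": bool(result.low_confidence),
              "n_landmarks": int(len(result.landmarks))}
    prefix.with_suffix(".json").write_text(json.dumps(report, indent=2))


def save_state_model(prefix, model):
    """Per-frame labels as a table; ordering and transition matrices as JSON."""
    prefix = Path(prefix)
    pd.DataFrame({"frame_index": model.frame_index, "state": model.labels}).to_csv(
        prefix.with_suffix(".labels.csv"), index=False)
    payload = {"n_states": int(model.n_states),
               "ordering": None if model.ordering is None else
               [int(s) for s in model.ordering],
               "ordering_mode": model.ordering_mode}
    for name in ("frame_transitions", "segment_transitions"):
        mat = getattr(model, name)
        payload[name] = None if mat is None else np.asarray(mat).tolist()
    prefix.with_suffix(".json").write_text(json.dumps(payload, indent=2))


def save_decode_result(prefix, result, frame_index=None):
    """Per-frame decode table plus a JSON summary (mse, EV, shuffle p, gauge)."""
    prefix = Path(prefix)
    n = len(result.decoded)
    cols = {"frame": np.arange(n) if frame_index is None else frame_index,
            "decoded": result.decoded}
    if result.actual is not None:
        cols["actual"] = result.actual
    if result.error_series is not None:
        cols["error"] = result.error_series
    pd.DataFrame(cols).to_csv(prefix.with_suffix(".csv"), index=False)
    summary = {"mse": result.mse, "explained_variance": result.explained_variance,
               "shuffle_p": result.shuffle_p, "mode": result.mode,
               "gauge": {k: (bool(v) if isinstance(v, (bool, np.bool_)) else float(v))
                         for k, v in result.gauge.items()}}
    prefix.with_suffix(".json").write_text(json.dumps(summary, indent=2))


def stability_table(result) -> pd.DataFrame:
    """Per-day-pair stability results as a tidy table."""
    return pd.DataFrame({
        "day_a": [p[0] for p in result.day_pairs],
        "day_b": [p[1] for p in result.day_pairs],
        "elapsed": result.elapsed,
        "code_corr": result.code_corr,
        "structure_corr": result.structure_corr,
        "shuffle_p": result.shuffle_p,
    })
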