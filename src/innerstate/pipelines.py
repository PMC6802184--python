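"""End-to-end analysis pipelines composing the package's stages.

These helpers wire the canonical orderings of operations: embed -> cluster ->
segment -> subtype-split -> order -> reconstruct -> tuning curves.  They are
what the command line, the validation suite and the reproduction script run;
each stage remains available separately for custom analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import (
    ActivityMatrix,
    BehaviorTrack,
    Embedding,
    InternalTrajectory,
    Segment,
    StateModel,
)
from .embedding import P2_DEFAULT, embed_two_stage
from .states import (
    traversal_end_states,
    choose_max_gap,
    choose_min_length,
    cluster_states,
    order_states,
    segment_subtypes,
    temporal_segments,
    transition_matrix,
)
from .tuning import InsufficientEvents, internal_tuning_curve, reconstruct_internal_variable


def restrict_frames(m: ActivityMatrix, frames: np.ndarray) -> ActivityMatrix:
    """Copy of the activity matrix with retained_frames narrowed to ``frames``."""
    keep = np.intersect1d(m.retained_frames, np.asarray(frames))
    return ActivityMatrix(values=m.values, bin_width=m.bin_width, modality=m.modality,
                          retained_frames=keep)


@dataclass
class StateAnalysis:
    """Clustered, segmented and (cyclically) ordered description of a session."""

    embedding: Embedding
    model: StateModel
    segments: list[Segment] = field(default_factory=list)
    subtype_of_segment: np.ndarray | None = None
    resolved_state_of_segment: np.ndarray | None = None
    n_resolved: int = 0
    resolved_ordering: np.ndarray | None = None
    resolved_transitions: np.ndarray | None = None
    max_gap: int = 2
    min_length: int = 5


def analyze_states(embedding: Embedding, activity: ActivityMatrix,
                   min_points: int = 250, seed: int = 0,
                   max_gap: int | None = None, min_length: int | None = None,
                   ) -> StateAnalysis:
    """Topological clustering plus temporal segmentation and subtype split.

    Each state's segments are split into subtypes by segment-level PCA;
    (state, subtype) pairs become "resolved" states, whose segment-level
    transition matrix is ordered cyclically when 3 <= M <= 10.
    """
    model = cluster_states(embedding, mode="topological", min_points=min_points, seed=seed)
    out = StateAnalysis(embedding=embedding, model=model)
    if model.n_states == 0:
        return out
    labels = model.labels
    if max_gap is None:
        max_gap = choose_max_gap(labels)
    if min_length is None:
        min_length = choose_min_length(labels, max_gap=max_gap)
    out.max_gap, out.min_length = max_gap, min_length
    segments = temporal_segments(labels, max_gap=max_gap, min_length=min_length)
    out.segments = segments
    model.segments = segments
    model.frame_transitions = transition_matrix(labels, model.n_states, level="frame")

    # subtype split per state
    subtype = np.zeros(len(segments), dtype=np.int64)
    resolved = {}
    res_ids = np.empty(len(segments), dtype=np.int64)
    for s in range(model.n_states):
        idx = [i for i, seg in enumerate(segments) if seg.state == s]
        segs = [segments[i] for i in idx]
        labs = segment_subtypes(activity, segs, embedding.frame_index)
        for i, lab in zip(idx, labs):
            subtype[i] = lab
            segments[i].subtype = int(lab)
    for i, seg in enumerate(segments):
        key = (seg.state, subtype[i])
        if key not in resolved:
            resolved[key] = len(resolved)
        res_ids[i] = resolved[key]
    out.subtype_of_segment = subtype
    out.resolved_state_of_segment = res_ids
    out.n_resolved = len(resolved)

    if out.n_resolved >= 2:
        seq = res_ids[np.argsort([seg.start for seg in segments], kind="stable")]
        trans = np.zeros((out.n_resolved, out.n_resolved))
        np.add.at(trans, (seq[:-1], seq[1:]), 1.0)
        rows = trans.sum(axis=1, keepdims=True)
        trans = np.where(rows > 0, trans / np.maximum(rows, 1e-300), 0.0)
        out.resolved_transitions = trans
        model.segment_transitions = transition_matrix(segments, model.n_states,
                                                      level="segment")
        if 3 <= out.n_resolved <= 10:
            out.resolved_ordering = order_states(trans, mode="cyclic")
    return out


def winding_numbers(behavior: BehaviorTrack, analysis: StateAnalysis,
                    min_segments: int = 3) -> np.ndarray:
    """|winding| of the state sequence through the cyclic ordering per run cycle.

    A full behavioral cycle spans consecutive entries into drinking at the
    left end.  The cyclic ordering positions of the in-cycle segments are
    unwrapped (steps mapped to (-M/2, M/2]) and the absolute net rotation in
    units of full turns is returned per cycle.
    """
    if analysis.resolved_ordering is None:
        raise ValueError("analysis has no cyclic ordering")
    m = analysis.n_resolved
    pos = np.empty(m, dtype=np.int64)
    pos[analysis.resolved_ordering] = np.arange(m)
    lab = behavior.behavior_label
    is_start = (lab == "drink_L") & np.r_[True, lab[:-1] != "drink_L"]
    cycle_starts = np.flatnonzero(is_start)
    if len(cycle_starts) < 2:
        return np.empty(0)
    order = np.argsort([seg.start for seg in analysis.segments], kind="stable")
    seg_frames = np.array([analysis.embedding.frame_index[analysis.segments[i].start]
                           for i in order])
    seg_pos = pos[analysis.resolved_state_of_segment[order]]
    windings = []
    for c0, c1 in zip(cycle_starts[:-1], cycle_starts[1:]):
        sel = (seg_frames >= c0) & (seg_frames < c1)
        p = seg_pos[sel]
        if len(p) < min_segments:
            continue
        # close the loop with the first segment of the next cycle so a full
        # behavioral cycle maps to a closed path on the state ring
        after = np.flatnonzero(seg_frames >= c1)
        if after.size:
            p = np.r_[p, seg_pos[after[0]]]
        steps = np.diff(p.astype(float))
        steps = np.mod(steps + m / 2, m) - m / 2  # wrap into [-M/2, M/2)
        # a jump of exactly half the ring is directionally ambiguous (it
        # arises when intermediate states are skipped); resolve it toward the
        # rotation direction of the unambiguous steps
        amb = steps == -m / 2
        if amb.any():
            majority = np.sign(steps[~amb].sum()) or 1.0
            steps[amb] = majority * m / 2
        windings.append(abs(steps.sum()) / m)
    return np.asarray(windings)


@dataclass
class LinearReconstruction:
    embedding: Embedding
    model: StateModel
    trajectory: InternalTrajectory
    frames: np.ndarray


def linear_reconstruction(activity: ActivityMatrix, behavior: BehaviorTrack,
                          frames: np.ndarray, seed: int = 0, mode: str = "kmeans",
                          n_subclusters: int = 10, min_points: int = 50,
                          p1: float = 0.005, p2: float = P2_DEFAULT,
                          min_k1: int = 30) -> LinearReconstruction:
    """Reconstruct an internal position from one running state's frames.

    ``frames`` are the original time bins of the running subtype (e.g. one
    direction).  The sub-population of frames is re-embedded and
    sub-clustered; since the running frames form a continuum rather than
    discrete blobs, the default parameterization is K-means (the standard
    choice for continuously distributed points), with topological
    sub-clustering (min 50 points per component, floor raised while more
    than 10 components appear, keeping the factorial ordering tractable)
    available via ``mode='topological'``.  Sub-clusters are ordered linearly
    with the traversal end-constraint trick and assigned evenly spaced
    internal positions; the reflection gauge is fixed against the measured
    position.  What matters for the stage-1 graph of a small sub-population
    is the neighbor *count*, not the fraction: the working fractions were
    set at full-session scale, where they give each node ~30-90 neighbors,
    so the count is floored at ``min_k1`` (and the fraction defaults to the
    top of its range) to keep the local geometry equally sampled here.
    """
    sub = restrict_frames(activity, frames)
    n_sub = len(sub.retained_frames)
    p1_eff = max(p1, min(0.5, min_k1 / max(n_sub, 1)))
    emb = embed_two_stage(sub, p1=p1_eff, p2=p2, seed=seed)
    if mode == "kmeans":
        model = cluster_states(emb, mode="kmeans", k=n_subclusters, seed=seed)
    else:
        mp = min_points
        while True:
            model = cluster_states(emb, mode="topological", min_points=mp, seed=seed)
            if model.n_states <= 10:
                break
            mp = int(mp * 1.5)
    if model.n_states < 3:
        raise ValueError(f"only {model.n_states} sub-clusters found; cannot order")
    gap = choose_max_gap(model.labels, candidates=range(1, 6))
    segments = temporal_segments(model.labels, max_gap=gap, min_length=3)
    model.segments = segments
    model.segment_transitions = transition_matrix(segments, model.n_states, level="segment")
    # frame-level transitions order the sub-clusters: fast mid-track clusters
    # are crossed in a handful of frames, so segment-level successions
    # under-sample them while consecutive data points do not
    model.frame_transitions = transition_matrix(model.labels, model.n_states, level="frame")
    ends = traversal_end_states(model.labels, emb.frame_index, model.n_states)
    model.ordering = order_states(model.frame_transitions, mode="linear", ends=ends)
    model.ordering_mode = "linear"
    external = behavior.position[emb.frame_index]
    traj = reconstruct_internal_variable(model, "linear", external=external)
    return LinearReconstruction(embedding=emb, model=model, trajectory=traj,
                                frames=emb.frame_index)


@dataclass
class RingReconstruction:
    embedding: Embedding
    model: StateModel
    trajectory: InternalTrajectory
    curves: dict


def ring_reconstruction(activity: ActivityMatrix, behavior: BehaviorTrack | None = None,
                        frames: np.ndarray | None = None, seed: int = 0,
                        n_states: int = 8, fit_gauge: bool = True) -> RingReconstruction:
    """K-means states, cyclic ordering and internal angle for ring-like data.

    The standard route for head-direction-like populations: continuous data
    get K-means (K = 8) parameterization, the clusters are ordered cyclically
    by their transition probabilities, frames receive the internal angle
    2*pi*k/M (temporally smoothed), and internal tuning curves are computed
    on 40 angular bins.  The rotation/reflection gauge is fixed against
    ``behavior.head_direction`` when available and requested.
    """
    sub = activity if frames is None else restrict_frames(activity, frames)
    emb = embed_two_stage(sub, seed=seed)
    model = cluster_states(emb, mode="kmeans", k=n_states, seed=seed)
    model.frame_transitions = transition_matrix(model.labels, model.n_states, level="frame")
    model.ordering = order_states(model.frame_transitions, mode="cyclic")
    model.ordering_mode = "cyclic"
    external = None
    if behavior is not None and fit_gauge and behavior.head_direction is not None:
        external = behavior.head_direction[emb.frame_index]
    traj = reconstruct_internal_variable(model, "circular", external=external)
    curves = {}
    for neuron in range(activity.n_neurons):
        try:
            curves[neuron] = internal_tuning_curve(activity, traj, neuron)
        except InsufficientEvents:
            continue
    return RingReconstruction(embedding=emb, model=model, trajectory=traj, curves=curves)


def running_frames(behavior: BehaviorTrack, activity: ActivityMatrix,
                   direction: int | None = None) -> np.ndarray:
    """Retained frames during running (optionally one direction)."""
    sel = behavior.running_direction != 0 if direction is None else \
        behavior.running_direction == direction
    return np.intersect1d(np.flatnonzero(sel), activity.retained_frames)
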