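"""From probability rasters to events and recording-level labels.

The raster is thresholded per class (``>=`` convention) into a boolean
activation matrix; maximal runs of active frames become events, brief gaps
are merged, and events shorter than the class's definitional minimum
duration (80 ms for wheezes, 100 ms for rhonchi, one 10 ms frame for
crackles) are discarded.  A recording is labeled positive for a class iff
at least one event of that class survives.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .phenomena import (
    CLASSES,
    FRAME_HOP_S,
    MIN_EVENT_DURATION_S,
    PhenomenonEvent,
    RecordingLabels,
)

#: Default gap (seconds) below which two runs of the same class are merged.
#: Tonal sounds may dip briefly in amplitude without ending; crackles are
#: individual transients and are never merged.
DEFAULT_MERGE_GAP_S = {
    "wheeze": 0.030,
    "rhonchus": 0.030,
    "fine_crackle": 0.0,
    "coarse_crackle": 0.0,
    "noise": 0.0,
}


def threshold_raster(raster: np.ndarray, thresholds=0.5) -> np.ndarray:
    """Boolean activation matrix: ``activation[i, c] = raster[i, c] >= t_c``.

    ``thresholds`` is a scalar or a per-class vector, each value in the open
    interval (0, 1).
    """
    r = np.asarray(raster, dtype=np.float64)
    if r.ndim != 2:
        raise ValueError(f"raster must be 2-D (frames x classes), got shape {r.shape}")
    t = np.broadcast_to(np.asarray(thresholds, dtype=np.float64), (r.shape[1],))
    if np.any(t <= 0.0) or np.any(t >= 1.0):
        raise ValueError(f"thresholds must lie strictly inside (0, 1), got {t}")
    return r >= t


def _runs(column: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) frame indices, end exclusive."""
    padded = np.diff(np.concatenate(([0], column.astype(np.int8), [0])))
    starts = np.nonzero(padded == 1)[0]
    ends = np.nonzero(padded == -1)[0]
    return list(zip(starts.tolist(), ends.tolist()))


def extract_events(
    activation: np.ndarray,
    class_names: Sequence[str] = CLASSES,
    merge_gap: Mapping[str, float] | float | None = None,
    min_duration: Mapping[str, float] | None = None,
    frame_hop: float = FRAME_HOP_S,
) -> list[PhenomenonEvent]:
    """Decode an activation matrix into per-class events.

    Per class: maximal runs of active frames become candidate events
    ``[start*hop, end*hop)``; runs separated by a gap of at most the class
    merge gap are joined; candidates shorter than the class minimum duration
    are discarded.
    """
    act = np.asarray(activation, dtype=bool)
    if act.ndim != 2 or act.shape[1] != len(class_names):
        raise ValueError(
            f"activation shape {act.shape} does not match {len(class_names)} classes"
        )
    if isinstance(merge_gap, (int, float)):
        merge_gap = {c: float(merge_gap) for c in class_names}
    gaps = {**DEFAULT_MERGE_GAP_S, **(merge_gap or {})}
    mins = {**MIN_EVENT_DURATION_S, **(min_duration or {})}
    events: list[PhenomenonEvent] = []
    eps = 1e-9
    for j, c in enumerate(class_names):
        gap_frames = int(round(gaps.get(c, 0.0) / frame_hop))
        min_frames = int(np.ceil(mins.get(c, 0.0) / frame_hop - eps))
        merged: list[list[int]] = []
        for start, end in _runs(act[:, j]):
            if merged and start - merged[-1][1] <= gap_frames:
                merged[-1][1] = end
            else:
                merged.append([start, end])
        for start, end in merged:
            if end - start < min_frames:
                continue
            events.append(
                PhenomenonEvent(c, round(start * frame_hop, 6), round(end * frame_hop, 6))
            )
    events.sort(key=lambda e: (e.onset, e.class_name))
    return events


def events_to_activation(
    events: Sequence[PhenomenonEvent],
    n_frames: int,
    class_names: Sequence[str] = CLASSES,
    frame_hop: float = FRAME_HOP_S,
) -> np.ndarray:
    """Inverse of :func:`extract_events` for events on the frame grid."""
    act = np.zeros((n_frames, len(class_names)), dtype=bool)
    index = {c: j for j, c in enumerate(class_names)}
    for ev in events:
        if ev.class_name not in index:
            continue
        first = int(round(ev.onset / frame_hop))
        last = int(round(ev.offset / frame_hop))
        act[max(first, 0) : min(last, n_frames), index[ev.class_name]] = True
    return act


def aggregate_labels(
    events: Sequence[PhenomenonEvent], class_names: Sequence[str] = CLASSES
) -> RecordingLabels:
    """Recording-level labels: class positive iff >= 1 surviving event."""
    present = {c: False for c in CLASSES}
    for ev in events:
        if ev.class_name in present:
            present[ev.class_name] = True
    return RecordingLabels(**present)


def decode_raster(
    raster: np.ndarray,
    thresholds=0.5,
    class_names: Sequence[str] = CLASSES,
    **kwargs,
) -> tuple[np.ndarray, list[PhenomenonEvent], RecordingLabels]:
    """Full post-processing chain: threshold, extract, aggregate."""
    act = threshold_raster(raster, thresholds)
    events = extract_events(act, class_names=class_names, **kwargs)
    return act, events, aggregate_labels(events, class_names)
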