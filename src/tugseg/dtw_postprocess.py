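"""Order-constrained correction of frame-level predictions and event extraction.

A TUG trial follows a strict subtask order — sit, sit-to-stand, walk, turn,
walk back, stand-to-sit, sit — but a frame classifier can emit short runs
of a wrong class inside a correct segment (fragmentation errors).  Aligning
the frame sequence to the canonical 7-slot template with a monotone
(DTW-style) assignment removes every out-of-order run: the corrected
labeling is the template-ordered segmentation minimizing the summed local
cost ``1 - p_t(class of the assigned slot)``, i.e. maximizing the total
probability mass the model itself put on the assigned classes.

The six slot boundaries of the optimal alignment are exactly the six TUG
events (StartMove..EndSit).  Boundary misplacement between *adjacent*
subtasks (shift/ambiguity errors) is inherently uncorrectable by an order
constraint and is out of scope here.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .labels import CANONICAL_TEMPLATE, N_CLASSES, Subtask
from .skeleton_io import EventTimes

#: class index of each of the 7 template slots
TEMPLATE_CLASSES = np.array([int(s) for s in CANONICAL_TEMPLATE])


@dataclasses.dataclass(frozen=True)
class SegmentBoundaries:
    """First-frame indices of template slots 1..6, partitioning [0, T).

    Slot s occupies frames ``[frames[s-1], frames[s])`` (with slot 0
    starting at frame 0 and slot 6 ending at ``n_frames``). The leading or
    trailing SIT slot may be empty; the five active slots may not.
    """

    frames: tuple[int, int, int, int, int, int]
    n_frames: int

    def __post_init__(self) -> None:
        f = self.frames
        if len(f) != 6:
            raise ValueError("need 6 boundary frames")
        if f[0] < 0 or f[5] > self.n_frames:
            raise ValueError("boundaries outside [0, T]")
        if any(f[i] >= f[i + 1] for i in range(5)):
            raise ValueError("active segments must be non-empty (strictly increasing boundaries)")

    def segment_slices(self) -> list[slice]:
        edges = [0, *self.frames, self.n_frames]
        return [slice(edges[i], edges[i + 1]) for i in range(7)]

    def labels(self) -> np.ndarray:
        """Per-frame class sequence implied by the boundaries."""
        out = np.empty(self.n_frames, dtype=np.int64)
        for slot, sl in enumerate(self.segment_slices()):
            out[sl] = TEMPLATE_CLASSES[slot]
        return out


def _as_probabilities(frame_input: np.ndarray) -> np.ndarray:
    x = np.asarray(frame_input)
    if x.ndim == 1:  # hard labels -> one-hot
        if not np.issubdtype(x.dtype, np.integer):
            raise ValueError("1-D input must be integer class labels")
        if x.min() < 0 or x.max() >= N_CLASSES:
            raise ValueError(f"labels must lie in [0, {N_CLASSES})")
        probs = np.zeros((len(x), N_CLASSES))
        probs[np.arange(len(x)), x] = 1.0
        return probs
    if x.ndim != 2 or x.shape[1] != N_CLASSES:
        raise ValueError(f"expected (T, {N_CLASSES}) probabilities or (T,) labels")
    if not np.all(np.isfinite(x)) or np.any(x < 0):
        raise ValueError("probabilities must be finite and non-negative")
    return x.astype(float)


def dtw_correct(
    frame_input: np.ndarray,
) -> tuple[np.ndarray, SegmentBoundaries]:
    """Align frame predictions to the canonical template.

    Parameters
    ----------
    frame_input : ndarray
        Either a ``(T, 5)`` matrix of per-frame class probabilities or a
        ``(T,)`` integer label sequence (treated as one-hot).

    Returns
    -------
    labels : ndarray, shape (T,)
        The corrected, template-ordered class per frame.
    boundaries : SegmentBoundaries
        The six slot boundaries of the optimal alignment.

    Notes
    -----
    Dynamic programming over (frame, slot): a frame may stay in its
    predecessor's slot or open the next slot; the leading and trailing SIT
    slots may be skipped. Ties are broken toward the earliest feasible
    boundaries. Optimal w.r.t. exhaustive enumeration of all boundary
    placements (checked against a brute-force oracle in the test suite).
    """
    probs = _as_probabilities(frame_input)
    T = len(probs)
    if T < 5:
        raise ValueError("need at least 5 frames to host the 5 active segments")

    cost = 1.0 - probs[:, TEMPLATE_CLASSES]  # (T, 7)

    # suffix DP: E[t, s] = min cost of frames t..T-1 with frame t in slot s
    E = np.full((T, 7), np.inf)
    E[T - 1, 5] = cost[T - 1, 5]
    E[T - 1, 6] = cost[T - 1, 6]
    for t in range(T - 2, -1, -1):
        nxt = E[t + 1]
        stay_or_advance = np.minimum(nxt, np.append(nxt[1:], np.inf))
        E[t] = cost[t] + stay_or_advance

    # greedy forward reconstruction; advancing whenever optimal yields the
    # lexicographically smallest boundary vector
    slot = 1 if E[0, 1] <= E[0, 0] else 0
    first_frame = {slot: 0}
    s = slot
    for t in range(1, T):
        if s < 6 and E[t, s + 1] <= E[t, s]:
            s += 1
            first_frame[s] = t
    edges = []
    for k in range(1, 7):
        if k in first_frame:
            edges.append(first_frame[k])
        else:  # trailing SIT never entered
            edges.append(T)
    boundaries = SegmentBoundaries(tuple(edges), T)
    return boundaries.labels(), boundaries


def alignment_cost(frame_input: np.ndarray, boundaries: SegmentBoundaries) -> float:
    """Total ``1 - p`` cost of a given template segmentation."""
    probs = _as_probabilities(frame_input)
    cost = 1.0 - probs[:, TEMPLATE_CLASSES]
    return float(sum(cost[sl, slot].sum() for slot, sl in enumerate(boundaries.segment_slices())))


def extract_events(boundaries: SegmentBoundaries, fps: float) -> EventTimes:
    """Convert the six slot boundaries to event times in seconds.

    StartMove = first sit-to-stand frame, StartWalk = first walk frame,
    StartTurn = first turn frame, EndTurn = first walk-back frame,
    StartSit = first stand-to-sit frame, EndSit = first trailing-sit frame.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    times = [f / fps for f in boundaries.frames]
    return EventTimes(*times)


def walk_segments(boundaries: SegmentBoundaries) -> tuple[slice, slice]:
    """The outbound-walk and walk-back frame ranges (template slots 2 and 4)."""
    slices = boundaries.segment_slices()
    return slices[2], slices[4]


__all__ = [
    "SegmentBoundaries",
    "TEMPLATE_CLASSES",
    "Subtask",
    "alignment_cost",
    "dtw_correct",
    "extract_events",
    "walk_segments",
]
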