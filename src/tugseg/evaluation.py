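"""Segmentation quality metrics.

Frame-level quality is scored per subtask class with one-vs-rest precision,
recall and their harmonic mean (F1), plus overall frame accuracy.  Timing
quality is scored as the mean absolute error (MAE) and population standard
deviation, in seconds, of the six event times across trials, and of the
total TUG time (StartMove to EndSit).  Ground-truth label reliability
between two raters is measured with the intraclass correlation
coefficient, ICC(2,1): two-way random effects, absolute agreement, single
rater.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Sequence

import numpy as np

from .dtw_postprocess import SegmentBoundaries
from .labels import EVENT_NAMES, PHASE_ORDER_DOC, Subtask
from .skeleton_io import EventTimes


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest frame counts for a single subtask class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred: np.ndarray, truth: np.ndarray, cls: int | Subtask) -> ConfusionCounts:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    p = pred == int(cls)
    t = truth == int(cls)
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def precision_recall_f1(
    counts: ConfusionCounts,
) -> tuple[float | None, float | None, float | None]:
    """Precision TP/(TP+FP), recall TP/(TP+FN), F1 = harmonic mean.

    A metric whose denominator is zero (class never predicted, or absent
    from the ground truth) is undefined and reported as None with a
    warning; F1 is None if either constituent is.
    """
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp > 0 else None
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else None
    if precision is None or recall is None:
        warnings.warn("undefined precision/recall (empty denominator)", stacklevel=2)
        f1 = None
    else:
        f1 = f1_score(precision, recall)
    return precision, recall, f1


def accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of frames whose predicted class equals the ground truth."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    if pred.size == 0:
        raise ValueError("empty input")
    return float(np.mean(pred == truth))


def event_errors(pred: EventTimes, truth: EventTimes) -> np.ndarray:
    """Per-event absolute timing error (seconds), in canonical event order."""
    return np.abs(pred.as_array() - truth.as_array())


def total_time_error(pred: EventTimes, truth: EventTimes) -> float:
    """Absolute error of the total TUG time (a uniform shift cancels)."""
    return abs(pred.total_tug_time - truth.total_tug_time)


def aggregate_event_errors(
    pairs: Sequence[tuple[EventTimes, EventTimes]],
) -> dict[str, dict[str, float]]:
    """MAE and population STD over trials, per event and for the total time."""
    if not pairs:
        raise ValueError("no trials to aggregate")
    errs = np.array([event_errors(p, t) for p, t in pairs])  # (n, 6)
    totals = np.array([total_time_error(p, t) for p, t in pairs])
    out = {
        name: {"mae": float(errs[:, i].mean()), "std": float(errs[:, i].std())}
        for i, name in enumerate(EVENT_NAMES)
    }
    out["total_tug_time"] = {"mae": float(totals.mean()), "std": float(totals.std())}
    return out


def icc(ratings: np.ndarray) -> float | None:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is an ``(n targets, k raters)`` table. Computed from the
    standard ANOVA mean squares (rows MSR, columns MSC, residual MSE):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    Returns None (undefined) when the table has no variance at all.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need an (n, k>=2) ratings table")
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 targets")
    grand = x.mean()
    if np.allclose(x, grand):
        warnings.warn("zero total variance: ICC undefined", stacklevel=2)
        return None
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        warnings.warn("zero denominator: ICC undefined", stacklevel=2)
        return None
    return float((msr - mse) / denom)


def subtask_durations(
    boundaries: SegmentBoundaries, fps: float, walk_distance: float = 3.0
) -> dict[str, float]:
    """Per-subtask durations (s) and mean walk speeds (m/s).

    Durations of the seven template segments sum to the recording length;
    walking speed is the straight-line course length divided by the
    segment duration, for the outbound walk and the walk back separately.
    """
    if fps <= 0 or walk_distance <= 0:
        raise ValueError("fps and walk_distance must be positive")
    edges = [0, *boundaries.frames, boundaries.n_frames]
    durs = [(edges[i + 1] - edges[i]) / fps for i in range(7)]
    out = dict(zip(PHASE_ORDER_DOC, durs))
    out["walk_speed"] = walk_distance / out["walk"]
    out["walk_back_speed"] = walk_distance / out["walk_back"]
    return out


@dataclasses.dataclass
class SegmentationReport:
    """Aggregate evaluation of a set of trials."""

    n_trials: int
    n_frames: int
    accuracy: float
    per_subtask: dict[str, dict[str, float | None]]
    event_timing: dict[str, dict[str, float]] | None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def evaluate_segmentation(
    pred_labels: Sequence[np.ndarray],
    truth_labels: Sequence[np.ndarray],
    event_pairs: Sequence[tuple[EventTimes, EventTimes]] | None = None,
) -> SegmentationReport:
    """Pooled (micro) frame metrics over trials, plus event-timing errors.

    Frame counts are pooled across trials before computing the per-class
    precision/recall/F1 and the overall accuracy; timing errors are
    aggregated per trial.
    """
    if len(pred_labels) != len(truth_labels) or not pred_labels:
        raise ValueError("need matching, non-empty prediction and truth lists")
    pred_all = np.concatenate([np.asarray(p) for p in pred_labels])
    truth_all = np.concatenate([np.asarray(t) for t in truth_labels])
    per_subtask: dict[str, dict[str, float | None]] = {}
    for cls in Subtask:
        if not np.any(truth_all == int(cls)) and not np.any(pred_all == int(cls)):
            per_subtask[cls.name] = {"precision": None, "recall": None, "f1": None}
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, r, f1 = precision_recall_f1(confusion(pred_all, truth_all, cls))
        per_subtask[cls.name] = {"precision": p, "recall": r, "f1": f1}
    return SegmentationReport(
        n_trials=len(pred_labels),
        n_frames=int(truth_all.size),
        accuracy=accuracy(pred_all, truth_all),
        per_subtask=per_subtask,
        event_timing=aggregate_event_errors(event_pairs) if event_pairs else None,
    )
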