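"""High-level model/results interface for TUG subtask segmentation.

`TugSegmenter` bundles the full pipeline behind a statsmodels-style API:
construct the model object from labeled trials, call :meth:`fit` to train
the dilated TCN on a subject-wise 6:2:2 split, and use the returned
`TugSegmenterResults` to predict, evaluate and summarize.

    >>> trials = batch_generate(60, DEFAULT_PRESETS["older_adult"], 0)
    >>> res = TugSegmenter(trials).fit(seed=0)
    >>> print(res.summary())
    >>> seg = res.predict_trial(trials[0].recording)
    >>> seg.events.total_tug_time
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .dtw_postprocess import SegmentBoundaries, dtw_correct, extract_events
from .evaluation import SegmentationReport, accuracy, evaluate_segmentation
from .joints import JointId
from .labels import Subtask
from .preprocess import FilterSpec, WindowSpec, make_windows, preprocess_features
from .skeleton_io import EventTimes, TrialRecording
from .synthetic_tug import SynthTrial
from .tcn_model import (
    ModelConfig,
    TCNModel,
    TrainConfig,
    TrainHistory,
    count_parameters,
    holdout_split,
    predict_frames,
    train,
)


@dataclasses.dataclass
class PredictedSegmentation:
    """Per-trial output: probabilities, raw and corrected labels, events."""

    probs: np.ndarray  # (T, 5)
    raw_labels: np.ndarray  # argmax, before order correction
    labels: np.ndarray  # template-ordered, after correction
    boundaries: SegmentBoundaries
    events: EventTimes


class TugSegmenter:
    """End-to-end TUG subtask segmentation model.

    Parameters
    ----------
    trials : sequence
        Labeled trials: `SynthTrial` objects or ``(recording, labels,
        events)`` tuples (events may be None).
    joints : tuple of JointId
        Input feature joints; the pelvis alone is the reference choice.
    model_config, train_config, filter_spec
        Architecture, optimization and preprocessing settings. The model
        ``input_dim`` is derived from the joint selection.
    """

    def __init__(
        self,
        trials: Sequence[SynthTrial | tuple],
        joints: tuple[JointId, ...] = (JointId.PELVIS,),
        model_config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
        filter_spec: FilterSpec | None = None,
    ):
        self.trials = [t if isinstance(t, SynthTrial) else SynthTrial(*t) for t in trials]
        if not self.trials:
            raise ValueError("need at least one trial")
        self.joints = tuple(joints)
        base = model_config or ModelConfig()
        self.model_config = dataclasses.replace(base, input_dim=3 * len(self.joints))
        self.train_config = train_config or TrainConfig()
        self.filter_spec = filter_spec
        self.window_spec = WindowSpec(window_size=self.model_config.window_size)

    # ------------------------------------------------------------------
    def _features(self, recording: TrialRecording) -> np.ndarray:
        spec = self.filter_spec or FilterSpec(fs_hz=recording.fps)
        return preprocess_features(recording, self.joints, spec)

    def _windows(self, trials: Sequence[SynthTrial]) -> tuple[np.ndarray, np.ndarray]:
        xs, ys = [], []
        for tr in trials:
            w, centers = make_windows(self._features(tr.recording), self.window_spec)
            xs.append(w.astype(np.float32))
            ys.append(np.asarray(tr.labels)[centers])
        return np.concatenate(xs), np.concatenate(ys)

    def fit(self, seed: int | None = None, verbose: bool = False) -> "TugSegmenterResults":
        """Train on a subject-wise 6:2:2 split and evaluate on the test subjects."""
        tc = self.train_config if seed is None else dataclasses.replace(self.train_config, seed=seed)
        subjects = [t.recording.subject_id for t in self.trials]
        tr_ids, va_ids, te_ids = holdout_split(subjects, tc.split, seed=tc.seed)
        by = lambda ids: [t for t in self.trials if t.recording.subject_id in set(ids)]
        train_trials, val_trials, test_trials = by(tr_ids), by(va_ids), by(te_ids)
        net = TCNModel(self.model_config, seed=tc.seed)
        net, history = train(net, self._windows(train_trials), self._windows(val_trials), tc, verbose=verbose)
        return TugSegmenterResults(
            model=self,
            network=net,
            history=history,
            split_subjects=(tr_ids, va_ids, te_ids),
            test_trials=test_trials,
        )


class TugSegmenterResults:
    """Fit results: the trained network, training history and test split."""

    def __init__(
        self,
        model: TugSegmenter,
        network: TCNModel,
        history: TrainHistory,
        split_subjects: tuple[list[str], list[str], list[str]],
        test_trials: list[SynthTrial],
    ):
        self.model = model
        self.network = network
        self.history = history
        self.split_subjects = split_subjects
        self.test_trials = test_trials
        self._report: SegmentationReport | None = None

    # ------------------------------------------------------------------
    def predict_trial(self, recording: TrialRecording) -> PredictedSegmentation:
        """Segment one recording: probabilities -> order correction -> events."""
        feats = self.model._features(recording)
        probs = predict_frames(self.network, feats)
        labels, boundaries = dtw_correct(probs)
        return PredictedSegmentation(
            probs=probs,
            raw_labels=probs.argmax(axis=1),
            labels=labels,
            boundaries=boundaries,
            events=extract_events(boundaries, recording.fps),
        )

    def evaluate(self, trials: Sequence[SynthTrial] | None = None) -> SegmentationReport:
        """Frame and timing metrics on held-out trials (default: test split)."""
        trials = list(trials) if trials is not None else self.test_trials
        preds, truths, event_pairs = [], [], []
        for tr in trials:
            seg = self.predict_trial(tr.recording)
            preds.append(seg.labels)
            truths.append(np.asarray(tr.labels))
            if tr.events is not None:
                event_pairs.append((seg.events, tr.events))
        report = evaluate_segmentation(preds, truths, event_pairs or None)
        if trials is self.test_trials or self._report is None:
            self._report = report
        return report

    def raw_vs_corrected_accuracy(
        self, trials: Sequence[SynthTrial] | None = None
    ) -> tuple[float, float]:
        """Mean frame accuracy before and after order correction."""
        trials = list(trials) if trials is not None else self.test_trials
        raw, cor = [], []
        for tr in trials:
            seg = self.predict_trial(tr.recording)
            truth = np.asarray(tr.labels)
            raw.append(accuracy(seg.raw_labels, truth))
            cor.append(accuracy(seg.labels, truth))
        return float(np.mean(raw)), float(np.mean(cor))

    def summary(self) -> str:
        """Human-readable fit summary."""
        report = self._report or self.evaluate()
        cfg = self.model.model_config
        lines = [
            "TUG Subtask Segmentation Results",
            "=" * 48,
            f"Input joints:       {', '.join(j.name for j in self.model.joints)}",
            f"Architecture:       {cfg.n_temporal_blocks} blocks x "
            f"{cfg.conv_layers_per_block} conv layers, kernel {cfg.kernel_size}, "
            f"window {cfg.window_size}",
            f"Trainable params:   {count_parameters(self.network)}",
            f"Epochs run:         {self.history.n_epochs} "
            f"(best {self.history.best_epoch}, {self.history.stop_reason})",
            f"Val accuracy:       {self.history.val_acc[self.history.best_epoch - 1]:.4f}",
            f"Test trials:        {report.n_trials} ({report.n_frames} frames)",
            f"Test frame accuracy:{report.accuracy:.4f}",
            "-" * 48,
            f"{'subtask':<12}{'precision':>10}{'recall':>10}{'F1':>10}",
        ]
        for cls in Subtask:
            m = report.per_subtask[cls.name]
            fmt = lambda v: "   n/a" if v is None else f"{v:10.3f}"
            lines.append(f"{cls.name:<12}{fmt(m['precision'])}{fmt(m['recall'])}{fmt(m['f1'])}")
        if report.event_timing:
            lines.append("-" * 48)
            lines.append(f"{'event':<16}{'MAE (s)':>10}{'STD (s)':>10}")
            for name, stats in report.event_timing.items():
                lines.append(f"{name:<16}{stats['mae']:10.3f}{stats['std']:10.3f}")
        return "\n".join(lines)
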