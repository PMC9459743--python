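"""Metrics: confusion counts, precision/recall/F1, accuracy, timing errors, ICC."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tugseg.dtw_postprocess import SegmentBoundaries, dtw_correct
from tugseg.evaluation import (
    ConfusionCounts,
    accuracy,
    aggregate_event_errors,
    confusion,
    event_errors,
    evaluate_segmentation,
    icc,
    precision_recall_f1,
    subtask_durations,
    total_time_error,
)
from tugseg.labels import Subtask
from tugseg.skeleton_io import EventTimes


class TestConfusion:
    def test_perfect_prediction(self):
        truth = np.array([0, 1, 2, 3, 4, 2, 2])
        for cls in Subtask:
            c = confusion(truth, truth, cls)
            assert c.fp == 0 and c.fn == 0

    def test_all_predicted_half_true(self):
        pred = np.full(20, 2)
        truth = np.array([2] * 10 + [0] * 10)
        c = confusion(pred, truth, 2)
        assert (c.tp, c.fp, c.fn, c.tn) == (10, 10, 0, 0)

    def test_counts_partition_total(self, rng):
        pred = rng.integers(0, 5, 100)
        truth = rng.integers(0, 5, 100)
        for cls in Subtask:
            assert confusion(pred, truth, cls).total == 100

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.zeros(3), np.zeros(4), 0)


class TestPrecisionRecallF1:
    def test_perfect_scores(self):
        p, r, f1 = precision_recall_f1(ConfusionCounts(10, 0, 0, 5))
        assert (p, r, f1) == (1.0, 1.0, 1.0)

    def test_undefined_reported_as_none(self):
        with pytest.warns(UserWarning):
            p, r, f1 = precision_recall_f1(ConfusionCounts(0, 0, 3, 7))
        assert p is None and f1 is None
        assert r == 0.0

    @given(
        tp=st.integers(0, 1000), fp=st.integers(0, 1000), fn=st.integers(0, 1000)
    )
    def test_f1_between_precision_and_recall(self, tp, fp, fn):
        c = ConfusionCounts(tp, fp, fn, 0)
        if tp + fp == 0 or tp + fn == 0:
            return
        p, r, f1 = precision_recall_f1(c)
        assert 0.0 <= p <= 1.0 and 0.0 <= r <= 1.0 and 0.0 <= f1 <= 1.0
        assert min(p, r) - 1e-12 <= f1 <= max(p, r) + 1e-12


class TestAccuracy:
    def test_identical_and_half_wrong(self, rng):
        x = rng.integers(0, 5, 30)
        assert accuracy(x, x) == 1.0
        y = x.copy()
        y[:15] = (y[:15] + 1) % 5
        assert accuracy(y, x) == 0.5

    def test_multiclass_micro_equivalence(self):
        """7 of 9 frames correct -> 7/9, equal to pooling Eq-style counts."""
        truth = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        pred = np.array([0, 0, 1, 1, 1, 1, 2, 2, 0])
        assert accuracy(pred, truth) == pytest.approx(7 / 9)
        correct = sum(confusion(pred, truth, c).tp for c in range(3))
        assert correct / len(truth) == pytest.approx(7 / 9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy(np.array([]), np.array([]))


class TestEventErrors:
    def test_identical_events_zero_error(self):
        ev = EventTimes(1, 2, 3, 4, 5, 6)
        assert np.all(event_errors(ev, ev) == 0)

    def test_uniform_shift_cancels_in_total_time(self):
        truth = EventTimes(1, 2, 3, 4, 5, 6)
        shift = 3 / 30  # +3 frames at 30 fps
        pred = EventTimes(*(truth.as_array() + shift))
        assert np.allclose(event_errors(pred, truth), 0.1)
        assert total_time_error(pred, truth) == pytest.approx(0.0)

    def test_mae_and_population_std(self):
        t = EventTimes(1, 2, 3, 4, 5, 6)
        p1 = EventTimes(1, 2, 3, 4, 5, 6.1)  # total-time error 0.1
        p2 = EventTimes(1, 2, 3, 4, 5, 6.3)  # total-time error 0.3
        agg = aggregate_event_errors([(p1, t), (p2, t)])
        assert agg["total_tug_time"]["mae"] == pytest.approx(0.2)
        assert agg["total_tug_time"]["std"] == pytest.approx(0.1)


class TestICC:
    def test_identical_raters_give_one(self):
        x = np.column_stack([np.arange(5.0), np.arange(5.0)])
        assert icc(x) == pytest.approx(1.0)

    def test_constant_offset_penalized(self):
        x = np.column_stack([np.arange(5.0), np.arange(5.0) + 10.0])
        assert icc(x) < 1.0

    def test_matches_anova_mean_squares_oracle(self):
        table = np.array([[9.0, 2.0], [6.0, 1.0], [8.0, 4.0], [7.0, 1.0], [10.0, 5.0]])
        n, k = table.shape
        grand = table.mean()
        msr = k * np.sum((table.mean(1) - grand) ** 2) / (n - 1)
        msc = n * np.sum((table.mean(0) - grand) ** 2) / (k - 1)
        mse = (
            np.sum((table - table.mean(1, keepdims=True) - table.mean(0) + grand) ** 2)
            / ((n - 1) * (k - 1))
        )
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc(table) == pytest.approx(expected)

    def test_matches_pingouin_icc2(self):
        """Independent cross-check against pingouin's ICC2 on a toy table."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(0)
        base = rng.normal(size=12)
        table = np.column_stack([base, base + rng.normal(0, 0.3, 12)])
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(12), 2),
                "raters": np.tile([0, 1], 12),
                "scores": table.reshape(-1),
            }
        )
        ref = pingouin.intraclass_corr(df, "targets", "raters", "scores")
        # ICC(A,1): two-way, absolute agreement, single rater
        ref_icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc(table) == pytest.approx(ref_icc2, abs=1e-9)

    def test_zero_variance_undefined(self):
        with pytest.warns(UserWarning):
            assert icc(np.full((4, 2), 3.0)) is None


class TestDurations:
    def test_walk_segment_speed(self):
        bounds = SegmentBoundaries((30, 60, 150, 180, 270, 300), 330)
        d = subtask_durations(bounds, fps=30.0, walk_distance=3.0)
        assert d["walk"] == pytest.approx(3.0)
        assert d["walk_speed"] == pytest.approx(1.0)

    def test_durations_sum_to_recording_length(self):
        bounds = SegmentBoundaries((10, 30, 80, 95, 150, 170), 200)
        d = subtask_durations(bounds, fps=30.0)
        phase_keys = [k for k in d if not k.endswith("_speed")]
        assert sum(d[k] for k in phase_keys) == pytest.approx(200 / 30.0)

    def test_noiseless_trial_durations_match_plan(self, clean_trials):
        trial = clean_trials[0]
        _, bounds = dtw_correct(np.asarray(trial.labels))
        d = subtask_durations(bounds, trial.recording.fps)
        # boundaries are frame-quantized; durations match within one frame each
        from tugseg.labels import PHASE_ORDER_DOC

        events = trial.events.as_array()
        plan_durs = np.diff([0.0, *events, trial.recording.n_frames / trial.recording.fps])
        got = np.array([d[k] for k in PHASE_ORDER_DOC])
        assert np.all(np.abs(got - plan_durs) <= 2 / trial.recording.fps + 1e-9)


class TestReport:
    def test_report_purity(self, clean_trials):
        """Same inputs -> byte-identical JSON report."""
        preds = [np.asarray(t.labels) for t in clean_trials]
        pairs = [(t.events, t.events) for t in clean_trials]
        r1 = evaluate_segmentation(preds, preds, pairs).to_json()
        r2 = evaluate_segmentation(preds, preds, pairs).to_json()
        assert r1 == r2
        assert '"accuracy": 1.0' in r1
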