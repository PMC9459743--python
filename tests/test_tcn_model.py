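"""Architecture, parameter counting, training protocol, splits."""

import numpy as np
import pytest

from conftest import noiseless_preset
from tugseg import tcn_model
from tugseg.model import TugSegmenter
from tugseg.synthetic_tug import batch_generate
from tugseg.tcn_model import (
    ConfigError,
    ModelConfig,
    REFERENCE_PARAM_COUNT,
    TCNModel,
    TrainConfig,
    build_model,
    count_parameters,
    holdout_split,
    kfold_split,
    predict_frames,
    train,
)


def dense_only_config():
    return ModelConfig(n_temporal_blocks=0, window_size=1, input_dim=3, n_classes=5)


class TestBuild:
    def test_dense_toy_has_twenty_parameters(self):
        model = build_model(dense_only_config())
        assert count_parameters(model) == 20  # 3*5 weights + 5 biases

    def test_default_config_probabilities_normalized(self):
        model = build_model(ModelConfig(), seed=0)
        windows = np.random.default_rng(0).normal(size=(11, 8, 3))
        probs = model.predict_proba(windows)
        assert probs.shape == (11, 5)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_own_count_recorded_alongside_reference(self):
        """The reference architecture prints 41,879 parameters; the exact
        layer composition is not recoverable, so the package records its
        own count (same order of magnitude) next to the reference."""
        model = build_model(ModelConfig())
        own = count_parameters(model)
        assert REFERENCE_PARAM_COUNT == 41_879
        assert 10_000 < own < 100_000

    def test_window_below_receptive_minimum_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(window_size=2, kernel_size=3)

    def test_dilations_double_per_block(self):
        assert ModelConfig(n_temporal_blocks=4, channel_plan=(8, 8, 8, 8)).dilations() == (1, 2, 4, 8)

    def test_count_equals_per_layer_tally(self):
        """Brute-force per-tensor tally oracle."""
        model = build_model(ModelConfig(channel_plan=(16, 24, 32)))
        tally = 0
        for block in model.blocks:
            for conv in block.convs:
                tally += conv.W.size + conv.b.size
            if block.shortcut is not None:
                tally += block.shortcut.W.size + block.shortcut.b.size
        tally += model.head.W.size + model.head.b.size
        assert count_parameters(model) == tally

    def test_doubling_channels_increases_count(self):
        small = count_parameters(build_model(ModelConfig(channel_plan=(16, 16, 16))))
        big = count_parameters(build_model(ModelConfig(channel_plan=(32, 32, 32))))
        assert big > small


class TestTraining:
    def _toy_data(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 1, 3)).astype(np.float32)
        y = (X[:, 0, 0] > 0).astype(np.int64)  # linearly separable
        return (X[: n // 2], y[: n // 2]), (X[n // 2 :], y[n // 2 :])

    def test_early_stop_contract(self, monkeypatch):
        """patience=1 with validation loss forced non-improving after the
        first epoch stops exactly at epoch 2."""
        epoch_counter = iter(range(100))
        monkeypatch.setattr(
            tcn_model, "_evaluate", lambda *a, **k: (1.0 + next(epoch_counter), 0.5)
        )
        tr, va = self._toy_data()
        model = build_model(dense_only_config())
        cfg = TrainConfig(patience=1, max_epochs=50, learning_rate=1e-3)
        _, hist = train(model, tr, va, cfg)
        assert hist.n_epochs == 2
        assert hist.best_epoch == 1
        assert hist.stop_reason.startswith("early_stop")

    def test_same_seed_identical_history(self):
        tr, va = self._toy_data()
        runs = []
        for _ in range(2):
            model = build_model(dense_only_config(), seed=5)
            _, hist = train(model, tr, va, TrainConfig(max_epochs=5, learning_rate=1e-3, seed=5))
            runs.append(hist)
        assert runs[0].train_loss == runs[1].train_loss
        assert runs[0].val_loss == runs[1].val_loss

    def test_best_epoch_has_minimal_validation_loss(self):
        tr, va = self._toy_data()
        model = build_model(dense_only_config(), seed=1)
        _, hist = train(model, tr, va, TrainConfig(max_epochs=20, learning_rate=1e-3))
        assert hist.val_loss[hist.best_epoch - 1] == min(hist.val_loss)

    def test_empty_split_rejected(self):
        tr, _ = self._toy_data()
        model = build_model(dense_only_config())
        with pytest.raises(ValueError):
            train(model, tr, (np.empty((0, 1, 3)), np.empty(0, dtype=int)), TrainConfig())

    def test_noiseless_trials_become_separable(self):
        """A short training run on 10 noiseless trials reaches >0.9 frame
        accuracy on its own training data (separable toy)."""
        trials = batch_generate(10, noiseless_preset(total_mean=8.0), master_seed=2)
        seg = TugSegmenter(
            trials,
            train_config=TrainConfig(max_epochs=200, patience=25, seed=0),
        )
        res = seg.fit()
        train_ids = set(res.split_subjects[0])
        train_trials = [t for t in trials if t.recording.subject_id in train_ids]
        accs = []
        for t in train_trials:
            pred = res.predict_trial(t.recording)
            accs.append(np.mean(pred.raw_labels == t.labels))
        assert np.mean(accs) > 0.9


class TestPrediction:
    def test_row_sums_and_single_frame(self):
        model = build_model(ModelConfig())
        probs = predict_frames(model, np.zeros((1, 3)))
        assert probs.shape == (1, 5)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_feature_dim_mismatch_rejected(self):
        model = build_model(ModelConfig())
        with pytest.raises(ValueError):
            predict_frames(model, np.zeros((10, 6)))

    def test_prediction_depends_only_on_window(self):
        """Perturbing frames outside a frame's window leaves its
        probabilities unchanged (receptive field is the window)."""
        model = build_model(ModelConfig(), seed=3)
        feats = np.random.default_rng(0).normal(size=(60, 3))
        base = predict_frames(model, feats)
        perturbed = feats.copy()
        perturbed[40:] += 100.0  # far outside frame 10's window [7, 14]
        after = predict_frames(model, perturbed)
        assert np.allclose(base[10], after[10], atol=1e-6)

    def test_serialization_round_trip(self):
        model = build_model(ModelConfig(channel_plan=(8, 8, 8)), seed=2)
        clone = TCNModel.from_dict(model.to_dict())
        x = np.random.default_rng(1).normal(size=(4, 8, 3))
        assert np.allclose(model.predict_proba(x), clone.predict_proba(x))


class TestSplits:
    def test_fifty_subjects_five_folds_of_ten(self):
        subjects = [f"s{i:02d}" for i in range(50)]
        folds = kfold_split(subjects, k=5, seed=0)
        assert [len(f) for f in folds] == [10] * 5
        assert sorted(sum(folds, [])) == subjects  # disjoint cover

    def test_kfold_same_seed_same_folds(self):
        subjects = [f"s{i}" for i in range(17)]
        assert kfold_split(subjects, seed=4) == kfold_split(subjects, seed=4)

    def test_kfold_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(["a", "b"], k=5)

    def test_holdout_mirrors_thirty_ten_ten(self):
        subjects = [f"s{i:02d}" for i in range(50)]
        tr, va, te = holdout_split(subjects, (0.6, 0.2, 0.2), seed=1)
        assert (len(tr), len(va), len(te)) == (30, 10, 10)
        assert set(tr) | set(va) | set(te) == set(subjects)
        assert not (set(tr) & set(va) or set(tr) & set(te) or set(va) & set(te))

    def test_holdout_subject_disjoint_with_repeated_trials(self):
        # multiple trials per subject must land in exactly one partition
        ids = [f"s{i}" for i in range(10)] * 3
        tr, va, te = holdout_split(ids, seed=0)
        assert len(tr) + len(va) + len(te) == 10
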