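"""Dilated temporal convolutional frame classifier.

The classifier maps a short window of preprocessed joint trajectories
(default 8 frames x 3 coordinates of the pelvis) to a class probability
vector for the window's centre frame, one of the five subtask classes.
Features are produced by a stack of temporal blocks — dilated convolutions
with residual skip connections, dilation doubling per block (1, 2, 4, ...)
— followed by a dense softmax head on the flattened block output.
Training uses categorical cross-entropy, Adam at learning rate 7e-5,
batches of 1024 windows, and early stopping on validation loss with a
patience of 50 epochs, restoring the best-epoch weights.

Dataset splits are always by subject: a 6:2:2 train/validation/test
holdout (e.g. 30:10:10 subjects out of 50) and 5-fold cross-validation.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from ._nn import OPTIMIZERS, Dense, DilatedConv1d, Layer, TemporalBlock, cross_entropy_grad, softmax
from .labels import N_CLASSES
from .preprocess import WindowSpec, make_windows


class ConfigError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Architecture knobs of the dilated TCN.

    The reference architecture is kernel size 3, window size 8, three
    temporal blocks of two convolutional layers each. ``channel_plan``
    gives per-block channel widths (a free default here; the source work
    prints only total parameter counts, which are not exactly recoverable).
    """

    kernel_size: int = 3
    window_size: int = 8
    n_temporal_blocks: int = 3
    conv_layers_per_block: int = 2
    channel_plan: tuple[int, ...] = (32, 32, 48)
    n_classes: int = N_CLASSES
    input_dim: int = 3

    def __post_init__(self) -> None:
        for name in ("kernel_size", "window_size", "conv_layers_per_block", "n_classes", "input_dim"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_temporal_blocks < 0:
            raise ConfigError("n_temporal_blocks must be >= 0")
        if self.n_temporal_blocks > 0 and len(self.channel_plan) < self.n_temporal_blocks:
            raise ConfigError("channel_plan shorter than n_temporal_blocks")
        if self.n_temporal_blocks > 0 and self.window_size < self.kernel_size:
            raise ConfigError(
                f"window {self.window_size} is smaller than the minimum receptive "
                f"field (kernel size {self.kernel_size})"
            )

    def dilations(self) -> tuple[int, ...]:
        """Dilation doubles per successive block: 1, 2, 4, ..."""
        return tuple(2**i for i in range(self.n_temporal_blocks))


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol (grid-search optimum of the reference study)."""

    learning_rate: float = 7e-5
    optimizer: str = "adam"
    patience: int = 50
    batch_size: int = 1024
    max_epochs: int = 200
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.patience < 1 or self.batch_size < 1 or self.max_epochs < 1:
            raise ConfigError("learning_rate, patience, batch_size, max_epochs must be positive")
        if self.optimizer.lower() not in OPTIMIZERS:
            raise ConfigError(f"optimizer must be one of {sorted(OPTIMIZERS)}")
        if any(f <= 0 for f in self.split) or not np.isclose(sum(self.split), 1.0):
            raise ConfigError("split fractions must be positive and sum to 1")
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")


@dataclasses.dataclass
class TrainHistory:
    train_loss: list[float]
    train_acc: list[float]
    val_loss: list[float]
    val_acc: list[float]
    best_epoch: int  # 1-based
    stop_reason: str

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


class TCNModel:
    """A built (possibly trained) dilated TCN."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        layers: list[Layer] = []
        c = config.input_dim
        for block, dil in enumerate(config.dilations()):
            c_out = config.channel_plan[block]
            layers.append(
                TemporalBlock(c, c_out, config.kernel_size, dil, config.conv_layers_per_block, rng)
            )
            c = c_out
        self.blocks = layers
        self.head = Dense(config.window_size * c, config.n_classes, rng)
        self._layers: list[Layer] = [*layers, self.head]

    # -- parameters -----------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        return [p for l in self._layers for p in l.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for l in self._layers for g in l.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w

    def to_dict(self) -> dict:
        return {
            "config": dataclasses.asdict(self.config),
            "weights": [p.tolist() for p in self.params],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "TCNModel":
        cfg = dict(payload["config"])
        cfg["channel_plan"] = tuple(cfg["channel_plan"])
        model = cls(ModelConfig(**cfg))
        model.set_weights([np.asarray(w, dtype=np.float32) for w in payload["weights"]])
        return model

    # -- forward --------------------------------------------------------
    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = np.ascontiguousarray(x, dtype=np.float32)
        for block in self.blocks:
            h = block.forward(h, train)
        h = h.reshape(h.shape[0], -1)
        return self.head.forward(h, train)

    def _backward(self, glogits: np.ndarray, batch_shape: tuple[int, ...]) -> None:
        g = self.head.backward(glogits)
        B, W = batch_shape[0], self.config.window_size
        g = g.reshape(B, W, -1)
        for block in reversed(self.blocks):
            g = block.backward(g)

    def predict_proba(self, windows: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        """Class probabilities for a ``(N, window, input_dim)`` batch."""
        windows = np.asarray(windows)
        if windows.shape[1:] != (self.config.window_size, self.config.input_dim):
            raise ValueError(
                f"expected windows of shape (N, {self.config.window_size}, "
                f"{self.config.input_dim}), got {windows.shape}"
            )
        out = []
        for i in range(0, len(windows), batch_size):
            out.append(softmax(self._forward(windows[i : i + batch_size], train=False)))
        return np.concatenate(out, axis=0)


def build_model(config: ModelConfig = ModelConfig(), seed: int = 0) -> TCNModel:
    """Build an untrained model; all weight initialization is seeded."""
    return TCNModel(config, seed=seed)


def count_parameters(model: TCNModel) -> int:
    """Total number of trainable scalar parameters."""
    return int(sum(p.size for p in model.params))


#: Parameter count printed by the reference study for kernel 3 / window 8.
#: Reported for context only; the exact layer composition behind it is not
#: recoverable, so implementations record their own count alongside it.
REFERENCE_PARAM_COUNT = 41_879


def _evaluate(model: TCNModel, X: np.ndarray, y: np.ndarray, batch_size: int) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, len(X), batch_size):
        logits = model._forward(X[i : i + batch_size], train=False)
        loss, _ = cross_entropy_grad(logits, y[i : i + batch_size])
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) == y[i : i + batch_size]).sum())
    return float(np.sum(losses) / len(X)), correct / len(X)


def train(
    model: TCNModel,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    config: TrainConfig = TrainConfig(),
    verbose: bool = False,
) -> tuple[TCNModel, TrainHistory]:
    """Train with mini-batch gradient descent and early stopping.

    Stops when the validation loss has not improved for ``patience``
    consecutive epochs (or at ``max_epochs``) and restores the weights of
    the best validation epoch. Shuffling is driven by ``config.seed``.
    """
    X, y = train_set
    Xv, yv = val_set
    if len(X) == 0 or len(Xv) == 0:
        raise ValueError("empty training or validation split")
    X = np.ascontiguousarray(X, dtype=np.float32)
    Xv = np.ascontiguousarray(Xv, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    yv = np.asarray(yv, dtype=np.int64)

    rng = np.random.default_rng(config.seed)
    opt = OPTIMIZERS[config.optimizer.lower()](model.params, model.grads, config.learning_rate)

    hist = TrainHistory([], [], [], [], best_epoch=0, stop_reason="max_epochs")
    best_loss = np.inf
    best_weights = model.get_weights()
    since_improve = 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(X))
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, yb = X[idx], y[idx]
            opt.zero_grad()
            logits = model._forward(xb, train=True)
            loss, glogits = cross_entropy_grad(logits, yb)
            model._backward(glogits, xb.shape)
            opt.step()
            ep_loss += loss * len(idx)
            ep_correct += int((logits.argmax(axis=1) == yb).sum())
        vloss, vacc = _evaluate(model, Xv, yv, config.batch_size)
        hist.train_loss.append(ep_loss / len(X))
        hist.train_acc.append(ep_correct / len(X))
        hist.val_loss.append(vloss)
        hist.val_acc.append(vacc)
        if verbose:
            print(
                f"epoch {epoch:3d}  loss {hist.train_loss[-1]:.4f}  acc {hist.train_acc[-1]:.4f}"
                f"  val_loss {vloss:.4f}  val_acc {vacc:.4f}"
            )
        if vloss < best_loss:
            best_loss = vloss
            best_weights = model.get_weights()
            hist.best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.patience:
                hist.stop_reason = f"early_stop(patience={config.patience})"
                break

    model.set_weights(best_weights)
    return model, hist


def predict_frames(
    model: TCNModel, features: np.ndarray, window_spec: WindowSpec | None = None
) -> np.ndarray:
    """Per-frame class probabilities for a ``(T, d)`` preprocessed feature matrix."""
    features = np.asarray(features, dtype=np.float32)
    if features.ndim == 1:
        features = features[:, None]
    if features.shape[1] != model.config.input_dim:
        raise ValueError(
            f"feature dimension {features.shape[1]} != model input_dim {model.config.input_dim}"
        )
    spec = window_spec or WindowSpec(window_size=model.config.window_size)
    if spec.window_size != model.config.window_size:
        raise ValueError("window_spec.window_size must match the model")
    windows, _ = make_windows(features, spec)
    return model.predict_proba(windows)


# ---------------------------------------------------------------------------
# subject-wise splits


def kfold_split(subject_ids: Sequence[str], k: int = 5, seed: int = 0) -> list[list[str]]:
    """Partition subjects into k disjoint folds, as balanced as possible."""
    subjects = sorted(set(subject_ids))
    if k > len(subjects):
        raise ValueError(f"k={k} exceeds number of subjects ({len(subjects)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    return [sorted(subjects[i] for i in fold) for fold in np.array_split(order, k)]


def holdout_split(
    subject_ids: Sequence[str],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[list[str], list[str], list[str]]:
    """Subject-disjoint train/validation/test split (default 6:2:2)."""
    if any(f <= 0 for f in fractions) or not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must be positive and sum to 1")
    subjects = sorted(set(subject_ids))
    n = len(subjects)
    if n < 3:
        raise ValueError("need at least 3 subjects for a 3-way split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    counts = np.floor(np.asarray(fractions) * n).astype(int)
    # distribute the remainder by largest fractional part
    rem = np.asarray(fractions) * n - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    counts = np.maximum(counts, 1)
    while counts.sum() > n:  # only possible if a floor was bumped to 1
        counts[np.argmax(counts)] -= 1
    c1, c2 = counts[0], counts[0] + counts[1]
    train = sorted(subjects[i] for i in order[:c1])
    val = sorted(subjects[i] for i in order[c1:c2])
    test = sorted(subjects[i] for i in order[c2:])
    return train, val, test
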