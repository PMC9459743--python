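"""Trajectory preprocessing: axis alignment, low-pass filtering, min-max
normalization, and model-input windowing.

The pipeline order is alignment -> low-pass filter -> min-max
normalization.  Filtering removes tracking jitter (pelvis motion in a TUG
trial lives well below 1 Hz); normalization removes between-subject range
differences (body height, camera distance) so each channel spans [0, 1]
per trial; axis alignment rotates the camera frame about the vertical so
the walking direction is +x regardless of where the camera stood.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import signal as sps

from .joints import JointId
from .skeleton_io import TrialRecording, select_features


class AlignmentError(ValueError):
    """The trial has too little horizontal displacement to define a walking axis."""


@dataclasses.dataclass(frozen=True)
class FilterSpec:
    """Butterworth low-pass design: 4th order, 0.3 Hz cutoff at 30 Hz."""

    order: int = 4
    cutoff_hz: float = 0.3
    fs_hz: float = 30.0
    mode: str = "zero_phase"  # or "causal"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not 0 < self.cutoff_hz < self.fs_hz / 2:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz must lie in (0, Nyquist={self.fs_hz / 2} Hz)"
            )
        if self.mode not in ("zero_phase", "causal"):
            raise ValueError("mode must be 'zero_phase' or 'causal'")

    def ba(self) -> tuple[np.ndarray, np.ndarray]:
        return sps.butter(self.order, self.cutoff_hz, btype="low", fs=self.fs_hz)


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """Per-frame model-input windows: 8 frames, stride 1, edge replication."""

    window_size: int = 8
    stride: int = 1

    def __post_init__(self) -> None:
        if self.window_size < 1 or self.stride < 1:
            raise ValueError("window_size and stride must be >= 1")


def butterworth_lowpass(x: np.ndarray, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Low-pass filter a ``(T,)`` or ``(T, d)`` series along time.

    ``zero_phase`` mode runs the filter forward and backward (squared
    magnitude response, no group delay); ``causal`` runs a single forward
    pass, retained for ablation.
    """
    x = np.asarray(x, dtype=float)
    T = x.shape[0]
    if T <= 3 * spec.order:
        raise ValueError(f"need more than {3 * spec.order} samples for order {spec.order}")
    b, a = spec.ba()
    if spec.mode == "zero_phase":
        padlen = min(3 * (max(len(a), len(b)) - 1), T - 1)
        return sps.filtfilt(b, a, x, axis=0, padlen=padlen)
    return sps.lfilter(b, a, x, axis=0)


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Map each column of a ``(T, d)`` matrix affinely onto [0, 1].

    Constant columns carry no range information and are mapped to zeros
    (with a warning) rather than dividing by zero.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")
    single = x.ndim == 1
    if single:
        x = x[:, None]
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    span = hi - lo
    flat = span == 0
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} constant column(s) mapped to zeros in min-max normalization",
            stacklevel=2,
        )
    span = np.where(flat, 1.0, span)
    out = (x - lo) / span
    out[:, flat] = 0.0
    return out[:, 0] if single else out


def walking_axis(recording: TrialRecording, min_span: float = 0.5) -> np.ndarray:
    """Unit horizontal (x, z) walking direction of the pelvis, outbound positive.

    The direction is the first principal direction of the horizontal pelvis
    displacements from the first frame; its sign is chosen so the largest
    displacement excursion (the out-and-back apex at the cone) is positive.
    """
    pelvis = recording.positions[:, recording.joint_index(JointId.PELVIS), :]
    hor = pelvis[:, [0, 2]]
    disp = hor - hor[0]
    cov = np.cov(disp.T)
    eigval, eigvec = np.linalg.eigh(cov)
    v = eigvec[:, np.argmax(eigval)]
    proj = disp @ v
    if proj.max() - proj.min() < min_span:
        raise AlignmentError(
            f"horizontal pelvis span {proj.max() - proj.min():.3f} m < {min_span} m"
        )
    if proj[np.argmax(np.abs(proj))] < 0:
        v = -v
    return v


def align_axes(recording: TrialRecording) -> TrialRecording:
    """Rotate the recording about the vertical axis so walking is along +x.

    Pure rotation: the vertical (y) coordinate and all pairwise distances
    are untouched. Idempotent up to numerical tolerance.
    """
    vx, vz = walking_axis(recording)
    # rotation about y mapping (vx, vz) -> (1, 0)
    R = np.array([[vx, 0.0, vz], [0.0, 1.0, 0.0], [-vz, 0.0, vx]])
    return recording.with_positions(recording.positions @ R.T)


def make_windows(
    features: np.ndarray, spec: WindowSpec = WindowSpec()
) -> tuple[np.ndarray, np.ndarray]:
    """Cut a ``(T, d)`` feature matrix into per-frame windows.

    Returns ``(windows, centers)`` where ``windows`` has shape
    ``(N, window_size, d)`` and ``centers[i]`` is the frame index whose
    label window ``i`` predicts. With stride 1 there is one window centred
    on every frame (N = T); edges are handled by replicating the first and
    last frame. The centre sits at offset ``(window_size - 1) // 2``.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[:, None]
    T = features.shape[0]
    if T < 1:
        raise ValueError("empty feature matrix")
    W = spec.window_size
    left = (W - 1) // 2
    right = W - 1 - left
    padded = np.pad(features, ((left, right), (0, 0)), mode="edge")
    centers = np.arange(0, T, spec.stride)
    idx = centers[:, None] + np.arange(W)[None, :]
    return padded[idx], centers


def preprocess_features(
    recording: TrialRecording,
    joints: list[JointId] | tuple[JointId, ...] = (JointId.PELVIS,),
    filter_spec: FilterSpec | None = None,
    align: bool = True,
) -> np.ndarray:
    """Full feature pipeline: align axes, select joints, filter, normalize."""
    if align:
        recording = align_axes(recording)
    feats = select_features(recording, list(joints))
    spec = filter_spec or FilterSpec(fs_hz=recording.fps)
    feats = butterworth_lowpass(feats, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant channels are fine here
        return minmax_normalize(feats)
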