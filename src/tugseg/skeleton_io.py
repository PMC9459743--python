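"""Reading, validating and writing skeleton trajectory recordings.

Two on-disk formats are supported:

* a wide CSV with header ``frame,timestamp,<JOINT>_x,<JOINT>_y,<JOINT>_z,...``
  (one row per frame, coordinates in metres, timestamps in seconds from the
  first frame) preceded by ``#key=value`` metadata comment lines, and
* a JSON mirror of the Azure-Kinect body-tracking export
  (``{"frames": [{"frame": i, "timestamp": t, "positions": {...}}, ...]}``).

Event labels travel in a sidecar CSV ``event,label,time_s`` carrying the six
TUG events (StartMove..EndSit, labels 0-5).
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .joints import JointId
from .labels import EVENT_NAMES

GROUPS = ("healthy_young", "older_adult", "stroke")

_EVENT_CSV_NAMES = (
    "StartMove",
    "StartWalk",
    "StartTurn",
    "EndTurn",
    "StartSit",
    "EndSit",
)


class SkeletonFormatError(ValueError):
    """The file does not conform to the declared dialect."""


class SkeletonValidationError(ValueError):
    """The data violate a recording invariant (monotonicity, finiteness...)."""


@dataclasses.dataclass
class TrialRecording:
    """Per-frame 3-D joint positions of one TUG trial.

    Attributes
    ----------
    subject_id : str
        Opaque subject identifier.
    group : str
        One of ``healthy_young``, ``older_adult``, ``stroke``.
    fps : float
        Sampling rate in frames per second (nominally 30).
    timestamps : ndarray, shape (T,)
        Seconds from the first frame, strictly increasing.
    positions : ndarray, shape (T, J, 3)
        Joint coordinates in metres. Frame indexing is 0-based.
    joints : tuple of JointId
        The J joints present, in column order.
    """

    subject_id: str
    group: str
    fps: float
    timestamps: np.ndarray
    positions: np.ndarray
    joints: tuple[JointId, ...]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.joints = tuple(JointId(j) for j in self.joints)
        self.validate()

    def validate(self) -> None:
        T = len(self.timestamps)
        if self.group not in GROUPS:
            raise SkeletonValidationError(f"unknown group {self.group!r}")
        if T < 2:
            raise SkeletonValidationError("a recording needs at least 2 frames")
        if self.positions.shape != (T, len(self.joints), 3):
            raise SkeletonValidationError(
                f"positions shape {self.positions.shape} does not match "
                f"{T} frames x {len(self.joints)} joints x 3"
            )
        if len(self.joints) > 32:
            raise SkeletonValidationError("more than 32 joints")
        if len(set(self.joints)) != len(self.joints):
            raise SkeletonValidationError("duplicate joints")
        if not np.all(np.diff(self.timestamps) > 0):
            raise SkeletonValidationError("timestamps are not strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise SkeletonValidationError("non-finite joint positions")
        if not (self.fps > 0 and math.isfinite(self.fps)):
            raise SkeletonValidationError("fps must be positive and finite")

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        """Recording span in seconds, including the last frame interval."""
        return float(self.timestamps[-1] - self.timestamps[0] + 1.0 / self.fps)

    def joint_index(self, joint: JointId) -> int:
        try:
            return self.joints.index(JointId(joint))
        except ValueError:
            raise KeyError(f"joint {JointId(joint).name} not present") from None

    def with_positions(self, positions: np.ndarray) -> "TrialRecording":
        """Copy of this recording with replaced coordinates."""
        return TrialRecording(
            subject_id=self.subject_id,
            group=self.group,
            fps=self.fps,
            timestamps=self.timestamps.copy(),
            positions=np.asarray(positions, dtype=float),
            joints=self.joints,
        )


@dataclasses.dataclass
class EventTimes:
    """The six labeled TUG event instants, seconds from recording start.

    The events split the trial at: 45-degree trunk tilt rising from the
    chair (start_move), first step off the ground (start_walk), body starts
    rotating at the cone (start_turn), body faces the chair again
    (end_turn), body arrives standing at the chair (start_sit), 45-degree
    trunk tilt leaning back into the chair (end_sit).
    """

    start_move: float
    start_walk: float
    start_turn: float
    end_turn: float
    start_sit: float
    end_sit: float

    def __post_init__(self) -> None:
        times = self.as_array()
        if not np.all(np.isfinite(times)):
            raise SkeletonValidationError("non-finite event time")
        if not np.all(np.diff(times) > 0):
            raise SkeletonValidationError("event times must be strictly increasing")
        if times[0] < 0:
            raise SkeletonValidationError("event times must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in EVENT_NAMES], dtype=float)

    @property
    def total_tug_time(self) -> float:
        """Elapsed time between the first (StartMove) and last (EndSit) event."""
        return self.end_sit - self.start_move


# ---------------------------------------------------------------------------
# trial files


def _joint_columns(joints: Sequence[JointId]) -> list[str]:
    return [f"{JointId(j).name}_{ax}" for j in joints for ax in "xyz"]


def _infer_fps(timestamps: np.ndarray) -> float:
    dt = float(np.median(np.diff(timestamps)))
    return round(1.0 / dt, 6)


def write_trial(recording: TrialRecording, path: str | Path, format: str = "csv") -> Path:
    """Write a recording to ``path``; lossless round trip with `read_trial`."""
    recording.validate()
    path = Path(path)
    T, J, _ = recording.positions.shape
    if format == "csv":
        cols = _joint_columns(recording.joints)
        with open(path, "w") as fh:
            fh.write(f"#subject_id={recording.subject_id}\n")
            fh.write(f"#group={recording.group}\n")
            fh.write("frame,timestamp," + ",".join(cols) + "\n")
            flat = recording.positions.reshape(T, 3 * J)
            for i in range(T):
                row = [str(i), repr(float(recording.timestamps[i]))]
                row += [repr(float(v)) for v in flat[i]]
                fh.write(",".join(row) + "\n")
    elif format == "json":
        payload = {
            "subject_id": recording.subject_id,
            "group": recording.group,
            "fps": recording.fps,
            "joints": [j.name for j in recording.joints],
            "frames": [
                {
                    "frame": i,
                    "timestamp": float(recording.timestamps[i]),
                    "positions": recording.positions[i].tolist(),
                }
                for i in range(T)
            ],
        }
        path.write_text(json.dumps(payload))
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_trial(path: str | Path, format: str | None = None) -> TrialRecording:
    """Read and validate a recording written in the CSV or JSON dialect.

    ``format`` defaults to the file suffix. The sampling rate is inferred
    from the timestamp spacing (median frame interval).
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key] = value
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, float_precision="round_trip")
        if "frame" not in df.columns or "timestamp" not in df.columns:
            raise SkeletonFormatError("missing required columns frame/timestamp")
        joint_cols = [c for c in df.columns if c not in ("frame", "timestamp")]
        joints = []
        for col in joint_cols:
            name, _, axis = col.rpartition("_")
            if axis not in ("x", "y", "z") or name not in JointId.__members__:
                raise SkeletonFormatError(f"unknown joint column {col!r}")
            joint = JointId[name]
            if joint not in joints:
                joints.append(joint)
        expected = _joint_columns(joints)
        if joint_cols != expected:
            raise SkeletonFormatError(
                "joint columns must come in complete x,y,z triples per joint "
                f"(got {joint_cols}, expected {expected})"
            )
        timestamps = df["timestamp"].to_numpy(dtype=float)
        positions = df[expected].to_numpy(dtype=float).reshape(len(df), len(joints), 3)
        subject_id = meta.get("subject_id", path.stem)
        group = meta.get("group", "healthy_young")
    elif format == "json":
        payload = json.loads(Path(path).read_text())
        try:
            joints = [JointId[name] for name in payload["joints"]]
            frames = payload["frames"]
            timestamps = np.array([f["timestamp"] for f in frames], dtype=float)
            positions = np.array([f["positions"] for f in frames], dtype=float)
        except KeyError as exc:
            raise SkeletonFormatError(f"malformed JSON trial file: {exc}") from exc
        subject_id = payload.get("subject_id", path.stem)
        group = payload.get("group", "healthy_young")
    else:
        raise ValueError(f"unknown format {format!r}")

    if len(timestamps) < 2:
        raise SkeletonValidationError("a recording needs at least 2 frames")
    if not np.all(np.diff(timestamps) > 0):
        raise SkeletonValidationError("timestamps are not strictly increasing")
    return TrialRecording(
        subject_id=subject_id,
        group=group,
        fps=_infer_fps(timestamps),
        timestamps=timestamps,
        positions=positions,
        joints=tuple(joints),
    )


# ---------------------------------------------------------------------------
# event sidecar files


def write_events(events: EventTimes, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("event,label,time_s\n")
        for label, (csv_name, field) in enumerate(zip(_EVENT_CSV_NAMES, EVENT_NAMES)):
            fh.write(f"{csv_name},{label},{repr(float(getattr(events, field)))}\n")
    return path


def read_events(path: str | Path) -> EventTimes:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["event", "label", "time_s"]:
        raise SkeletonFormatError("event sidecar must have columns event,label,time_s")
    by_label = df.sort_values("label")
    if list(by_label["event"]) != list(_EVENT_CSV_NAMES):
        raise SkeletonFormatError(f"expected the six events {_EVENT_CSV_NAMES}")
    times = by_label["time_s"].to_numpy(dtype=float)
    return EventTimes(*times)


# ---------------------------------------------------------------------------
# feature selection


def select_features(recording: TrialRecording, joints: Sequence[JointId]) -> np.ndarray:
    """Extract a ``T x 3k`` feature matrix for the requested joints.

    Columns are joint-major (all of x,y,z for the first joint, then the
    second, ...), matching the CSV column order.
    """
    joints = list(joints)
    if not joints:
        raise ValueError("empty joint selection")
    idx = [recording.joint_index(j) for j in joints]
    T = recording.n_frames
    return recording.positions[:, idx, :].reshape(T, 3 * len(joints))
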