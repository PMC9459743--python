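"""Synthetic 3 m TUG trial generator.

The study protocol is a 3 m out-and-back walk from a chair with armrests:
the subject sits, rises on the "start" signal, walks 3 m to a cone, turns,
walks back, sits down and leans against the backrest, with one extra second
of seated rest recorded before and after the signals.  This module emulates
that protocol kinematically so every downstream stage (preprocessing,
classifier, order-constrained correction, evaluation) can be exercised
without the study's unreleased recordings.

What is emulated: 30 Hz sampling, the seven ordered phases, the 1 s seated
padding, group-dependent total durations (healthy young / older adults /
stroke), the 45-degree trunk-tilt criterion at the first and last event,
minimum-jerk displacement profiles, pelvis-relative secondary joints with
arm-swing and step oscillations, a random camera azimuth (so axis alignment
is a real operation), and Gaussian position noise.

What is NOT emulated: biomechanically validated gait, pathology-specific
gait signatures beyond duration scaling, tracking dropouts.

Group total-duration means follow the study cohorts; the duration spreads,
the per-phase fractions of active time and the noise level are this
package's own defaults (the source cohort statistics report totals only).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .joints import JointId
from .labels import CANONICAL_TEMPLATE, PHASE_ORDER_DOC as PHASE_NAMES, Subtask
from .skeleton_io import EventTimes, TrialRecording

#: Joints the generator synthesizes: the five study input groups.
SYNTH_JOINTS: tuple[JointId, ...] = (
    JointId.PELVIS,
    JointId.SPINE_CHEST,
    JointId.HEAD,
    JointId.HAND_LEFT,
    JointId.HAND_RIGHT,
    JointId.ANKLE_LEFT,
    JointId.ANKLE_RIGHT,
)

_PAD = 2.0  # seconds of seated padding (1 s lead + 1 s trail)


@dataclasses.dataclass(frozen=True)
class GroupPreset:
    """Stochastic description of one subject group's TUG trials."""

    group: str
    total_mean: float  # mean total recording duration, s
    total_sigma: float  # spread of total duration, s
    #: fractions of the active (non-padding) time given to
    #: sit-to-stand, walk, turn, walk-back, stand-to-sit; sum to 1.
    phase_fractions: tuple[float, ...] = (0.15, 0.30, 0.10, 0.30, 0.15)
    walk_distance: float = 3.0  # m, chair to cone
    chair_height: float = 0.45  # m, pelvis height seated
    stand_height: float = 0.95  # m, pelvis height standing
    noise_sigma: float = 0.01  # m, isotropic position noise
    lead_sit: float = 1.0  # s
    trail_sit: float = 1.0  # s
    fps: float = 30.0

    def __post_init__(self) -> None:
        fr = np.asarray(self.phase_fractions, dtype=float)
        if len(fr) != 5 or np.any(fr <= 0) or not np.isclose(fr.sum(), 1.0):
            raise ValueError("phase_fractions must be 5 positive values summing to 1")
        if self.total_sigma < 0:
            raise ValueError("total_sigma must be >= 0")
        if self.walk_distance <= 0:
            raise ValueError("walk_distance must be > 0")
        if self.total_mean <= self.lead_sit + self.trail_sit:
            raise ValueError("total_mean must exceed the seated padding")


#: Cohort presets. Total-duration means are the study cohort averages;
#: sigmas are this package's choices (healthy gait variability is small,
#: stroke variability is large).
DEFAULT_PRESETS: dict[str, GroupPreset] = {
    "healthy_young": GroupPreset("healthy_young", 11.34, 1.2),
    "older_adult": GroupPreset("older_adult", 15.33, 1.8),
    "stroke": GroupPreset("stroke", 43.11, 6.0),
}


@dataclasses.dataclass(frozen=True)
class PhasePlan:
    """Durations (s) of the seven ordered trial phases."""

    durations: tuple[float, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.durations, dtype=float)
        if len(d) != 7 or np.any(d <= 0):
            raise ValueError("need 7 positive phase durations")

    @property
    def total(self) -> float:
        return float(np.sum(self.durations))

    def boundaries(self) -> np.ndarray:
        """The six interior phase-boundary times, seconds."""
        return np.cumsum(self.durations)[:6]

    def event_times(self) -> EventTimes:
        return EventTimes(*self.boundaries())


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_phase_plan(preset: GroupPreset, rng_seed: int | np.random.Generator) -> PhasePlan:
    """Draw a PhasePlan for one trial.

    The total duration is drawn from a normal truncated below at 2 s of
    active time beyond the seated padding; active-phase durations are the
    preset fractions of the active time. With ``total_sigma == 0`` the plan
    is deterministic at the preset mean.
    """
    rng = _as_rng(rng_seed)
    pad = preset.lead_sit + preset.trail_sit
    lower = pad + 2.0
    if preset.total_sigma == 0:
        total = preset.total_mean
        if total <= lower:
            raise ValueError("preset mean leaves less than 2 s of active time")
    else:
        a = (lower - preset.total_mean) / preset.total_sigma
        total = float(
            truncnorm.rvs(a, np.inf, loc=preset.total_mean, scale=preset.total_sigma, random_state=rng)
        )
    active = total - pad
    fr = np.asarray(preset.phase_fractions, dtype=float)
    durations = (preset.lead_sit, *(fr * active), preset.trail_sit)
    return PhasePlan(tuple(float(d) for d in durations))


# ---------------------------------------------------------------------------
# kinematic primitives


def _minjerk(u: np.ndarray) -> np.ndarray:
    """Minimum-jerk smoothstep on [0, 1] (zero velocity/acceleration at ends)."""
    u = np.clip(u, 0.0, 1.0)
    return u**3 * (10.0 - 15.0 * u + 6.0 * u**2)


_TRUNK_PITCH_MAX = np.deg2rad(70.0)
# fraction of the pitch sweep at which the 45-degree criterion is crossed
_U45 = brentq(lambda u: _minjerk(np.array([u]))[0] - np.deg2rad(45.0) / _TRUNK_PITCH_MAX, 0.0, 1.0)


def _trunk_pitch(t: np.ndarray, plan: PhasePlan) -> np.ndarray:
    """Forward trunk-pitch profile (rad), crossing 45 degrees exactly at the
    first (start_move) and last (end_sit) event times."""
    b = plan.boundaries()
    lead, d_s2s = plan.durations[0], plan.durations[1]
    d_sit, trail = plan.durations[5], plan.durations[6]

    pitch = np.zeros_like(t)
    # rising sweep 0 -> max around start_move, return to 0 by start_walk
    w1 = min(1.2, 0.95 * lead / _U45, 0.5 * d_s2s / (1.0 - _U45))
    a1 = b[0] - _U45 * w1
    up = _minjerk((t - a1) / w1)
    down_start, down_end = a1 + w1, b[1]
    down = 1.0 - _minjerk((t - down_start) / max(down_end - down_start, 1e-9))
    pitch += _TRUNK_PITCH_MAX * np.where(t < down_start, up, down)

    # sitting sweep 0 -> max -> 0, crossing 45 degrees at end_sit
    w2 = min(1.2, 0.95 * trail / _U45, 0.5 * d_sit / (1.0 - _U45))
    c1 = b[5] + _U45 * w2  # descent start such that crossing lands on end_sit
    rise_start = b[4]
    rise_end = c1 - w2
    up2 = _minjerk((t - rise_start) / max(rise_end - rise_start, 1e-9))
    down2 = _minjerk((c1 - t) / w2)
    sit_pitch = _TRUNK_PITCH_MAX * np.where(t < rise_end, up2, down2)
    pitch = np.where(t >= rise_start, sit_pitch, pitch)
    return pitch


def synthesize_trial(
    plan: PhasePlan,
    preset: GroupPreset,
    rng_seed: int | np.random.Generator,
    subject_id: str = "synth",
) -> tuple[TrialRecording, np.ndarray, EventTimes]:
    """Generate one labeled trial.

    Returns the recording (camera frame: random walking azimuth, vertical
    y), the per-frame ground-truth class sequence, and the six event times.
    Labels and events come from the plan, never from the noisy signal.
    """
    rng = _as_rng(rng_seed)
    fps = preset.fps
    T = int(round(fps * plan.total))
    t = np.arange(T) / fps
    b = plan.boundaries()
    d = plan.durations
    D = preset.walk_distance

    # phase index per frame (0..6) and per-phase normalized time
    phase = np.searchsorted(b, t, side="right")

    def u_of(i: int) -> np.ndarray:
        start = 0.0 if i == 0 else b[i - 1]
        return np.clip((t - start) / d[i], 0.0, 1.0)

    # --- pelvis in the aligned local frame (x forward, y vertical, z lateral)
    rise_shift = 0.15  # forward pelvis shift when standing up, m
    forward = np.select(
        [phase == 0, phase == 1, phase == 2, phase == 3, phase == 4, phase == 5, phase == 6],
        [
            0.0,
            rise_shift * _minjerk(u_of(1)),
            rise_shift + (D - rise_shift) * _minjerk(u_of(2)),
            D,
            D - (D - rise_shift) * _minjerk(u_of(4)),
            rise_shift * (1.0 - _minjerk(u_of(5))),
            0.0,
        ],
    )
    h0, h1 = preset.chair_height, preset.stand_height
    height = np.select(
        [phase == 0, phase == 1, phase == 2, phase == 3, phase == 4, phase == 5, phase == 6],
        [
            h0,
            h0 + (h1 - h0) * _minjerk(u_of(1)),
            h1,
            h1,
            h1,
            h1 - (h1 - h0) * _minjerk(u_of(5)),
            h0,
        ],
    )
    # lateral excursion while rounding the cone + small walking sway
    lateral = np.zeros(T)
    lateral += 0.15 * np.sin(np.pi * u_of(3)) * (phase == 3)
    # heading: 0 outbound, pi after the turn
    heading = np.select(
        [phase <= 2, phase == 3, phase >= 4],
        [0.0, np.pi * _minjerk(u_of(3)), np.pi],
    )

    # step oscillations, gated smoothly inside each walking phase
    def walk_envelope(i: int) -> np.ndarray:
        return np.sin(np.pi * u_of(i)) * (phase == i)

    env = walk_envelope(2) + walk_envelope(4)
    n_steps_out = max(2, int(round(1.8 * d[2])))
    n_steps_back = max(2, int(round(1.8 * d[4])))
    stride_phase = 2 * np.pi * (n_steps_out * u_of(2) * (phase <= 3) + n_steps_back * u_of(4) * (phase >= 4))
    height = height + 0.015 * env * np.sin(2 * stride_phase)
    lateral = lateral + 0.02 * env * np.sin(stride_phase)

    fwd_dir = np.stack([np.cos(heading), np.zeros(T), np.sin(heading)], axis=1)
    side_dir = np.stack([-np.sin(heading), np.zeros(T), np.cos(heading)], axis=1)
    up_dir = np.array([0.0, 1.0, 0.0])

    pelvis = forward[:, None] * np.array([1.0, 0.0, 0.0]) + height[:, None] * up_dir + lateral[:, None] * np.array([0.0, 0.0, 1.0])

    pitch = _trunk_pitch(t, plan)
    trunk_dir = np.cos(pitch)[:, None] * up_dir + np.sin(pitch)[:, None] * fwd_dir

    chest = pelvis + 0.30 * trunk_dir
    head = pelvis + 0.65 * trunk_dir
    swing = 0.15 * env * np.sin(stride_phase)
    hand_l = pelvis + 0.18 * side_dir + (-0.05) * up_dir + swing[:, None] * fwd_dir
    hand_r = pelvis - 0.18 * side_dir + (-0.05) * up_dir - swing[:, None] * fwd_dir
    step = 0.25 * env * np.sin(stride_phase)
    ground = 0.08 - height  # ankles ride near the floor, not with the pelvis
    ankle_l = pelvis + 0.10 * side_dir + ground[:, None] * up_dir + step[:, None] * fwd_dir
    ankle_r = pelvis - 0.10 * side_dir + ground[:, None] * up_dir - step[:, None] * fwd_dir

    local = np.stack([pelvis, chest, head, hand_l, hand_r, ankle_l, ankle_r], axis=1)

    # --- embed in a camera frame: random walking azimuth + chair offset
    azimuth = rng.uniform(0.0, 2 * np.pi)
    c, s = np.cos(azimuth), np.sin(azimuth)
    R = np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])
    offset = np.array([rng.uniform(-0.5, 0.5), 0.0, rng.uniform(1.5, 3.0)])
    cam = local @ R.T + offset
    if preset.noise_sigma > 0:
        cam = cam + rng.normal(0.0, preset.noise_sigma, size=cam.shape)

    recording = TrialRecording(
        subject_id=subject_id,
        group=preset.group,
        fps=fps,
        timestamps=t,
        positions=cam,
        joints=SYNTH_JOINTS,
    )
    labels = np.array([CANONICAL_TEMPLATE[p] for p in phase], dtype=np.int64)
    return recording, labels, plan.event_times()


def labels_from_events(events: EventTimes, n_frames: int, fps: float) -> np.ndarray:
    """Reconstruct the per-frame ground-truth classes from the six events.

    Frame f (time f/fps) belongs to the template slot whose boundary
    interval contains it; identical to the generator's own labeling, so a
    round trip through an event sidecar file reproduces the labels.
    """
    t = np.arange(n_frames) / fps
    phase = np.searchsorted(events.as_array(), t, side="right")
    return np.array([CANONICAL_TEMPLATE[p] for p in phase], dtype=np.int64)


@dataclasses.dataclass
class SynthTrial:
    recording: TrialRecording
    labels: np.ndarray
    events: EventTimes

    @property
    def group(self) -> str:
        return self.recording.group


def batch_generate(
    n: int,
    preset: GroupPreset | Sequence[GroupPreset],
    master_seed: int,
    subject_prefix: str = "sub",
) -> list[SynthTrial]:
    """Generate ``n`` reproducible trials.

    ``preset`` may be a single group preset or a sequence of presets, in
    which case trials cycle through the groups. Per-trial seeds derive
    deterministically from ``master_seed``, so the same seed yields a
    byte-identical dataset. Each trial gets its own subject id.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    presets = [preset] if isinstance(preset, GroupPreset) else list(preset)
    out = []
    for i in range(n):
        p = presets[i % len(presets)]
        rng = np.random.default_rng(np.random.SeedSequence([int(master_seed), i]))
        plan = sample_phase_plan(p, rng)
        rec, labels, events = synthesize_trial(plan, p, rng, subject_id=f"{subject_prefix}{i:03d}")
        out.append(SynthTrial(rec, labels, events))
    return out
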