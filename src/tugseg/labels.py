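"""Frame-level subtask classes and the canonical subtask order.

A TUG trial decomposes into seven ordered phases: an initial seated rest,
sit-to-stand, the outbound walk, the turn at the cone, the return walk,
stand-to-sit, and a final seated rest.  The classifier distinguishes five
classes only — outbound and return walking are the same motion pattern and
share the WALK class; they are separated positionally by the postprocessor.
"""

from __future__ import annotations

import enum


class Subtask(enum.IntEnum):
    SIT = 0
    SIT2STAND = 1
    WALK = 2
    TURN = 3
    STAND2SIT = 4


N_CLASSES = len(Subtask)

#: Canonical 7-slot template: sit, sit-to-stand, walk, turn, walk-back,
#: stand-to-sit, sit.  Leading/trailing SIT slots may be empty in a
#: recording; the five active slots may not.
CANONICAL_TEMPLATE: tuple[Subtask, ...] = (
    Subtask.SIT,
    Subtask.SIT2STAND,
    Subtask.WALK,
    Subtask.TURN,
    Subtask.WALK,
    Subtask.STAND2SIT,
    Subtask.SIT,
)

#: Slots of the template that must contain at least one frame.
ACTIVE_SLOTS: tuple[int, ...] = (1, 2, 3, 4, 5)

#: Human-readable names of the seven template phases, in order.
PHASE_ORDER_DOC: tuple[str, ...] = (
    "lead_sit",
    "sit_to_stand",
    "walk",
    "turn",
    "walk_back",
    "stand_to_sit",
    "trail_sit",
)

#: Names of the six events separating the template slots, in order.
EVENT_NAMES: tuple[str, ...] = (
    "start_move",
    "start_walk",
    "start_turn",
    "end_turn",
    "start_sit",
    "end_sit",
)
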