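"""Azure-Kinect body-tracking joint set.

The body-tracking SDK reports 32 joints per skeleton; the enumeration below
follows the SDK's canonical order so that index-based exports can be mapped
back by position as well as by name.
"""

from __future__ import annotations

import enum


class JointId(enum.IntEnum):
    """The 32 joints of the Azure Kinect body-tracking skeleton."""

    PELVIS = 0
    SPINE_NAVEL = 1
    SPINE_CHEST = 2
    NECK = 3
    CLAVICLE_LEFT = 4
    SHOULDER_LEFT = 5
    ELBOW_LEFT = 6
    WRIST_LEFT = 7
    HAND_LEFT = 8
    HANDTIP_LEFT = 9
    THUMB_LEFT = 10
    CLAVICLE_RIGHT = 11
    SHOULDER_RIGHT = 12
    ELBOW_RIGHT = 13
    WRIST_RIGHT = 14
    HAND_RIGHT = 15
    HANDTIP_RIGHT = 16
    THUMB_RIGHT = 17
    HIP_LEFT = 18
    KNEE_LEFT = 19
    ANKLE_LEFT = 20
    FOOT_LEFT = 21
    HIP_RIGHT = 22
    KNEE_RIGHT = 23
    ANKLE_RIGHT = 24
    FOOT_RIGHT = 25
    HEAD = 26
    NOSE = 27
    EYE_LEFT = 28
    EAR_LEFT = 29
    EYE_RIGHT = 30
    EAR_RIGHT = 31


#: The five proximal/distal feature groups compared as model inputs:
#: pelvis, spine chest, head, hand pair, ankle pair.
FEATURE_GROUPS: dict[str, tuple[JointId, ...]] = {
    "pelvis": (JointId.PELVIS,),
    "spine_chest": (JointId.SPINE_CHEST,),
    "head": (JointId.HEAD,),
    "hands": (JointId.HAND_LEFT, JointId.HAND_RIGHT),
    "ankles": (JointId.ANKLE_LEFT, JointId.ANKLE_RIGHT),
}
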