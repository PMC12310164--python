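"""BODY_25 keypoint layout used by the OpenPose pose-estimation model.

The BODY_25 model emits 25 named 2D landmarks per person per frame:
nose, neck, mid-hip, and bilateral eyes, ears, shoulders, elbows, wrists,
hips, knees, ankles, heels, big toes and small toes. Indices follow the
OpenPose output ordering (``pose_keypoints_2d`` packs 25 triplets of
x, y, confidence in this order).
"""

from __future__ import annotations

KEYPOINT_NAMES: tuple[str, ...] = (
    "nose",            # 0
    "neck",            # 1
    "right_shoulder",  # 2
    "right_elbow",     # 3
    "right_wrist",     # 4
    "left_shoulder",   # 5
    "left_elbow",      # 6
    "left_wrist",      # 7
    "mid_hip",         # 8
    "right_hip",       # 9
    "right_knee",      # 10
    "right_ankle",     # 11
    "left_hip",        # 12
    "left_knee",       # 13
    "left_ankle",      # 14
    "right_eye",       # 15
    "left_eye",        # 16
    "right_ear",       # 17
    "left_ear",        # 18
    "left_big_toe",    # 19
    "left_small_toe",  # 20
    "left_heel",       # 21
    "right_big_toe",   # 22
    "right_small_toe", # 23
    "right_heel",      # 24
)

N_KEYPOINTS = len(KEYPOINT_NAMES)

INDEX: dict[str, int] = {name: i for i, name in enumerate(KEYPOINT_NAMES)}

MID_HIP = INDEX["mid_hip"]

#: (left index, right index) pairs for the lower limb; a left/right identity
#: switch in single-camera pose estimation exchanges these jointly.
LOWER_LIMB_PAIRS: tuple[tuple[int, int], ...] = (
    (INDEX["left_hip"], INDEX["right_hip"]),
    (INDEX["left_knee"], INDEX["right_knee"]),
    (INDEX["left_ankle"], INDEX["right_ankle"]),
    (INDEX["left_heel"], INDEX["right_heel"]),
    (INDEX["left_big_toe"], INDEX["right_big_toe"]),
    (INDEX["left_small_toe"], INDEX["right_small_toe"]),
)

SIDES = ("left", "right")


def side_keypoint(side: str, joint: str) -> int:
    """Index of a lateral joint ('hip', 'knee', 'ankle', 'heel', 'big_toe',
    'small_toe', ...) on 'left' or 'right'."""
    if side not in SIDES:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    return INDEX[f"{side}_{joint}"]


def other_side(side: str) -> str:
    return "right" if side == "left" else "left"
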