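"""Reading OpenPose BODY_25 output and pixel-to-meter calibration.

OpenPose writes one JSON file per video frame; each file lists the people
detected in that frame with a flat ``pose_keypoints_2d`` array of 75
floats (25 keypoints x (x px, y px, confidence)). Keypoints the network
could not place carry the sentinel position (0, 0) with confidence 0.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import body25
from .errors import CalibrationError, FormatError, FrameGapError
from .trajectory import KeypointTrajectorySet

_FRAME_RE = re.compile(r"(\d+)")


@dataclass(frozen=True)
class CalibrationScale:
    """Pixel-to-meter scale, from tape marks in the image or from config."""

    pixels_per_meter: float
    source: str = "config"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.pixels_per_meter) and self.pixels_per_meter > 0):
            raise CalibrationError(
                f"pixels_per_meter must be positive and finite, got {self.pixels_per_meter}"
            )


def calibrate_scale(
    mark_a: tuple[float, float], mark_b: tuple[float, float], known_distance: float
) -> CalibrationScale:
    """Scale from two annotated marks a known distance apart (e.g. the ends
    of a 0.1 m tape on the walkway)."""
    if known_distance <= 0:
        raise CalibrationError(f"known_distance must be positive, got {known_distance}")
    d_px = math.hypot(mark_b[0] - mark_a[0], mark_b[1] - mark_a[1])
    if d_px == 0.0:
        raise CalibrationError("calibration marks are coincident")
    return CalibrationScale(pixels_per_meter=d_px / known_distance, source="tape_marks")


def _frame_index(path: Path) -> int:
    matches = _FRAME_RE.findall(path.stem)
    if not matches:
        raise FormatError(f"cannot extract a frame index from filename {path.name!r}")
    return int(matches[-1])


def _parse_people(path: Path) -> list[np.ndarray]:
    """(25, 3) arrays, one per person, in file order."""
    try:
        doc = json.loads(path.read_text())
        people = doc["people"]
        out = []
        for person in people:
            kp = np.asarray(person["pose_keypoints_2d"], dtype=float)
            if kp.size != 3 * body25.N_KEYPOINTS:
                raise ValueError(f"expected 75 floats, got {kp.size}")
            out.append(kp.reshape(body25.N_KEYPOINTS, 3))
        return out
    except (KeyError, ValueError, TypeError, json.JSONDecodeError) as exc:
        raise FormatError(f"unparseable OpenPose frame file {path}: {exc}") from exc


def _person_validity(kp: np.ndarray, confidence_threshold: float) -> np.ndarray:
    sentinel = (kp[:, 0] == 0.0) & (kp[:, 1] == 0.0)
    return ~sentinel & (kp[:, 2] >= confidence_threshold)


def _bbox_height(kp: np.ndarray, valid: np.ndarray) -> float:
    if not valid.any():
        return -np.inf
    ys = kp[valid, 1]
    return float(ys.max() - ys.min())


def _select_person(
    people: list[np.ndarray],
    confidence_threshold: float,
    prev_mid_hip: np.ndarray | None,
) -> np.ndarray | None:
    """Track the walking subject across frames.

    The person whose mid-hip is nearest the previously selected mid-hip
    wins; in the first usable frame the largest bounding-box height wins
    (the subject is closest to the camera). People without a valid mid-hip
    fall back to their valid-keypoint centroid for the distance.
    """
    if not people:
        return None
    scores = []
    for kp in people:
        valid = _person_validity(kp, confidence_threshold)
        if prev_mid_hip is None:
            scores.append(_bbox_height(kp, valid))
        else:
            if valid[body25.MID_HIP]:
                ref = kp[body25.MID_HIP, :2]
            elif valid.any():
                ref = kp[valid, :2].mean(axis=0)
            else:
                scores.append(-np.inf)
                continue
            scores.append(-float(np.hypot(*(ref - prev_mid_hip))))
    best = int(np.argmax(scores))
    if scores[best] == -np.inf:
        return None
    return people[best]


def read_openpose_sequence(
    directory: str | Path,
    frame_rate: float = 100.0,
    confidence_threshold: float = 0.1,
    meta: dict | None = None,
) -> KeypointTrajectorySet:
    """Read a directory of per-frame OpenPose JSON files into a trajectory set.

    Frames are ordered by the frame index embedded in each filename and
    must be contiguous. Multi-person frames are resolved by nearest-mid-hip
    tracking (largest person in the first frame). Keypoints at the (0, 0)
    sentinel or below ``confidence_threshold`` are marked missing.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.json"), key=_frame_index)
    if not files:
        raise FormatError(f"no per-frame JSON files found in {directory}")
    indices = [_frame_index(p) for p in files]
    expected = list(range(indices[0], indices[0] + len(indices)))
    if indices != expected:
        missing = sorted(set(expected) - set(indices))
        raise FrameGapError(
            f"non-contiguous frame indices in {directory}; missing {missing[:20]}"
        )

    n = len(files)
    positions = np.zeros((n, body25.N_KEYPOINTS, 2))
    confidence = np.zeros((n, body25.N_KEYPOINTS))
    missing = np.ones((n, body25.N_KEYPOINTS), dtype=bool)
    prev_mid_hip: np.ndarray | None = None
    for i, path in enumerate(files):
        people = _parse_people(path)
        kp = _select_person(people, confidence_threshold, prev_mid_hip)
        if kp is None:
            continue  # fully missing row
        valid = _person_validity(kp, confidence_threshold)
        positions[i] = kp[:, :2]
        confidence[i] = kp[:, 2]
        missing[i] = ~valid
        positions[i][~valid] = 0.0
        if valid[body25.MID_HIP]:
            prev_mid_hip = kp[body25.MID_HIP, :2]

    return KeypointTrajectorySet(
        times=np.arange(n) / frame_rate,
        positions=positions,
        confidence=confidence,
        missing=missing,
        frame_rate=frame_rate,
        units="px",
        meta={**(meta or {}), "provenance": ["read_openpose"]},
    )
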