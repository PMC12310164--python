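"""Synthetic sagittal-plane gait keypoint streams with known ground truth.

The generator produces what a single RGB camera plus the BODY_25
pose-estimation model would deliver for a hemiparetic walking trial: a
per-frame stream of 25 keypoints (x px, y px, confidence) on a uniform
100 Hz grid, degraded with pixel noise, missing keypoints (pose-estimator
sentinel (0, 0) with confidence 0) and whole-leg left/right identity
swaps. Every trial carries a :class:`GroundTruth` with the exact initial
contact / toe-off times, the noise-free trajectories and the injected
degradation log, so downstream detectors and parameter estimators can be
scored against a known answer.

Kinematic model (deliberately minimal, sagittal, orthographic):

* Each foot alternates a strictly stationary foot-flat stance with a swing
  that advances the heel by one stride length along a smoothstep
  (3u^2 - 2u^3) profile — C^1, zero forward velocity at both ends.
* The mid-hip advances at the profile's gait speed with a small periodic
  fluctuation (two oscillations per stride).
* Vertical coordinates follow a fixed body template scaled to the subject
  height; upper-body keypoints are static offsets from the mid-hip.

Asymmetry enters through per-side step lengths and stance/swing times;
the two sides share one stride time so the gait is periodic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import body25
from .errors import GenerationError, ProfileValidationError
from .trajectory import KeypointTrajectorySet

# Body template: landmark heights as fractions of subject stature.
_ANKLE_H = 0.039
_KNEE_H = 0.285
_HIP_H = 0.530
_SHOULDER_H = 0.810
_NECK_H = 0.820
_NOSE_H = 0.930
_EYE_H = 0.940
_EAR_H = 0.925
_FOOT_LEN = 0.152   # heel to big toe, fraction of stature
_FOOT_LIFT = 0.090  # peak swing heel clearance, fraction of stature

PROFILE_PARAMS = (
    "gait_speed",
    "cadence",
    "paretic_step_fraction",
    "stance_duty_paretic",
    "stance_duty_nonparetic",
)

OUTCOME_COLUMNS = (
    "gait_speed",
    "cadence",
    "step_length_paretic",
    "step_length_nonparetic",
    "stance_time_paretic",
    "stance_time_nonparetic",
    "swing_time_paretic",
    "swing_time_nonparetic",
)

CONDITIONS = ("no_afo", "spring1", "spring2", "spring3", "spring4")
#: AFO plantarflexion-resistance stiffness per spring condition (Nm/deg);
#: carried as metadata only.
STIFFNESS_NM_PER_DEG = {
    "no_afo": 0.0,
    "spring1": 0.64,
    "spring2": 1.14,
    "spring3": 1.57,
    "spring4": 1.74,
}


def _smoothstep(u: np.ndarray) -> np.ndarray:
    return u * u * (3.0 - 2.0 * u)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaitProfile:
    """Ground-truth spatiotemporal parameters of one simulated trial.

    Times in seconds, lengths in meters, speed in m/s, cadence in
    steps/min. Both sides share one stride time (stance + swing), and the
    closure ``gait_speed * stride_time = step_length_paretic +
    step_length_nonparetic`` ties the spatial and temporal parameters
    together.
    """

    gait_speed: float
    cadence: float
    step_length_paretic: float
    step_length_nonparetic: float
    stance_time_paretic: float
    stance_time_nonparetic: float
    swing_time_paretic: float
    swing_time_nonparetic: float
    hemiparetic_side: str = "left"
    walking_direction: str = "+x"

    def __post_init__(self) -> None:
        self.validate()

    @property
    def stride_time(self) -> float:
        return self.stance_time_paretic + self.swing_time_paretic

    @property
    def stride_length(self) -> float:
        return self.step_length_paretic + self.step_length_nonparetic

    def validate(self) -> None:
        pos_fields = (
            "gait_speed", "cadence",
            "step_length_paretic", "step_length_nonparetic",
            "stance_time_paretic", "stance_time_nonparetic",
            "swing_time_paretic", "swing_time_nonparetic",
        )
        for name in pos_fields:
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ProfileValidationError(f"{name} must be strictly positive, got {v}")
        if self.hemiparetic_side not in ("left", "right"):
            raise ProfileValidationError(
                f"hemiparetic_side must be 'left' or 'right', got {self.hemiparetic_side!r}"
            )
        if self.walking_direction not in ("+x", "-x"):
            raise ProfileValidationError(
                f"walking_direction must be '+x' or '-x', got {self.walking_direction!r}"
            )
        stride_p = self.stance_time_paretic + self.swing_time_paretic
        stride_np = self.stance_time_nonparetic + self.swing_time_nonparetic
        if abs(stride_p - stride_np) > 1e-9:
            raise ProfileValidationError(
                f"stride time must be equal on both sides: {stride_p} vs {stride_np}"
            )
        if abs(self.cadence - 120.0 / stride_p) > 1e-6:
            raise ProfileValidationError(
                f"cadence {self.cadence} inconsistent with stride time {stride_p}"
                f" (expected {120.0 / stride_p})"
            )
        if abs(self.gait_speed * stride_p - self.stride_length) > 1e-6:
            raise ProfileValidationError(
                "gait_speed * stride_time must equal the summed step lengths: "
                f"{self.gait_speed * stride_p} vs {self.stride_length}"
            )

    @classmethod
    def from_speed_cadence(
        cls,
        gait_speed: float,
        cadence: float,
        paretic_step_fraction: float = 0.5,
        stance_duty_paretic: float = 0.62,
        stance_duty_nonparetic: float = 0.68,
        hemiparetic_side: str = "left",
        walking_direction: str = "+x",
    ) -> "GaitProfile":
        """Build a consistent profile from free parameters.

        ``paretic_step_fraction`` is the paretic share of the stride
        length; stance duties are stance time / stride time per side.
        """
        stride_time = 120.0 / cadence
        stride_length = gait_speed * stride_time
        stance_p = stance_duty_paretic * stride_time
        stance_np = stance_duty_nonparetic * stride_time
        return cls(
            gait_speed=gait_speed,
            cadence=cadence,
            step_length_paretic=paretic_step_fraction * stride_length,
            step_length_nonparetic=(1.0 - paretic_step_fraction) * stride_length,
            stance_time_paretic=stance_p,
            stance_time_nonparetic=stance_np,
            swing_time_paretic=stride_time - stance_p,
            swing_time_nonparetic=stride_time - stance_np,
            hemiparetic_side=hemiparetic_side,
            walking_direction=walking_direction,
        )

    def side_params(self, side: str) -> dict[str, float]:
        """Step length / stance / swing for image-side 'left' or 'right'."""
        role = "paretic" if side == self.hemiparetic_side else "nonparetic"
        return {
            "step_length": getattr(self, f"step_length_{role}"),
            "stance_time": getattr(self, f"stance_time_{role}"),
            "swing_time": getattr(self, f"swing_time_{role}"),
        }


@dataclass(frozen=True)
class CameraModel:
    """Orthographic sagittal camera: one pixel scale for the whole scene."""

    resolution: tuple[int, int] = (720, 520)
    frame_rate: float = 100.0
    pixels_per_meter: float = 70.0
    subject_height_px: float = 119.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise GenerationError("frame_rate must be positive")
        if self.pixels_per_meter <= 0:
            raise GenerationError("pixels_per_meter must be positive")

    @property
    def subject_height_m(self) -> float:
        return self.subject_height_px / self.pixels_per_meter


@dataclass(frozen=True)
class DegradationModel:
    """Pose-estimator failure modes injected after the ideal projection.

    ``missing_prob_per_keypoint_frame`` is the marginal probability that a
    keypoint is absent in a frame; absences arrive in runs of 1 to
    ``max_gap_length`` frames. ``swap_prob_per_frame`` is the marginal
    probability that a frame lies in a left/right identity-swap run
    (geometric run length, mean ``swap_run_mean``) in which all six
    lower-limb keypoint pairs are exchanged jointly.
    """

    pixel_noise_sd: float = 2.0
    missing_prob_per_keypoint_frame: float = 0.02
    max_gap_length: int = 8
    swap_prob_per_frame: float = 0.02
    swap_run_mean: float = 3.0
    confidence_mean: float = 0.85
    confidence_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_prob_per_keypoint_frame <= 1.0:
            raise GenerationError("missing probability must be in [0, 1]")
        if not 0.0 <= self.swap_prob_per_frame <= 1.0:
            raise GenerationError("swap probability must be in [0, 1]")
        if self.pixel_noise_sd < 0:
            raise GenerationError("pixel_noise_sd must be >= 0")


NO_DEGRADATION = DegradationModel(
    pixel_noise_sd=0.0,
    missing_prob_per_keypoint_frame=0.0,
    swap_prob_per_frame=0.0,
    confidence_mean=1.0,
    confidence_sd=0.0,
)


@dataclass
class GroundTruth:
    """Exact answers for one simulated trial."""

    profile: GaitProfile
    ic_times: dict[str, np.ndarray]        # image side -> sorted IC times (s)
    to_times: dict[str, np.ndarray]        # image side -> sorted TO times (s)
    true_positions: np.ndarray             # (n_frames, 25, 2) noise-free px
    swap_frames: np.ndarray                # injected swap frame indices
    missing_injected: np.ndarray | None = None  # (n_frames, 25) bool

    def events(self) -> list[tuple[float, str, str]]:
        """All (time, side, type) events sorted by time."""
        ev: list[tuple[float, str, str]] = []
        for side in body25.SIDES:
            ev += [(t, side, "IC") for t in self.ic_times[side]]
            ev += [(t, side, "TO") for t in self.to_times[side]]
        return sorted(ev)


# ---------------------------------------------------------------------------
# trial-level generation
# ---------------------------------------------------------------------------


def _foot_timeline(t: np.ndarray, t0: float, stride_time: float, stance: float,
                   stride_length: float, origin: float):
    """Heel forward position (m), height (m) and swing phase u for one side.

    Stance holds the heel at its placement; swing advances it by one stride
    length along a smoothstep with sin^2 vertical clearance.
    """
    k = np.floor((t - t0) / stride_time)
    t_in = t - t0 - k * stride_time
    swing = stride_time - stance
    in_swing = t_in >= stance
    u = np.where(in_swing, (t_in - stance) / swing, 0.0)
    forward = k * stride_length + origin + stride_length * _smoothstep(u)
    return forward, u, in_swing


def simulate_trial(
    profile: GaitProfile,
    camera: CameraModel | None = None,
    degrade: DegradationModel | None = None,
    n_strides: int = 6,
    hip_fluctuation_m: float = 0.01,
    hip_bob_fraction: float = 0.010,
) -> tuple[KeypointTrajectorySet, GroundTruth]:
    """Simulate one walking trial and its exact ground truth.

    Parameters
    ----------
    profile : validated gait parameters (the trial's ground truth).
    camera : pixel geometry; defaults to the 720x520 @ 100 Hz model.
    degrade : degradation model, or None for a clean, full-confidence trial.
    n_strides : number of complete strides (>= 3).
    hip_fluctuation_m : amplitude of the periodic mid-hip forward
        fluctuation about the constant-speed ramp (two cycles per stride).
    hip_bob_fraction : vertical mid-hip oscillation amplitude as a fraction
        of stature.
    """
    profile.validate()
    if n_strides < 3:
        raise GenerationError(f"n_strides must be >= 3, got {n_strides}")
    camera = camera or CameraModel()
    fps = camera.frame_rate
    H = camera.subject_height_m
    T = profile.stride_time
    D = profile.stride_length
    left = profile.side_params("left")
    right = profile.side_params("right")

    # Timing: left ICs at t0 + k*T; the right IC trails the left by delta,
    # chosen midway between the bounds that guarantee double support
    # (contralateral IC strictly inside each stance).
    if right["swing_time"] >= left["stance_time"] or left["swing_time"] >= right["stance_time"]:
        raise ProfileValidationError(
            "profile admits no double support (a swing time exceeds the "
            "contralateral stance time)"
        )
    delta = 0.5 * (right["swing_time"] + left["stance_time"])
    t_lead = 0.75 * T
    t_total = t_lead + n_strides * T + 0.75 * T
    n_frames = int(round(t_total * fps)) + 1
    t = np.arange(n_frames) / fps

    t0 = {"left": t_lead, "right": t_lead + delta}
    origin = {"left": 0.0, "right": right["step_length"]}
    stance = {"left": left["stance_time"], "right": right["stance_time"]}

    heel_f: dict[str, np.ndarray] = {}
    heel_h: dict[str, np.ndarray] = {}
    swing_u: dict[str, np.ndarray] = {}
    for side in body25.SIDES:
        f, u, in_swing = _foot_timeline(t, t0[side], T, stance[side], D, origin[side])
        heel_f[side] = f
        swing_u[side] = np.where(in_swing, u, 0.0)
        heel_h[side] = _FOOT_LIFT * H * np.sin(np.pi * swing_u[side]) ** 2

    phase = 4.0 * np.pi * (t - t_lead) / T
    hip_f = profile.gait_speed * t + hip_fluctuation_m * np.sin(phase)
    # keep the trunk over the base of support: shift the hip ramp by a
    # constant so its mean rides over the mid-point of the two heels
    foot_center = 0.5 * (heel_f["left"] + heel_f["right"]) + 0.4 * _FOOT_LEN * H
    hip_f = hip_f + float(np.mean(foot_center - hip_f))
    hip_h = _HIP_H * H + hip_bob_fraction * H * np.sin(phase + np.pi / 3)

    # Assemble forward (m, walking frame) and height (m above ground).
    fwd = np.zeros((n_frames, body25.N_KEYPOINTS))
    hgt = np.zeros((n_frames, body25.N_KEYPOINTS))

    def put(idx: int, f: np.ndarray | float, h: np.ndarray | float) -> None:
        fwd[:, idx] = f
        hgt[:, idx] = h

    put(body25.MID_HIP, hip_f, hip_h)
    trunk = hip_h - _HIP_H * H  # vertical bob carried by the whole trunk
    put(body25.INDEX["neck"], hip_f + 0.01 * H, _NECK_H * H + trunk)
    put(body25.INDEX["nose"], hip_f + 0.045 * H, _NOSE_H * H + trunk)
    for side, lat in (("left", 1.0), ("right", -1.0)):
        put(body25.side_keypoint(side, "shoulder"), hip_f + 0.008 * H * lat,
            _SHOULDER_H * H + trunk)
        put(body25.side_keypoint(side, "elbow"), hip_f - 0.02 * H + 0.005 * H * lat,
            0.63 * H + trunk)
        put(body25.side_keypoint(side, "wrist"), hip_f + 0.01 * H + 0.005 * H * lat,
            0.47 * H + trunk)
        put(body25.side_keypoint(side, "eye"), hip_f + 0.055 * H + 0.003 * H * lat,
            _EYE_H * H + trunk)
        put(body25.side_keypoint(side, "ear"), hip_f + 0.02 * H + 0.003 * H * lat,
            _EAR_H * H + trunk)

    foot_len = _FOOT_LEN * H
    for side, lat in (("left", 1.0), ("right", -1.0)):
        hf, hh, u = heel_f[side], heel_h[side], swing_u[side]
        put(body25.side_keypoint(side, "heel"), hf, hh)
        put(body25.side_keypoint(side, "big_toe"), hf + 0.85 * foot_len, hh)
        put(body25.side_keypoint(side, "small_toe"), hf + 0.70 * foot_len,
            hh + 0.005 * H)
        ankle_f = hf + 0.25 * foot_len
        ankle_h = hh + _ANKLE_H * H
        put(body25.side_keypoint(side, "ankle"), ankle_f, ankle_h)
        side_hip_f = hip_f + 0.006 * H * lat
        put(body25.side_keypoint(side, "hip"), side_hip_f, hip_h + 0.01 * H)
        knee_bump = 0.04 * H * np.sin(np.pi * u) ** 2
        put(body25.side_keypoint(side, "knee"),
            0.5 * (side_hip_f + ankle_f) + knee_bump, _KNEE_H * H)

    # Orthographic projection to pixels.
    dir_sign = 1.0 if profile.walking_direction == "+x" else -1.0
    ppm = camera.pixels_per_meter
    x_raw = dir_sign * fwd * ppm
    margin = 10.0
    x = x_raw + (margin - x_raw.min())
    width, height_px = camera.resolution
    if x.max() > width - margin:
        raise GenerationError(
            "trial span exceeds the image width; reduce n_strides or "
            "pixels_per_meter"
        )
    ground_y = height_px - 0.05 * height_px
    y = ground_y - hgt * ppm
    if y.min() < margin:
        raise GenerationError("subject extends above the image; reduce subject_height_px")

    true_positions = np.stack([x, y], axis=-1)
    positions = true_positions.copy()
    confidence = np.ones((n_frames, body25.N_KEYPOINTS))
    missing = np.zeros((n_frames, body25.N_KEYPOINTS), dtype=bool)
    swap_frames = np.empty(0, dtype=int)

    if degrade is not None:
        positions, confidence, missing, swap_frames = _apply_degradations(
            positions, degrade
        )

    traj = KeypointTrajectorySet(
        times=t,
        positions=positions,
        confidence=confidence,
        missing=missing,
        frame_rate=fps,
        units="px",
        meta={
            "hemiparetic_side": profile.hemiparetic_side,
            "walking_direction": profile.walking_direction,
            "pixels_per_meter": ppm,
            "provenance": ["simulate"],
        },
    )

    ks = np.arange(-3, n_strides + 4)
    ic_times: dict[str, np.ndarray] = {}
    to_times: dict[str, np.ndarray] = {}
    t_end = t[-1]
    for side in body25.SIDES:
        ic = t0[side] + ks * T
        to = ic + stance[side]
        ic_times[side] = ic[(ic >= 0) & (ic <= t_end)]
        to_times[side] = to[(to >= 0) & (to <= t_end)]

    truth = GroundTruth(
        profile=profile,
        ic_times=ic_times,
        to_times=to_times,
        true_positions=true_positions,
        swap_frames=swap_frames,
        missing_injected=missing.copy(),
    )
    return traj, truth


def _run_starts(rng: np.random.Generator, n: int, marginal_prob: float,
                mean_run: float) -> np.ndarray:
    if marginal_prob <= 0:
        return np.empty(0, dtype=int)
    p_start = min(1.0, marginal_prob / mean_run)
    return np.flatnonzero(rng.random(n) < p_start)


def _apply_degradations(positions: np.ndarray, degrade: DegradationModel):
    n_frames, n_kp, _ = positions.shape
    rng = np.random.default_rng(degrade.seed)
    out = positions.copy()

    # 1) whole-leg left/right identity swaps, contiguous runs
    swapped = np.zeros(n_frames, dtype=bool)
    for start in _run_starts(rng, n_frames, degrade.swap_prob_per_frame,
                             degrade.swap_run_mean):
        length = min(rng.geometric(1.0 / degrade.swap_run_mean), 3 * int(degrade.swap_run_mean))
        swapped[start:start + length] = True
    swap_frames = np.flatnonzero(swapped)
    for li, ri in body25.LOWER_LIMB_PAIRS:
        tmp = out[swap_frames, li].copy()
        out[swap_frames, li] = out[swap_frames, ri]
        out[swap_frames, ri] = tmp

    # 2) Gaussian pixel noise
    if degrade.pixel_noise_sd > 0:
        out += rng.normal(0.0, degrade.pixel_noise_sd, out.shape)

    # 3) confidence scores
    confidence = np.clip(
        rng.normal(degrade.confidence_mean, degrade.confidence_sd, (n_frames, n_kp)),
        0.05, 1.0,
    )

    # 4) missing keypoints in runs; sentinel (0, 0) with confidence 0
    missing = np.zeros((n_frames, n_kp), dtype=bool)
    mean_gap = 0.5 * (1 + degrade.max_gap_length)
    for k in range(n_kp):
        for start in _run_starts(rng, n_frames,
                                 degrade.missing_prob_per_keypoint_frame, mean_gap):
            length = int(rng.integers(1, degrade.max_gap_length + 1))
            missing[start:start + length, k] = True
    out[missing] = 0.0
    confidence[missing] = 0.0

    return out, confidence, missing, swap_frames


def score_swap_correction(corrected: KeypointTrajectorySet, truth: GroundTruth,
                          ambiguity_px: float = 1.0) -> dict[str, int]:
    """Score a left/right-swap correction against the injected ground truth.

    A frame's labeling is judged by majority vote of its visible heel and
    big-toe keypoints: each votes for whichever true side it lies closest
    to (votes within ``ambiguity_px`` of indifference abstain — the heels
    genuinely coincide while crossing). Returns counts of evaluable
    injected-swap frames, how many of them end up correctly labeled, and
    the number of clean frames left wrongly labeled (false positives).
    """
    witnesses = [
        (body25.INDEX["left_heel"], body25.INDEX["right_heel"]),
        (body25.INDEX["right_heel"], body25.INDEX["left_heel"]),
        (body25.INDEX["left_big_toe"], body25.INDEX["right_big_toe"]),
        (body25.INDEX["right_big_toe"], body25.INDEX["left_big_toe"]),
    ]
    injected = set(int(f) for f in truth.swap_frames)
    n_injected = n_injected_ok = n_false = 0
    for i in range(corrected.n_frames):
        votes = []
        for k, partner in witnesses:
            if corrected.missing[i, k]:
                continue
            d_own = float(np.hypot(*(corrected.positions[i, k]
                                     - truth.true_positions[i, k])))
            d_other = float(np.hypot(*(corrected.positions[i, k]
                                       - truth.true_positions[i, partner])))
            if abs(d_own - d_other) < ambiguity_px:
                continue
            votes.append(d_own < d_other)
        if not votes:
            continue
        ok = sum(votes) > len(votes) / 2
        if i in injected:
            n_injected += 1
            n_injected_ok += ok
        elif not ok:
            n_false += 1
    return {"injected_evaluable": n_injected, "injected_corrected": n_injected_ok,
            "false_positives": n_false}



# ---------------------------------------------------------------------------
# static decoy (for person-selection tests)
# ---------------------------------------------------------------------------


def static_decoy(camera: CameraModel | None = None, x_px: float = 650.0,
                 height_scale: float = 0.6) -> tuple[np.ndarray, np.ndarray]:
    """A motionless bystander skeleton for multi-person frame files.

    Returns (positions (25, 2), confidence (25,)). Smaller than the subject
    (farther from the camera) and off the walkway.
    """
    camera = camera or CameraModel()
    profile = GaitProfile.from_speed_cadence(1.0, 120.0)
    # borrow the standing pose from frame 0 of a clean trial
    traj, _ = simulate_trial(profile, camera, None, n_strides=3)
    pose = traj.positions[0].copy()
    mid = pose[body25.MID_HIP].copy()
    pose = (pose - mid) * height_scale
    ground_y = camera.resolution[1] - 0.05 * camera.resolution[1]
    pose += np.array([x_px, ground_y - 0.5 * _HIP_H * camera.subject_height_px])
    return pose, np.full(body25.N_KEYPOINTS, 0.7)


# ---------------------------------------------------------------------------
# persistence: OpenPose-dialect JSON + ground-truth CSV
# ---------------------------------------------------------------------------


def write_openpose_sequence(
    traj: KeypointTrajectorySet,
    directory: str | Path,
    extra_people: list[tuple[np.ndarray, np.ndarray]] | None = None,
    extra_first: bool = False,
) -> list[Path]:
    """Write one OpenPose-dialect JSON file per frame.

    Each file holds ``{"version": 1.3, "people": [{"pose_keypoints_2d":
    [x0, y0, c0, ..., x24, y24, c24]}]}`` with zero-padded frame numbers in
    the filename. ``extra_people`` adds static skeletons to every frame
    (before the subject if ``extra_first``).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(traj.n_frames):
        kp = np.concatenate(
            [traj.positions[i], traj.confidence[i][:, None]], axis=1
        ).ravel()
        subject = {"person_id": [-1], "pose_keypoints_2d": [round(v, 4) for v in kp.tolist()]}
        people = [subject]
        for pos, conf in extra_people or []:
            extra = np.concatenate([pos, conf[:, None]], axis=1).ravel()
            person = {"person_id": [-1], "pose_keypoints_2d": [round(v, 4) for v in extra.tolist()]}
            people.insert(0, person) if extra_first else people.append(person)
        path = directory / f"frame_{i:012d}_keypoints.json"
        path.write_text(json.dumps({"version": 1.3, "people": people}))
        paths.append(path)
    return paths


def write_ground_truth(truth: GroundTruth, directory: str | Path) -> None:
    """Persist events and profile as small CSV files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = [{"side": s, "type": k, "time_s": t} for t, s, k in truth.events()]
    pd.DataFrame(rows).to_csv(directory / "events.csv", index=False)
    prof = {f: getattr(truth.profile, f) for f in (
        "gait_speed", "cadence", "step_length_paretic", "step_length_nonparetic",
        "stance_time_paretic", "stance_time_nonparetic",
        "swing_time_paretic", "swing_time_nonparetic",
        "hemiparetic_side", "walking_direction",
    )}
    pd.DataFrame(
        {"parameter": list(prof), "value": list(prof.values())}
    ).to_csv(directory / "profile.csv", index=False)


# ---------------------------------------------------------------------------
# cohort-level generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResponderModel:
    """Assigns each participant a true best condition and its benefit.

    ``weights`` gives the probability that each condition is a
    participant's designated best; ``best_effects`` the additive shifts
    that condition receives on the free profile parameters. The generator
    guarantees the designated condition ends up with the strictly highest
    true gait speed (resampling the within-subject draws on violation).
    """

    weights: dict[str, float] = field(default_factory=lambda: {
        "no_afo": 0.10, "spring1": 0.225, "spring2": 0.225,
        "spring3": 0.225, "spring4": 0.225,
    })
    best_effects: dict[str, float] = field(default_factory=lambda: {
        "gait_speed": 0.11, "cadence": 8.79,
    })
    enforce_argmax: bool = True
    max_resample: int = 100


_BOUNDS = {
    "gait_speed": (0.15, 2.5),
    "cadence": (40.0, 160.0),
    "paretic_step_fraction": (0.30, 0.70),
    "stance_duty_paretic": (0.52, 0.80),
    "stance_duty_nonparetic": (0.52, 0.80),
}


@dataclass(frozen=True)
class CohortSpec:
    """Study-shaped cohort: n participants x 5 conditions.

    Baseline distributions describe a post-stroke inpatient population
    walking at self-selected speed; condition effects are additive shifts
    per condition on the free profile parameters; within-subject SD is the
    trial-to-trial (participant x condition) variation.
    """

    n_participants: int = 32
    conditions: tuple[str, ...] = CONDITIONS
    baseline_mean: dict[str, float] = field(default_factory=lambda: {
        "gait_speed": 0.55, "cadence": 85.0, "paretic_step_fraction": 0.52,
        "stance_duty_paretic": 0.62, "stance_duty_nonparetic": 0.68,
    })
    between_subject_sd: dict[str, float] = field(default_factory=lambda: {
        "gait_speed": 0.15, "cadence": 10.0, "paretic_step_fraction": 0.04,
        "stance_duty_paretic": 0.025, "stance_duty_nonparetic": 0.025,
    })
    within_subject_sd: dict[str, float] = field(default_factory=lambda: {
        "gait_speed": 0.05, "cadence": 3.0, "paretic_step_fraction": 0.015,
        "stance_duty_paretic": 0.01, "stance_duty_nonparetic": 0.01,
    })
    condition_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    responder: ResponderModel | None = field(default_factory=ResponderModel)
    prob_left_hemiparetic: float = 0.5
    n_strides: int = 6
    camera: CameraModel = field(default_factory=CameraModel)
    degradation: DegradationModel = field(default_factory=DegradationModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if tuple(self.conditions) != CONDITIONS:
            raise GenerationError(f"conditions must be {CONDITIONS}")


def _in_bounds(params: dict[str, float]) -> bool:
    for name, (lo, hi) in _BOUNDS.items():
        if not lo <= params[name] <= hi:
            return False
    # double support must exist on both sides
    if params["stance_duty_paretic"] + params["stance_duty_nonparetic"] <= 1.02:
        return False
    # physiological stride length (also keeps a trial inside the camera field)
    stride_length = params["gait_speed"] * 120.0 / params["cadence"]
    if not 0.2 <= stride_length <= 1.4:
        return False
    return True


def simulate_cohort_outcomes(spec: CohortSpec) -> pd.DataFrame:
    """True per-trial outcome table for a cohort, without keypoint streams.

    One row per participant x condition with the eight spatiotemporal
    outcomes derived from the sampled free parameters, plus the designated
    best condition, the randomized condition order and a tie flag. This is
    the fast path for study-level simulation; :func:`simulate_cohort`
    renders the same rows as full keypoint trials.
    """
    rng = np.random.default_rng(spec.seed)
    params = PROFILE_PARAMS
    rows = []
    for pid in range(1, spec.n_participants + 1):
        for _ in range(200):
            base = {
                p: spec.baseline_mean[p] + spec.between_subject_sd[p] * rng.standard_normal()
                for p in params
            }
            if _in_bounds(base):
                break
        else:
            raise GenerationError("could not sample a valid baseline profile")

        designated = None
        if spec.responder is not None:
            conds = list(spec.responder.weights)
            w = np.array([spec.responder.weights[c] for c in conds], dtype=float)
            designated = conds[rng.choice(len(conds), p=w / w.sum())]

        def draw_condition(cond: str) -> dict[str, float]:
            eff = spec.condition_effects.get(cond, {})
            for _ in range(100):
                vals = {}
                for p in params:
                    v = base[p] + eff.get(p, 0.0)
                    if designated == cond and spec.responder is not None:
                        v += spec.responder.best_effects.get(p, 0.0)
                    v += spec.within_subject_sd[p] * rng.standard_normal()
                    vals[p] = v
                if _in_bounds(vals):
                    return vals
            raise GenerationError(
                f"participant {pid}: condition {cond} repeatedly out of bounds"
            )

        max_attempts = spec.responder.max_resample if spec.responder else 1
        for attempt in range(max_attempts):
            per_cond = {cond: draw_condition(cond) for cond in spec.conditions}
            if (
                designated is not None
                and spec.responder.enforce_argmax
                and any(s > 0 for s in spec.within_subject_sd.values())
            ):
                speeds = {c: per_cond[c]["gait_speed"] for c in spec.conditions}
                if max(speeds, key=speeds.get) != designated:
                    continue
            break
        else:
            raise GenerationError(
                f"participant {pid}: designated best condition never had the "
                f"highest gait speed after {max_attempts} resampling attempts"
            )

        side = "left" if rng.random() < spec.prob_left_hemiparetic else "right"
        order = ["no_afo"] + [
            spec.conditions[1:][i] for i in rng.permutation(4)
        ]
        speeds = {c: per_cond[c]["gait_speed"] for c in spec.conditions}
        max_speed = max(speeds.values())
        tie = sum(1 for v in speeds.values() if v == max_speed) > 1
        for cond in spec.conditions:
            v = per_cond[cond]
            T = 120.0 / v["cadence"]
            D = v["gait_speed"] * T
            stance_p = v["stance_duty_paretic"] * T
            stance_np = v["stance_duty_nonparetic"] * T
            rows.append({
                "participant": pid,
                "condition": cond,
                "stiffness_nm_per_deg": STIFFNESS_NM_PER_DEG[cond],
                "condition_order": order.index(cond) + 1,
                "hemiparetic_side": side,
                "designated_best": designated,
                "speed_tie": tie,
                "gait_speed": v["gait_speed"],
                "cadence": v["cadence"],
                "step_length_paretic": v["paretic_step_fraction"] * D,
                "step_length_nonparetic": (1 - v["paretic_step_fraction"]) * D,
                "stance_time_paretic": stance_p,
                "stance_time_nonparetic": stance_np,
                "swing_time_paretic": T - stance_p,
                "swing_time_nonparetic": T - stance_np,
            })
    return pd.DataFrame(rows)


def profile_from_row(row: pd.Series | dict[str, Any],
                     walking_direction: str = "+x") -> GaitProfile:
    """Rebuild the free-parameter profile from an outcome-table row."""
    T = 120.0 / row["cadence"]
    D = row["gait_speed"] * T
    return GaitProfile.from_speed_cadence(
        gait_speed=row["gait_speed"],
        cadence=row["cadence"],
        paretic_step_fraction=row["step_length_paretic"] / D,
        stance_duty_paretic=row["stance_time_paretic"] / T,
        stance_duty_nonparetic=row["stance_time_nonparetic"] / T,
        hemiparetic_side=row["hemiparetic_side"],
        walking_direction=walking_direction,
    )


def simulate_cohort(spec: CohortSpec) -> tuple[list[dict[str, Any]], pd.DataFrame]:
    """Render a full cohort as keypoint trials with ground truth.

    Returns ``(records, manifest)``: one record per participant x
    condition holding the trajectory set, the ground truth and the derived
    per-trial seed; the manifest maps trials to metadata (and, once
    written, to files).
    """
    outcomes = simulate_cohort_outcomes(spec)
    seeds = np.random.SeedSequence(spec.seed).spawn(len(outcomes))
    records = []
    manifest_rows = []
    width_m = spec.camera.resolution[0] / spec.camera.pixels_per_meter
    for (_, row), ss in zip(outcomes.iterrows(), seeds):
        profile = profile_from_row(row)
        trial_seed = int(ss.generate_state(1)[0] % (2**31))
        degrade = replace(spec.degradation, seed=trial_seed)
        # fast walkers cover the camera field in fewer strides
        n_fit = int((width_m - 1.2) / profile.stride_length - 1.5)
        n_strides = max(4, min(spec.n_strides, n_fit))
        traj, truth = simulate_trial(profile, spec.camera, degrade, n_strides)
        traj.meta.update(
            participant=int(row["participant"]), condition=row["condition"]
        )
        rec = {
            "participant": int(row["participant"]),
            "condition": row["condition"],
            "stiffness_nm_per_deg": row["stiffness_nm_per_deg"],
            "traj": traj,
            "truth": truth,
            "seed": trial_seed,
            "designated_best": row["designated_best"],
            "speed_tie": bool(row["speed_tie"]),
        }
        records.append(rec)
        manifest_rows.append({k: rec[k] for k in (
            "participant", "condition", "stiffness_nm_per_deg", "seed",
            "designated_best", "speed_tie",
        )})
    return records, pd.DataFrame(manifest_rows)


def write_cohort(records: list[dict[str, Any]], manifest: pd.DataFrame,
                 directory: str | Path) -> Path:
    """Write every trial's frame files and ground truth plus a manifest CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in records:
        sub = directory / f"p{rec['participant']:03d}" / rec["condition"]
        write_openpose_sequence(rec["traj"], sub / "frames")
        write_ground_truth(rec["truth"], sub / "truth")
        paths.append(str((sub / "frames").relative_to(directory)))
    manifest = manifest.copy()
    manifest["path"] = paths
    out = directory / "manifest.csv"
    manifest.to_csv(out, index=False)
    return out
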