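"""Spatiotemporal gait outcomes for one trial.

All quantities follow the conventions of sagittal single-camera gait
analysis: gait speed from the average forward speed of the mid-hip
keypoint, cadence from the elapsed time of two consecutive steps (three
alternating initial contacts span ``dt``; instantaneous cadence is
``120 / dt``), step length as the anterior heel-to-heel distance at each
initial contact, and stance/swing times from the per-side event intervals.
Because hemiparetic gait is asymmetric, per-side outcomes are reported for
the paretic and nonparetic side separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import body25
from .errors import GaitPoseError, InsufficientStridesError, MissingLandmarkError, UnitError
from .gait_events import GaitEventSequence, stance_swing_intervals
from .trajectory import KeypointTrajectorySet


@dataclass(frozen=True)
class SpatiotemporalResult:
    """Per-trial outcome bundle (speed m/s, cadence steps/min, lengths m,
    times s), labeled by paretic / nonparetic side."""

    gait_speed: float
    cadence: float
    step_length_paretic: float
    step_length_nonparetic: float
    stance_time_paretic: float
    stance_time_nonparetic: float
    swing_time_paretic: float
    swing_time_nonparetic: float
    n_strides_used: int
    analysis_window: tuple[float, float]

    def as_dict(self) -> dict[str, float]:
        return {
            "gait_speed": self.gait_speed,
            "cadence": self.cadence,
            "step_length_paretic": self.step_length_paretic,
            "step_length_nonparetic": self.step_length_nonparetic,
            "stance_time_paretic": self.stance_time_paretic,
            "stance_time_nonparetic": self.stance_time_nonparetic,
            "swing_time_paretic": self.swing_time_paretic,
            "swing_time_nonparetic": self.swing_time_nonparetic,
        }


def _require_meters(traj: KeypointTrajectorySet) -> None:
    if traj.units != "m":
        raise UnitError("trajectory must be converted to meters first")


def compute_gait_speed(
    traj_m: KeypointTrajectorySet, window: tuple[float, float]
) -> float:
    """|mid-hip forward displacement| / duration over the analysis window."""
    _require_meters(traj_m)
    t0, t1 = window
    if t0 < traj_m.times[0] - 1e-9 or t1 > traj_m.times[-1] + 1e-9 or t1 <= t0:
        raise GaitPoseError(f"analysis window {window} outside trial time range")
    hip = traj_m.x(body25.MID_HIP)
    in_win = np.flatnonzero(
        (traj_m.times >= t0 - 1e-9) & (traj_m.times <= t1 + 1e-9) & ~np.isnan(hip)
    )
    if len(in_win) < 2:
        raise GaitPoseError("mid-hip not available inside the analysis window")
    i0, i1 = in_win[0], in_win[-1]
    return float(abs(hip[i1] - hip[i0]) / (traj_m.times[i1] - traj_m.times[i0]))


def compute_cadence(seq: GaitEventSequence) -> float:
    """Mean instantaneous cadence over all consecutive two-step windows.

    Every three successive initial contacts of alternating sides spanning
    ``dt`` seconds contribute ``120 / dt`` steps/min.
    """
    ics = seq.all_ic()
    if len(ics) < 3:
        raise InsufficientStridesError("cadence needs at least 3 initial contacts")
    spans = []
    for a, b, c in zip(ics, ics[1:], ics[2:]):
        if a.side != b.side and b.side != c.side:
            spans.append(c.time - a.time)
    if not spans:
        raise InsufficientStridesError("no alternating two-step windows found")
    spans = np.asarray(spans)
    # a window bridging a detection hole spans extra strides; in steady
    # walking the two-step time is stable, so such windows are excluded
    med = float(np.median(spans))
    keep = spans[np.abs(spans - med) <= 0.3 * med]
    return float(np.mean(120.0 / keep))


def _position_at(traj_m: KeypointTrajectorySet, keypoint: int, time: float) -> float:
    idx = int(round(time * traj_m.frame_rate - traj_m.times[0] * traj_m.frame_rate))
    idx = min(max(idx, 0), traj_m.n_frames - 1)
    x = traj_m.positions[idx, keypoint, 0]
    if traj_m.missing[idx, keypoint]:
        return float("nan")
    return float(x)


def compute_step_lengths(
    traj_m: KeypointTrajectorySet, seq: GaitEventSequence
) -> dict[str, float]:
    """Per-side mean anterior heel-to-heel distance at initial contact.

    At each IC of a side, that side's step length is the forward distance
    from the contralateral heel to the ipsilateral heel (ankle fallback
    when a heel is masked). Negative individual steps (foot-behind
    landings) are retained in the mean.
    """
    _require_meters(traj_m)
    sign = seq.direction_sign
    out: dict[str, float] = {}
    for side in body25.SIDES:
        other = body25.other_side(side)
        vals = []
        for e in seq.side_events(side, "IC"):
            own = _position_at(traj_m, body25.side_keypoint(side, "heel"), e.time)
            if np.isnan(own):
                own = _position_at(traj_m, body25.side_keypoint(side, "ankle"), e.time)
            contra = _position_at(traj_m, body25.side_keypoint(other, "heel"), e.time)
            if np.isnan(contra):
                contra = _position_at(traj_m, body25.side_keypoint(other, "ankle"), e.time)
            if np.isnan(own) or np.isnan(contra):
                continue
            vals.append(sign * (own - contra))
        if not vals:
            raise MissingLandmarkError(
                f"no initial contact with both heels present on the {side} side"
            )
        out[side] = float(np.mean(vals))
    return out


def compute_phase_times(
    intervals: dict[str, dict[str, list[tuple[float, float]]]]
) -> dict[str, dict[str, float]]:
    """Per-side mean stance and swing durations from event intervals."""
    out: dict[str, dict[str, float]] = {}
    for side, iv in intervals.items():
        stance = [b - a for a, b in iv["stance"]]
        swing = [b - a for a, b in iv["swing"]]
        if len(stance) < 2:
            raise InsufficientStridesError(
                f"need >= 2 complete stance phases on the {side} side, got {len(stance)}"
            )
        out[side] = {
            "stance": float(np.mean(stance)),
            "swing": float(np.mean(swing)) if swing else float("nan"),
        }
    return out


def summarize_trial(
    traj_m: KeypointTrajectorySet, seq: GaitEventSequence
) -> SpatiotemporalResult:
    """Bundle all spatiotemporal outcomes for one trial.

    The analysis window is clipped to [first IC, last IC] pooled across
    sides so speed and cadence cover the same strides. Image sides are
    mapped to paretic / nonparetic using the trajectory's
    ``hemiparetic_side`` metadata.
    """
    ics = seq.all_ic()
    if len(ics) < 3:
        raise InsufficientStridesError("trial has fewer than 2 complete strides")
    window = (ics[0].time, ics[-1].time)
    speed = compute_gait_speed(traj_m, window)
    cadence = compute_cadence(seq)
    steps = compute_step_lengths(traj_m, seq)
    phases = compute_phase_times(stance_swing_intervals(seq))
    paretic = traj_m.meta.get("hemiparetic_side", "left")
    nonparetic = body25.other_side(paretic)
    n_strides = min(len(seq.ic_times("left")), len(seq.ic_times("right"))) - 1
    return SpatiotemporalResult(
        gait_speed=speed,
        cadence=cadence,
        step_length_paretic=steps[paretic],
        step_length_nonparetic=steps[nonparetic],
        stance_time_paretic=phases[paretic]["stance"],
        stance_time_nonparetic=phases[nonparetic]["stance"],
        swing_time_paretic=phases[paretic]["swing"],
        swing_time_nonparetic=phases[nonparetic]["swing"],
        n_strides_used=n_strides,
        analysis_window=window,
    )
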