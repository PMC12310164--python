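"""Coordinate-based gait event detection from preprocessed keypoints.

Initial contact (IC) and toe-off (TO) are located per side from the
relative forward displacement of distal keypoints with respect to the
mid-hip: IC candidates at local maxima of ``ankle_x - midhip_x`` (signed
by walking direction) and TO candidates at local minima of
``bigtoe_x - midhip_x``. An IC candidate is confirmed — and its time
refined — by the heel's forward speed dropping below a threshold just
after the peak; a TO candidate is refined to the last near-zero big-toe
speed just before the minimum. The knee substitutes for a masked ankle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks, medfilt, savgol_filter

from . import body25
from .errors import InsufficientStridesError, SequenceError, StationaryTrialError
from .trajectory import KeypointTrajectorySet

log = logging.getLogger(__name__)


@dataclass
class GaitEvent:
    time: float
    side: str           # image side: 'left' / 'right'
    kind: str           # 'IC' / 'TO'
    signal_value: float = float("nan")

    def astuple(self):
        return (self.time, self.side, self.kind)


@dataclass
class GaitEventSequence:
    """Validated alternating IC/TO events for both sides of one trial."""

    events: list[GaitEvent]
    direction_sign: int
    frame_rate: float
    time_range: tuple[float, float] = (0.0, float("inf"))
    meta: dict = field(default_factory=dict)

    def side_events(self, side: str, kind: str | None = None) -> list[GaitEvent]:
        return [e for e in self.events if e.side == side and (kind is None or e.kind == kind)]

    def ic_times(self, side: str) -> np.ndarray:
        return np.array([e.time for e in self.side_events(side, "IC")])

    def to_times(self, side: str) -> np.ndarray:
        return np.array([e.time for e in self.side_events(side, "TO")])

    def all_ic(self) -> list[GaitEvent]:
        return sorted(self.side_events("left", "IC") + self.side_events("right", "IC"),
                      key=lambda e: e.time)

    def validate(self, strict: bool = True,
                 max_violation_frac: float = 0.3) -> int:
        """Check alternation, stance containment of the contralateral IC,
        and time bounds.

        Per-side alternation and time bounds always raise
        :class:`SequenceError` on violation. Containment of the
        contralateral IC in every stance (double support) is exact for
        true gait; a detected sequence may carry holes where single events
        were locally unrecoverable, so with ``strict=False`` containment
        violations are only counted (returned, and stored in ``meta``) and
        raise only when they exceed ``max_violation_frac`` of the stances
        — that pattern indicates a structurally broken detection rather
        than an isolated hole.
        """
        lo, hi = self.time_range
        for e in self.events:
            if not lo <= e.time <= hi:
                raise SequenceError(f"event at {e.time:.3f}s outside trial range")
        stances: dict[str, list[tuple[float, float]]] = {}
        for side in body25.SIDES:
            ev = sorted(self.side_events(side), key=lambda e: e.time)
            for a, b in zip(ev, ev[1:]):
                if a.kind == b.kind:
                    raise SequenceError(
                        f"{side} events do not alternate near t={b.time:.3f}s"
                    )
            stances[side] = [
                (a.time, b.time) for a, b in zip(ev, ev[1:])
                if a.kind == "IC" and b.kind == "TO"
            ]
        violations = 0
        n_stances = 0
        for side in body25.SIDES:
            other = body25.other_side(side)
            contra_ics = self.ic_times(other)
            for ic, to in stances[side]:
                n_stances += 1
                if not np.any((contra_ics > ic) & (contra_ics < to)):
                    if strict:
                        raise SequenceError(
                            f"no contralateral IC inside {side} stance "
                            f"[{ic:.3f}, {to:.3f}]s (double support missing)"
                        )
                    violations += 1
        self.meta["containment_violations"] = violations
        if n_stances and violations > max_violation_frac * n_stances:
            raise SequenceError(
                f"{violations}/{n_stances} stances lack a contralateral IC; "
                "detection is structurally inconsistent"
            )
        return violations


def infer_direction(traj: KeypointTrajectorySet, min_displacement_m: float = 0.2) -> int:
    """Walking direction from the net mid-hip horizontal displacement.

    Returns +1 (increasing x) or -1. A trial whose net displacement is
    below ``min_displacement_m`` (converted through the trajectory's pixel
    scale when still in px) raises :class:`StationaryTrialError`.
    """
    hip = traj.x(body25.MID_HIP)
    valid = np.flatnonzero(~np.isnan(hip))
    if len(valid) < 0.5 * traj.n_frames:
        raise StationaryTrialError("mid-hip valid on fewer than half the frames")
    disp = hip[valid[-1]] - hip[valid[0]]
    if traj.units == "m":
        disp_m = disp
    else:
        ppm = traj.meta.get("pixels_per_meter", 1.0)
        disp_m = disp / ppm
    if abs(disp_m) < min_displacement_m:
        raise StationaryTrialError(
            f"net mid-hip displacement {abs(disp_m):.3f} m is below "
            f"{min_displacement_m} m; cannot infer walking direction"
        )
    return 1 if disp > 0 else -1


@dataclass(frozen=True)
class EventConfig:
    min_period_s: float = 0.4        # merge extrema closer than this
    confirm_window_s: float = 0.25   # half-width of the stop-crossing search around a peak
    persistence_s: float = 0.08      # a foot-stop must hold this long to confirm
    speed_threshold_frac: float = 0.5  # of the median mid-hip speed
    edge_exclusion_s: float = 0.30   # candidates this close to the edges are unreliable
    motion_window_s: float = 0.12    # swing-motion gate span around a candidate
    motion_factor: float = 1.5       # mean swing speed must exceed this multiple of the threshold


def _relative_signal(traj: KeypointTrajectorySet, side: str, distal: str,
                     direction: int) -> np.ndarray:
    """direction * (distal_x - midhip_x), with knee fallback where the
    distal keypoint is masked."""
    d = traj.x(body25.side_keypoint(side, distal))
    knee = traj.x(body25.side_keypoint(side, "knee"))
    d = np.where(np.isnan(d), knee, d)
    return direction * (d - traj.x(body25.MID_HIP))


def _smooth_for_peaks(x: np.ndarray, window: int = 31, order: int = 2) -> np.ndarray:
    """Heavily smoothed copy of a relative-displacement signal for peak
    *location* only (event timing never comes from these peaks). Missing
    samples are bridged so masked runs cannot fabricate edge peaks."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    valid = np.isfinite(x)
    if valid.sum() < window:
        return np.full(n, -np.inf)
    xi = x.copy()
    idx = np.arange(n)
    xi[~valid] = np.interp(idx[~valid], idx[valid], x[valid])
    return savgol_filter(xi, window, order)


def _forward_speed(x: np.ndarray, frame_rate: float, window: int = 11,
                   order: int = 2) -> np.ndarray:
    """|dx/dt| via a Savitzky-Golay derivative.

    A plain central difference at 100 Hz amplifies pixel noise to the same
    order as the stillness threshold; the local-polynomial derivative
    keeps the swing-speed ramps (locally linear) unbiased while averaging
    the noise down. Missing samples are bridged for the fit and returned
    as NaN.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    valid = np.isfinite(x)
    if valid.sum() < window:
        return np.full(n, np.nan)
    xi = x.copy()
    idx = np.arange(n)
    xi[~valid] = np.interp(idx[~valid], idx[valid], x[valid])
    v = savgol_filter(xi, window, order, deriv=1, delta=1.0 / frame_rate)
    v[~valid] = np.nan
    return np.abs(v)


def _falling_crossing(below: np.ndarray, p: int, w: int, persist: int) -> int | None:
    """Index near ``p`` where the speed drops below threshold and stays
    there (a foot coming to rest). Searches [p - w, p + w]; if the foot is
    already at rest at the window start (the locating peak came late), the
    onset of that rest run is recovered by walking backward."""
    n = len(below)
    lo, hi = max(1, p - w), min(n - 1, p + w)
    if below[lo]:
        i = lo
        while i > 1 and below[i - 1] and lo - i < 3 * w:
            i -= 1
        j = min(n, i + persist)
        if np.mean(below[i:j]) >= 0.8:
            return i
        return None
    for i in range(lo, hi + 1):
        if below[i] and not below[i - 1]:
            j = min(n, i + persist)
            if np.mean(below[i:j]) >= 0.8:
                return i
    return None


def _rising_crossing(below: np.ndarray, p: int, w: int, persist: int) -> int | None:
    """Last still index near ``p`` where the speed leaves a lasting rest
    (a foot starting to move). Searches [p - w, p + w] backward; if the
    foot is still at rest at the window end (the locating trough came
    early), the end of that rest run is recovered by walking forward."""
    n = len(below)
    lo, hi = max(1, p - w), min(n - 1, p + w)
    if below[hi]:
        i = hi
        while i < n - 1 and below[i + 1] and i - hi < 3 * w:
            i += 1
        # i is the last still frame of this run
        j = max(0, i - persist + 1)
        if np.mean(below[j : i + 1]) >= 0.8:
            return i
        return None
    for i in range(hi, lo - 1, -1):
        if not below[i] and below[i - 1]:
            j = max(0, i - persist)
            if np.mean(below[j:i]) >= 0.8:
                return i - 1
    return None


def _merge_peaks(peaks: np.ndarray, values: np.ndarray, min_gap: int) -> list[int]:
    """Greedy merge of extrema closer than min_gap frames, keeping the larger."""
    kept: list[int] = []
    for p in peaks:
        if kept and p - kept[-1] < min_gap:
            if values[p] > values[kept[-1]]:
                kept[-1] = int(p)
        else:
            kept.append(int(p))
    return kept


def _prune_short_phases(events: list[GaitEvent], min_phase_s: float = 0.15) -> list[GaitEvent]:
    """Remove IC/TO pairs that form implausibly short stance or swing phases.

    A noise-induced spurious IC/TO pair shows up as a stance or swing far
    shorter than the side's typical phase; such pairs are dropped (both
    events) relative to the per-side median duration. Real stances missing
    their contralateral IC are left alone — that hole belongs to the other
    side. Iterates to a fixed point.
    """
    for _ in range(5):
        drop: set[int] = set()
        for side in body25.SIDES:
            ev = sorted((e for e in events if e.side == side), key=lambda e: e.time)
            pairs = list(zip(ev, ev[1:]))
            stances = [(a, b) for a, b in pairs if a.kind == "IC" and b.kind == "TO"]
            swings = [(a, b) for a, b in pairs if a.kind == "TO" and b.kind == "IC"]
            for kind_pairs in (stances, swings):
                if len(kind_pairs) < 2:
                    continue
                durations = np.array([b.time - a.time for a, b in kind_pairs])
                floor = max(min_phase_s, 0.5 * float(np.median(durations)))
                for (a, b), dur in zip(kind_pairs, durations):
                    if dur < floor:
                        log.info("dropping spurious %s %s-%s pair [%.3f, %.3f]s",
                                 side, a.kind, b.kind, a.time, b.time)
                        drop.add(id(a))
                        drop.add(id(b))
        if not drop:
            break
        events = [e for e in events if id(e) not in drop]
        events = _repair_alternation(events)
    return events


def detect_events(
    traj: KeypointTrajectorySet,
    min_period: float | None = None,
    cfg: EventConfig | None = None,
) -> GaitEventSequence:
    """Detect IC and TO per side on a preprocessed trajectory set.

    Requires at least two complete strides per side. Candidates closer
    than ``min_period`` merge (larger extremum wins); events that cannot
    be paired into strict alternation are dropped with a log entry.
    """
    cfg = cfg or EventConfig()
    if min_period is not None:
        cfg = replace(cfg, min_period_s=min_period)
    direction = infer_direction(traj)
    fps = traj.frame_rate
    t = traj.times
    min_gap = max(1, int(round(cfg.min_period_s * fps)))
    hip_speed = _forward_speed(traj.x(body25.MID_HIP), fps)
    v_thresh = cfg.speed_threshold_frac * np.nanmedian(hip_speed)
    w = max(1, int(round(cfg.confirm_window_s * fps)))
    persist = max(2, int(round(cfg.persistence_s * fps)))
    w_motion = max(1, int(round(cfg.motion_window_s * fps)))
    v_motion = cfg.motion_factor * v_thresh
    edge = int(round(cfg.edge_exclusion_s * fps))

    events: list[GaitEvent] = []
    for side in body25.SIDES:
        d_ic = _relative_signal(traj, side, "ankle", direction)
        d_to = _relative_signal(traj, side, "big_toe", direction)
        heel_x = traj.x(body25.side_keypoint(side, "heel"))
        heel_x = np.where(np.isnan(heel_x), traj.x(body25.side_keypoint(side, "ankle")), heel_x)
        heel_speed = _forward_speed(heel_x, fps)
        toe_x = traj.x(body25.side_keypoint(side, "big_toe"))
        toe_speed = _forward_speed(toe_x, fps)
        # median-filter the speeds before thresholding so isolated noise
        # pops cannot break or fake a stillness crossing
        heel_below = medfilt(np.nan_to_num(heel_speed, nan=1e9), 5) <= v_thresh
        toe_below = medfilt(np.nan_to_num(toe_speed, nan=1e9), 5) <= v_thresh

        d_ic_smooth = _smooth_for_peaks(d_ic)
        ic_peaks, _ = find_peaks(d_ic_smooth, distance=min_gap)
        for p in _merge_peaks(ic_peaks, d_ic_smooth, min_gap):
            if p < edge or p > len(t) - 1 - edge:
                continue
            # confirm and time the event: the heel must come to a lasting
            # stop near the peak; the event is the stop-crossing instant
            idx = _falling_crossing(heel_below, p, w, persist)
            if idx is None:
                log.info("%s IC candidate at %.3fs not confirmed by heel stop", side, t[p])
                continue
            if idx < edge or idx > len(t) - 1 - edge:
                continue
            # gate: a true IC ends a swing, so the heel must have been
            # moving fast shortly before it stopped (rejects mid-stance
            # noise wiggles, whose heel never moved)
            before = np.nan_to_num(heel_speed[max(0, idx - w_motion) : idx], nan=0.0)
            if before.size == 0 or before.mean() < v_motion:
                continue
            events.append(GaitEvent(time=float(t[idx]), side=side, kind="IC",
                                    signal_value=float(d_ic[p])))

        d_to_smooth = _smooth_for_peaks(d_to)
        to_troughs, _ = find_peaks(-d_to_smooth, distance=min_gap)
        for p in _merge_peaks(to_troughs, -d_to_smooth, min_gap):
            if p < edge or p > len(t) - 1 - edge:
                continue
            # confirm and time the event: the toe must leave a lasting
            # rest near the trough; the event is the last still instant
            idx = _rising_crossing(toe_below, p, w, persist)
            if idx is None:
                log.info("%s TO candidate at %.3fs not confirmed by toe start", side, t[p])
                continue
            if idx < edge or idx > len(t) - 1 - edge:
                continue
            # gate: a true TO starts a swing, so the toe must accelerate
            # shortly after leaving rest
            after = np.nan_to_num(toe_speed[idx + 1 : idx + 1 + w_motion], nan=0.0)
            if after.size == 0 or after.mean() < v_motion:
                continue
            events.append(GaitEvent(time=float(t[idx]), side=side, kind="TO",
                                    signal_value=float(d_to[p])))

    pre_repair = [(e.time, e.side, e.kind) for e in sorted(events, key=lambda e: e.time)]
    events = _repair_alternation(events)
    events = _prune_short_phases(events)
    seq = GaitEventSequence(
        events=sorted(events, key=lambda e: e.time),
        direction_sign=direction,
        frame_rate=fps,
        time_range=(float(t[0]), float(t[-1])),
        meta={"pre_repair_events": pre_repair},
    )
    for side in body25.SIDES:
        if len(seq.ic_times(side)) < 2:
            raise InsufficientStridesError(
                f"fewer than 2 initial contacts detected on the {side} side"
            )
    seq.validate(strict=False)
    return seq


def _repair_alternation(events: list[GaitEvent],
                        duplicate_window_s: float = 0.4) -> list[GaitEvent]:
    """Per side, reduce the event list to strict IC/TO alternation.

    Two same-kind events in a row are either duplicates of one true event
    (close together: keep the stronger signal) or the footprint of a
    missed opposite event between them (about a stride apart). In the
    hole case the survivor is chosen so the remaining pairings stay
    phase-true: the *later* IC still opens a real stance with the next TO,
    and the *earlier* TO still closes a real stance with the previous IC;
    the bridged phase this leaves behind is filtered by duration
    downstream.
    """
    out: list[GaitEvent] = []
    for side in body25.SIDES:
        ev = sorted((e for e in events if e.side == side), key=lambda e: e.time)
        kept: list[GaitEvent] = []
        for e in ev:
            if kept and kept[-1].kind == e.kind:
                log.info("resolving duplicated %s %s at %.3fs", side, e.kind, e.time)
                if e.time - kept[-1].time <= duplicate_window_s:
                    if abs(e.signal_value) > abs(kept[-1].signal_value):
                        kept[-1] = e
                elif e.kind == "IC":
                    kept[-1] = e      # keep the later IC
                # for TO keep the earlier one (do nothing)
                continue
            kept.append(e)
        out.extend(kept)
    return out


def stance_swing_intervals(
    seq: GaitEventSequence, duration_filter: bool = True
) -> dict[str, dict[str, list[tuple[float, float]]]]:
    """Per-side stance ([IC, TO]) and swing ([TO, next IC]) intervals.

    Only complete intervals are returned; a trailing unmatched event is
    excluded. Within each stride, stance + swing equals the stride
    duration exactly. With ``duration_filter`` (default), intervals whose
    duration deviates from the side's median by more than 50% are
    excluded — in steady walking these are phases bridged across a
    detection hole, not real gait phases.
    """
    out: dict[str, dict[str, list[tuple[float, float]]]] = {}
    for side in body25.SIDES:
        ev = sorted(seq.side_events(side), key=lambda e: e.time)
        stance, swing = [], []
        for a, b in zip(ev, ev[1:]):
            if a.kind == "IC" and b.kind == "TO":
                stance.append((a.time, b.time))
            elif a.kind == "TO" and b.kind == "IC":
                swing.append((a.time, b.time))
        if duration_filter:
            stance = _filter_durations(stance, side, "stance")
            swing = _filter_durations(swing, side, "swing")
        out[side] = {"stance": stance, "swing": swing}
    return out


def _filter_durations(intervals: list[tuple[float, float]], side: str,
                      label: str) -> list[tuple[float, float]]:
    if len(intervals) < 3:
        return intervals
    durations = np.array([b - a for a, b in intervals])
    med = float(np.median(durations))
    keep = [iv for iv, d in zip(intervals, durations) if 0.5 * med <= d <= 1.5 * med]
    for iv, d in zip(intervals, durations):
        if not 0.5 * med <= d <= 1.5 * med:
            log.info("excluding %s %s of %.3fs (median %.3fs) as bridged/hole",
                     side, label, d, med)
    return keep


def match_events(
    detected: GaitEventSequence,
    truth_ic: dict[str, np.ndarray],
    truth_to: dict[str, np.ndarray],
    tolerance_s: float = 0.05,
    region: tuple[float, float] | None = None,
) -> dict[str, object]:
    """Score detected events against ground truth inside a time region.

    Each truth event must be matched by exactly one detected event of the
    same side and kind within ``tolerance_s``. Returns matched absolute
    errors plus the missed and spurious counts.
    """
    lo, hi = region if region is not None else detected.time_range
    errors: list[float] = []
    missed = spurious = 0
    for side in body25.SIDES:
        for kind, truth_times in (("IC", truth_ic[side]), ("TO", truth_to[side])):
            truth_in = [t for t in truth_times if lo <= t <= hi]
            det = [e.time for e in detected.side_events(side, kind)
                   if lo - tolerance_s <= e.time <= hi + tolerance_s]
            used = set()
            for tt in truth_in:
                if not det:
                    missed += 1
                    continue
                diffs = [abs(d - tt) if j not in used else np.inf for j, d in enumerate(det)]
                j = int(np.argmin(diffs))
                if diffs[j] <= tolerance_s:
                    used.add(j)
                    errors.append(diffs[j])
                else:
                    missed += 1
            spurious += sum(1 for j, d in enumerate(det)
                            if j not in used and lo <= d <= hi)
    return {
        "errors": np.array(errors),
        "mae": float(np.mean(errors)) if errors else float("nan"),
        "missed": missed,
        "spurious": spurious,
    }
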