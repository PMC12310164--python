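"""Keypoint trajectory conditioning before event detection.

The pipeline order is fixed and recorded in trajectory provenance:

1. :func:`fix_swaps` — left/right identity-switch correction from the heel
   coordinates (before interpolation, so swap excursions cannot poison the
   spline fits);
2. :func:`interpolate_gaps` — cubic-spline filling of short interior gaps;
3. :func:`lowpass_filter` — 6 Hz cut-off 4th-order Butterworth, applied
   forward-backward (zero phase);
4. :func:`to_meters` — pixel-to-meter conversion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from . import body25
from .errors import FilterError, GaitPoseError, UnitError
from .pose_io import CalibrationScale
from .trajectory import KeypointTrajectorySet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunables of the conditioning chain.

    ``max_interp_gap`` caps the interior gap length (frames) a cubic
    spline is trusted to fill; longer gaps stay masked. The swap-labeling
    penalties are expressed as multiples of the trial's own heel-track
    noise floor (``swap_change_scale`` per label change,
    ``swap_state_scale`` per frame spent in the swapped state) so the
    corrector adapts to the pixel noise of the pose estimator.
    """

    spline_order: int = 3
    interp_support: int = 10
    max_interp_gap: int = 10
    filter_order: int = 4
    cutoff_hz: float = 6.0
    zero_phase: bool = True
    swap_window: int = 5
    swap_change_scale: float = 5.0
    swap_state_scale: float = 0.7
    max_swap_run: int = 20

    def validate(self, frame_rate: float) -> None:
        if self.cutoff_hz >= frame_rate / 2:
            raise GaitPoseError("cutoff_hz must be below the Nyquist frequency")
        if self.filter_order < 2 or self.filter_order % 2:
            raise GaitPoseError("filter_order must be even and >= 2")
        if self.max_interp_gap < 1:
            raise GaitPoseError("max_interp_gap must be >= 1")
        if self.spline_order != 3:
            raise GaitPoseError("only cubic (order 3) spline interpolation is supported")


def _gap_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) half-open intervals."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(int), [0]))))
    return [(int(idx[i]), int(idx[i + 1])) for i in range(0, len(idx), 2)]


def _fill_gap_cubic(t: np.ndarray, xy: np.ndarray, valid: np.ndarray,
                    start: int, stop: int, support: int) -> np.ndarray | None:
    """Least-squares cubic fill of one interior gap.

    The cubic is fit to up to ``support`` valid frames on each side of the
    gap. A spline forced *through* every anchor rings badly when the
    anchors carry pixel noise; regression over a local support keeps the
    third-order model while averaging the noise away. On noise-free data
    (or data sampled from an exact cubic) the fit reproduces the signal to
    machine precision.
    """
    left = np.flatnonzero(valid[:start])[-support:]
    right = stop + np.flatnonzero(valid[stop:])[:support]
    if len(left) < 2 or len(right) < 2 or len(left) + len(right) < 4:
        return None
    idx = np.concatenate([left, right])
    t0 = t[start:stop].mean()
    scale = max(t[idx].max() - t[idx].min(), 1e-9)
    ts = (t[idx] - t0) / scale
    coeffs = np.polynomial.polynomial.polyfit(ts, xy[idx], deg=3)
    return np.polynomial.polynomial.polyval(
        (t[start:stop] - t0) / scale, coeffs
    ).T


def interpolate_gaps(
    traj: KeypointTrajectorySet, cfg: PreprocessConfig | None = None
) -> KeypointTrajectorySet:
    """Fill short interior missing runs per keypoint with a local cubic fit.

    Each gap is filled per coordinate by a third-order (cubic) fit to the
    neighboring valid frames (least squares over a local support window).
    Leading and trailing missing runs are never extrapolated; gaps longer
    than ``cfg.max_interp_gap`` stay masked (logged). Keypoints with fewer
    than 4 usable frames around a gap are left untouched with a warning.
    Filled cells are flagged in ``interpolated``.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate(traj.frame_rate)
    out = traj.copy()
    t = out.times
    for k in range(body25.N_KEYPOINTS):
        miss = out.missing[:, k]
        if not miss.any() or miss.all():
            continue
        valid = ~miss
        first, last = np.flatnonzero(valid)[[0, -1]]
        interior = miss.copy()
        interior[: first + 1] = False
        interior[last:] = False
        if not interior.any():
            continue
        if valid.sum() < 4:
            log.warning("keypoint %s has <4 valid frames; gaps left masked",
                        body25.KEYPOINT_NAMES[k])
            continue
        for start, stop in _gap_runs(interior):
            if stop - start > cfg.max_interp_gap:
                log.info("keypoint %s: gap of %d frames exceeds max_interp_gap; masked",
                         body25.KEYPOINT_NAMES[k], stop - start)
                continue
            filled = _fill_gap_cubic(t, out.positions[:, k, :], valid,
                                     start, stop, cfg.interp_support)
            if filled is None:
                log.warning("keypoint %s: too few anchors around gap %d-%d",
                            body25.KEYPOINT_NAMES[k], start, stop)
                continue
            out.positions[start:stop, k, :] = filled
            out.missing[start:stop, k] = False
            out.interpolated[start:stop, k] = True
    out.add_provenance("interpolate_gaps")
    return out


def _exchange_lower_limbs(traj: KeypointTrajectorySet, frame: int) -> None:
    for li, ri in body25.LOWER_LIMB_PAIRS:
        for arr in (traj.positions, traj.confidence, traj.missing, traj.interpolated):
            tmp = arr[frame, li].copy()
            arr[frame, li] = arr[frame, ri]
            arr[frame, ri] = tmp


def _predict_linear(t_fit: np.ndarray, y_fit: np.ndarray, t_new: float) -> np.ndarray:
    """Constant-velocity (degree-1 least squares) extrapolation of (x, y)."""
    if len(t_fit) == 1:
        return y_fit[0]
    tc = t_fit - t_fit.mean()
    slope = (tc[:, None] * (y_fit - y_fit.mean(axis=0))).sum(axis=0) / (tc**2).sum()
    return y_fit.mean(axis=0) + slope * (t_new - t_fit.mean())


def _swap_emissions(pos: np.ndarray, miss: np.ndarray) -> np.ndarray:
    """Per-frame continuity cost of every (state, prev, prevprev) combo.

    ``pos`` is (n, 2 heels, 2 xy), ``miss`` (n, 2). Returns (8, n) where
    combo index encodes the swap bits (b0 = frame i, b1 = i-1, b2 = i-2)
    as b0*4 + b1*2 + b2. The cost of a combo is the summed 2D
    constant-velocity prediction error of both assigned heel tracks
    (second difference; first difference when one anchor is missing).
    """
    n = len(pos)
    out = np.zeros((8, n))

    def term(s0: int, s1: int, s2: int) -> np.ndarray:
        p0, p1, p2 = pos[2:, s0], pos[1:-1, s1], pos[:-2, s2]
        m_second = miss[2:, s0] | miss[1:-1, s1] | miss[:-2, s2]
        m_first = miss[2:, s0] | miss[1:-1, s1]
        second = np.hypot(*(p0 - 2.0 * p1 + p2).T)
        first = np.hypot(*(p0 - p1).T)
        return np.where(~m_second, second, np.where(~m_first, first, 0.0))

    for b0 in (0, 1):
        for b1 in (0, 1):
            for b2 in (0, 1):
                combo = b0 * 4 + b1 * 2 + b2
                out[combo, 2:] = (term(b0, b1, b2)
                                  + term(1 - b0, 1 - b1, 1 - b2))
    return out


def _heel_noise_floor(emis: np.ndarray) -> float:
    """Per-heel continuity noise level: half the median identity-state
    emission (each emission sums both heels). The swing acceleration
    contributes negligibly next to pixel noise at 100 Hz, so this is a
    robust estimate of the per-frame prediction-error floor."""
    vals = emis[0, 2:]
    vals = vals[vals > 0]
    if len(vals) == 0:
        return 1.0
    return max(0.5, float(np.median(vals)) / 2.0)


def _optimal_swap_states(pos: np.ndarray, miss: np.ndarray,
                         cfg: PreprocessConfig) -> np.ndarray:
    """Minimum-cost swap labeling of all frames by dynamic programming.

    The objective is the total heel-track continuity cost plus two prior
    terms reflecting how pose-estimator identity switches actually behave:
    a boundary penalty per state change (switches are discrete events) and
    a per-frame penalty for the swapped state (switches are brief). The
    per-frame term is what makes the labeling identifiable at all: a
    *constant* wrong labeling of a long stretch has exactly the same
    continuity cost as the correct one (the two assigned tracks simply
    exchange names), so only the prior can rule it out.
    """
    n = len(pos)
    states = np.zeros(n, dtype=bool)
    if n < 3:
        return states
    emis = _swap_emissions(pos, miss)
    noise = _heel_noise_floor(emis)
    pen_change = cfg.swap_change_scale * noise
    pen_state = cfg.swap_state_scale * noise
    BIG = 1e18
    dp = np.full((2, 2), BIG)     # (state at i-1, state at i)
    bp = np.zeros((n, 2, 2), dtype=np.int8)
    for s0 in (0, 1):
        for s1 in (0, 1):
            dp[s0, s1] = (pen_state * (s0 + s1)
                          + (pen_change if s1 != s0 else 0.0)
                          + emis[s1 * 4 + s0 * 2 + s0, 1] if n > 1 else 0.0)
    for i in range(2, n):
        ndp = np.full((2, 2), BIG)
        for sp in (0, 1):
            for sc in (0, 1):
                base = (pen_change if sc != sp else 0.0) + pen_state * sc
                best, arg = BIG, 0
                for spp in (0, 1):
                    c = dp[spp, sp] + base + emis[sc * 4 + sp * 2 + spp, i]
                    if c < best:
                        best, arg = c, spp
                ndp[sp, sc] = best
                bp[i, sp, sc] = arg
        dp = ndp
    sp, sc = np.unravel_index(int(np.argmin(dp)), dp.shape)
    states[n - 1], states[n - 2] = bool(sc), bool(sp)
    for i in range(n - 1, 1, -1):
        states[i - 2] = bool(bp[i, int(states[i - 1]), int(states[i])])
    return states


def _labeling_cost(pos: np.ndarray, miss: np.ndarray, states: np.ndarray,
                   lo: int, hi: int) -> float:
    """Total second-difference discontinuity of the assigned heel tracks
    over frames [lo, hi) under a hypothesized state labeling."""
    n = len(pos)
    cost = 0.0
    for i in range(max(2, lo), min(n, hi)):
        for h in (0, 1):
            slots = [(1 - h if states[j] else h) for j in (i, i - 1, i - 2)]
            if miss[i, slots[0]] or miss[i - 1, slots[1]] or miss[i - 2, slots[2]]:
                continue
            pred = 2.0 * pos[i - 1, slots[1]] - pos[i - 2, slots[2]]
            cost += float(np.hypot(*(pos[i, slots[0]] - pred)))
    return cost


def fix_swaps(
    traj: KeypointTrajectorySet, cfg: PreprocessConfig | None = None
) -> tuple[KeypointTrajectorySet, list[int]]:
    """Detect and undo whole-leg left/right identity switches.

    Frame labels are modeled as a two-state sequence (identity / swapped)
    over the whole trial, scored from the heel coordinates: each frame and
    state contributes the constant-velocity prediction error of the two
    assigned heel tracks, a state change costs ``cfg.swap_margin_px``
    (switches are discrete events) and every swapped frame costs
    ``cfg.swap_state_penalty_px`` (switches are brief). The minimum-cost
    state path — found exactly by dynamic programming — cannot be captured
    by a locally ambiguous instant (heels crossing mid-swing, or a switch
    boundary hidden by missing data), which defeats greedy frame-by-frame
    trackers.

    As a final guard, a surviving swap stretch longer than
    ``cfg.max_swap_run`` frames is re-examined against the identity
    labeling and reverted if not clearly supported.

    All six left/right lower-limb keypoint pairs are exchanged jointly on
    frames labeled swapped. Returns the corrected set and the swapped
    frame indices.
    """
    cfg = cfg or PreprocessConfig()
    out = traj.copy()
    lh, rh = body25.INDEX["left_heel"], body25.INDEX["right_heel"]
    pos = out.positions[:, [lh, rh], :]
    miss = out.missing[:, [lh, rh]]

    states = _optimal_swap_states(pos, miss, cfg)

    # safety net: review implausibly long stretches (nearby runs merged)
    merged: list[tuple[int, int]] = []
    for a, b in _gap_runs(states):
        if merged and a - merged[-1][1] <= 3:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    for a, b in merged:
        if b - a < cfg.max_swap_run:
            continue
        pad = cfg.swap_window
        cand = states.copy()
        cand[a:b] = False
        noise = _heel_noise_floor(_swap_emissions(pos, miss))
        cost_keep = (_labeling_cost(pos, miss, states, a - pad, b + pad)
                     + cfg.swap_state_scale * noise * (b - a))
        cost_clear = _labeling_cost(pos, miss, cand, a - pad, b + pad)
        if cost_clear < cost_keep:
            log.warning("reverting %d-frame swap run at %d-%d "
                        "(suspected identity desync)", b - a, a, b - 1)
            states[a:b] = False

    swapped = [int(i) for i in np.flatnonzero(states)]
    for i in swapped:
        _exchange_lower_limbs(out, i)
    if swapped:
        log.info("corrected %d left/right swapped frames", len(swapped))
    out.add_provenance("fix_swaps")
    return out, swapped


def butterworth_response(freq_hz, cutoff_hz: float = 6.0, order: int = 4,
                         zero_phase: bool = True, fs: float | None = None):
    """Magnitude response of the (optionally forward-backward) Butterworth
    low-pass: |H| = (1 + (f/fc)^(2 order))^(-1/2), squared when zero-phase.

    With ``fs`` given, frequencies are prewarped (tan mapping of the
    bilinear transform) so the closed form matches the discrete filter
    exactly; without it, the analog prototype response is returned.
    """
    f = np.asarray(freq_hz, dtype=float)
    if fs is not None:
        ratio = np.tan(np.pi * f / fs) / math.tan(np.pi * cutoff_hz / fs)
    else:
        ratio = f / cutoff_hz
    mag = 1.0 / np.sqrt(1.0 + ratio ** (2 * order))
    return mag**2 if zero_phase else mag


def lowpass_filter(
    traj: KeypointTrajectorySet, cfg: PreprocessConfig | None = None
) -> KeypointTrajectorySet:
    """Low-pass filter every coordinate (4th-order Butterworth, 6 Hz).

    Applied forward-backward for zero phase lag. Each keypoint's maximal
    contiguous valid run is filtered independently; masked leading/trailing
    runs (and unfilled gaps) are excluded. Confidence and masks pass
    through unchanged.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate(traj.frame_rate)
    out = traj.copy()
    b, a = butter(cfg.filter_order, cfg.cutoff_hz, fs=traj.frame_rate)
    padlen = 3 * (max(len(a), len(b)) - 1)
    min_len = max(padlen + 1, 3 * cfg.filter_order)
    if out.n_frames < min_len:
        raise FilterError(
            f"trial has {out.n_frames} frames; the zero-phase filter needs "
            f"at least {min_len}"
        )
    for k in range(body25.N_KEYPOINTS):
        for start, stop in _gap_runs(~out.missing[:, k]):
            if stop - start < min_len:
                if stop - start > 0:
                    log.info("keypoint %s: segment of %d frames too short to filter",
                             body25.KEYPOINT_NAMES[k], stop - start)
                continue
            seg = out.positions[start:stop, k, :]
            if cfg.zero_phase:
                out.positions[start:stop, k, :] = filtfilt(b, a, seg, axis=0, padlen=padlen)
            else:
                from scipy.signal import lfilter

                out.positions[start:stop, k, :] = lfilter(b, a, seg, axis=0)
    out.add_provenance("lowpass_filter")
    return out


def to_meters(
    traj: KeypointTrajectorySet, scale: CalibrationScale
) -> KeypointTrajectorySet:
    """Convert pixel positions to meters using the calibration scale."""
    if traj.units == "m":
        raise UnitError("trajectory is already in meters")
    out = traj.copy()
    out.positions = out.positions / scale.pixels_per_meter
    out.units = "m"
    out.add_provenance("to_meters")
    return out


def preprocess_pipeline(
    traj: KeypointTrajectorySet,
    scale: CalibrationScale,
    cfg: PreprocessConfig | None = None,
) -> tuple[KeypointTrajectorySet, list[int]]:
    """Run the full conditioning chain in its fixed order."""
    cfg = cfg or PreprocessConfig()
    out, swap_frames = fix_swaps(traj, cfg)
    out = interpolate_gaps(out, cfg)
    out = lowpass_filter(out, cfg)
    out = to_meters(out, scale)
    return out, swap_frames
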