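"""Conditioning chain: swap correction, gap filling, filtering, units."""

import numpy as np
import pytest

from gaitpose import (
    DegradationModel,
    GaitProfile,
    PreprocessConfig,
    fix_swaps,
    interpolate_gaps,
    lowpass_filter,
    preprocess_pipeline,
    simulate_trial,
    to_meters,
)
from gaitpose.errors import FilterError, GaitPoseError, UnitError
from gaitpose.pose_io import CalibrationScale
from gaitpose.preprocess import butterworth_response
from gaitpose.trajectory import KeypointTrajectorySet
from gaitpose import body25


def make_traj(n=200, frame_rate=100.0):
    """All 25 keypoints at distinct constant positions."""
    positions = np.zeros((n, body25.N_KEYPOINTS, 2))
    positions[:, :, 0] = 100.0 + 10.0 * np.arange(body25.N_KEYPOINTS)
    positions[:, :, 1] = 300.0
    return KeypointTrajectorySet(
        times=np.arange(n) / frame_rate,
        positions=positions,
        confidence=np.ones((n, body25.N_KEYPOINTS)),
        missing=np.zeros((n, body25.N_KEYPOINTS), dtype=bool),
        frame_rate=frame_rate,
    )


class TestInterpolateGaps:
    def test_cubic_polynomial_recovered_exactly(self):
        traj = make_traj(n=21)
        k = body25.INDEX["left_ankle"]
        t = np.arange(21, dtype=float)
        traj.positions[:, k, 0] = t**3 - 2 * t
        traj.positions[:, k, 1] = 0.5 * t**3 + t**2
        truth = traj.positions[:, k, :].copy()
        traj.missing[7:10, k] = True
        traj.positions[7:10, k, :] = 0.0
        out = interpolate_gaps(traj)
        assert np.abs(out.positions[:, k, :] - truth).max() < 1e-9
        assert out.interpolated[7:10, k].all()
        assert not out.missing[7:10, k].any()

    def test_no_missing_is_identity(self):
        traj = make_traj()
        out = interpolate_gaps(traj)
        assert np.array_equal(out.positions, traj.positions)
        assert not out.interpolated.any()

    def test_sinusoid_gap_error_below_one_percent(self):
        traj = make_traj(n=300)
        k = body25.INDEX["right_knee"]
        amp = 50.0
        traj.positions[:, k, 0] = 200.0 + amp * np.sin(2 * np.pi * 1.0 * traj.times)
        truth = traj.positions[:, k, 0].copy()
        traj.missing[150:155, k] = True
        traj.positions[150:155, k, :] = 0.0
        out = interpolate_gaps(traj)
        assert np.abs(out.positions[150:155, k, 0] - truth[150:155]).max() < 0.01 * amp

    def test_leading_and_trailing_runs_stay_masked(self):
        traj = make_traj()
        k = body25.INDEX["nose"]
        traj.missing[:5, k] = True
        traj.missing[-5:, k] = True
        out = interpolate_gaps(traj)
        assert out.missing[:5, k].all()
        assert out.missing[-5:, k].all()

    def test_long_gap_stays_masked(self):
        traj = make_traj()
        k = body25.INDEX["neck"]
        traj.missing[50:80, k] = True
        out = interpolate_gaps(traj, PreprocessConfig(max_interp_gap=10))
        assert out.missing[50:80, k].all()


class TestFixSwaps:
    def test_clean_trial_untouched(self, clean_trial):
        traj, _ = clean_trial
        out, swapped = fix_swaps(traj)
        assert swapped == []
        assert np.array_equal(out.positions, traj.positions)

    def test_injected_swaps_corrected(self, hemi_profile):
        d = DegradationModel(pixel_noise_sd=1.0, swap_prob_per_frame=0.05, seed=1)
        traj, truth = simulate_trial(hemi_profile, degrade=d, n_strides=6)
        out, swapped = fix_swaps(traj)
        lh = body25.INDEX["left_heel"]
        rh = body25.INDEX["right_heel"]
        wrong = 0
        checked = 0
        for i in range(traj.n_frames):
            if out.missing[i, lh] or out.missing[i, rh]:
                continue
            d_own = np.hypot(*(out.positions[i, lh] - truth.true_positions[i, lh]))
            d_sw = np.hypot(*(out.positions[i, lh] - truth.true_positions[i, rh]))
            checked += 1
            wrong += d_sw + 1.0 < d_own
        assert checked > 0
        assert wrong / checked < 0.01

    def test_idempotent(self, hemi_profile):
        d = DegradationModel(pixel_noise_sd=1.0, swap_prob_per_frame=0.05, seed=2)
        traj, _ = simulate_trial(hemi_profile, degrade=d, n_strides=6)
        once, _ = fix_swaps(traj)
        twice, swapped2 = fix_swaps(once)
        assert swapped2 == []
        assert np.array_equal(once.positions, twice.positions)


class TestLowpassFilter:
    def test_constant_signal_unchanged(self):
        out = lowpass_filter(make_traj())
        assert np.abs(out.positions - make_traj().positions).max() < 1e-9

    @pytest.mark.parametrize("freq,check", [
        (1.0, lambda gain: gain > 0.99),
        (20.0, lambda gain: gain < 0.01),
    ])
    def test_gain_matches_forward_backward_closed_form(self, freq, check):
        traj = make_traj(n=1000)
        k = body25.INDEX["left_wrist"]
        traj.positions[:, k, 0] = 100.0 * np.sin(2 * np.pi * freq * traj.times)
        out = lowpass_filter(traj)
        mid = slice(300, 700)
        basis = np.column_stack([
            np.sin(2 * np.pi * freq * traj.times[mid]),
            np.cos(2 * np.pi * freq * traj.times[mid]),
        ])
        coef, *_ = np.linalg.lstsq(basis, out.positions[mid, k, 0], rcond=None)
        gain = np.hypot(*coef) / 100.0
        phase = np.arctan2(coef[1], coef[0])
        expected = butterworth_response(freq, fs=100.0)
        assert check(gain)
        assert gain == pytest.approx(expected, rel=0.01)
        if freq == 1.0:
            assert abs(phase) < 1e-3  # zero-phase application

    def test_preserves_length_and_time_grid(self, noisy_trial):
        traj, _ = noisy_trial
        filled = interpolate_gaps(fix_swaps(traj)[0])
        out = lowpass_filter(filled)
        assert out.n_frames == traj.n_frames
        assert np.array_equal(out.times, traj.times)

    def test_short_trial_rejected(self):
        with pytest.raises(FilterError):
            lowpass_filter(make_traj(n=10))

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(GaitPoseError):
            lowpass_filter(make_traj(), PreprocessConfig(cutoff_hz=60.0))


class TestToMeters:
    def test_division_by_scale(self):
        traj = make_traj()
        out = to_meters(traj, CalibrationScale(pixels_per_meter=500.0))
        k = body25.INDEX["nose"]
        assert out.positions[0, k, 0] == pytest.approx(traj.positions[0, k, 0] / 500.0)
        assert out.units == "m"

    def test_round_trip_exact(self):
        traj = make_traj()
        out = to_meters(traj, CalibrationScale(pixels_per_meter=70.0))
        back = out.positions * 70.0
        assert np.abs(back - traj.positions).max() < 1e-12

    def test_double_conversion_rejected(self):
        out = to_meters(make_traj(), CalibrationScale(pixels_per_meter=70.0))
        with pytest.raises(UnitError):
            to_meters(out, CalibrationScale(pixels_per_meter=70.0))


class TestPipelineOrder:
    def test_provenance_records_fixed_stage_order(self, clean_trial):
        traj, _ = clean_trial
        scale = CalibrationScale(pixels_per_meter=traj.meta["pixels_per_meter"])
        out, _ = preprocess_pipeline(traj, scale)
        assert out.meta["provenance"][-4:] == [
            "fix_swaps", "interpolate_gaps", "lowpass_filter", "to_meters",
        ]

    def test_noise_free_chain_barely_moves_positions(self, clean_trial):
        """Sub-6 Hz content (the trunk) passes the chain essentially
        unchanged; foot trajectories lose only their sharp stance-swing
        corners to the 6 Hz filter."""
        traj, truth = clean_trial
        scale = CalibrationScale(pixels_per_meter=traj.meta["pixels_per_meter"])
        out, _ = preprocess_pipeline(traj, scale)
        err_m = np.abs(out.positions * scale.pixels_per_meter
                       - truth.true_positions) / scale.pixels_per_meter
        interior = slice(40, -40)  # zero-phase filter start-up transients
        assert err_m[interior, body25.MID_HIP, :].max() < 1e-3
        assert err_m[interior].max() < 0.015
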