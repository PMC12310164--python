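"""Simulator: profile invariants, trial kinematics, cohort structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitpose import (
    CohortSpec,
    DegradationModel,
    GaitProfile,
    ResponderModel,
    simulate_cohort,
    simulate_cohort_outcomes,
    simulate_trial,
)
from gaitpose.errors import GenerationError, ProfileValidationError
from gaitpose.gait_events import GaitEvent, GaitEventSequence
from gaitpose import body25


class TestGaitProfile:
    def test_from_speed_cadence_satisfies_all_invariants(self):
        p = GaitProfile.from_speed_cadence(0.75, 95.0, 0.55, 0.64, 0.70)
        assert p.stride_time == pytest.approx(120.0 / 95.0)
        assert p.gait_speed * p.stride_time == pytest.approx(p.stride_length)

    @given(
        speed=st.floats(0.3, 1.4),
        cadence=st.floats(60.0, 130.0),
        frac=st.floats(0.40, 0.60),
        duty_p=st.floats(0.58, 0.72),
        duty_np=st.floats(0.58, 0.72),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_derived_profiles_always_consistent(self, speed, cadence, frac,
                                                duty_p, duty_np):
        p = GaitProfile.from_speed_cadence(speed, cadence, frac, duty_p, duty_np)
        stride_p = p.stance_time_paretic + p.swing_time_paretic
        stride_np = p.stance_time_nonparetic + p.swing_time_nonparetic
        assert abs(stride_p - stride_np) < 1e-9
        assert abs(p.cadence - 120.0 / stride_p) < 1e-6
        assert abs(p.gait_speed * stride_p - p.stride_length) < 1e-6

    @pytest.mark.parametrize("field,value", [
        ("gait_speed", -0.5),
        ("cadence", 0.0),
        ("stance_time_paretic", -1.0),
    ])
    def test_invalid_profiles_name_the_violated_invariant(self, field, value):
        kwargs = dict(
            gait_speed=0.75, cadence=96.0,
            step_length_paretic=0.5, step_length_nonparetic=0.4375,
            stance_time_paretic=0.8, stance_time_nonparetic=0.85,
            swing_time_paretic=0.45, swing_time_nonparetic=0.40,
        )
        kwargs[field] = value
        with pytest.raises(ProfileValidationError, match=field):
            GaitProfile(**kwargs)

    def test_inconsistent_cadence_rejected(self):
        with pytest.raises(ProfileValidationError, match="cadence"):
            GaitProfile(
                gait_speed=0.75, cadence=80.0,
                step_length_paretic=0.5, step_length_nonparetic=0.4375,
                stance_time_paretic=0.8, stance_time_nonparetic=0.85,
                swing_time_paretic=0.45, swing_time_nonparetic=0.40,
            )


class TestSimulateTrial:
    def test_midhip_advances_at_gait_speed(self):
        # symmetric 1 m/s walker: displacement = speed x elapsed time
        p = GaitProfile.from_speed_cadence(1.0, 120.0)
        traj, _ = simulate_trial(p, degrade=None, n_strides=6)
        hip = traj.positions[:, body25.MID_HIP, 0]
        ppm = traj.meta["pixels_per_meter"]
        disp_m = (hip[-1] - hip[0]) / ppm
        duration = traj.times[-1] - traj.times[0]
        assert disp_m == pytest.approx(1.0 * duration, abs=1e-6)

    def test_ground_truth_cadence_matches_stride_time(self):
        p = GaitProfile.from_speed_cadence(1.0, 120.0, 0.5, 0.7, 0.7)
        assert p.stance_time_paretic == pytest.approx(0.7)
        assert p.swing_time_paretic == pytest.approx(0.3)
        _, truth = simulate_trial(p, degrade=None, n_strides=4)
        assert truth.profile.cadence == pytest.approx(120.0)

    def test_fixed_seed_is_bit_identical(self, hemi_profile):
        d = DegradationModel(missing_prob_per_keypoint_frame=0.05, seed=42)
        a, _ = simulate_trial(hemi_profile, degrade=d)
        b, _ = simulate_trial(hemi_profile, degrade=d)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.confidence, b.confidence)
        assert np.array_equal(a.missing, b.missing)

    def test_ground_truth_events_pass_strict_validation(self):
        # asymmetric hemiparetic timing: long paretic stance, unequal steps
        p = GaitProfile(
            gait_speed=0.6, cadence=96.0,
            step_length_paretic=0.30, step_length_nonparetic=0.45,
            stance_time_paretic=0.85, stance_time_nonparetic=0.70,
            swing_time_paretic=0.40, swing_time_nonparetic=0.55,
        )
        traj, truth = simulate_trial(p, degrade=None, n_strides=5)
        events = [GaitEvent(t, side, kind)
                  for side in body25.SIDES
                  for kind, times in (("IC", truth.ic_times[side]),
                                      ("TO", truth.to_times[side]))
                  for t in times]
        seq = GaitEventSequence(events=sorted(events, key=lambda e: e.time),
                                direction_sign=1, frame_rate=traj.frame_rate,
                                time_range=(traj.times[0], traj.times[-1]))
        assert seq.validate(strict=True) == 0

    def test_stance_heel_is_stationary_and_swing_monotonic(self, clean_trial):
        traj, truth = clean_trial
        heel = truth.true_positions[:, body25.INDEX["left_heel"], 0]
        t = np.asarray([traj.times]).ravel()
        ics = truth.ic_times["left"]
        tos = truth.to_times["left"]
        ic = ics[2]
        to = tos[tos > ic][0]
        stance = (t >= ic) & (t <= to)
        assert np.ptp(heel[stance]) < 1e-9
        nxt = ics[ics > to][0]
        swing = (t > to) & (t < nxt)
        assert np.all(np.diff(heel[swing]) >= -1e-12)

    def test_positions_inside_image_bounds(self, noisy_trial):
        traj, truth = noisy_trial
        assert truth.true_positions[:, :, 0].min() >= 0
        assert truth.true_positions[:, :, 0].max() <= 720
        assert truth.true_positions[:, :, 1].max() <= 520

    def test_too_few_strides_rejected(self, hemi_profile):
        with pytest.raises(GenerationError):
            simulate_trial(hemi_profile, n_strides=2)

    def test_trial_too_wide_for_frame_rejected(self):
        p = GaitProfile.from_speed_cadence(1.4, 100.0)
        with pytest.raises(GenerationError, match="width"):
            simulate_trial(p, degrade=None, n_strides=10)


class TestCohort:
    def test_zero_effect_zero_noise_cohort_flags_speed_ties(self):
        spec = CohortSpec(
            n_participants=4, responder=None,
            within_subject_sd={k: 0.0 for k in
                               ("gait_speed", "cadence", "paretic_step_fraction",
                                "stance_duty_paretic", "stance_duty_nonparetic")},
            seed=1,
        )
        df = simulate_cohort_outcomes(spec)
        assert df["speed_tie"].all()
        speeds = df.pivot_table(index="participant", columns="condition",
                                values="gait_speed")
        assert np.allclose(speeds.std(axis=1), 0.0)

    def test_designated_best_has_highest_true_speed(self):
        df = simulate_cohort_outcomes(CohortSpec(n_participants=16, seed=5))
        for pid, grp in df.groupby("participant"):
            best = grp.set_index("condition")["gait_speed"].idxmax()
            assert best == grp["designated_best"].iloc[0]

    def test_full_cohort_manifest_is_reproducible(self):
        spec = CohortSpec(n_participants=32, seed=11)
        records, manifest = simulate_cohort(spec)
        assert len(records) == 32 * 5
        assert len(manifest) == 160
        _, manifest2 = simulate_cohort(spec)
        assert manifest.equals(manifest2)

    def test_condition_order_randomized_with_no_afo_first(self):
        df = simulate_cohort_outcomes(CohortSpec(n_participants=10, seed=2))
        first = df[df["condition_order"] == 1]["condition"]
        assert (first == "no_afo").all()
        spring_orders = df[df["condition"] != "no_afo"].pivot_table(
            index="participant", columns="condition", values="condition_order")
        assert spring_orders.nunique().gt(1).any()
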