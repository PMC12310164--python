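import logging

import pytest

from gaitpose import (
    DegradationModel,
    GaitProfile,
    detect_events,
    preprocess_pipeline,
    simulate_trial,
)
from gaitpose.pose_io import CalibrationScale

logging.disable(logging.INFO)

#: hemiparetic reference profile used throughout: slow asymmetric gait with
#: longer paretic step and shorter paretic stance, as after stroke
HEMI = dict(gait_speed=0.75, cadence=95.0, paretic_step_fraction=0.55,
            stance_duty_paretic=0.64, stance_duty_nonparetic=0.70)


@pytest.fixture(scope="session")
def hemi_profile():
    return GaitProfile.from_speed_cadence(**HEMI)


@pytest.fixture(scope="session")
def clean_trial(hemi_profile):
    return simulate_trial(hemi_profile, degrade=None, n_strides=6)


@pytest.fixture(scope="session")
def noisy_trial(hemi_profile):
    return simulate_trial(hemi_profile, degrade=DegradationModel(seed=0), n_strides=6)


def run_pipeline(traj):
    """Preprocess a simulated trial and detect its events."""
    scale = CalibrationScale(pixels_per_meter=traj.meta["pixels_per_meter"])
    traj_m, swap_frames = preprocess_pipeline(traj, scale)
    seq = detect_events(traj_m)
    return traj_m, seq, swap_frames


@pytest.fixture(scope="session")
def clean_processed(clean_trial):
    traj, truth = clean_trial
    traj_m, seq, _ = run_pipeline(traj)
    return traj_m, seq, truth
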