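"""Shared fixtures: one small synthetic stimulus set and its model suite."""

from __future__ import annotations

import numpy as np
import pytest

from dynrsa import (
    generate_gaze,
    generate_kinematics,
    render_frames,
)
from dynrsa.pipeline import build_model_suite

# scaled-down settings used across the suite: 5 stimuli, 8 markers, 2 s at
# 50 Hz, 4 Hz cutoff (dynamic enough for 1.5-s segments), 32x30 frames
SMALL = dict(n_stimuli=5, n_markers=8, duration_s=2.0, fs=50.0, cutoff_hz=4.0)


@pytest.fixture(scope="session")
def traj_small():
    return generate_kinematics(seed=7, **SMALL)


@pytest.fixture(scope="session")
def frames_small(traj_small):
    return render_frames(traj_small, height=32, width=30, marker_sigma=2.0)


@pytest.fixture(scope="session")
def gaze_small():
    return generate_gaze(n_stimuli=5, duration_s=2.0, fs=50.0, cutoff_hz=4.0, seed=8)


@pytest.fixture(scope="session")
def kinematic_models(traj_small, gaze_small):
    """Cheap models that need no frame rendering."""
    return build_model_suite(
        traj_small, None, gaze_small,
        names=["posture_vd", "posture_vi", "motion_vd", "motion_vi", "accel_vd", "gaze"],
    )


@pytest.fixture(scope="session")
def full_suite(traj_small, frames_small, gaze_small):
    """The 8-model validation suite (no acceleration)."""
    return build_model_suite(
        traj_small, frames_small, gaze_small, sigma=2.0,
        names=["pixelwise", "flow_magnitude", "flow_direction",
               "posture_vd", "posture_vi", "motion_vd", "motion_vi", "gaze"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
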