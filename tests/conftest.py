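import numpy as np
import pytest

from swvm import (
    AcquisitionModel,
    Calibration,
    Frame,
    Phantom,
    Pose,
    RigidTransform,
    Sweep,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def identity_calibration():
    return Calibration.identity()


@pytest.fixture
def uniform_phantom():
    return Phantom(background_swv=2.5)


@pytest.fixture
def clean_acquisition():
    """Noise-free, jitter-free, dropout-free scanner at default rates."""
    return AcquisitionModel(
        sweep_speed=5.0,
        noise_sd=0.0,
        dropout_prob=0.0,
        tracking_jitter_rms=0.0,
        frame_shape=(8, 8),
        spacing=(2.0, 2.0),
    )


def make_static_sweep(frames_pixels, spacing=(1.0, 1.0), t_step=1.0):
    """Sweep with an identity pose track covering the frame times."""
    frames = [
        Frame(i * t_step, px, spacing, modality="swe")
        for i, px in enumerate(frames_pixels)
    ]
    t_end = max(len(frames_pixels) - 1, 1) * t_step
    poses = [
        Pose(0.0, RigidTransform.identity()),
        Pose(t_end + 1.0, RigidTransform.identity()),
    ]
    return Sweep(frames=frames, poses=poses)


def make_moving_sweep(frames_pixels, step_mm, spacing=(1.0, 1.0)):
    """Sweep translating by step_mm along +z between consecutive frames."""
    frames = [
        Frame(float(i), px, spacing, modality="swe")
        for i, px in enumerate(frames_pixels)
    ]
    n = len(frames_pixels)
    poses = [
        Pose(
            float(i),
            RigidTransform(
                RigidTransform.identity().rotation,
                np.array([0.0, 0.0, i * step_mm]),
            ),
        )
        for i in range(max(n, 2))
    ]
    return Sweep(frames=frames, poses=poses)
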