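import numpy as np
import pytest

from playmotion import (
    RunConfig,
    TrajectoryScript,
    constant_velocity_script,
    render_sequence,
)
from playmotion.pipeline import velocity_recovery_experiment


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def moving_square():
    """24x24 square marching +2 px/frame in x at 2000 mm, 3 s, noiseless."""
    script = TrajectoryScript(
        object_id="sq",
        width_px=24,
        height_px=24,
        path=[(0.0, 50.0, 240.0, 2000.0), (3000.0, 230.0, 240.0, 2000.0)],
    )
    frames, truth = render_sequence(script, 3.0, noise_sd=0.0, seed=0)
    return script, frames, truth


@pytest.fixture(scope="session")
def stationary_scene():
    script = TrajectoryScript(
        object_id="still",
        width_px=40,
        height_px=40,
        path=[(0.0, 320.0, 240.0, 2000.0), (2000.0, 320.0, 240.0, 2000.0)],
    )
    frames, truth = render_sequence(script, 2.0, noise_sd=0.0, seed=0)
    return frames, truth


@pytest.fixture(scope="session")
def velocity_recovery():
    """Constant-velocity fixtures spanning the per-plane working ranges."""
    return velocity_recovery_experiment(
        velocities_by_plane={
            "x": [0.5, 2.0, 3.5],
            "y": [0.3, 1.4, 2.5],
            "z": [0.5, 2.0, 3.5],
        },
        duration_s=8.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
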