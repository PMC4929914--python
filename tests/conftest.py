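import numpy as np
import pytest

from flapsim.config import default_calliope_config
from flapsim.geometry import reconstruct_wing_series, refine_in_time
from flapsim.kinematics import default_kinematic_program, generate_markers


@pytest.fixture(scope="session")
def config():
    return default_calliope_config()


@pytest.fixture(scope="session")
def clean_markers(config):
    """Noiseless default-program markers over 3 cycles."""
    program = default_kinematic_program(
        Phi_deg=config.Phi, n_frames_per_cycle=22, n_cycles=3, noise_sd=0.0)
    return generate_markers(config, program, seed=0)


@pytest.fixture(scope="session")
def left_wing_mesh(clean_markers):
    """Reconstructed + temporally refined left wing (moderate resolution)."""
    mesh = reconstruct_wing_series(clean_markers, "left", target_elements=700)
    return refine_in_time(mesh, 4)
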