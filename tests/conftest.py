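import numpy as np
import pytest
from hypothesis import settings

import porewave as pw

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def preset_rates() -> pw.RingKineticRates:
    """Measured kinetic preset: k_open 1.8, initiation 0.2, k12 13, k23 15."""
    return pw.measured_rates()


@pytest.fixture(scope="session")
def quiet_conv() -> pw.HeightConventions:
    """Noise-free height conventions."""
    return pw.HeightConventions(noise_sigma=0.0)


@pytest.fixture(scope="session")
def preset_trajectories(preset_rates) -> list[pw.RingTrajectory]:
    """Shared 300-ring, 30 s preset ensemble (seeded)."""
    return pw.simulate_ensemble(preset_rates, 300, 30.0, seed=2024)


@pytest.fixture(scope="session")
def preset_state_matrices(preset_trajectories) -> list[pw.StateMatrix]:
    """Ground-truth 200 ms quantization of the shared ensemble."""
    return [
        pw.trajectory_to_state_matrix(t, 150, 0.2) for t in preset_trajectories
    ]


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
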