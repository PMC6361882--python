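import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def geometry():
    from pgoe import CameraGeometry

    return CameraGeometry.small_phantom()


@pytest.fixture(scope="session")
def energy_model():
    from pgoe import EnergyResolutionModel

    return EnergyResolutionModel()


@pytest.fixture(scope="session")
def o16_exact(geometry, energy_model):
    """Small blur-free 16O dataset with true origins (exact-geometry oracle)."""
    import numpy as np

    from pgoe.simulate import EmissionModel, events_from_origins

    rng = np.random.default_rng(7)
    model = EmissionModel.preset("16O")
    origins = model.sample_origin(rng, 1500)
    data, valid, true_pos = events_from_origins(
        origins, model.line_energy, geometry, energy_model, rng,
        blur=False, quantize=False,
    )
    return data, origins[valid], true_pos


@pytest.fixture(scope="session")
def o16_blurred_small(geometry, energy_model):
    """Small 16O dataset with full detector degradation (study blur)."""
    from pgoe.simulate import simulate_dataset

    data, truth, manifest = simulate_dataset("16O", n_events=6000, seed=11)
    return data, truth, manifest
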