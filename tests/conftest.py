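import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def phase_params():
    from cellvox.params import PhaseParams
    return PhaseParams()


@pytest.fixture
def volume_params():
    from cellvox.params import VolumeParams
    return VolumeParams()


@pytest.fixture
def mech_params():
    from cellvox.params import MechanicsParams
    return MechanicsParams()


def make_population(positions, V=None, phase=2, volume_params=None):
    """Cells at given positions with standard quiescent composition."""
    from cellvox.params import VolumeParams
    from cellvox.population import CellPopulation

    vp = volume_params or VolumeParams()
    positions = np.atleast_2d(np.asarray(positions, float))
    n = positions.shape[0]
    V = np.full(n, vp.V_std) if V is None else np.asarray(V, float)
    scale = V / vp.V_std
    return CellPopulation(
        positions, np.full(n, phase), V,
        vp.V_F_std * scale,
        vp.V_NS_target[2] * scale,
        vp.V_CS_target[2] * scale,
    )


@pytest.fixture
def pop_factory():
    return make_population
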