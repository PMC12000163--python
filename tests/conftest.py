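import numpy as np
import pytest

from syrsed import BufferSpec, ModelConstants, ParticleSpec, SyringeSpec


@pytest.fixture(scope="session")
def ps_bead() -> ParticleSpec:
    """5 µm polystyrene bead."""
    return ParticleSpec(radius=5e-6, density=1070.0)


@pytest.fixture(scope="session")
def water() -> BufferSpec:
    """Water at room temperature (also a good PBS stand-in)."""
    return BufferSpec(density=997.0, viscosity=1e-3)


@pytest.fixture(scope="session")
def pbs() -> BufferSpec:
    return BufferSpec(density=1000.0, viscosity=1e-3)


@pytest.fixture(scope="session")
def syringe_1ml() -> SyringeSpec:
    """1 ml syringe barrel (R_S = 2.3 mm) with a 0.5 mm concentric outlet."""
    return SyringeSpec(
        barrel_radius=2.3e-3, barrel_length=40e-3,
        outlet_radius=0.5e-3, outlet_length=5e-3,
    )


@pytest.fixture(scope="session")
def constants() -> ModelConstants:
    return ModelConstants()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
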