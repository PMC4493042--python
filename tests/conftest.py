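import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sprkin as sk

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")

# fitted coefficients of the HBsAg/HBsAb reference run (16 ng/mL)
REF_ASSOC = sk.AssociationParams(a=3358.232, b=0.01188)
REF_DISSOC = sk.DissociationParams(a=3358.73684, m=0.00073)
REF_CL = 16e-9  # g/mL


@pytest.fixture
def ref_assoc() -> sk.AssociationParams:
    return REF_ASSOC


@pytest.fixture
def ref_dissoc() -> sk.DissociationParams:
    return REF_DISSOC


@pytest.fixture
def ref_cl() -> float:
    return REF_CL


@pytest.fixture
def assoc_grid() -> np.ndarray:
    """1 Hz time grid spanning the 251 s association phase."""
    return np.arange(252.0)


@pytest.fixture
def noiseless_assoc(ref_assoc, assoc_grid):
    """Noiseless association phase at the reference coefficients."""
    return assoc_grid, sk.association_response(ref_assoc, assoc_grid)


@pytest.fixture
def noiseless_dissoc(ref_dissoc):
    """Noiseless 38 s dissociation phase at the reference coefficients."""
    t = np.arange(39.0)
    return t, sk.dissociation_response(ref_dissoc, t)


@pytest.fixture
def noisy_assoc(noiseless_assoc):
    """Association phase with 20 RU Gaussian noise (seeded)."""
    t, y = noiseless_assoc
    rng = np.random.default_rng(42)
    return t, y + rng.normal(0.0, 20.0, len(t))


@pytest.fixture
def reference_sensorgram():
    """Noiseless three-phase synthetic sensorgram at the reference conditions."""
    return sk.generate(sk.GeneratorSpec(noise_sd=0.0))
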