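import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from remipkpd import (DEFAULT_VARIABILITY, REMIMAZOLAM_PD, REMIMAZOLAM_PK,
                      VariabilitySpec, default_design, generate_dataset)

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pk():
    return REMIMAZOLAM_PK


@pytest.fixture(scope="session")
def pd_params():
    return REMIMAZOLAM_PD


@pytest.fixture(scope="session")
def variability():
    return DEFAULT_VARIABILITY


@pytest.fixture(scope="session")
def tiny_noise():
    """Near-noiseless residual spec (exact-zero SDs would make the Gaussian
    likelihood singular)."""
    return VariabilitySpec(omega={}, sigma_prop_parent=1e-4,
                           sigma_prop_metab=1e-4, sigma_add_metab=1e-4,
                           sigma_prop_bis=1e-4)


@pytest.fixture(scope="session")
def study_dataset(pk, pd_params, variability):
    """One replicate of the full two-study design at the published truth."""
    table, truth = generate_dataset(default_design(), pk, pd_params,
                                    variability, seed=2024)
    return table, truth


@pytest.fixture(scope="session")
def grid_0_300():
    return np.linspace(0.0, 300.0, 601)
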