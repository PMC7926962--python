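import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import phmd
from phmd.cphmd import fit_model_compound


@pytest.fixture(scope="session")
def double_well():
    return phmd.make_double_well(5.0, well_separation=2.0)


@pytest.fixture(scope="session")
def mini_fab():
    return phmd.make_mini_fab(n_residues_per_loop=5, seed=0)


@pytest.fixture(scope="session")
def compound():
    return phmd.make_titratable_compound(6.0)


@pytest.fixture(scope="session")
def compound_fit(compound):
    # shared across tests: the model-compound fit is deterministic for a seed
    return fit_model_compound(compound, seed=3)


@pytest.fixture(scope="session")
def fab_complex():
    return phmd.make_fab_fixture(phmd.FabLayout(include_antigen=True))


@pytest.fixture(scope="session")
def fab_only():
    return phmd.make_fab_fixture(phmd.FabLayout(include_antigen=False))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
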