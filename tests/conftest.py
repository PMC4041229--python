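import pytest
from hypothesis import HealthCheck, settings

import solvtol as st

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def solvents():
    return st.read_solvents_toml()


@pytest.fixture(scope="session")
def ct(solvents):
    return solvents["CT"]


@pytest.fixture
def simple_solvent():
    """A solvent with round-number constants for hand calculations."""
    return st.SolventSpec(
        name="X", molar_mass=100.0, liquid_density=1.0, log_pow=2.0,
        aqueous_solubility=1e6, henry_points=((30.0, 0.2),),
    )


@pytest.fixture(scope="session")
def default_assay():
    """One seeded default-panel assay (8 species x 4 solvents) plus truth."""
    od, truth = st.simulate_assay(st.default_true_params(), st.SimConfig(seed=20))
    return od, truth


@pytest.fixture(scope="session")
def default_report(default_assay):
    od, _ = default_assay
    return st.run_report(st.od_frame_to_series(od))
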