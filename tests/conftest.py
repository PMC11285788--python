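import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from crispr_spread import (IntegrationSettings, ModelParameters,
                           PopulationState, fig1_parameters)

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def fig1_params() -> ModelParameters:
    """Illustrative-scenario parameters (c_R=0.05, c_I=0, mu=A=0)."""
    return fig1_parameters()


@pytest.fixture
def costfree_params() -> ModelParameters:
    """Cost- and mutation-free limit in which the reduced equation is exact."""
    return fig1_parameters(c_R=0.0)


@pytest.fixture
def fig1_state() -> PopulationState:
    """N(0)=1e6, V(0)=1e4, 50% CRISPR+; protected fractions 0.30 (CRISPR+,
    split evenly between R+ and C+) and 0.15 (CRISPR-), so f_delta(0)=+0.15."""
    return PopulationState(S_minus=4.25e5, R_minus=0.75e5,
                           S_plus=3.5e5, R_plus=0.75e5, C_plus=0.75e5,
                           V=1e4)


@pytest.fixture
def default_settings() -> IntegrationSettings:
    return IntegrationSettings()


def mix_state(crispr_freq: float, protected_plus: float, resistant_minus: float,
              immune_share: float, N0: float = 1e6, V0: float = 1e4
              ) -> PopulationState:
    """State from subpopulation-level design values (test helper)."""
    plus, minus = N0 * crispr_freq, N0 * (1 - crispr_freq)
    return PopulationState(
        S_minus=minus * (1 - resistant_minus),
        R_minus=minus * resistant_minus,
        S_plus=plus * (1 - protected_plus),
        R_plus=plus * protected_plus * (1 - immune_share),
        C_plus=plus * protected_plus * immune_share,
        V=V0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240619)
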