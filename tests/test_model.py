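"""Core model: right-hand sides, f_delta, frequencies, selection coefficient."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from crispr_spread import (InvalidModelInput, ModelParameters, PopulationState,
                           UndefinedStatisticError, crispr_frequency,
                           derivatives, derived_stats, f_delta,
                           fig1_parameters, reduced_rhs, selection_coefficient)

densities = st.floats(min_value=0.0, max_value=1e9, allow_nan=False)
positive_densities = st.floats(min_value=1.0, max_value=1e9, allow_nan=False)


def states(min_value=0.0):
    base = st.floats(min_value=min_value, max_value=1e9, allow_nan=False)
    return st.builds(PopulationState, S_minus=base, R_minus=base, S_plus=base,
                     R_plus=base, C_plus=base, V=densities)


class TestValidation:
    def test_parameter_invariants_enforced(self):
        with pytest.raises(InvalidModelInput):
            ModelParameters(r=-1, K=1e9)
        with pytest.raises(InvalidModelInput):
            ModelParameters(r=0.5, K=0)
        with pytest.raises(InvalidModelInput):
            ModelParameters(r=0.5, K=1e9, mu=1.5)
        with pytest.raises(InvalidModelInput):
            ModelParameters(r=0.5, K=1e9, c_R=1.0)

    def test_negative_density_rejected(self):
        with pytest.raises(InvalidModelInput):
            PopulationState(-1, 0, 0, 0, 0, 0)

    def test_parameters_roundtrip_dict(self):
        p = fig1_parameters(mu=1e-7)
        assert ModelParameters.from_dict(p.to_dict()) == p


class TestDerivatives:
    def test_null_state_is_fixed_point(self, fig1_params):
        state = PopulationState(0, 0, 0, 0, 0, 0)
        assert np.all(derivatives(state, fig1_params) == 0)

    def test_pure_sensitive_logistic_growth(self):
        # single compartment, no phage: dS-/dt = r(1 - N/K) S-
        p = ModelParameters(r=0.5, K=1e9)
        state = PopulationState(1e6, 0, 0, 0, 0, 0)
        dy = derivatives(state, p)
        assert dy[0] == pytest.approx(0.5 * (1 - 1e-3) * 1e6)  # 499500
        assert np.all(dy[1:] == 0)

    def test_fig1_state_term_by_term(self, fig1_params):
        # hand-computed oracle: g = 0.5*(1-1e-3) = 0.4995, alpha*V = 1e-5
        state = PopulationState(S_minus=2.5e5, R_minus=2.5e5, S_plus=2.5e5,
                                R_plus=1.25e5, C_plus=1.25e5, V=1e4)
        expected = np.array([
            (0.4995 - 1e-5) * 2.5e5,          # S-: growth minus infection
            0.4995 * 0.95 * 2.5e5,            # R-: costly growth
            (0.4995 - 1e-5) * 2.5e5,          # S+
            0.4995 * 0.95 * 1.25e5,           # R+
            0.4995 * 1.25e5,                  # C+: cost-free growth (c_I=0)
            (1e-9 * 100 * 5e5 - 1e-9 * 6.25e5) * 1e4,   # V: burst - adsorption
        ])
        np.testing.assert_allclose(derivatives(state, fig1_params), expected,
                                   rtol=1e-12)
        # frozen literals for the same oracle
        np.testing.assert_allclose(
            expected,
            [124872.5, 118631.25, 124872.5, 59315.625, 62437.5, 493.75])

    @given(state=states())
    def test_bacterial_sum_matches_symbolic_dN(self, state):
        """Sum of the five bacterial components equals dN/dt derived by hand."""
        p = fig1_parameters(mu=1e-5, A=0.1, m_b=0.02, m_v=0.1, c_I=0.1)
        dy = derivatives(state, p)
        N = state.N
        g = p.r * (1 - N / p.K)
        expected = (g * (state.S_minus + state.S_plus)
                    + g * (1 - p.c_R) * (state.R_minus + state.R_plus)
                    + g * (1 - p.c_I) * state.C_plus
                    + p.alpha * p.A * state.V * state.S_plus
                    - p.alpha * state.V * (state.S_minus + state.S_plus)
                    - p.m_b * N)
        assert dy[:5].sum() == pytest.approx(expected, rel=1e-9, abs=1e-6)

    @given(state=st.builds(
        PopulationState,
        **{k: st.floats(0.0, 1.9e8) for k in
           ("S_minus", "R_minus", "S_plus", "R_plus", "C_plus")},
        V=densities))
    def test_no_flux_out_of_empty_compartment(self, state):
        # holds below carrying capacity (N <= K); above K the logistic factor
        # is negative and the mutation influx term reverses sign
        p = fig1_parameters(mu=1e-5, A=0.1, m_b=0.02, m_v=0.1)
        y = state.as_array()
        for i in range(6):
            z = y.copy()
            z[i] = 0.0
            dy = derivatives(PopulationState.from_array(z), p)
            assert dy[i] >= 0.0

    @given(state=states())
    def test_phage_only_decays_without_burst(self, state):
        p = fig1_parameters(B=0.0, m_v=0.0)
        assert derivatives(state, p)[5] <= 0.0


class TestFDelta:
    def test_worked_example_30_vs_15_percent(self):
        # CRISPR+ 30% protected, CRISPR- 15% resistant -> 0.15
        state = PopulationState(S_minus=8.5e5, R_minus=1.5e5,
                                S_plus=7e5, R_plus=1.5e5, C_plus=1.5e5, V=0)
        assert f_delta(state) == pytest.approx(0.30 - 0.15, abs=1e-12)

    @pytest.mark.parametrize("state,expected", [
        (PopulationState(1e5, 0, 1e5, 0, 0, 0), 0.0),     # no resistance at all
        (PopulationState(1e5, 0, 0, 0, 1e5, 0), 1.0),     # all-immune vs none
        (PopulationState(0, 1e5, 1e5, 0, 0, 0), -1.0),    # resistant only on -
    ])
    def test_extreme_and_null_cases(self, state, expected):
        assert f_delta(state) == pytest.approx(expected, abs=1e-12)

    def test_empty_subpopulation_is_an_error(self):
        with pytest.raises(UndefinedStatisticError):
            f_delta(PopulationState(1e5, 1e5, 0, 0, 0, 0))
        with pytest.raises(UndefinedStatisticError):
            f_delta(PopulationState(0, 0, 1e5, 0, 0, 0))

    @given(state=states(min_value=1.0))
    def test_bounded_in_unit_interval(self, state):
        assert -1.0 <= f_delta(state) <= 1.0


class TestFrequenciesAndSelection:
    def test_crispr_frequency_cases(self):
        assert crispr_frequency(PopulationState(1e5, 0, 0, 0, 0, 0)) == 0.0
        assert crispr_frequency(
            PopulationState(1e5, 1e5, 1e5, 1e5, 1e5, 0)) == pytest.approx(0.6)
        with pytest.raises(UndefinedStatisticError):
            crispr_frequency(PopulationState(0, 0, 0, 0, 0, 1e4))

    def test_fig1_initial_frequency_is_half(self, fig1_state):
        assert crispr_frequency(fig1_state) == pytest.approx(0.5)

    def test_reduced_rhs_arithmetic_and_boundaries(self):
        assert reduced_rhs(0.5, 0.15, 1e4, 1e-9) == pytest.approx(3.75e-7)
        assert reduced_rhs(0.5, 0.7, 0.0, 1e-9) == 0.0
        assert reduced_rhs(0.0, 0.5, 1e4, 1e-9) == 0.0
        assert reduced_rhs(1.0, 0.5, 1e4, 1e-9) == 0.0
        with pytest.raises(InvalidModelInput):
            reduced_rhs(1.5, 0.5, 1e4, 1e-9)

    @given(n=st.floats(0, 1), f=st.floats(-1, 1), v=densities)
    def test_reduced_rhs_antisymmetric_in_f_delta(self, n, f, v):
        assert reduced_rhs(n, -f, v, 1e-9) == pytest.approx(
            -reduced_rhs(n, f, v, 1e-9), rel=1e-12, abs=1e-300)

    def test_selection_coefficient(self, fig1_params, fig1_state):
        assert selection_coefficient(fig1_state, fig1_params) == pytest.approx(
            1e-9 * 1e4 * 0.15)
        quiet = PopulationState(4.25e5, 0.75e5, 3.5e5, 0.75e5, 0.75e5, 0.0)
        assert selection_coefficient(quiet, fig1_params) == 0.0
        negative = PopulationState(1e5, 9e5, 9e5, 1e5, 0, 1e4)
        assert selection_coefficient(negative, fig1_params) < 0

    def test_derived_stats_bundle(self, fig1_params, fig1_state):
        d = derived_stats(fig1_state, fig1_params)
        assert d.N_total == pytest.approx(1e6)
        assert d.N_plus_freq == pytest.approx(0.5)
        assert d.f_delta == pytest.approx(0.15)
        assert d.resistance_freq == pytest.approx(0.225)
        assert d.sel_coeff == pytest.approx(1.5e-6)
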