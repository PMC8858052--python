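"""Tests for the compartmental model: field, equilibria, condition checks."""

import warnings
from math import inf

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from numpy.testing import assert_allclose

from cfcancer.model import (
    PARAM_NAMES,
    ConditionReport,
    DegenerateEquilibriumError,
    EquilibriumError,
    ModelParameters,
    StateVector,
    TranscriptionWarning,
    build_linear_system,
    equilibrium_closed_form,
    equilibrium_linear_solve,
    existence_uniqueness_check,
    lipschitz_constants,
    stability_eigenvalues,
    vector_field,
)
from conftest import random_parameters

nonneg = st.floats(min_value=0.0, max_value=1e3, allow_nan=False)


class TestParametersAndState:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="delta_AD"):
            ModelParameters(**{**dict.fromkeys(PARAM_NAMES, 0.1), "delta_AD": -0.1})

    def test_k_aggregates(self, base_params):
        p = base_params
        assert p.k1 == p.delta_AD + p.delta_AB
        assert p.k2 == p.delta_BD + p.delta_BC + p.delta_BE + p.gamma2
        assert p.k3 == p.delta_CD + p.delta_CE + p.gamma3

    def test_state_nonnegativity(self):
        with pytest.raises(ValueError, match="C_C"):
            StateVector(1.0, 1.0, -0.5, 0.0, 0.0)

    def test_dict_round_trip(self, base_params):
        assert ModelParameters.from_dict(base_params.as_dict()) == base_params


class TestVectorField:
    def test_empty_cohort_gives_recruitment(self, base_params):
        f = vector_field(np.zeros(5), base_params)
        assert_allclose(
            f, [base_params.eta1, base_params.eta2, base_params.eta3, 0.0, 0.0]
        )

    def test_zero_at_equilibrium(self, base_params):
        eq = equilibrium_linear_solve(base_params)
        assert np.max(np.abs(vector_field(eq, base_params))) < 1e-10

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(state=st.tuples(nonneg, nonneg, nonneg, nonneg, nonneg))
    def test_conservation_identity(self, state):
        # internal transfers cancel in pairs; only recruitment and deaths
        # change the total population
        p = ModelParameters(
            eta1=0.3, eta2=0.2, eta3=0.1, delta_AB=0.4, delta_AD=0.2,
            delta_BC=0.3, delta_BD=0.25, delta_BE=0.15, delta_CD=0.2,
            delta_CE=0.3, delta_DB=0.05, delta_DC=0.04, delta_DE=0.35,
            gamma1=0.12, gamma2=0.08, gamma3=0.2,
        )
        s = np.array(state)
        total = vector_field(s, p).sum()
        expected = (
            p.eta1 + p.eta2 + p.eta3
            - p.gamma2 * s[1] - p.gamma3 * s[2] - p.gamma1 * s[4]
        )
        assert total == pytest.approx(expected, abs=1e-9 * (1 + abs(expected)))


class TestLinearSystem:
    def test_matches_vector_field_on_random_states(self, base_params):
        sys = build_linear_system(base_params)
        rng = np.random.default_rng(3)
        for _ in range(20):
            s = rng.uniform(0, 100, 5)
            assert_allclose(sys(s), vector_field(s, base_params), rtol=1e-13, atol=1e-10)

    def test_structure(self, base_params):
        sys = build_linear_system(base_params)
        p = base_params
        # stage 1-2 feeds stage 3 at delta_AB; recruitment enters as offset
        assert sys.A[1, 0] == p.delta_AB
        assert_allclose(sys.b, [p.eta1, p.eta2, p.eta3, 0.0, 0.0])
        off_diag = sys.A[~np.eye(5, dtype=bool)]
        assert np.all(off_diag >= 0)  # Metzler
        assert_allclose(
            sys.A.sum(axis=0), [0.0, -p.gamma2, -p.gamma3, 0.0, -p.gamma1], atol=1e-15
        )

    def test_column_sums_random_draws(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            p = random_parameters(rng)
            sys = build_linear_system(p)
            assert_allclose(
                sys.A.sum(axis=0),
                [0.0, -p.gamma2, -p.gamma3, 0.0, -p.gamma1],
                atol=1e-14,
            )


class TestEquilibrium:
    def test_hand_solved_chain(self, hand_params):
        assert_allclose(
            equilibrium_linear_solve(hand_params), [1.0, 1.0, 0.0, 0.0, 0.0], atol=1e-14
        )

    def test_no_recruitment_gives_origin(self, base_params):
        p = base_params.replace(eta1=0.0, eta2=0.0, eta3=0.0)
        assert_allclose(equilibrium_linear_solve(p), np.zeros(5), atol=1e-14)

    def test_all_zero_rates_singular(self):
        p = ModelParameters(**{**dict.fromkeys(PARAM_NAMES, 0.0), "eta1": 1.0})
        with pytest.raises(EquilibriumError, match="rank"):
            equilibrium_linear_solve(p)

    def test_residual_on_random_draws(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = random_parameters(rng)
            eq = equilibrium_linear_solve(p)
            assert np.max(np.abs(vector_field(eq, p))) < 1e-10

    def test_flow_preserves_nonnegative_orthant(self, base_params):
        # Metzler A with b >= 0: classical trajectories stay nonnegative
        from cfcancer.solver import solve_classical_rk4

        rng = np.random.default_rng(9)
        for _ in range(5):
            y0 = rng.uniform(0, 50, 5)
            tr = solve_classical_rk4(base_params, y0, h=0.01, T=20.0)
            assert tr.states.min() >= -1e-12


class TestClosedForm:
    def test_first_component_always_exact(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            p = random_parameters(rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", TranscriptionWarning)
                state, expansion = equilibrium_closed_form(p)
            assert state[0] == pytest.approx(p.eta1 / p.k1, rel=1e-14)
            # either the transcription agrees or it was flagged
            assert expansion.consistent in (True, False)

    def test_midstage_recovery_ratio(self):
        # C_A* = eta1 / (delta_AD + delta_AB) = 0.1 / 0.2
        p = ModelParameters(
            **{**dict.fromkeys(PARAM_NAMES, 0.3), "eta1": 0.1, "delta_AD": 0.1, "delta_AB": 0.1}
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", TranscriptionWarning)
            state, _ = equilibrium_closed_form(p)
        assert state[0] == pytest.approx(0.5, rel=1e-14)

    def test_warning_carries_discrepancy(self, base_params):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", TranscriptionWarning)
            state, expansion = equilibrium_closed_form(base_params)
        if not expansion.consistent:
            assert any(issubclass(w.category, TranscriptionWarning) for w in caught)
            assert expansion.discrepancy is not None and expansion.discrepancy.shape == (5,)
        # C_A agrees with the linear solve regardless
        assert state[0] == pytest.approx(equilibrium_linear_solve(base_params)[0], rel=1e-12)

    def test_degenerate_denominators(self, base_params):
        with pytest.raises(DegenerateEquilibriumError, match="gamma1"):
            equilibrium_closed_form(base_params.replace(gamma1=0.0))
        with pytest.raises(DegenerateEquilibriumError, match="k1"):
            equilibrium_closed_form(base_params.replace(delta_AD=0.0, delta_AB=0.0))


class TestLipschitz:
    def test_constants_are_outflow_totals(self, base_params):
        p = base_params
        rep = lipschitz_constants(p)
        assert rep.mu1 == p.delta_AD + p.delta_AB
        assert rep.mu2 == p.delta_BD + p.delta_BC + p.delta_BE + p.gamma2
        assert rep.mu3 == p.delta_CD + p.delta_CE + p.gamma3
        assert rep.mu4 == p.delta_DB + p.delta_DC + p.delta_DE
        assert rep.mu5 == p.gamma1
        assert np.all(rep.mus >= 0)

    def test_zero_rates_give_zero_constants(self):
        p = ModelParameters(**dict.fromkeys(PARAM_NAMES, 0.0))
        assert_allclose(lipschitz_constants(p).mus, 0.0)

    def test_mu2_matches_numerical_lipschitz_estimate(self, base_params):
        # perturb only C_B and measure |L2(C) - L2(C')| / |C_B - C_B'|
        rng = np.random.default_rng(17)
        best = 0.0
        for _ in range(200):
            s = rng.uniform(0, 100, 5)
            s2 = s.copy()
            s2[1] = rng.uniform(0, 100)
            num = abs(vector_field(s, base_params)[1] - vector_field(s2, base_params)[1])
            den = abs(s[1] - s2[1])
            if den > 1e-9:
                best = max(best, num / den)
        assert best == pytest.approx(lipschitz_constants(base_params).mu2, rel=1e-9)


class TestExistenceUniqueness:
    def _params_with_mu1(self, mu1):
        return ModelParameters(
            **{**dict.fromkeys(PARAM_NAMES, 0.0), "delta_AD": mu1 / 2, "delta_AB": mu1 / 2,
               "gamma1": 0.1}
        )

    def test_contraction_horizon_arithmetic(self):
        # (1 - c1 mu1) / (c2 mu1) at mu1=0.2, theta=0.5 -> 9
        rep = existence_uniqueness_check(self._params_with_mu1(0.2), 0.5, t=1.0)
        assert rep.t0_max == pytest.approx(9.0, rel=1e-12)
        # theta=1 (c1=0): t0_max = 1/mu1
        rep = existence_uniqueness_check(self._params_with_mu1(0.5), 1.0, t=1.0)
        assert rep.t0_max == pytest.approx(2.0, rel=1e-12)

    def test_zero_mu1_unconditional(self):
        rep = existence_uniqueness_check(self._params_with_mu1(0.0), 0.7, t=1e9)
        assert rep.t0_max == inf
        assert rep.existence_ok and rep.uniqueness_ok and rep.contraction_ok

    def test_uniqueness_flag_flips_at_horizon(self):
        params = self._params_with_mu1(0.2)
        t0 = existence_uniqueness_check(params, 0.5, t=0.0).t0_max
        eps = 1e-9
        assert existence_uniqueness_check(params, 0.5, t=t0 - eps).uniqueness_ok
        assert not existence_uniqueness_check(params, 0.5, t=t0 + eps).uniqueness_ok
        assert not existence_uniqueness_check(params, 0.5, t=t0).uniqueness_ok

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        mu_pair=st.tuples(
            st.floats(min_value=0.01, max_value=0.9),
            st.floats(min_value=0.01, max_value=0.9),
        )
    )
    def test_horizon_monotone_in_mu1(self, mu_pair):
        lo, hi = sorted(mu_pair)
        if hi - lo < 1e-6:
            return
        t_lo = existence_uniqueness_check(self._params_with_mu1(lo), 0.6, 1.0).t0_max
        t_hi = existence_uniqueness_check(self._params_with_mu1(hi), 0.6, 1.0).t0_max
        assert t_lo > t_hi

    def test_uniqueness_monotone_in_t(self):
        params = self._params_with_mu1(0.3)
        flags = [
            existence_uniqueness_check(params, 0.8, t=t).uniqueness_ok
            for t in np.linspace(0, 20, 41)
        ]
        # True ... True False ... False, no re-entry
        assert flags == sorted(flags, reverse=True)

    def test_report_type(self, base_params):
        rep = existence_uniqueness_check(base_params, 0.9, 5.0)
        assert isinstance(rep, ConditionReport)
        assert rep.contraction_ok  # mu1 = 0.1151 < 1

    def test_theta_domain(self, base_params):
        with pytest.raises(ValueError):
            existence_uniqueness_check(base_params, 0.0, 1.0)


def test_baseline_stability_metadata(base_params):
    eig = stability_eigenvalues(base_params)
    assert np.all(eig.real < 0)
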