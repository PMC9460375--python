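"""Closed-form phase solutions: printed values, boundary behaviour, identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bfmnu import (
    CompositeParams,
    RedistributiveRates,
    anabolic_mass,
    catabolic_mass,
    composite_mass,
    food_mass_from_constant,
    metabolic_constant,
    redistributive_mass_approx,
    redistributive_state_exact,
    roots_alpha_beta,
)
from bfmnu.model import _exact_tracks

from conftest import random_consistent_rates

rates_st = st.builds(
    random_consistent_rates,
    st.integers(0, 2**31 - 1).map(np.random.default_rng),
)


class TestPhaseSolutions:
    @pytest.mark.parametrize(
        "M_i, k_v, t, expected",
        [
            (80.0, 0.001, 0.0, 80.0),
            (80.0, 0.001, 720.0, 80.0 * math.exp(-0.72)),
            (80.0, 0.001, 1e7, 0.0),
        ],
    )
    def test_catabolic_values(self, M_i, k_v, t, expected):
        assert catabolic_mass(M_i, k_v, t) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize(
        "M_f, k_n, t, expected",
        [
            (65.0, 0.002, 0.0, 0.0),
            (65.0, 0.002, 500.0, 65.0 * (1.0 - math.exp(-1.0))),
            (65.0, 0.002, 1e7, 65.0),
        ],
    )
    def test_anabolic_values(self, M_f, k_n, t, expected):
        assert anabolic_mass(M_f, k_n, t) == pytest.approx(expected, abs=1e-9)

    def test_catabolic_strictly_decreasing_anabolic_increasing(self):
        t = np.linspace(0.0, 5000.0, 400)
        assert np.all(np.diff(catabolic_mass(80.0, 0.001, t)) < 0.0)
        assert np.all(np.diff(anabolic_mass(65.0, 0.002, t)) > 0.0)

    @pytest.mark.parametrize(
        "fn, kwargs",
        [
            (catabolic_mass, dict(M_i=-1.0, k_v=0.001, t=1.0)),
            (catabolic_mass, dict(M_i=80.0, k_v=0.0, t=1.0)),
            (catabolic_mass, dict(M_i=80.0, k_v=0.001, t=-1.0)),
            (anabolic_mass, dict(M_f=0.0, k_n=0.002, t=1.0)),
            (anabolic_mass, dict(M_f=65.0, k_n=-0.1, t=1.0)),
        ],
    )
    def test_domain_errors(self, fn, kwargs):
        with pytest.raises(ValueError):
            fn(**kwargs)


class TestRoots:
    def test_worked_example(self, worked_rates):
        alpha, beta = roots_alpha_beta(worked_rates)
        assert alpha == pytest.approx(0.002, rel=1e-12)
        assert beta == pytest.approx(0.005, rel=1e-12)

    def test_symmetric_case(self):
        k, c = 0.004, 0.0015
        rates = RedistributiveRates(k_v=k, k_n=k, k_vn=c, k_nv=c)
        alpha, beta = roots_alpha_beta(rates)
        assert alpha == pytest.approx(k - c, rel=1e-12)
        assert beta == pytest.approx(k + c, rel=1e-12)

    @given(rates_st)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_root_identity_alpha_ke_beta_K(self, rates):
        # under k_v - k_vn = k_n - k_nv the quadratic factors as (s+k_e)(s+K)
        alpha, beta = roots_alpha_beta(rates)
        assert alpha == pytest.approx(rates.k_e, rel=1e-12)
        assert beta == pytest.approx(rates.K, rel=1e-12)

    @given(rates_st)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_vieta_relations(self, rates):
        alpha, beta = roots_alpha_beta(rates)
        assert alpha + beta == pytest.approx(rates.k_v + rates.k_n, rel=1e-12)
        assert alpha * beta == pytest.approx(
            rates.k_v * rates.k_n - rates.k_nv * rates.k_vn, rel=1e-12
        )

    def test_inconsistent_rates_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            RedistributiveRates(k_v=0.003, k_n=0.004, k_vn=0.001, k_nv=0.0005)

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            RedistributiveRates(k_v=0.003, k_n=0.004, k_vn=-0.001, k_nv=0.0)


class TestRedistributiveExact:
    def test_initial_conditions(self, worked_rates):
        st0 = redistributive_state_exact(50.0, 20.0, worked_rates, 0.0)
        assert st0.V == pytest.approx(50.0, abs=1e-12)
        assert st0.N == pytest.approx(20.0, abs=1e-12)
        assert st0.M == pytest.approx(70.0, abs=1e-12)

    @given(rates_st, st.floats(0.0, 5000.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_total_decays_with_elimination_constant(self, rates, t):
        # V + N = (V_x + N_x) e^{-k_e t}: total mass obeys dM/dt = -k_e M
        state = redistributive_state_exact(50.0, 20.0, rates, t)
        assert state.M == pytest.approx(70.0 * math.exp(-rates.k_e * t), rel=1e-10)

    def test_total_identity_on_grid(self, worked_rates):
        t = np.linspace(0.0, 2000.0, 300)
        V, N = _exact_tracks(50.0, 20.0, worked_rates, t)
        np.testing.assert_allclose(V + N, 70.0 * np.exp(-0.002 * t), rtol=1e-12)

    def test_degenerate_roots_raise(self):
        # vanishing transfer rates push K toward k_e: beta - alpha below tolerance
        rates = RedistributiveRates(k_v=0.002, k_n=0.002, k_vn=1e-13, k_nv=1e-13)
        with pytest.raises(ValueError, match="degenerate"):
            redistributive_state_exact(50.0, 20.0, rates, 100.0)


class TestRedistributiveApprox:
    def test_zero_at_both_ends(self):
        assert redistributive_mass_approx(80.0, 65.0, 0.002, 0.005, 0.0) == 0.0
        assert abs(redistributive_mass_approx(80.0, 65.0, 0.002, 0.005, 1e7)) < 1e-9

    def test_peak_location_and_value(self):
        alpha, beta = 0.002, 0.005
        t_star = math.log(beta / alpha) / (beta - alpha)
        assert t_star == pytest.approx(305.430, abs=1e-3)
        assert redistributive_mass_approx(80.0, 65.0, alpha, beta, t_star) == pytest.approx(
            47.23, abs=0.01
        )

    def test_unimodal_nonnegative_by_grid_scan(self):
        alpha, beta = 0.002, 0.005
        t = np.linspace(0.0, 20000.0, 4000)
        y = redistributive_mass_approx(80.0, 65.0, alpha, beta, t)
        assert np.all(y >= 0.0)
        k = int(np.argmax(y))
        assert 0 < k < t.size - 1
        assert np.all(np.diff(y[: k + 1]) >= 0.0) and np.all(np.diff(y[k:]) <= 0.0)
        t_star = math.log(beta / alpha) / (beta - alpha)
        assert abs(t[k] - t_star) <= t[1] - t[0]

    def test_degenerate_roots_take_zero_limit_branch(self):
        y = redistributive_mass_approx(80.0, 65.0, 0.002, 0.002, 500.0)
        assert y == pytest.approx(0.0, abs=1e-9)


class TestComposite:
    def test_boundary_conditions(self, example_params):
        assert composite_mass(example_params, 0.0) == example_params.M_i
        assert composite_mass(example_params, 1e7) == pytest.approx(
            example_params.M_f, abs=1e-6
        )

    def test_additivity_of_phase_terms(self, example_params):
        p, t = example_params, 720.0
        expected = (
            catabolic_mass(p.M_i, p.k_mi, t)
            + anabolic_mass(p.M_f, p.k_mf, t)
            + redistributive_mass_approx(p.M_i, p.M_f, p.alpha, p.beta, t)
        )
        assert composite_mass(p, t) == pytest.approx(expected, rel=1e-15)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CompositeParams(M_i=80.0, M_f=65.0, k_mi=0.001, k_mf=0.001, alpha=0.005, beta=0.002)
        with pytest.raises(ValueError):
            CompositeParams(M_i=-80.0, M_f=65.0, k_mi=0.001, k_mf=0.001, alpha=0.002, beta=0.005)


class TestMetabolicConstant:
    def test_printed_formula_values(self):
        assert metabolic_constant(70.0, 0.0) == 0.0
        assert metabolic_constant(70.0, 2.0) == pytest.approx(
            math.log(70.0 / 68.0) / 24.0, rel=1e-12
        )

    def test_increasing_in_food_mass(self):
        k = [metabolic_constant(70.0, a) for a in (0.0, 1.0, 2.0, 5.0)]
        assert all(b > a for a, b in zip(k, k[1:]))

    @pytest.mark.parametrize("M_c, M_a", [(70.0, 70.0), (70.0, 80.0), (0.0, 0.0), (70.0, -1.0)])
    def test_domain_errors(self, M_c, M_a):
        with pytest.raises(ValueError):
            metabolic_constant(M_c, M_a)

    def test_known_inverse_value(self):
        assert food_mass_from_constant(70.0, 0.0) == 0.0
        assert food_mass_from_constant(70.0, 0.0012078140363855) == pytest.approx(2.0, abs=1e-4)

    @given(
        st.floats(20.0, 200.0),
        st.floats(0.0, 0.45),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_round_trip_identity(self, M_c, frac):
        M_a = frac * M_c
        assert food_mass_from_constant(M_c, metabolic_constant(M_c, M_a)) == pytest.approx(
            M_a, abs=1e-10 * max(M_a, 1.0)
        )
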