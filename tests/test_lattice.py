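"""Unit and property tests of the lattice operators and synchronous step."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colonycml import (
    LatticeState,
    ModelParams,
    SimulationError,
    antagonist_growth,
    diffusion_inflow,
    diffusion_outflow,
    neighborhood_antagonist_density,
    sensitive_growth,
    step,
)
from colonycml.lattice import DIFFUSION_KERNEL, NEIGHBORHOOD_KERNEL

from conftest import scalar_euler_oracle


class TestKernels:
    def test_neighborhood_kernel_weights(self):
        assert NEIGHBORHOOD_KERNEL[1, 1] == 0.5
        assert NEIGHBORHOOD_KERNEL[0, 1] == 1 / 12
        assert NEIGHBORHOOD_KERNEL[0, 0] == 1 / 24

    def test_kernels_sum_to_exactly_one(self):
        assert NEIGHBORHOOD_KERNEL.sum() == 1.0
        assert DIFFUSION_KERNEL.sum() == 1.0

    def test_diffusion_kernel_retains_nothing(self):
        assert DIFFUSION_KERNEL[1, 1] == 0.0
        assert DIFFUSION_KERNEL[1, 0] == 1 / 6
        assert DIFFUSION_KERNEL[0, 0] == 1 / 12


class TestNeighborhoodDensity:
    def test_uniform_field_is_fixed_point(self):
        a = np.full((7, 9), 0.37)
        na = neighborhood_antagonist_density(a)
        np.testing.assert_allclose(na, 0.37, rtol=0, atol=1e-15)

    def test_zero_maps_to_zero(self):
        na = neighborhood_antagonist_density(np.zeros((5, 5)))
        assert np.all(na == 0.0)

    def test_point_source_weights(self):
        a = np.zeros((5, 5))
        a[2, 2] = 1.0
        na = neighborhood_antagonist_density(a)
        assert na[2, 2] == pytest.approx(0.5)
        for r, c in [(1, 2), (3, 2), (2, 1), (2, 3)]:
            assert na[r, c] == pytest.approx(1 / 12)
        for r, c in [(1, 1), (1, 3), (3, 1), (3, 3)]:
            assert na[r, c] == pytest.approx(1 / 24)
        assert na.sum() == pytest.approx(1.0)

    def test_periodic_wrapping(self):
        a = np.zeros((5, 5))
        a[0, 0] = 1.0
        na = neighborhood_antagonist_density(a, "periodic")
        assert na[4, 0] == pytest.approx(1 / 12)
        assert na[4, 4] == pytest.approx(1 / 24)

    @pytest.mark.parametrize("shape", [(2, 5), (5, 2), (1, 1)])
    def test_small_periodic_grids_rejected(self, shape):
        with pytest.raises(ValueError, match="own neighbor"):
            neighborhood_antagonist_density(np.zeros(shape), "periodic")
        with pytest.raises(ValueError, match="own neighbor"):
            diffusion_inflow(np.zeros(shape), "periodic")


class TestGrowth:
    def test_sensitive_at_carrying_capacity(self, default_params):
        g = sensitive_growth(
            np.array([[1.0]]), np.array([[0.0]]), np.array([[0.0]]),
            default_params,
        )
        assert g[0, 0] == 0.0

    def test_sensitive_hand_value(self, default_params):
        g = sensitive_growth(
            np.array([[0.5]]), np.array([[0.0]]), np.array([[0.0]]),
            default_params,
        )
        assert g[0, 0] == pytest.approx(0.025, abs=1e-15)

    @pytest.mark.parametrize("s,a", [(0.3, 0.1), (0.9, 0.4), (0.05, 0.0)])
    def test_half_inhibition_at_ka(self, s, a, default_params):
        sg = np.array([[s]])
        ag = np.array([[a]])
        g0 = sensitive_growth(sg, ag, np.array([[0.0]]), default_params)
        gk = sensitive_growth(
            sg, ag, np.array([[default_params.K_a]]), default_params
        )
        assert gk[0, 0] == pytest.approx(0.5 * g0[0, 0], rel=1e-14)

    def test_zero_sensitive_gives_zero_growth(self, default_params, rng):
        s = np.zeros((4, 4))
        a = rng.uniform(0, 1, (4, 4))
        g = sensitive_growth(s, a, a / 2, default_params)
        assert np.all(g == 0.0)

    def test_overshoot_correction_is_negative(self, default_params):
        g = sensitive_growth(
            np.array([[0.9]]), np.array([[0.5]]), np.array([[0.0]]),
            default_params,
        )
        assert g[0, 0] < 0.0

    def test_antagonist_hand_values(self):
        p = ModelParams(beta=1.0)
        assert antagonist_growth(
            np.array([[0.0]]), np.array([[0.5]]), p
        )[0, 0] == pytest.approx(0.025, abs=1e-15)
        assert antagonist_growth(
            np.array([[0.5]]), np.array([[0.25]]), p
        )[0, 0] == pytest.approx(0.00625, abs=1e-15)
        assert antagonist_growth(np.array([[0.0]]), np.array([[1.0]]), p)[0, 0] == 0.0

    @settings(max_examples=60, derandomize=True)
    @given(
        s=st.floats(0.01, 0.6),
        a=st.floats(0.0, 0.2),
        na_lo=st.floats(0.0, 0.5),
        na_hi=st.floats(0.0, 0.5),
    )
    def test_inhibition_monotone_in_neighborhood_density(self, s, a, na_lo, na_hi):
        """More neighborhood antagonists never increase sensitive growth."""
        p = ModelParams()
        if s + p.alpha * a >= 1:
            return
        lo, hi = sorted((na_lo, na_hi))
        g_lo = sensitive_growth(np.array([[s]]), np.array([[a]]),
                                np.array([[lo]]), p)
        g_hi = sensitive_growth(np.array([[s]]), np.array([[a]]),
                                np.array([[hi]]), p)
        assert g_hi[0, 0] <= g_lo[0, 0] + 1e-18


class TestDiffusion:
    def test_outflow_proportionality(self, rng):
        x = rng.uniform(0, 1, (6, 6))
        out = diffusion_outflow(x, 0.01)
        np.testing.assert_array_equal(out, 0.01 * x)
        assert out.sum() == pytest.approx(0.01 * x.sum())

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            diffusion_outflow(np.ones((3, 3)), -0.1)

    def test_point_source_distribution(self):
        out = np.zeros((5, 5))
        out[2, 2] = 0.12
        inflow = diffusion_inflow(out)
        for r, c in [(1, 2), (3, 2), (2, 1), (2, 3)]:
            assert inflow[r, c] == pytest.approx(0.02)
        for r, c in [(1, 1), (1, 3), (3, 1), (3, 3)]:
            assert inflow[r, c] == pytest.approx(0.01)
        assert inflow[2, 2] == 0.0

    def test_uniform_outflow_maps_to_itself(self):
        out = np.full((6, 8), 0.004)
        np.testing.assert_allclose(diffusion_inflow(out), 0.004, atol=1e-18)

    def test_periodic_conservation(self, rng):
        out = rng.uniform(0, 0.01, (9, 9))
        inflow = diffusion_inflow(out, "periodic")
        assert inflow.sum() == pytest.approx(out.sum(), rel=1e-14)

    def test_absorbing_loses_edge_mass(self):
        out = np.zeros((5, 5))
        out[0, 0] = 1.0
        inflow = diffusion_inflow(out, "absorbing")
        assert inflow.sum() < out.sum()


class TestStep:
    def test_pure_diffusion_conserves_mass(self, random_state):
        p = ModelParams(r_s=0.0, r_a=0.0)
        S0, A0 = random_state.totals()
        state = random_state
        for _ in range(1000):
            state = step(state, p)
        S, A = state.totals()
        assert S == pytest.approx(S0, rel=1e-11)
        assert A == pytest.approx(A0, rel=1e-11)

    def test_uniform_state_stays_uniform(self, default_params):
        state = LatticeState(np.full((9, 9), 0.3), np.full((9, 9), 0.1))
        for _ in range(50):
            state = step(state, default_params)
            assert np.ptp(state.s) < 1e-12 and np.ptp(state.a) < 1e-12

    def test_isolated_compartment_matches_scalar_oracle(self):
        p = ModelParams(D_s=0.0, D_a=0.0)
        s = np.zeros((5, 5))
        a = np.zeros((5, 5))
        s[2, 2], a[2, 2] = 0.15, 0.07
        state = LatticeState(s, a)
        ss, aa = scalar_euler_oracle(0.15, 0.07, p, 200)
        for i in range(1, 201):
            state = step(state, p)
            assert state.s[2, 2] == pytest.approx(ss[i], abs=1e-12)
            assert state.a[2, 2] == pytest.approx(aa[i], abs=1e-12)

    @pytest.mark.parametrize("alpha,beta", [(0.5, 0.5), (0.3, 0.6)])
    def test_coexistence_fixed_point_is_stationary(self, alpha, beta):
        """Interior Lotka-Volterra equilibrium (alpha, beta < 1) is a fixed
        point of the full spatial map: growth vanishes there and diffusion
        cancels by uniformity; the inhibition factor scales the rate, not
        the equilibrium."""
        p = ModelParams(alpha=alpha, beta=beta)
        s_star = (1 - alpha) / (1 - alpha * beta)
        a_star = (1 - beta) / (1 - alpha * beta)
        state = LatticeState(np.full((7, 7), s_star), np.full((7, 7), a_star))
        new = step(state, p)
        np.testing.assert_allclose(new.s, s_star, rtol=0, atol=1e-12)
        np.testing.assert_allclose(new.a, a_star, rtol=0, atol=1e-12)

    def test_step_is_pure_and_deterministic(self, random_state, default_params):
        out1 = step(random_state.copy(), default_params)
        out2 = step(random_state.copy(), default_params)
        assert np.array_equal(out1.s, out2.s)
        assert np.array_equal(out1.a, out2.a)

    def test_invalid_regime_raises(self):
        # the antagonist map has no inhibition brake, so a huge
        # competition load drives it below zero in one step
        with pytest.warns(UserWarning):
            p = ModelParams(r_a=0.5, beta=10.0)
        state = LatticeState(np.ones((5, 5)), np.ones((5, 5)))
        with pytest.raises(SimulationError, match="negative"):
            step(state, p)

    def test_population_soft_bound(self, rng, default_params):
        state = LatticeState(rng.uniform(0, 1, (21, 21)),
                             rng.uniform(0, 1, (21, 21)))
        bound = 1 + 10 * max(default_params.D_s, default_params.D_a)
        for _ in range(300):
            state = step(state, default_params)
            assert state.s.max() <= bound and state.a.max() <= bound


class TestModelParams:
    def test_defaults_match_reference_rates(self, default_params):
        assert default_params.r_s == 0.1
        assert default_params.r_a == 0.1
        assert default_params.D_s == 0.01
        assert default_params.K_a == 0.08
        assert default_params.hill_n == 4.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"r_s": -0.1},
            {"r_a": 0.6},
            {"D_s": -0.01},
            {"K_a": 0.0},
            {"alpha": -1.0},
            {"hill_n": 0.5},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_large_rates_warn(self):
        with pytest.warns(UserWarning, match="0.2"):
            ModelParams(r_s=0.3)

    def test_state_validation(self):
        with pytest.raises(ValueError, match="shape"):
            LatticeState(np.zeros((3, 3)), np.zeros((4, 3)))
        with pytest.raises(ValueError, match="negative"):
            LatticeState(np.full((3, 3), -0.1), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="boundary"):
            LatticeState(np.zeros((3, 3)), np.zeros((3, 3)), "reflecting")
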