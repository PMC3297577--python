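"""Growth law, closed-form distances and zero-truncated Gaussian machinery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from tipsplit.core import (
    InfeasibleTruncationError,
    ModelParams,
    bb_distance_large_p,
    beta_for_mean_distance,
    grow_focus,
    sample_focus_size,
    solve_trunc_gauss,
    tip_to_branch_distance,
)


def _stepwise_distance(N0, Nb, v, beta, dt):
    """Independent oracle: step the growth ODE until the threshold is hit."""
    N, t = N0, 0.0
    while N < Nb:
        N *= math.exp(beta * dt)
        t += dt
    return v * t


class TestGrowFocus:
    def test_identity_at_t0(self, wildtype):
        assert grow_focus(1700.0, wildtype, 0.0) == 1700.0

    def test_linear_law_matches_ode_integration(self):
        p = ModelParams(beta=1.0, dt=0.05)
        t = math.log(10000.0 / 1700.0)
        sol = integrate.solve_ivp(
            lambda _, y: 1.0 * y, (0.0, t), [1700.0], rtol=1e-12, atol=1e-9
        )
        assert grow_focus(1700.0, p, t) == pytest.approx(10000.0, rel=1e-9)
        assert grow_focus(1700.0, p, t) == pytest.approx(sol.y[0, -1], rel=1e-8)

    def test_constant_law_is_linear_arithmetic(self):
        p = ModelParams(beta=100.0, growth_law="constant")
        assert grow_focus(1700.0, p, 10.0) == pytest.approx(2700.0)

    def test_monotone_in_time(self, wildtype):
        t = np.linspace(0, 30, 50)
        n = grow_focus(1700.0, wildtype, t)
        assert np.all(np.diff(n) >= 0)

    @pytest.mark.parametrize("bad", [(-1.0, 1.0), (0.0, 1.0), (10.0, -0.5)])
    def test_domain_errors(self, wildtype, bad):
        with pytest.raises(ValueError):
            grow_focus(bad[0], wildtype, bad[1])


class TestTipToBranchDistance:
    def test_zero_when_sizes_equal_or_reversed(self):
        assert tip_to_branch_distance(5000.0, 5000.0, 1.0, 1.0) == 0.0
        assert tip_to_branch_distance(6000.0, 5000.0, 1.0, 1.0) == 0.0

    def test_against_stepwise_oracle(self):
        d = tip_to_branch_distance(1700.0, 10000.0, 1.0, 1.0)
        assert d == pytest.approx(1.77196, abs=1e-5)
        # stepwise integration converges to the closed form as dt -> 0
        for dt in (1e-3, 1e-4):
            assert abs(_stepwise_distance(1700.0, 10000.0, 1.0, 1.0, dt) - d) <= 1.0 * dt + 1e-12

    def test_proportional_to_speed(self):
        d1 = tip_to_branch_distance(1700.0, 10000.0, 1.0, 1.0)
        d2 = tip_to_branch_distance(1700.0, 10000.0, 2.0, 1.0)
        assert d2 == pytest.approx(2.0 * d1)

    def test_closed_form_matches_stepwise_on_grid(self):
        # discretisation error of the stepwise oracle is at most v*dt
        rng = np.random.default_rng(0)
        dt = 0.01
        for _ in range(100):
            N0 = rng.uniform(200.0, 8000.0)
            Nb = N0 * rng.uniform(1.01, 20.0)
            v = rng.uniform(0.2, 2.0)
            beta = rng.uniform(0.05, 2.0)
            d = tip_to_branch_distance(N0, Nb, v, beta)
            assert abs(_stepwise_distance(N0, Nb, v, beta, dt) - d) <= v * dt + 1e-9

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            tip_to_branch_distance(-1.0, 10.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            tip_to_branch_distance(1.0, 10.0, 0.0, 1.0)

    @given(c=st.floats(0.1, 10.0))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_joint_rescaling_of_v_and_beta_leaves_distance_unchanged(self, c):
        d1 = tip_to_branch_distance(1700.0, 10000.0, 0.5, 0.2)
        d2 = tip_to_branch_distance(1700.0, 10000.0, 0.5 * c, 0.2 * c)
        assert d2 == pytest.approx(d1, rel=1e-12)


class TestBbDistanceLargeP:
    def test_half_depletion_gives_ln2(self):
        assert bb_distance_large_p(5000.0, 10000.0, 1.0, 1.0) == pytest.approx(math.log(2.0))

    def test_vanishes_as_n0_to_zero(self):
        assert bb_distance_large_p(1e-9, 10000.0, 1.0, 1.0) < 1e-12

    def test_table_values(self):
        assert bb_distance_large_p(1700.0, 10000.0, 1.0, 1.0) == pytest.approx(0.18633, abs=1e-5)

    def test_strictly_increasing_in_n0(self):
        n0 = np.linspace(100.0, 9900.0, 50)
        d = bb_distance_large_p(n0, 10000.0, 1.0, 1.0)
        assert np.all(np.diff(d) > 0)

    def test_emptying_tip_focus_rejected(self):
        with pytest.raises(ValueError):
            bb_distance_large_p(10000.0, 10000.0, 1.0, 1.0)


class TestSolveTruncGauss:
    def test_zero_variance_is_point_mass(self):
        spec = solve_trunc_gauss(1700.0, 0.0)
        assert spec.degenerate
        assert spec.underlying_mean == 1700.0

    def test_mild_truncation_underlying_close_to_targets(self):
        # at mean/sd = 8.5 the truncated tail is negligible
        spec = solve_trunc_gauss(1700.0, 200.0)
        assert spec.underlying_mean == pytest.approx(1700.0, rel=1e-6)
        assert spec.underlying_sd == pytest.approx(200.0, rel=1e-6)

    def test_heavy_truncation_shifts_underlying_mean_down(self):
        spec = solve_trunc_gauss(1700.0, 1000.0)
        assert spec.underlying_mean < 1700.0
        # independent oracle: quadrature of the truncated moments
        m, s = spec.underlying_mean, spec.underlying_sd
        z = stats.norm.sf(-m / s)
        mean = integrate.quad(lambda x: x * stats.norm.pdf(x, m, s) / z, 0, m + 12 * s)[0]
        ex2 = integrate.quad(lambda x: x * x * stats.norm.pdf(x, m, s) / z, 0, m + 12 * s)[0]
        assert mean == pytest.approx(1700.0, rel=1e-6)
        assert math.sqrt(ex2 - mean**2) == pytest.approx(1000.0, rel=1e-6)

    def test_infeasible_moment_pair_reported(self):
        with pytest.raises(InfeasibleTruncationError):
            solve_trunc_gauss(1000.0, 1100.0)

    @given(
        mean=st.floats(1.0, 5e4),
        ratio=st.floats(1.1, 20.0),
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_truncated_moment_round_trip(self, mean, ratio):
        sd = mean / ratio
        spec = solve_trunc_gauss(mean, sd)
        m_back, s_back = spec.moments()
        assert m_back == pytest.approx(mean, rel=1e-6)
        assert s_back == pytest.approx(sd, rel=1e-6)


class TestSampleFocusSize:
    def test_degenerate_is_constant(self, rng):
        spec = solve_trunc_gauss(1700.0, 0.0)
        assert sample_focus_size(spec, rng) == 1700.0
        assert np.all(sample_focus_size(spec, rng, 100) == 1700.0)

    def test_positivity_and_clt_convergence(self, rng):
        spec = solve_trunc_gauss(1700.0, 1000.0)
        x = sample_focus_size(spec, rng, 10**6)
        assert np.all(x > 0)
        assert abs(x.mean() - 1700.0) < 3.0 * 1000.0 / 1000.0  # 3 SE at n = 1e6
        assert abs(x.std() - 1000.0) < 10.0


class TestModelParams:
    def test_resolution_guard(self):
        with pytest.raises(ValueError):
            ModelParams(dt=1.0, p_split=0.2)
        with pytest.raises(ValueError):
            ModelParams(dt=1.0, beta=0.2, p_split=0.05)

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ModelParams.from_dict({"v": 0.5, "bogus": 1.0})

    def test_beta_default_hits_target_distance(self, wildtype):
        d = tip_to_branch_distance(wildtype.mu_N0, wildtype.mu_Nb, wildtype.v, wildtype.beta)
        assert d == pytest.approx(5.0)
        assert beta_for_mean_distance(0.5, 1700.0, 10000.0, 5.0) == pytest.approx(wildtype.beta)
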