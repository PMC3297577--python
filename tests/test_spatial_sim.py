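"""2D colony model: tip walks, curvature gating, pool accounting, nucleation."""

import math

import numpy as np
import pytest
from scipy import stats

from tipsplit.core import ModelParams
from tipsplit.spatial_sim import (
    Scenario,
    SpatialParams,
    TipState,
    advance_tip,
    curvature_at_tip,
    simulate_colony,
)


def _tips(n):
    return TipState(
        x=np.zeros(n), y=np.zeros(n), theta=np.zeros(n),
        s=np.zeros(n), N=np.full(n, 1700.0), t_birth=np.zeros(n),
    )


class TestAdvanceTip:
    def test_zero_noise_gives_straight_line(self, rng):
        t = _tips(1)
        for _ in range(100):
            advance_tip(t, 0.5, 0.0, 0.1, rng)
        assert t.y[0] == pytest.approx(0.0)
        assert t.x[0] == pytest.approx(100 * 0.5 * 0.1)

    def test_path_length_is_exact(self, rng):
        t = _tips(1)
        for _ in range(57):
            advance_tip(t, 0.5, 0.4, 0.1, rng)
        assert t.s[0] == pytest.approx(57 * 0.05)

    def test_heading_variance_grows_diffusively(self, rng):
        # ensemble of 10^4 walkers: Var(theta) = sigma_theta^2 * t
        sigma, dt, steps = 0.4, 0.1, 80
        t = _tips(10**4)
        for _ in range(steps):
            advance_tip(t, 0.5, sigma, dt, rng)
        expected = sigma**2 * steps * dt
        assert t.theta.var() == pytest.approx(expected, rel=0.05)


class TestCurvature:
    def test_straight_path_zero(self):
        pts = np.c_[np.linspace(0, 5, 100), np.zeros(100)]
        assert curvature_at_tip(pts, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_circle_radius_recovered(self):
        R = 5.0
        phi = np.linspace(0, 1.5, 400)
        pts = np.c_[R * np.sin(phi), R * (1 - np.cos(phi))]
        # counter-clockwise circle: curvature +1/R, window <= R/5
        assert curvature_at_tip(pts, 1.0) == pytest.approx(1.0 / R, rel=0.01)

    def test_reflection_flips_sign(self):
        R = 5.0
        phi = np.linspace(0, 1.5, 400)
        pts = np.c_[R * np.sin(phi), R * (1 - np.cos(phi))]
        refl = pts * np.array([1.0, -1.0])
        assert curvature_at_tip(refl, 1.0) == pytest.approx(-curvature_at_tip(pts, 1.0), rel=1e-9)

    def test_short_polyline_rejected(self):
        pts = np.c_[np.linspace(0, 0.3, 10), np.zeros(10)]
        with pytest.raises(ValueError):
            curvature_at_tip(pts, 1.0)


class TestCurvatureGate:
    def test_straight_growth_never_splits_with_threshold(self):
        p = ModelParams()
        sp = SpatialParams(sigma_theta=0.0, kappa_star=0.3, tip_cap=50)
        col = simulate_colony(p, sp, Scenario("wildtype"), T_end=120.0, seed=1)
        assert len(col.branch_records) == 0

    def test_foci_placed_on_outer_side_of_bend(self):
        p = ModelParams()
        sp = SpatialParams(kappa_star=0.3, tip_cap=200)
        col = simulate_colony(p, sp, Scenario("wildtype"), T_end=300.0, seed=2)
        br = col.branch_records
        splits = br[br["origin"] == "split"]
        assert len(splits) > 10
        # outer side of a left bend (kappa > 0) is the right side (side = -1)
        assert np.all(splits["side"] == -np.sign(splits["kappa_at_split"]))


class TestPoolAccounting:
    def test_conservation_wildtype(self):
        col = simulate_colony(ModelParams(), SpatialParams(tip_cap=300),
                              Scenario("wildtype"), T_end=150.0, seed=3)
        assert col.max_conservation_err < 1e-9

    def test_conservation_under_overexpression(self):
        col = simulate_colony(ModelParams(), SpatialParams(tip_cap=100),
                              Scenario("overexpress", t_induce=60.0), T_end=120.0, seed=4)
        assert col.max_conservation_err < 1e-9

    def test_wildtype_density_stays_below_nucleation_threshold(self):
        sp = SpatialParams(tip_cap=200)
        col = simulate_colony(ModelParams(), sp, Scenario("wildtype"), T_end=150.0, seed=5)
        assert col.rho < sp.rho_star
        assert col.n_nucleations == 0

    def test_underexpression_halves_density(self):
        sp = SpatialParams(tip_cap=100)
        col = simulate_colony(ModelParams(), sp, Scenario("underexpress"), T_end=60.0, seed=6)
        assert col.rho == pytest.approx(0.5 * sp.rho0)

    def test_overexpression_crosses_threshold_and_nucleates(self):
        sp = SpatialParams(tip_cap=100)
        col = simulate_colony(ModelParams(), sp, Scenario("overexpress", t_induce=60.0),
                              T_end=140.0, seed=7)
        assert col.n_nucleations > 0


@pytest.fixture(scope="module")
def pinned_high_density():
    # a single straight hypha with the pool pinned above the nucleation
    # threshold and splitting disabled: nucleation is the only focus
    # source and runs at rate c_nuc*(rho - rho_star) per unit length
    sp = SpatialParams(tip_cap=1, sigma_theta=0.0, c_nuc=2.5e-5,
                       rho0=10000.0, rho_star=4000.0, k_bind=2e-5)
    params = ModelParams(N_min=1e9, p_split=1e-3)
    return sp, simulate_colony(params, sp, Scenario("wildtype"), T_end=260.0, seed=8)


class TestNucleation:

    @staticmethod
    def _length_at(col, t):
        # founding tip ramps for t_ramp then extends at full speed
        mp, v = col.mp, col.params.v
        return float(v * (mp.f0 * min(t, mp.t_ramp)
                          + (1 - mp.f0) * min(t, mp.t_ramp) ** 2 / (2 * mp.t_ramp)
                          + max(t - mp.t_ramp, 0.0)))

    def test_positions_uniform_along_the_hypha(self, pinned_high_density):
        sp, col = pinned_high_density
        nuc = col.branch_records[col.branch_records["origin"] == "nucleation"]
        late = nuc[nuc["t_created"] >= 200.0]
        s200 = self._length_at(col, 200.0)
        pos = late["position"].to_numpy()
        pos = pos[pos <= s200]  # conditioning on the common support keeps uniformity
        assert len(pos) > 200
        assert stats.kstest(pos / s200, "uniform").pvalue > 0.01

    def test_count_matches_rate_integral(self, pinned_high_density):
        # creation count over the whole run (emergence lags creation, so
        # branch records alone would undercount the final few minutes)
        sp, col = pinned_high_density
        p = col.params
        lam = sum(
            sp.c_nuc * (sp.rho0 - sp.rho_star) * self._length_at(col, t) * p.dt
            for t in np.arange(0.0, 260.0, p.dt)
        )  # rho pinned at rho0 by the balanced pool
        assert abs(col.n_nucleations - lam) < 4.0 * math.sqrt(lam)

    def test_no_nucleation_below_threshold(self):
        sp = SpatialParams(tip_cap=1, sigma_theta=0.0, c_nuc=2.5e-5,
                           rho0=3800.0, rho_star=4000.0, k_bind=2e-5)
        col = simulate_colony(ModelParams(N_min=1e9, p_split=1e-3), sp,
                              Scenario("wildtype"), T_end=200.0, seed=10)
        assert col.n_nucleations == 0


class TestFirstOffshoot:
    def test_critical_mass_above_branch_size_depletes_short_offshoots(self):
        p = ModelParams()
        sp = SpatialParams(tip_cap=500)
        thresh = 0.5 * (p.v / p.beta) * math.log(2.0)
        fracs = {}
        for nmin in (p.mu_Nb, 2 * p.mu_Nb):
            col = simulate_colony(p.replace(N_min=nmin), sp, Scenario("wildtype"),
                                  T_end=250.0, seed=9)
            fo = col.first_offshoot_distances()
            assert len(fo) > 100
            fracs[nmin] = np.mean(fo < thresh)
        # N_min = mu_Nb: no depleted region near zero; N_min = 2 mu_Nb: a gap
        assert fracs[2 * p.mu_Nb] < 0.5 * fracs[p.mu_Nb]
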