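"""Minimal single-hypha simulator and trim-protocol measurement."""

import math

import numpy as np
import pytest
from scipy import stats

from tipsplit.core import ModelParams, bb_distance_large_p, tip_to_branch_distance
from tipsplit.minimal_sim import (
    HyphaSnapshot,
    collect_distances,
    simulate_hypha,
    snapshot_measure,
)


class TestSimulateHypha:
    def test_deterministic_distances_at_zero_variance(self, rng):
        p = ModelParams(sigma_N0=0.0, sigma_Nb=0.0)
        s = simulate_hypha(p, 20.0, rng)
        expected = tip_to_branch_distance(p.mu_N0, p.mu_Nb, p.v, p.beta)
        assert len(s.d_tb) > 0
        assert np.allclose(s.d_tb, expected)

    def test_no_split_below_critical_mass(self, rng):
        s = simulate_hypha(ModelParams(), 30.0, rng)
        assert np.all(s.N_at_split >= s.params.N_min)

    def test_records_are_ordered_and_within_hypha(self, rng):
        s = simulate_hypha(ModelParams(), 30.0, rng)
        assert np.all(np.diff(s.position) > 0)
        assert np.all(s.position <= s.X)
        assert np.all(s.t_emerge >= s.t_split)
        assert np.all(s.d_tb >= 0)

    def test_large_p_limit_matches_regrowth_distance(self):
        p = ModelParams(sigma_N0=0.0, sigma_Nb=0.0, p_split=45.0, dt=0.002)
        target = bb_distance_large_p(p.mu_N0, p.N_min, p.v, p.beta)
        rng = np.random.default_rng(7)
        gaps = []
        for _ in range(40):
            s = simulate_hypha(p, 30.0, rng)
            gaps.append(np.diff(s.position[3:]))
        g = np.concatenate(gaps)
        assert len(g) > 1500
        assert np.mean(g) == pytest.approx(target, rel=0.02)

    def test_poisson_limit_without_critical_mass(self):
        # N_min = 0: constant split hazard -> exponential spacings, mean v/p
        p = ModelParams(N_min=0.0, p_split=0.1, sigma_N0=0.0, sigma_Nb=0.0, dt=0.02)
        rng = np.random.default_rng(3)
        gaps = []
        for _ in range(200):
            s = simulate_hypha(p, 50.0, rng)
            gaps.append(np.diff(s.position)[5:20])
        g = np.concatenate(gaps)
        assert stats.kstest(g, "expon", args=(0, p.v / p.p_split)).pvalue > 0.01


def _synthetic_snapshot(params, X, positions, d_tb):
    """Snapshot with prescribed record geometry (emergence from d via v)."""
    positions = np.asarray(positions, dtype=float)
    d_tb = np.asarray(d_tb, dtype=float)
    t_split = positions / params.v
    return HyphaSnapshot(
        t=X / params.v,
        X=X,
        params=params,
        position=positions,
        t_split=t_split,
        N0_drawn=np.full_like(positions, 1.0),
        Nb_drawn=np.full_like(positions, 2.0),
        t_emerge=t_split + d_tb / params.v,
        d_tb=d_tb,
    )


class TestSnapshotMeasure:
    def test_empty_window_gives_empty_output(self, wildtype):
        s = _synthetic_snapshot(wildtype, 40.0, [1.0, 2.0], [0.5, 0.5])
        td = snapshot_measure(s, 15.0)
        assert len(td.tb) == 0 and len(td.bb) == 0

    def test_all_values_bounded_by_trim(self, rng):
        s = simulate_hypha(ModelParams(), 15.0, rng)
        td = snapshot_measure(s, 15.0)
        assert np.all(td.tb >= 0) and np.all(td.tb <= 15.0)
        assert np.all(td.bb >= 0) and np.all(td.bb <= 15.0)

    def test_latent_foci_invisible(self, wildtype):
        X, L = 40.0, 15.0
        s = _synthetic_snapshot(wildtype, X, [30.0, 35.0], [5.0, 50.0])
        td = snapshot_measure(s, L)
        # second record has not emerged (position + d > X)
        assert np.allclose(td.tb, [5.0])

    def test_length_bias_weight(self, wildtype):
        # uniform emergence distances on [0, 2L] observed through snapshots
        # must be thinned by the window-survival weight (L - d)
        rng = np.random.default_rng(11)
        L, X = 10.0, 60.0
        kept = []
        for _ in range(3000):
            pos = np.sort(rng.uniform(0.0, X, size=8))
            d = rng.uniform(0.0, 2 * L, size=8)
            td = snapshot_measure(_synthetic_snapshot(wildtype, X, pos, d), L)
            kept.append(td.tb)
        d_obs = np.concatenate(kept)
        # expected density on [0, L] is triangular: 2 (L - d) / L^2
        edges = np.linspace(0.0, L, 11)
        counts, _ = np.histogram(d_obs, edges)
        expected = len(d_obs) * np.diff(-((L - edges) ** 2)) / L**2
        chi2 = stats.chisquare(counts, expected)
        assert chi2.pvalue > 0.01


class TestCollectDistances:
    def test_reproducible_given_seed(self, wildtype):
        a = collect_distances(wildtype, 15.0, 300, seed=42)
        b = collect_distances(wildtype, 15.0, 300, seed=42)
        assert np.array_equal(a.tb, b.tb) and np.array_equal(a.bb, b.bb)

    def test_pooling_independent_of_chunking(self, wildtype):
        a = collect_distances(wildtype, 15.0, 600, seed=9, chunk_size=4096)
        b = collect_distances(wildtype, 15.0, 600, seed=9, chunk_size=4096)
        assert np.array_equal(a.tb, b.tb)

    def test_standard_error_shrinks_with_sample_size(self, wildtype):
        means = {
            n: np.array(
                [collect_distances(wildtype, 15.0, n, seed=s).tb.mean() for s in range(8)]
            )
            for n in (200, 1600)
        }
        assert means[1600].std() < means[200].std()

    def test_short_gap_suppression_below_regrowth_distance(self, wildtype):
        # gaps below half the regrowth distance occur far less often than an
        # exponential law with the same mean would imply
        td = collect_distances(wildtype, 15.0, 8000, seed=21)
        d_star = bb_distance_large_p(wildtype.mu_N0, wildtype.N_min, wildtype.v, wildtype.beta)
        frac = np.mean(td.bb < d_star / 2.0)
        expo = 1.0 - math.exp(-(d_star / 2.0) / td.bb.mean())
        se = math.sqrt(frac * (1.0 - frac) / len(td.bb))
        assert frac < expo - 3.0 * se

    def test_scale_invariance_of_distances_under_joint_rescaling(self, wildtype):
        # (v, beta) -> (2v, 2beta) leaves the distance distribution unchanged
        scaled = wildtype.replace(v=2 * wildtype.v, beta=2 * wildtype.beta, dt=wildtype.dt / 2)
        a = collect_distances(wildtype, 15.0, 4000, seed=5)
        b = collect_distances(scaled, 15.0, 4000, seed=6)
        edges = np.linspace(0, 15.0, 21)
        ha = np.histogram(a.tb, edges)[0] / len(a.tb)
        hb = np.histogram(b.tb, edges)[0] / len(b.tb)
        assert 0.5 * np.abs(ha - hb).sum() < 0.03
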