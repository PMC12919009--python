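"""Spherical-window Ka/Ks, filters, IAT, block bootstrap and permutation."""

import numpy as np
import pytest

from endoclock.seqdiv import CodonAlignment, ng86_kaks
from endoclock.structure_windows import (
    KS_SENTINEL,
    ResidueCloud,
    WindowSeries,
    block_permutation_p,
    block_plan,
    delta_log_omega,
    delta_log_omega_pairs,
    filter_windows,
    integrated_autocorrelation_time,
    moving_block_bootstrap_bca,
    spherical_window_kaks,
)
from endoclock.synthetic_data import SimulationConfig, simulate_omega_series

from conftest import mutate_sites, random_codon_seq


def _cloud(xyz: np.ndarray, plddt: float = 90.0) -> ResidueCloud:
    n = len(xyz)
    return ResidueCloud(
        index=np.arange(1, n + 1), xyz=xyz, plddt=np.full(n, plddt)
    )


def _pair(rng, n_codons: int, n_mut: int) -> CodonAlignment:
    a = random_codon_seq(rng, n_codons)
    b = mutate_sites(a, list(rng.choice(3 * n_codons, n_mut, replace=False)), rng)
    return CodonAlignment(taxa=("p", "q"), sequences={"p": a, "q": b})


class TestSphericalWindows:
    def test_degenerate_geometry_equals_global(self, rng):
        # all residues within radius of each other: every window = global
        n = 30
        xyz = rng.uniform(0, 2.0, size=(n, 3))
        aln = _pair(rng, n, 25)
        series = spherical_window_kaks(_cloud(xyz), aln, "p", "q", radius=10.0)
        global_est = ng86_kaks(aln, "p", "q")
        assert np.allclose(series.Ka, global_est.Ka)
        assert np.allclose(series.Ks, global_est.Ks)

    def test_disjoint_clusters_stay_separate(self, rng):
        n = 40
        xyz = rng.uniform(0, 3.0, size=(n, 3))
        xyz[20:, 0] += 25.0  # second cluster 25 A away
        aln = _pair(rng, n, 30)
        series = spherical_window_kaks(_cloud(xyz), aln, "p", "q", radius=10.0)
        # windows in cluster 1 must equal the Ka/Ks of cluster-1 codons only
        sub = CodonAlignment(
            taxa=("p", "q"),
            sequences={
                "p": aln.sequence("p")[: 60],
                "q": aln.sequence("q")[: 60],
            },
        )
        est1 = ng86_kaks(sub, "p", "q")
        assert np.allclose(series.Ka[:20], est1.Ka)

    def test_matches_brute_force_distance_oracle(self, rng):
        n = 25
        xyz = rng.uniform(0, 12.0, size=(n, 3))
        aln = _pair(rng, n, 20)
        series = spherical_window_kaks(_cloud(xyz), aln, "p", "q", radius=6.0)
        codons_p = aln.codons("p")
        codons_q = aln.codons("q")
        for i in range(n):
            dists = np.sqrt(((xyz - xyz[i]) ** 2).sum(axis=1))
            members = [j for j in range(n) if dists[j] <= 6.0]
            sub = CodonAlignment(
                taxa=("p", "q"),
                sequences={
                    "p": "".join(codons_p[j] for j in members),
                    "q": "".join(codons_q[j] for j in members),
                },
            )
            try:
                est = ng86_kaks(sub, "p", "q")
                if est.Ks == 0.0 and est.n_syn_sites == 0.0:
                    assert series.Ks[i] == KS_SENTINEL
                else:
                    assert series.Ka[i] == pytest.approx(est.Ka)
                    assert series.Ks[i] == pytest.approx(est.Ks)
            except Exception:
                assert series.Ks[i] == KS_SENTINEL

    def test_length_mismatch_rejected(self, rng):
        aln = _pair(rng, 10, 5)
        cloud = _cloud(rng.uniform(0, 5, size=(11, 3)))
        with pytest.raises(ValueError, match="residue count"):
            spherical_window_kaks(cloud, aln, "p", "q")


class TestFilterWindows:
    def _series(self, ks, plddt):
        n = len(ks)
        return WindowSeries(
            residue=np.arange(n),
            Ka=np.full(n, 0.1),
            Ks=np.asarray(ks, float),
            plddt=np.asarray(plddt, float),
            retained=np.ones(n, bool),
        )

    def test_sentinel_and_boundaries(self):
        series = self._series(
            ks=[KS_SENTINEL, 0.05, 0.1, 2.0, 2.01, 0.5],
            plddt=[90, 90, 90, 90, 90, 69.9],
        )
        out = filter_windows(series)
        assert list(out.retained) == [False, False, True, True, False, False]

    def test_planted_violations_exactly_dropped(self, rng):
        n = 60
        ks = rng.uniform(0.2, 1.5, size=n)
        plddt = rng.uniform(75, 100, size=n)
        bad = rng.choice(n, size=12, replace=False)
        ks[bad[:4]] = KS_SENTINEL
        ks[bad[4:8]] = 0.01
        plddt[bad[8:]] = 50.0
        out = filter_windows(self._series(ks, plddt))
        assert set(np.nonzero(~out.retained)[0]) == set(bad)

    def test_idempotent(self, rng):
        series = self._series(rng.uniform(0, 3, 50), rng.uniform(50, 100, 50))
        once = filter_windows(series)
        twice = filter_windows(once)
        assert np.array_equal(once.retained, twice.retained)


class TestDeltaLogOmega:
    def test_identical_series(self):
        x = np.log(np.array([0.2, 0.4, 0.6]) + 1e-6)
        assert delta_log_omega(x, x) == 0.0
        dp, ratio = delta_log_omega_pairs([(x, x)])
        assert ratio == 1.0

    def test_e_fold_scaling(self):
        omega = np.array([0.5, 1.0, 2.0, 4.0])
        la = np.log(omega + 1e-6)
        lb = np.log(omega * np.e + 1e-6)
        assert delta_log_omega(la, lb) == pytest.approx(-1.0, abs=1e-5)

    def test_planted_median_gap_recovered(self):
        # pooled medians built to 0.29 vs 0.37
        rng = np.random.default_rng(4)
        a = 0.29 * np.exp(0.2 * rng.normal(size=4001))
        b = 0.37 * np.exp(0.2 * rng.normal(size=4001))
        delta = delta_log_omega(np.log(a + 1e-6), np.log(b + 1e-6))
        assert delta == pytest.approx(np.log(0.29 / 0.37), abs=0.02)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            delta_log_omega(np.array([]), np.array([1.0]))


class TestIat:
    def test_white_noise(self):
        rng = np.random.default_rng(8)
        tau = integrated_autocorrelation_time(rng.normal(size=5000))
        assert abs(tau - 1.0) < 0.15

    def test_ar1_analytic_value(self):
        phi = 0.7
        rng = np.random.default_rng(9)
        eps = rng.normal(size=20_000)
        x = np.empty(20_000)
        x[0] = eps[0]
        for t in range(1, 20_000):
            x[t] = phi * x[t - 1] + eps[t]
        tau = integrated_autocorrelation_time(x)
        truth = (1 + phi) / (1 - phi)
        assert abs(tau - truth) / truth < 0.10

    def test_alternating_series(self):
        x = np.tile([1.0, -1.0], 50)
        assert integrated_autocorrelation_time(x) < 1.0

    def test_constant_series_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            assert integrated_autocorrelation_time(np.ones(100)) == 1.0


class TestBlockPlan:
    @pytest.mark.parametrize(
        "ta,tb,expected",
        [(1.0, 1.0, 6), (40.0, 1.0, 30), (4.0, 7.0, 14), (3.0, 4.0, 8)],
    )
    def test_clamped_lengths(self, ta, tb, expected):
        assert block_plan(ta, tb).L == expected


class TestBlockBootstrap:
    def _planted_pairs(self, seed, gap=-0.25, phi=0.5, n=400, n_pairs=3):
        pairs = []
        for k in range(n_pairs):
            cfg = SimulationConfig(
                seed=seed * 100 + k, series_length=n, ar_phi=phi,
                log_median_gap=gap,
            )
            a, b, _ = simulate_omega_series(cfg)
            pairs.append((np.log(a + 1e-6), np.log(b + 1e-6)))
        return pairs

    def test_single_block_degenerate(self):
        x = np.log(np.linspace(0.2, 0.8, 12))
        y = np.log(np.linspace(0.3, 0.9, 12))
        with pytest.warns(UserWarning, match="single pair"):
            dp, lo, hi = moving_block_bootstrap_bca(
                [(x, y)], L=12, B=1000, seed=0
            )
        assert lo == pytest.approx(dp) and hi == pytest.approx(dp)

    def test_seed_determinism(self):
        pairs = self._planted_pairs(1)
        r1 = moving_block_bootstrap_bca(pairs, L=8, B=1000, seed=42)
        r2 = moving_block_bootstrap_bca(pairs, L=8, B=1000, seed=42)
        assert r1 == r2

    def test_coverage_of_planted_effect(self):
        # planted delta_p = -0.25 under AR(1) phi = 0.5 autocorrelation
        gap = -0.25
        covered = 0
        n_runs = 60
        for seed in range(n_runs):
            pairs = self._planted_pairs(seed, gap=gap)
            taus = [
                integrated_autocorrelation_time(np.concatenate([a, b]))
                for a, b in pairs
            ]
            L = block_plan(max(taus), max(taus)).L
            _, lo, hi = moving_block_bootstrap_bca(pairs, L, B=1000, seed=seed)
            covered += lo <= gap <= hi
        assert covered >= 0.90 * n_runs


class TestBlockPermutation:
    def test_extreme_p_values(self):
        rng = np.random.default_rng(12)
        noise = 0.05 * rng.normal(size=200)
        a = np.log(0.1) + noise
        b = np.log(0.9) + noise
        p_low = block_permutation_p([(a, b)], L=10, B=499, seed=0)
        assert p_low == pytest.approx(1.0 / 500.0)
        p_high = block_permutation_p([(b, a)], L=10, B=499, seed=0)
        assert p_high == 1.0

    def test_plus_one_convention(self):
        # observed below every permuted value: p = 1/(B+1)
        a = np.full(50, -3.0) + np.linspace(0, 0.01, 50)
        b = np.full(50, 3.0) + np.linspace(0, 0.01, 50)
        assert block_permutation_p([(a, b)], L=6, B=10, seed=1) == pytest.approx(
            1.0 / 11.0
        )

    def test_identical_series_null(self):
        # seriesA = seriesB: permuted deltas straddle 0, p well away from 0
        hits = 0
        n_runs = 40
        for seed in range(n_runs):
            rng = np.random.default_rng(500 + seed)
            x = rng.normal(size=120)
            p = block_permutation_p([(x, x.copy())], L=8, B=199, seed=seed)
            hits += p >= 0.4
        assert hits >= 0.95 * n_runs

    def test_null_super_uniform(self):
        hits = 0
        n_sim = 100
        for seed in range(n_sim):
            cfg = SimulationConfig(
                seed=7000 + seed, series_length=150, ar_phi=0.4,
                log_median_gap=0.0,
            )
            a, b, _ = simulate_omega_series(cfg)
            p = block_permutation_p(
                [(np.log(a + 1e-6), np.log(b + 1e-6))], L=8, B=99, seed=seed
            )
            hits += p < 0.05
        assert hits / n_sim <= 0.08

    def test_pipeline_detects_planted_effect(self):
        # the full pipeline reproduces the sign conclusion on fixtures with
        # a planted median gap of -0.23
        pairs = []
        for k in range(3):
            cfg = SimulationConfig(
                seed=40 + k, series_length=600, ar_phi=0.5, log_median_gap=-0.23
            )
            a, b, _ = simulate_omega_series(cfg)
            pairs.append((np.log(a + 1e-6), np.log(b + 1e-6)))
        taus = [
            integrated_autocorrelation_time(s) for pair in pairs for s in pair
        ]
        L = block_plan(max(taus), max(taus)).L
        dp, _ = delta_log_omega_pairs(pairs)
        assert dp < 0
        p = block_permutation_p(pairs, L, B=999, seed=2)
        assert p < 0.05
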