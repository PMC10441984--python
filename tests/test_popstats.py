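import numpy as np
import pytest

from admixscan import popstats, synthpop
from admixscan.pipeline import _merge_tables
from conftest import haps_to_sitetable, make_sitetable
from oracles import tajimas_d_bruteforce, wc_fst_anova


class TestPiWindows:
    def test_monomorphic_window_is_zero(self):
        t = make_sitetable([10, 20], np.zeros((2, 3), dtype=np.int8))
        pi = popstats.pi_windows(t, win=1000, step=1000, L=1000)
        assert pi["value"].iloc[0] == 0.0

    def test_single_site_arithmetic(self):
        # n=4 haplotypes, alt count j=2, 1 kb window:
        # per-site pi = 2*2*2/(4*3) = 1/3; window value = 1/3/1000
        t = make_sitetable([100], [[1, 1]])
        pi = popstats.pi_windows(t, win=1000, step=1000, L=1000)
        assert pi["value"].iloc[0] == pytest.approx(2 * 2 * 2 / 12 / 1000)
        assert pi["value"].iloc[0] == pytest.approx(6.67e-4, rel=1e-2)

    def test_admixed_cohort_exceeds_source_diversity(self, small_cohort):
        # mixing two diverged sources raises heterozygosity above either
        cfg, panels, truth = small_cohort
        adm = truth.target_sitetable(0)
        pi_adm = popstats.pi_windows(adm, L=cfg.L_bp)["value"].mean()
        for k in range(2):
            src = truth.panel_sitetable(0, ancestry=k)
            pi_src = popstats.pi_windows(src, L=cfg.L_bp)["value"].mean()
            assert pi_adm > pi_src

    def test_invariant_under_sample_reordering_and_allele_flip(self):
        rng = np.random.default_rng(3)
        gt = rng.integers(0, 3, size=(50, 6)).astype(np.int8)
        t = make_sitetable(np.arange(50) * 17, gt)
        base = popstats.pi_windows(t, win=500, step=500, L=1000)["value"]
        perm = rng.permutation(6)
        t2 = make_sitetable(np.arange(50) * 17, gt[:, perm])
        flipped = make_sitetable(np.arange(50) * 17, 2 - gt)
        for other in (t2, flipped):
            v = popstats.pi_windows(other, win=500, step=500, L=1000)["value"]
            assert np.allclose(base, v)

    def test_window_with_no_sites_flagged(self):
        t = make_sitetable([100], [[1, 1]])
        pi = popstats.pi_windows(t, win=500, step=500, L=1500)
        assert pi["n_sites"].iloc[1] == 0
        assert pi["value"].iloc[1] == 0.0


class TestTajimasD:
    def test_no_segregating_sites_is_nan(self):
        t = make_sitetable([10], np.full((1, 3), 2, dtype=np.int8))
        d = popstats.tajimas_d(t, win=100, step=100, L=100)
        assert np.isnan(d["value"].iloc[0])

    def test_fewer_than_four_haplotypes_raises(self):
        t = make_sitetable([10], [[1]])
        with pytest.raises(ValueError):
            popstats.tajimas_d(t)

    def test_matches_bruteforce_pairwise_oracle(self):
        rng = np.random.default_rng(8)
        haps = rng.integers(0, 2, size=(10, 30)).astype(np.int8)
        t = haps_to_sitetable(haps, np.arange(30) * 11)
        d = popstats.tajimas_d(t, win=400, step=400, L=400)["value"].iloc[0]
        assert d == pytest.approx(tajimas_d_bruteforce(haps), abs=1e-10)

    def test_neutral_coalescent_mean_near_zero(self):
        # msprime provides the independent neutral simulation
        import msprime

        ts = msprime.sim_ancestry(samples=15, sequence_length=2_000_000,
                                  recombination_rate=1e-8,
                                  population_size=10_000, random_seed=7)
        mts = msprime.sim_mutations(ts, rate=1e-8, random_seed=7)
        gm = mts.genotype_matrix()
        pos = np.array([int(s.position) for s in mts.sites()])
        biallelic = np.array([set(np.unique(row)) == {0, 1} for row in gm])
        gm, pos = gm[biallelic], pos[biallelic]
        _, first = np.unique(pos, return_index=True)
        gm, pos = gm[first], pos[first]
        t = haps_to_sitetable(gm.T, pos)
        d = popstats.tajimas_d(t, win=50_000, step=50_000, L=2_000_000)
        assert abs(np.nanmean(d["value"])) < 0.3


class TestThetaPiRatio:
    def grid(self, values):
        import pandas as pd

        return pd.DataFrame({
            "chrom": ["chr1"] * len(values),
            "start": np.arange(len(values)) * 100,
            "end": (np.arange(len(values)) + 1) * 100,
            "n_sites": 1, "partial": False, "value": values,
        })

    def test_equal_diversity_gives_zero(self):
        r = popstats.theta_pi_ratio(self.grid([0.01]), self.grid([0.01]))
        assert r["value"].iloc[0] == pytest.approx(0.0)

    def test_doubled_diversity_gives_log_two(self):
        r = popstats.theta_pi_ratio(self.grid([0.02]), self.grid([0.01]))
        assert r["value"].iloc[0] == pytest.approx(np.log(2), abs=1e-12)

    def test_zero_reference_diversity_is_flagged_nan(self):
        r = popstats.theta_pi_ratio(self.grid([0.02]), self.grid([0.0]))
        assert np.isnan(r["value"].iloc[0])
        assert bool(r["undefined"].iloc[0])

    def test_grid_mismatch_raises(self):
        a, b = self.grid([1, 2]), self.grid([1, 2])
        b["start"] += 50
        with pytest.raises(ValueError):
            popstats.theta_pi_ratio(a, b)


class TestWcFst:
    def two_pop_table(self, g1, g2):
        g = np.concatenate([g1, g2], axis=1).astype(np.int8)
        t = make_sitetable(np.arange(g.shape[0]) * 10, g)
        sa = t.samples[: g1.shape[1]]
        sb = t.samples[g1.shape[1]:]
        return t, sa, sb

    def test_fixed_difference_gives_fst_one(self):
        g1 = np.full((5, 4), 2, dtype=np.int8)
        g2 = np.zeros((5, 4), dtype=np.int8)
        t, sa, sb = self.two_pop_table(g1, g2)
        f = popstats.wc_fst_windows(t, sa, sb, win=1000, step=1000, L=1000)
        assert f["value"].iloc[0] == pytest.approx(1.0)

    def test_identical_populations_give_near_zero(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.1, 0.9, size=300)
        g1 = rng.binomial(2, p[:, None], size=(300, 10)).astype(np.int8)
        g2 = g1[:, rng.permutation(10)]
        t, sa, sb = self.two_pop_table(g1, g2)
        f = popstats.wc_fst_windows(t, sa, sb, win=3000, step=3000, L=3000)
        # no differentiation: small, and if anything negatively biased
        # (the estimator's finite-sample behaviour; negatives retained)
        assert f["value"].iloc[0] <= 0.01
        assert f["value"].iloc[0] > -0.1

    def test_matches_indicator_anova_oracle_per_site(self):
        rng = np.random.default_rng(5)
        g1 = rng.integers(0, 3, size=(40, 8))
        g2 = rng.integers(0, 3, size=(40, 6))
        t, sa, sb = self.two_pop_table(g1, g2)
        a, b, c, usable = popstats.wc_site_components(t, sa, sb)
        for i in range(40):
            if not usable[i]:
                continue
            ao, bo, co = wc_fst_anova(g1[i], g2[i])
            assert a[i] == pytest.approx(ao, abs=1e-10)
            assert b[i] == pytest.approx(bo, abs=1e-10)
            assert c[i] == pytest.approx(co, abs=1e-10)

    def test_ratio_of_sums_equals_oracle_aggregation(self):
        rng = np.random.default_rng(6)
        g1 = rng.integers(0, 3, size=(60, 8))
        g2 = rng.integers(0, 3, size=(60, 8))
        t, sa, sb = self.two_pop_table(g1, g2)
        f = popstats.wc_fst_windows(t, sa, sb, win=600, step=600, L=600)
        num = den = 0.0
        for i in range(60):
            p1, p2 = g1[i].mean() / 2, g2[i].mean() / 2
            if (p1 + p2) / 2 in (0.0, 1.0):
                continue
            ao, bo, co = wc_fst_anova(g1[i], g2[i])
            num, den = num + ao, den + ao + bo + co
        assert f["value"].iloc[0] == pytest.approx(num / den, abs=1e-10)

    def test_allele_flip_invariance(self):
        rng = np.random.default_rng(7)
        g1 = rng.integers(0, 3, size=(100, 8)).astype(np.int8)
        g2 = rng.integers(0, 3, size=(100, 8)).astype(np.int8)
        t, sa, sb = self.two_pop_table(g1, g2)
        tf, _, _ = self.two_pop_table(2 - g1, 2 - g2)
        f1 = popstats.wc_fst_windows(t, sa, sb, win=1000, step=1000, L=1000)
        f2 = popstats.wc_fst_windows(tf, sa, sb, win=1000, step=1000, L=1000)
        assert np.allclose(f1["value"], f2["value"])

    def test_empty_population_raises(self):
        t = make_sitetable([10], [[1, 1]])
        with pytest.raises((ValueError, KeyError)):
            popstats.wc_fst_windows(t, t.samples, ["missing"])


class TestKingKinship:
    def cohort(self, seed=31, n_sites=3000):
        cfg = synthpop.SimConfig(K=2, m=(0.5, 0.5), F=0.1, n_sites=n_sites,
                                 n_ref=40, n_adm=2, seed=seed)
        panels = synthpop.make_panels(cfg)
        return cfg, panels.chroms[0]

    def test_duplicated_sample_has_half_kinship(self):
        cfg, pc = self.cohort()
        hap = pc.haps[0][:2]
        haps = np.vstack([hap, hap])  # same diploid twice
        t = haps_to_sitetable(haps, pc.pos_bp)
        k = popstats.king_kinship(t)
        assert k["phi"].iloc[0] == pytest.approx(0.5, abs=0.02)
        assert k["degree"].iloc[0] == "duplicate"

    def test_parent_offspring_kinship_near_quarter(self):
        cfg, pc = self.cohort(seed=32)
        rng = np.random.default_rng(1)
        freqs = pc.freqs[0]
        parent = (rng.random((2, cfg.n_sites)) < freqs).astype(np.int8)
        other = (rng.random((1, cfg.n_sites)) < freqs).astype(np.int8)
        child = np.vstack([parent[0], other])  # inherits one parent hap
        t = haps_to_sitetable(np.vstack([parent, child]), pc.pos_bp)
        k = popstats.king_kinship(t)
        assert k["phi"].iloc[0] == pytest.approx(0.25, abs=0.03)
        assert bool(k["close_relative"].iloc[0])

    def test_unrelated_draws_have_zero_kinship(self):
        cfg, pc = self.cohort(seed=33)
        rng = np.random.default_rng(2)
        haps = (rng.random((4, cfg.n_sites)) < pc.freqs[0]).astype(np.int8)
        t = haps_to_sitetable(haps, pc.pos_bp)
        k = popstats.king_kinship(t)
        assert k["phi"].iloc[0] == pytest.approx(0.0, abs=0.02)
        assert k["degree"].iloc[0] == "unrelated"

    def test_too_few_joint_sites_gives_nan(self):
        gt = np.array([[1, -1]] * 50, dtype=np.int8)
        t = make_sitetable(np.arange(50) * 3, gt)
        with pytest.warns(UserWarning):
            k = popstats.king_kinship(t)
        assert np.isnan(k["phi"].iloc[0])


class TestEmpiricalRank:
    def test_rank_is_upper_tail_fraction(self):
        r = popstats.empirical_rank(np.array([1.0, 2.0, 3.0, 4.0]))
        assert np.allclose(r, [1.0, 0.75, 0.5, 0.25])

    def test_nan_values_excluded(self):
        r = popstats.empirical_rank(np.array([1.0, np.nan, 3.0]))
        assert np.isnan(r[1])
        assert r[2] == 0.5
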