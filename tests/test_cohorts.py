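"""Generator-level checks: drift moments, LD structure, liability calibration, kinship."""

import numpy as np
import pytest

from multiprs import (
    AncestryModel,
    EffectModel,
    LDBlockSpec,
    LiabilityModel,
    draw_ancestral_frequencies,
    draw_true_effects,
    drift_frequencies,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_related_pairs,
    simulate_sumstats,
)


class TestAncestralFrequencies:
    def test_degenerate_range_gives_constant(self):
        am = AncestryModel(("X",), (0.0,), ancestral_af_range=(0.5, 0.5))
        assert np.allclose(draw_ancestral_frequencies(5, am, 0), 0.5)

    def test_uniform_mean(self):
        am = AncestryModel(("X",), (0.0,), ancestral_af_range=(0.05, 0.95))
        p = draw_ancestral_frequencies(10_000, am, 42)
        se = (0.95 - 0.05) / np.sqrt(12) / np.sqrt(10_000)
        assert abs(p.mean() - 0.5) < 3 * se

    def test_deterministic_under_seed(self):
        am = AncestryModel()
        a = draw_ancestral_frequencies(100, am, 7)
        b = draw_ancestral_frequencies(100, am, 7)
        assert np.array_equal(a, b)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            AncestryModel(ancestral_af_range=(0.9, 0.1))


class TestDrift:
    def test_fst_zero_is_identity(self):
        am = AncestryModel(("X",), (0.0,))
        p = np.array([0.1, 0.5, 0.9])
        assert np.array_equal(drift_frequencies(p, am, 0)[0], p)

    def test_balding_nichols_moments(self):
        # E[AF] = p and Var = F p (1-p) for the Beta drift model
        am = AncestryModel(("X",), (0.1,))
        p = np.full(10_000, 0.5)
        d = drift_frequencies(p, am, 3)[0]
        var_target = 0.1 * 0.25
        assert abs(d.mean() - 0.5) < 3 * np.sqrt(var_target / 10_000)
        assert abs(d.var() - var_target) < 0.1 * var_target

    def test_larger_fst_spreads_more(self):
        am = AncestryModel(("lo", "hi"), (0.01, 0.2))
        p = np.full(10_000, 0.5)
        d = drift_frequencies(p, am, 4)
        ratio = d[1].var() / d[0].var()
        assert 12 < ratio < 30  # expected 20 under the Beta variance formula


class TestGenotypes:
    def test_no_ld_when_rho_zero(self):
        ld = LDBlockSpec(block_size=5, within_block_rho=0.0)
        afs = np.full((1, 10), 0.5)
        G = simulate_genotypes(afs, ld, {"X": 5000}, 5, ancestry_labels=("X",))
        r = np.corrcoef(G.dosages.T)
        off = r[np.triu_indices(10, 1)]
        assert np.all(off**2 < 0.01)

    def test_high_rho_high_r2_within_block(self):
        ld = LDBlockSpec(block_size=5, within_block_rho=0.99)
        afs = np.full((1, 5), 0.5)
        G = simulate_genotypes(afs, ld, {"X": 5000}, 6, ancestry_labels=("X",))
        r2 = np.corrcoef(G.dosages[:, 0], G.dosages[:, 1])[0, 1] ** 2
        assert r2 > 0.8

    def test_af_matches_target(self):
        afs = np.array([[0.1, 0.3, 0.7]])
        G = simulate_genotypes(afs, LDBlockSpec(block_size=1), {"X": 2000}, 7, ancestry_labels=("X",))
        emp = G.empirical_af()
        se = np.sqrt(afs[0] * (1 - afs[0]) / (2 * 2000))
        assert np.all(np.abs(emp - afs[0]) < 3 * se + 1e-12)

    def test_cross_block_independence(self):
        ld = LDBlockSpec(block_size=5, within_block_rho=0.9)
        afs = np.full((1, 10), 0.5)
        G = simulate_genotypes(afs, ld, {"X": 5000}, 8, ancestry_labels=("X",))
        r2 = np.corrcoef(G.dosages[:, 0], G.dosages[:, 7])[0, 1] ** 2
        assert r2 < 0.01


class TestEffects:
    def _setup(self, m=2000, rho=0.5, h2=0.3, frac=1.0):
        am = AncestryModel(("EA", "AA"), (0.02, 0.1))
        p = draw_ancestral_frequencies(m, am, 1)
        afs = drift_frequencies(p, am, 2)
        G = simulate_genotypes(afs, LDBlockSpec(block_size=1), {"EA": 10, "AA": 10}, 3, ancestry_labels=am.labels)
        em = EffectModel(n_causal_fraction=frac, heritability_liability=h2, cross_ancestry_corr=rho, apoe_variant=0)
        return G.variants, afs, em, am

    def test_perfect_correlation_gives_identical_effects(self):
        vi, afs, em, am = self._setup(rho=1.0, m=500)
        eff = draw_true_effects(vi, afs, em, am.labels, 5)
        assert np.allclose(eff["EA"].to_numpy(), eff["AA"].to_numpy(), atol=1e-9)

    def test_cross_ancestry_correlation_recovered(self):
        vi, afs, em, am = self._setup(rho=0.5, m=2000)
        eff = draw_true_effects(vi, afs, em, am.labels, 6)
        a, b = eff["EA"].to_numpy(), eff["AA"].to_numpy()
        nz = a != 0
        nz[em.apoe_variant] = False  # designated large-effect variant is not polygenic
        assert abs(np.corrcoef(a[nz], b[nz])[0, 1] - 0.5) < 0.05

    def test_null_architecture_keeps_only_apoe(self):
        vi, afs, em, am = self._setup(h2=0.0, m=100)
        eff = draw_true_effects(vi, afs, em, am.labels, 7)
        assert eff["EA"].iloc[0] == em.apoe_like_effect
        assert np.all(eff["EA"].iloc[1:] == 0)

    def test_h2_realized_on_ancestry_average(self):
        vi, afs, em, am = self._setup(h2=0.3, m=1000)
        eff = draw_true_effects(vi, afs, em, am.labels, 8)
        gvars = []
        for k, lab in enumerate(am.labels):
            beta = eff[lab].to_numpy().copy()
            beta[em.apoe_variant] = 0.0  # APOE effect sits on top of the polygenic h2 budget
            gvars.append(np.sum(beta**2 * 2 * afs[k] * (1 - afs[k])))
        assert np.isclose(np.mean(gvars), 0.3)


class TestPhenotypes:
    def test_prevalence_calibrated(self, small_cohort):
        n = 20_000
        afs = small_cohort["afs"]
        G = simulate_genotypes(afs, small_cohort["ld"], {"EA": n // 2, "AA": n // 2}, 21,
                               ancestry_labels=small_cohort["ancestry"].labels)
        phen = simulate_phenotypes(G, small_cohort["effects"], LiabilityModel(prevalence=0.1), 22, apoe_variant=7)
        frac = phen.table["ad_status"].mean()
        assert abs(frac - 0.1) < 3 * np.sqrt(0.1 * 0.9 / n)

    def test_null_model_no_case_control_separation(self):
        am = AncestryModel(("X",), (0.0,))
        p = draw_ancestral_frequencies(200, am, 31)
        afs = drift_frequencies(p, am, 32)
        G = simulate_genotypes(afs, LDBlockSpec(block_size=1), {"X": 4000}, 33, ancestry_labels=("X",))
        em = EffectModel(heritability_liability=0.0, apoe_like_effect=0.0, apoe_variant=0)
        eff = draw_true_effects(G.variants, afs, em, ("X",), 34)
        lm = LiabilityModel(prevalence=0.3, age_effect=0.0, sex_effect=0.0)
        phen = simulate_phenotypes(G, eff, lm, 35, apoe_variant=0)
        score = G.dosages @ np.random.default_rng(0).normal(size=200)
        y = phen.table["ad_status"].to_numpy()
        z = (score[y == 1].mean() - score[y == 0].mean()) / np.sqrt(
            score[y == 1].var() / (y == 1).sum() + score[y == 0].var() / (y == 0).sum()
        )
        assert abs(z) < 3

    def test_apoe_effect_monotone_in_dosage_gap(self):
        am = AncestryModel(("X",), (0.0,))
        p = draw_ancestral_frequencies(50, am, 41)
        afs = drift_frequencies(p, am, 42)
        G = simulate_genotypes(afs, LDBlockSpec(block_size=1), {"X": 3000}, 43, ancestry_labels=("X",))
        gaps = []
        for effect in (0.3, 0.6):
            em = EffectModel(heritability_liability=0.0, apoe_like_effect=effect, apoe_variant=0)
            eff = draw_true_effects(G.variants, afs, em, ("X",), 44)
            diffs = []
            for rep in range(10):
                phen = simulate_phenotypes(G, eff, LiabilityModel(prevalence=0.3), 100 + rep, apoe_variant=0)
                y = phen.table["ad_status"].to_numpy()
                d = G.dosages[:, 0]
                diffs.append(d[y == 1].mean() - d[y == 0].mean())
            gaps.append(np.mean(diffs))
        assert gaps[1] > gaps[0] > 0

    def test_apoe_counts_jointly_consistent(self, small_cohort):
        t = small_cohort["phen"].table
        assert ((t["apoe_e4_count"] + t["apoe_e2_count"]) <= 2).all()


class TestSumstats:
    def test_null_variants_type_i_error(self):
        # causal-free architecture: Wald p should be uniform
        am = AncestryModel(("X",), (0.0,))
        p = draw_ancestral_frequencies(1000, am, 51)
        afs = drift_frequencies(p, am, 52)
        G = simulate_genotypes(afs, LDBlockSpec(block_size=1), {"X": 1500}, 53, ancestry_labels=("X",))
        em = EffectModel(heritability_liability=0.0, apoe_like_effect=0.0, apoe_variant=0)
        eff = draw_true_effects(G.variants, afs, em, ("X",), 54)
        phen = simulate_phenotypes(G, eff, LiabilityModel(prevalence=0.3), 55, apoe_variant=0)
        ss = simulate_sumstats(G, phen, mode="regression", seed=56)
        pvals = ss.table["p"].dropna().to_numpy()
        frac = (pvals < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / len(pvals))

    def test_analytic_noise_free_limit(self, small_cohort):
        G = small_cohort["G"].subset_samples(small_cohort["G"].sample_ancestry == "EA")
        ss_big = simulate_sumstats(
            G, small_cohort["phen"], mode="analytic", seed=57,
            effects=small_cohort["effects"], liability=LiabilityModel(prevalence=0.2),
            n_analytic=10**12,
        )
        ss_big2 = simulate_sumstats(
            G, small_cohort["phen"], mode="analytic", seed=58,
            effects=small_cohort["effects"], liability=LiabilityModel(prevalence=0.2),
            n_analytic=10**12,
        )
        # se -> 0, so beta equals the deterministic marginal target regardless of seed
        a = ss_big.table["beta"].dropna()
        b = ss_big2.table["beta"].dropna()
        assert np.allclose(a, b, atol=1e-4)

    def test_regression_analytic_concordance(self, small_cohort):
        G = small_cohort["G"].subset_samples(small_cohort["G"].sample_ancestry == "EA")
        phen = small_cohort["phen"]
        causal = np.flatnonzero(small_cohort["effects"]["EA"].to_numpy() != 0)[:40]
        Gc = G.subset_variants(causal)
        eff = small_cohort["effects"].iloc[causal].reset_index(drop=True)
        # marginal targets must use the full genetic background, so keep G full for analytic
        ss_reg = simulate_sumstats(Gc, phen, mode="regression", seed=59)
        ss_an = simulate_sumstats(
            G, phen, mode="analytic", seed=60, effects=small_cohort["effects"],
            liability=LiabilityModel(prevalence=0.2), n_analytic=G.n_samples,
        )
        merged = ss_reg.table.merge(ss_an.table, on=["chrom", "pos"], suffixes=("_r", "_a"))
        ok = np.abs(merged["beta_r"] - merged["beta_a"]) < 2 * np.sqrt(
            merged["se_r"] ** 2 + merged["se_a"] ** 2
        )
        assert ok.mean() >= 0.85

    def test_monomorphic_flagged(self, small_cohort):
        G = small_cohort["G"].subset_samples(small_cohort["G"].sample_ancestry == "EA")
        G = G.subset_variants(np.arange(5))
        G.dosages[:, 2] = 0.0  # force monomorphic
        ss = simulate_sumstats(G, small_cohort["phen"], mode="regression", seed=90)
        assert bool(ss.table["monomorphic"].iloc[2])
        assert np.isnan(ss.table["beta"].iloc[2]) and np.isnan(ss.table["se"].iloc[2])

    def test_requires_single_ancestry(self, small_cohort):
        with pytest.raises(ValueError, match="one ancestry"):
            simulate_sumstats(small_cohort["G"], small_cohort["phen"], mode="regression", seed=1)


class TestRelatedPairs:
    def _parents(self, m=500, n=200, seed=61):
        am = AncestryModel(("X",), (0.0,))
        p = draw_ancestral_frequencies(m, am, seed)
        afs = drift_frequencies(p, am, seed + 1)
        return simulate_genotypes(afs, LDBlockSpec(block_size=1), {"X": n}, seed + 2, ancestry_labels=("X",))

    def test_mendelian_zero_constraint(self):
        G = self._parents()
        G.dosages[:2, :] = 0.0
        sibs, _ = simulate_related_pairs(G.subset_samples(np.arange(G.n_samples) < 2), 1, 62)
        assert np.all(sibs.dosages == 0)

    def test_sib_genotype_correlation(self):
        # centre by the population AF profile (shared across sibs) before
        # correlating, otherwise AF variation across variants inflates r
        G = self._parents(m=10_000, n=200, seed=63)
        sibs, _ = simulate_related_pairs(G, 50, 64)
        centred = sibs.dosages - 2 * G.empirical_af()
        rs = [
            np.corrcoef(centred[2 * i], centred[2 * i + 1])[0, 1] for i in range(50)
        ]
        assert abs(np.mean(rs) - 0.5) < 0.05

    def test_kinship_table_structure(self):
        G = self._parents(n=20, seed=65)
        _, kin = simulate_related_pairs(G, 5, 66)
        assert (kin.pairs["kinship"] == 0.25).all()
        # one sib-sib entry and four parent-offspring entries per pair
        assert len(kin.pairs) == 5 * 5
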