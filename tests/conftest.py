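import numpy as np
import pandas as pd
import pytest

from multiprs import (
    AncestryModel,
    EffectModel,
    GenotypeMatrix,
    LDBlockSpec,
    LiabilityModel,
    SummaryStats,
    draw_ancestral_frequencies,
    drift_frequencies,
    draw_true_effects,
    simulate_genotypes,
    simulate_phenotypes,
)


def make_genotypes(dosages, chrom="1", start=1_000_000, spacing=10_000, ancestry="EA"):
    """Wrap a raw dosage array in a GenotypeMatrix with a synthetic variant index."""
    import warnings

    dosages = np.asarray(dosages, float)
    n, m = dosages.shape
    pos = start + np.arange(m) * spacing
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        af = np.nanmean(dosages, axis=0) / 2 if n else np.full(m, 0.5)
    af = np.nan_to_num(af, nan=0.5)
    alleles = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos.astype(np.int64),
            "id": [f"v{j}" for j in range(m)],
            "effect_allele": [alleles[j % 4][0] for j in range(m)],
            "other_allele": [alleles[j % 4][1] for j in range(m)],
            "af_EA": af,
        }
    )
    ids = np.array([f"S{i}" for i in range(n)], dtype=object)
    anc = np.array([ancestry] * n, dtype=object)
    return GenotypeMatrix(dosages, variants, ids, anc)


def make_sumstats(G, beta, se, p=None, n=1000, study_label="study"):
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    from scipy.stats import norm

    if p is None:
        p = 2 * norm.sf(np.abs(beta / se))
    t = G.variants[["chrom", "pos", "id", "effect_allele", "other_allele"]].copy()
    t["beta"] = beta
    t["se"] = se
    t["p"] = p
    t["n"] = n
    t["af"] = G.empirical_af()
    return SummaryStats(t, study_label=study_label)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest two-ancestry cohort with LD, effects and phenotypes (shared, read-only)."""
    am = AncestryModel(("EA", "AA"), (0.02, 0.1))
    ld = LDBlockSpec(block_size=10, within_block_rho=0.6, inter_variant_spacing_bp=20_000)
    p = draw_ancestral_frequencies(300, am, 11)
    afs = drift_frequencies(p, am, 12)
    G = simulate_genotypes(afs, ld, {"EA": 800, "AA": 800}, 13, ancestry_labels=am.labels)
    em = EffectModel(n_causal_fraction=0.1, heritability_liability=0.3, apoe_variant=7)
    eff = draw_true_effects(G.variants, afs, em, am.labels, 14)
    phen = simulate_phenotypes(G, eff, LiabilityModel(prevalence=0.2), 15, apoe_variant=7)
    return {"ancestry": am, "ld": ld, "afs": afs, "G": G, "effects": eff, "phen": phen, "effect_model": em}
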