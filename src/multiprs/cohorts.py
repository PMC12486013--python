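"""Synthetic multi-ancestry cohort generation.

Real AD genetics cohorts (WGS dosages, GWAS summary statistics, family
structure) are access-restricted; this module generates cohorts with the
statistical structure the downstream PRS pipeline assumes so that every
stage can be exercised and tested without any download:

* ancestry-specific allele frequencies drifted from a shared ancestral
  frequency under the Balding-Nichols Beta model,
* block-structured LD via thresholded equicorrelated latent Gaussians
  (sufficient to exercise clumping; not coalescent-grade),
* a shared spike-and-slab polygenic architecture with a tunable
  cross-ancestry effect correlation and one designated large-effect
  APOE-like variant,
* liability-threshold case/control status with age and sex effects,
* sibling/parent-offspring structure for kinship filtering, and
* per-study GWAS summary statistics (exact per-variant logistic fits, or a
  fast analytic emulation for large n).

All generators are deterministic under a fixed integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._liability import liability_threshold, logistic_slope_from_liability

__all__ = [
    "AncestryModel",
    "LDBlockSpec",
    "EffectModel",
    "LiabilityModel",
    "GenotypeMatrix",
    "CohortPhenotypes",
    "KinshipTable",
    "draw_ancestral_frequencies",
    "drift_frequencies",
    "simulate_genotypes",
    "draw_true_effects",
    "simulate_phenotypes",
    "simulate_sumstats",
    "simulate_related_pairs",
]

N_PCS = 10
_ALLELES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class AncestryModel:
    """Labelled ancestry groups and their Balding-Nichols drift coefficients."""

    labels: tuple[str, ...] = ("EA", "AA")
    fst_per_ancestry: tuple[float, ...] = (0.01, 0.1)
    ancestral_af_range: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("ancestry labels must be unique")
        if len(self.fst_per_ancestry) != len(self.labels):
            raise ValueError("need one Fst per ancestry label")
        for f in self.fst_per_ancestry:
            if not 0.0 <= f < 1.0:
                raise ValueError(f"Fst must lie in [0,1), got {f}")
        lo, hi = self.ancestral_af_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError(f"ancestral AF range must satisfy 0 < low <= high < 1, got {self.ancestral_af_range}")


@dataclass(frozen=True)
class LDBlockSpec:
    """Block-constant latent correlation defining synthetic LD structure."""

    block_size: int = 20
    within_block_rho: float = 0.7
    inter_variant_spacing_bp: int = 5_000

    def __post_init__(self) -> None:
        if self.block_size < 1:
            raise ValueError("block_size must be positive")
        if not 0.0 <= self.within_block_rho < 1.0:
            raise ValueError("within_block_rho must lie in [0,1)")
        if self.inter_variant_spacing_bp < 1:
            raise ValueError("inter_variant_spacing_bp must be positive")


@dataclass(frozen=True)
class EffectModel:
    """Polygenic architecture: causal fraction, liability h2, cross-ancestry correlation."""

    n_causal_fraction: float = 0.1
    heritability_liability: float = 0.3
    cross_ancestry_corr: float = 0.5
    apoe_like_effect: float = 0.5
    apoe_variant: int = 0  # column index of the designated large-effect variant

    def __post_init__(self) -> None:
        if not 0.0 < self.n_causal_fraction <= 1.0:
            raise ValueError("n_causal_fraction must lie in (0,1]")
        if not 0.0 <= self.heritability_liability < 1.0:
            raise ValueError("heritability must lie in [0,1)")
        if not -1.0 <= self.cross_ancestry_corr <= 1.0:
            raise ValueError("cross_ancestry_corr must lie in [-1,1]")


@dataclass(frozen=True)
class LiabilityModel:
    """Liability-threshold case/control generating process with age and sex effects."""

    prevalence: float = 0.2
    age_effect: float = 0.1
    sex_effect: float = 0.05
    age_distribution: tuple[float, float] = (75.0, 8.0)
    age_bounds: tuple[float, float] = (60.0, 95.0)
    apoe_e2_freq: float = 0.08
    apoe_e2_effect: float = -0.3

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie strictly in (0,1)")


@dataclass
class GenotypeMatrix:
    """Samples x variants effect-allele dosage matrix with a variant index.

    ``dosages`` holds values in [0,2] (NaN = missing); ``variants`` is a frame
    with columns chrom, pos, id, effect_allele, other_allele and one
    ``af_<ancestry>`` column per ancestry.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sample_ids: np.ndarray
    sample_ancestry: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.sample_ancestry = np.asarray(self.sample_ancestry, dtype=object)
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.variants) != m:
            raise ValueError("variant index length does not match dosage columns")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def empirical_af(self) -> np.ndarray:
        """Effect-allele frequency from the observed dosages (missing ignored)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def subset_samples(self, mask_or_ids) -> "GenotypeMatrix":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            wanted = set(mask_or_ids)
            idx = np.flatnonzero([s in wanted for s in self.sample_ids])
        return GenotypeMatrix(
            self.dosages[idx], self.variants.copy(), self.sample_ids[idx], self.sample_ancestry[idx]
        )

    def subset_variants(self, col_idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[:, col_idx],
            self.variants.iloc[col_idx].reset_index(drop=True),
            self.sample_ids,
            self.sample_ancestry,
        )


@dataclass
class CohortPhenotypes:
    """Per-sample phenotypes and covariates (one row per sample)."""

    table: pd.DataFrame  # sample_id, ad_status, age, sex, apoe_e4_count, apoe_e2_count,
    #                      cohort_label, ancestry, pc1..pc10, liability_true

    def __post_init__(self) -> None:
        required = {"sample_id", "ad_status", "age", "sex", "apoe_e4_count", "apoe_e2_count"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in phenotype table")
        if ((self.table["apoe_e4_count"] + self.table["apoe_e2_count"]) > 2).any():
            raise ValueError("APOE e4+e2 allele counts exceed 2")

    @property
    def sample_ids(self) -> np.ndarray:
        return self.table["sample_id"].to_numpy()

    def aligned_to(self, sample_ids) -> pd.DataFrame:
        return self.table.set_index("sample_id").loc[list(sample_ids)].reset_index()


@dataclass
class KinshipTable:
    """Sparse symmetric kinship coefficients; absent pairs are 0."""

    pairs: pd.DataFrame  # sample_i, sample_j, kinship

    def __post_init__(self) -> None:
        if len(self.pairs) == 0:
            self.pairs = pd.DataFrame(columns=["sample_i", "sample_j", "kinship"])
            return
        if (self.pairs["sample_i"] == self.pairs["sample_j"]).any():
            raise ValueError("kinship table contains self-pairs")
        if (self.pairs["kinship"] < 0).any() or (self.pairs["kinship"] > 0.5).any():
            raise ValueError("kinship coefficients must lie in [0, 0.5]")

    @classmethod
    def empty(cls) -> "KinshipTable":
        return cls(pd.DataFrame(columns=["sample_i", "sample_j", "kinship"]))

    def pairs_at_or_above(self, threshold: float) -> pd.DataFrame:
        return self.pairs[self.pairs["kinship"] >= threshold]


# ---------------------------------------------------------------------------
# frequency generation


def draw_ancestral_frequencies(m_variants: int, model: AncestryModel, seed: int) -> np.ndarray:
    """Draw per-variant ancestral allele frequencies uniform on the model's range."""
    if m_variants < 1:
        raise ValueError("m_variants must be >= 1")
    lo, hi = model.ancestral_af_range
    rng = np.random.default_rng(seed)
    return rng.uniform(lo, hi, size=m_variants)


def drift_frequencies(ancestral_afs: np.ndarray, model: AncestryModel, seed: int) -> np.ndarray:
    """Balding-Nichols drift: per-ancestry AFs ~ Beta(p(1-F)/F, (1-p)(1-F)/F).

    Returns an (n_ancestries, m) matrix; F=0 reproduces the ancestral AFs
    exactly (no drift). Moments: E[AF] = p, Var[AF] = F * p * (1-p).
    """
    p = np.asarray(ancestral_afs, float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("ancestral AFs must lie strictly in (0,1)")
    rng = np.random.default_rng(seed)
    out = np.empty((len(model.labels), len(p)))
    for k, f in enumerate(model.fst_per_ancestry):
        if f == 0.0:
            out[k] = p
        else:
            a = p * (1 - f) / f
            b = (1 - p) * (1 - f) / f
            out[k] = np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)
    return out


def _make_variant_index(
    m: int, afs: np.ndarray, labels: tuple[str, ...], ld: LDBlockSpec, rng: np.random.Generator,
    chrom: str, start_bp: int,
) -> pd.DataFrame:
    pos = start_bp + np.arange(m) * ld.inter_variant_spacing_bp
    ea_idx = rng.integers(0, 4, size=m)
    oa_idx = (ea_idx + rng.integers(1, 4, size=m)) % 4
    # avoid strand-ambiguous (palindromic) pairs: harmonization would drop them
    comp = np.array([3, 2, 1, 0])  # A<->T, C<->G under _ALLELES order
    pal = oa_idx == comp[ea_idx]
    while pal.any():
        oa_idx[pal] = (ea_idx[pal] + rng.integers(1, 4, size=int(pal.sum()))) % 4
        pal = oa_idx == comp[ea_idx]
    frame = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos.astype(np.int64),
            "id": [f"{chrom}:{p}" for p in pos],
            "effect_allele": _ALLELES[ea_idx],
            "other_allele": _ALLELES[oa_idx],
        }
    )
    for k, lab in enumerate(labels):
        frame[f"af_{lab}"] = afs[k]
    return frame


def simulate_genotypes(
    afs: np.ndarray,
    ld: LDBlockSpec,
    n_per_ancestry: dict[str, int],
    seed: int,
    ancestry_labels: tuple[str, ...] | None = None,
    chrom: str = "1",
    start_bp: int = 1_000_000,
    id_prefix: str = "S",
    variant_index: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Simulate hard-call dosages with block-equicorrelated latent-Gaussian LD.

    Per haplotype, a latent standard normal with block-constant correlation
    rho is thresholded at the ancestry AF quantile; the dosage is the sum of
    two independent haplotypes.  Within-block dosage r2 increases with rho
    and is ~0 across blocks.
    """
    afs = np.atleast_2d(np.asarray(afs, float))
    if np.any(afs <= 0) or np.any(afs >= 1):
        raise ValueError("allele frequencies must lie strictly in (0,1)")
    n_anc, m = afs.shape
    if ancestry_labels is None:
        ancestry_labels = tuple(sorted(n_per_ancestry))
    if len(ancestry_labels) != n_anc:
        raise ValueError("one AF row per ancestry label required")
    rng = np.random.default_rng(seed)
    rho = ld.within_block_rho
    block_of = np.arange(m) // ld.block_size
    n_blocks = int(block_of.max()) + 1

    dosage_parts, id_parts, anc_parts = [], [], []
    counter = 0
    for k, lab in enumerate(ancestry_labels):
        n = int(n_per_ancestry[lab])
        if n == 0:
            continue
        thresh = norm.ppf(afs[k])  # allele carried when latent < threshold
        dos = np.zeros((n, m), dtype=np.float64)
        for _hap in range(2):
            shared = rng.standard_normal((n, n_blocks))[:, block_of]
            latent = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal((n, m))
            dos += latent < thresh
        dosage_parts.append(dos)
        id_parts.append([f"{id_prefix}{lab}{counter + i:06d}" for i in range(n)])
        anc_parts.append([lab] * n)
        counter += n

    dosages = np.vstack(dosage_parts) if dosage_parts else np.zeros((0, m))
    sample_ids = np.array(sum(id_parts, []), dtype=object)
    ancestry = np.array(sum(anc_parts, []), dtype=object)
    if variant_index is not None:
        if len(variant_index) != m:
            raise ValueError("supplied variant_index length does not match the AF matrix")
        variants = variant_index.copy()
    else:
        variants = _make_variant_index(m, afs, ancestry_labels, ld, rng, chrom, start_bp)
    return GenotypeMatrix(dosages, variants, sample_ids, ancestry)


# ---------------------------------------------------------------------------
# effects and phenotypes


def draw_true_effects(
    variant_index: pd.DataFrame,
    afs: np.ndarray,
    model: EffectModel,
    ancestry_labels: tuple[str, ...],
    seed: int,
) -> pd.DataFrame:
    """Draw per-ancestry liability-scale effect vectors (spike-and-slab).

    The causal set is shared across ancestries; causal effects are jointly
    normal across ancestries with equicorrelation ``cross_ancestry_corr``,
    and each ancestry's vector is rescaled so its realized liability genetic
    variance (under Hardy-Weinberg with that ancestry's AFs) equals h2.  The
    designated APOE-like variant receives ``apoe_like_effect`` everywhere.
    """
    m = len(variant_index)
    afs = np.atleast_2d(afs)
    k_anc = len(ancestry_labels)
    if not 0 <= model.apoe_variant < m:
        raise ValueError("designated APOE-like variant is outside the variant index")
    rng = np.random.default_rng(seed)
    betas = np.zeros((m, k_anc))
    h2 = model.heritability_liability
    if h2 > 0:
        pool = np.setdiff1d(np.arange(m), [model.apoe_variant])  # APOE effect is set separately
        n_causal = max(1, min(len(pool), round(model.n_causal_fraction * m)))
        causal = rng.choice(pool, size=n_causal, replace=False)
        rho = model.cross_ancestry_corr
        if k_anc > 1 and rho < -1.0 / (k_anc - 1):
            raise ValueError("cross_ancestry_corr below the equicorrelation feasibility bound")
        if rho >= 0:  # exact factor construction: rho=1 gives identical vectors
            common = rng.standard_normal((n_causal, 1))
            idio = rng.standard_normal((n_causal, k_anc))
            raw = np.sqrt(rho) * common + np.sqrt(1 - rho) * idio
        else:
            corr = np.full((k_anc, k_anc), rho)
            np.fill_diagonal(corr, 1.0)
            raw = rng.standard_normal((n_causal, k_anc)) @ np.linalg.cholesky(corr).T
        # one common scale (ancestry-averaged genetic variance): keeps
        # perfectly correlated architectures identical across ancestries
        gvars = [
            np.sum(raw[:, a] ** 2 * 2 * afs[a, causal] * (1 - afs[a, causal])) for a in range(k_anc)
        ]
        gvar = float(np.mean(gvars))
        if gvar <= 0:
            raise ValueError("h2 infeasible: no genetic variance among causal variants")
        betas[causal, :] = raw * np.sqrt(h2 / gvar)
    betas[model.apoe_variant, :] = model.apoe_like_effect
    out = pd.DataFrame(betas, columns=list(ancestry_labels))
    out.insert(0, "id", variant_index["id"].to_numpy())
    return out


def simulate_phenotypes(
    G: GenotypeMatrix,
    effects: pd.DataFrame,
    liability: LiabilityModel,
    seed: int,
    cohort_label: str = "synthetic",
    apoe_variant: int | None = None,
) -> CohortPhenotypes:
    """Liability-threshold phenotypes: genetic score + age + sex + residual.

    The residual variance is set to one minus the realized variance of the
    systematic components (floored at 0.05), so the total liability variance
    is ~1 and the case fraction is binomial around the stated prevalence.
    ``apoe_e4_count`` is the rounded dosage of the designated APOE-like
    variant (``apoe_variant``; when None, the variant with the largest
    effect shared by every ancestry is used).
    """
    rng = np.random.default_rng(seed)
    anc_cols = [c for c in effects.columns if c != "id"]
    n = G.n_samples
    beta_by_anc = {a: effects[a].to_numpy() for a in anc_cols}

    dos = np.nan_to_num(G.dosages, nan=0.0)
    g = np.zeros(n)
    for a in anc_cols:
        mask = G.sample_ancestry == a
        if mask.any():
            g[mask] = dos[mask] @ beta_by_anc[a]
    g = g - g.mean() if n > 0 else g

    mu, sd = liability.age_distribution
    lo, hi = liability.age_bounds
    age = np.clip(rng.normal(mu, sd, size=n), lo, hi)
    age_z = (age - age.mean()) / (age.std() if age.std() > 0 else 1.0)
    sex = rng.integers(0, 2, size=n).astype(float)
    e2 = rng.binomial(2, liability.apoe_e2_freq, size=n).astype(float)

    systematic = (
        g
        + liability.age_effect * age_z
        + liability.sex_effect * (sex - sex.mean())
        + liability.apoe_e2_effect * (e2 - e2.mean())
    )
    var_sys = systematic.var() if n > 1 else 0.0
    var_e = max(1.0 - var_sys, 0.05)
    sd_e = np.sqrt(var_e)
    lia = systematic + rng.normal(0.0, sd_e, size=n)
    # The systematic component is not exactly Gaussian (dosage terms are
    # discrete), so the threshold is solved under its realized distribution:
    # mean_i P(e > t - sys_i) = prevalence, keeping the case fraction
    # unbiased (binomial around the prevalence) rather than forced in-sample.
    if n > 0:
        from scipy.optimize import brentq

        lo = systematic.min() - 8 * sd_e
        hi = systematic.max() + 8 * sd_e
        t = brentq(lambda x: norm.sf((x - systematic) / sd_e).mean() - liability.prevalence, lo, hi)
    else:
        t = liability_threshold(liability.prevalence)
    status = (lia > t).astype(int)

    if apoe_variant is None:
        shared = np.abs(np.column_stack([beta_by_anc[a] for a in anc_cols])).min(axis=1)
        apoe_idx = int(np.argmax(shared))
    else:
        apoe_idx = int(apoe_variant)
    e4 = np.clip(np.round(np.nan_to_num(G.dosages[:, apoe_idx], nan=0.0)), 0, 2)
    e2 = np.minimum(e2, 2 - e4)  # joint consistency: at most 2 APOE alleles

    pcs = rng.normal(0.0, 0.3, size=(n, N_PCS))
    for j, a in enumerate(anc_cols[:-1]):
        pcs[:, j] += 2.0 * (G.sample_ancestry == a)

    table = pd.DataFrame(
        {
            "sample_id": G.sample_ids,
            "ad_status": status,
            "age": age,
            "sex": sex,
            "apoe_e4_count": e4.astype(int),
            "apoe_e2_count": e2.astype(int),
            "cohort_label": cohort_label,
            "ancestry": G.sample_ancestry,
            "liability_true": lia,
        }
    )
    for j in range(N_PCS):
        table[f"pc{j + 1}"] = pcs[:, j]
    return CohortPhenotypes(table)


# ---------------------------------------------------------------------------
# summary statistics


def _logistic_scan(dos: np.ndarray, y: np.ndarray, covars: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant logistic regression of y on dosage + covariates (Newton)."""
    import statsmodels.api as sm

    n, m = dos.shape
    betas = np.full(m, np.nan)
    ses = np.full(m, np.nan)
    base = np.column_stack([np.ones(n), covars])
    for j in range(m):
        x = dos[:, j]
        if np.nanstd(x) == 0:
            continue
        X = np.column_stack([base, x])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=50)
            betas[j] = res.params[-1]
            ses[j] = res.bse[-1]
        except Exception:
            continue
    return betas, ses


def simulate_sumstats(
    G: GenotypeMatrix,
    phen: CohortPhenotypes,
    mode: str = "regression",
    seed: int = 0,
    study_label: str = "synthetic_gwas",
    effects: pd.DataFrame | None = None,
    liability: LiabilityModel | None = None,
    n_analytic: int | None = None,
):
    """GWAS summary statistics for one ancestry group.

    ``regression`` fits per-variant logistic regressions of case status on
    dosage, age and sex and reports the Wald statistics.  ``analytic`` skips
    the fits: it computes each variant's true marginal liability slope from
    the realized genotypes and effect vector, maps it to the logistic scale
    numerically, and draws beta ~ Normal(target, se) with
    se = 1/sqrt(n * 2*AF*(1-AF) * v), v = K(1-K) the Bernoulli variance of
    the case fraction — a fast large-n emulation that ignores LD-induced
    correlation between the estimates (downstream clumping de-correlates).
    """
    from .sumstats import SummaryStats

    anc = set(G.sample_ancestry)
    if len(anc) > 1:
        raise ValueError(f"simulate_sumstats expects one ancestry per call, got {sorted(anc)}")
    ancestry_label = next(iter(anc)) if anc else "NA"
    ph = phen.aligned_to(G.sample_ids)
    y = ph["ad_status"].to_numpy(float)
    af = G.empirical_af()
    mono = (af <= 0) | (af >= 1) | ~np.isfinite(af)

    if mode == "regression":
        age_z = (ph["age"] - ph["age"].mean()) / max(ph["age"].std(), 1e-9)
        covars = np.column_stack([age_z.to_numpy(), ph["sex"].to_numpy(float)])
        dos = np.nan_to_num(G.dosages, nan=0.0)
        beta, se = _logistic_scan(dos, y, covars)
        n_eff = np.full(G.n_variants, G.n_samples)
    elif mode == "analytic":
        if effects is None or liability is None:
            raise ValueError("analytic mode requires the true effect frame and liability model")
        rng = np.random.default_rng(seed)
        beta_vec = effects[ancestry_label].to_numpy()
        dos = np.nan_to_num(G.dosages, nan=0.0)
        g = dos @ beta_vec
        gc = g - g.mean()
        dc = dos - dos.mean(axis=0)
        var_d = dc.var(axis=0)
        n_used = int(n_analytic or G.n_samples)
        kprev = liability.prevalence
        v = kprev * (1 - kprev)
        beta = np.full(G.n_variants, np.nan)
        se = np.full(G.n_variants, np.nan)
        for j in range(G.n_variants):
            if mono[j] or var_d[j] <= 0:
                continue
            alpha = float(dc[:, j] @ gc) / (len(gc) * var_d[j])
            p = af[j]
            hw = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
            cap = 0.95 / np.sqrt(max(var_d[j], 1e-9))
            alpha = float(np.clip(alpha, -cap, cap))
            target = logistic_slope_from_liability(alpha, np.array([0.0, 1.0, 2.0]), hw, kprev)
            se[j] = 1.0 / np.sqrt(n_used * 2 * p * (1 - p) * v)
            beta[j] = target + rng.normal(0.0, se[j])
        n_eff = np.full(G.n_variants, n_used)
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'regression' or 'analytic'")

    flagged = mono | ~np.isfinite(beta)
    beta = np.where(flagged, np.nan, beta)
    se = np.where(flagged, np.nan, se)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = 2 * norm.sf(np.abs(beta / se))
    table = G.variants[["chrom", "pos", "id", "effect_allele", "other_allele"]].copy()
    table["beta"] = beta
    table["se"] = se
    table["p"] = np.clip(p, np.nextafter(0, 1), 1.0)
    table["n"] = n_eff
    table["af"] = af
    table["monomorphic"] = mono
    return SummaryStats(table=table, study_label=study_label, ancestry_label=ancestry_label)


# ---------------------------------------------------------------------------
# relatedness


def simulate_related_pairs(
    G_parents: GenotypeMatrix, n_pairs: int, seed: int, id_prefix: str = "SIB"
) -> tuple[GenotypeMatrix, KinshipTable]:
    """Sibling pairs by Mendelian transmission from disjoint parent couples.

    Returns the offspring genotype matrix (two sibs per couple) and a
    kinship table with 0.25 for sib-sib and parent-offspring pairs.
    """
    dos = G_parents.dosages
    if np.any(~np.isin(np.nan_to_num(dos, nan=0.0), (0.0, 1.0, 2.0))):
        raise ValueError("parents must carry hard-call dosages in {0,1,2}")
    rng = np.random.default_rng(seed)
    n_parents = G_parents.n_samples
    if 2 * n_pairs > n_parents:
        raise ValueError("not enough parents for the requested number of sib pairs")
    order = rng.permutation(n_parents)[: 2 * n_pairs]
    kids, kid_ids, kid_anc, rows = [], [], [], []
    for i in range(n_pairs):
        pa, ma = order[2 * i], order[2 * i + 1]
        prob_pa, prob_ma = dos[pa] / 2.0, dos[ma] / 2.0
        sib_ids = [f"{id_prefix}{2 * i}", f"{id_prefix}{2 * i + 1}"]
        for s in range(2):
            child = rng.binomial(1, prob_pa) + rng.binomial(1, prob_ma)
            kids.append(child.astype(float))
            kid_ids.append(sib_ids[s])
            kid_anc.append(G_parents.sample_ancestry[pa])
            for parent in (pa, ma):
                rows.append((str(G_parents.sample_ids[parent]), sib_ids[s], 0.25))
        rows.append((sib_ids[0], sib_ids[1], 0.25))
    offspring = GenotypeMatrix(
        np.vstack(kids) if kids else np.zeros((0, G_parents.n_variants)),
        G_parents.variants.copy(),
        np.array(kid_ids, dtype=object),
        np.array(kid_anc, dtype=object),
    )
    kin = KinshipTable(pd.DataFrame(rows, columns=["sample_i", "sample_j", "kinship"]))
    return offspring, kin
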