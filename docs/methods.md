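# Methods

`multiprs` implements a multi-ancestry polygenic risk score (PRS) workflow
for case/control phenotypes of the kind used in Alzheimer disease (AD)
genetics: per-study PRS construction by clumping + thresholding (C+T) with
coefficient-of-variation model selection, fixed-effects meta-analysis of
GWAS summary statistics, three multi-study combination strategies,
APOE-region exclusion, train-referenced standardization, and association /
discrimination evaluation. Because the cohorts such workflows run on are
access-restricted, the package ships a first-class synthetic-cohort
generator that reproduces the statistical structure the pipeline assumes;
everything downstream is exercised and tested against it.

## The synthetic cohort model

**Allele frequencies.** Ancestral frequencies are uniform on a configurable
range (default 0.05–0.95). Ancestry-specific frequencies follow the
Balding–Nichols model: `AF_k ~ Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k)` for
drift coefficient `F_k ∈ [0,1)` per ancestry (defaults 0.01 for the
European-like and 0.1 for the African-like group), giving `E[AF]=p` and
`Var[AF]=F·p(1−p)`; `F=0` is handled as the identity.

**LD.** Per haplotype a latent Gaussian with block-constant correlation ρ
(default 0.7 over 20-variant blocks) is thresholded at the AF quantile;
dosage is the sum of two haplotypes. This produces within-block dosage r²
increasing in ρ and ≈0 across blocks — sufficient to exercise greedy
clumping, deliberately not coalescent-grade: no recombination gradients, no
allele-frequency–dependent LD, no admixture tracts. Variant indices (chrom,
pos, alleles) are drawn once per study and shared by every cohort, as
harmonized real studies would be; strand-ambiguous (A/T, C/G) pairs are not
generated because harmonization would drop them anyway.

**Effects.** A spike-and-slab architecture: a causal subset (default 10% of
variants) shared across ancestries, with effects jointly Gaussian across
ancestries under an equicorrelation structure (default cross-ancestry
correlation 0.5; correlation 1 yields exactly identical vectors via a
common-factor construction). One global scale sets the ancestry-averaged
liability genetic variance to h² (default 0.3), so perfectly correlated
architectures stay identical across ancestries; per-ancestry realized h²
then varies slightly with heterozygosity. One designated APOE-like variant
receives a fixed liability effect (default 0.5) in every ancestry, on top
of the polygenic budget; it is excluded from the causal pool so h² refers
to the polygenic background, matching the convention of reporting
APOE-independent polygenic risk. ε4 counts are the rounded dosage of that
variant; ε2 counts are drawn independently (frequency 0.08) with a
protective liability effect (default −0.3), truncated so ε4+ε2 ≤ 2.

**Phenotypes.** Liability = centred genetic score + age and sex effects +
Gaussian residual. The residual variance is 1 minus the realized variance
of the systematic components (floored at 0.05) so total variance ≈ 1. The
systematic part is not exactly Gaussian (dosage terms are discrete), so the
case threshold is solved numerically from
`mean_i P(e > t − sys_i) = prevalence` rather than taken as Φ⁻¹(1−K); the
case fraction is then unbiased and binomial around the prevalence without
in-sample forcing. Ages are normal (mean 75, sd 8) truncated to [60, 95],
matching the age-60+ analyses the workflow targets.

**Summary statistics.** `regression` mode fits per-variant logistic
regressions of status on dosage + age + sex (exact but O(m) fits).
`analytic` mode emulates a large-n GWAS: each variant's marginal liability
slope is computed from the realized genotypes and effects, mapped to the
logistic scale by numerically fitting a logistic curve to the
liability-implied case probabilities over the Hardy–Weinberg dosage
distribution, and the estimate is drawn `beta ~ N(target, se)` with
`se = 1/sqrt(n · 2·AF(1−AF) · v)`, `v = K(1−K)` the Bernoulli variance of
the case fraction. Analytic mode ignores LD-induced correlation between
marginal estimates; this is acceptable downstream because clumping
de-correlates the retained variants.

**Relatedness.** Sibling pairs are built by Mendelian transmission from
disjoint parent couples; the kinship table records 0.25 for sib–sib and
parent–offspring pairs. This exists to exercise the kinship < 0.04
unrelated-subset filter, not to model realistic pedigrees.

## The pipeline

**QC.** Variants with MAF ≤ 0.01 (boundary exclusionary) or missingness
> 1% are removed. Harmonization matches on (chrom, pos), flips beta and
reflects AF for swapped alleles, and drops palindromic, incompatible and
unmatched records with per-reason counts; it is idempotent. rsIDs are
annotation only — positions are the key.

**Meta-analysis.** Inverse-variance fixed effects:
`beta* = Σ(beta_i/se_i²)/Σ(1/se_i²)`, `se* = (Σ 1/se_i²)^(−1/2)`, two-sided
normal p, `n* = Σn_i`, n-weighted AF. Variants present in ≥1 study are
included; no heterogeneity statistics, no random effects.

**C+T.** Greedy clumping: repeatedly index the smallest-p unclumped variant
(ties by chrom, then position — deterministic across platforms), removing
unclumped variants within the window (center-to-center, PLINK convention)
whose dosage r² with the index exceeds the threshold. Monomorphic variants
have undefined r², treated as 0 with a warning. The default grid is
R² ∈ {0.1, 0.2, 0.3} × windows {100, 250, 500} kb × the 8-point p-ladder
{5e−8, 1e−6, 1e−4, 1e−3, 0.01, 0.05, 0.1, 0.5} (the ladder interpolates the
conventional 5×10⁻⁸–0.5 span and is fully configurable). Candidate
selection splits the unrelated tuning samples into k=5 random subsets and
takes the candidate minimizing cv = sd/|mean| of the per-subset logistic
PRS effects (covariates: age, sex, APOE ε4/ε2 counts, 10 PCs — mirroring
the weight-training model). |mean| keeps cv sign-free: candidates whose
effect sign is unstable get large cv and lose.

**Combination.** Per-source PRSs are standardized against the evaluation
cohort (the study's scaling reference). Strategies: (1) meta-first —
meta-analyze, then C+T; (2) unweighted — sum of standardized source PRSs;
(3) weighted — `Σ w_k·PRS_k` with `w_k` the PRS coefficient from a logistic
regression of status on each source PRS in an independent training cohort
(covariates: age, sex, ancestry and cohort dummies, 10 PCs, ε4/ε2 counts).
The default is one marginal regression per source; a joint mode enters all
sources together and reports near-collinearity (condition number of the
standardized source block) in the fit metadata. Negative weights pass
through. The weighted model collapses to one per-variant table
(`Σ_k w_k·β_jk/sd_k`), which reproduces the weighted combination up to an
additive constant — verified to machine precision — so a single exportable
weight table plus a frozen scaling reference transfers the score to
external cohorts.

**APOE masking.** `mask_region` removes weight-table variants within a
flank (default ±1 Mb) of a region, default GRCh38 chr19:44,905,791–
44,909,393. "Within 1 Mb of the region" is read as a ±1 Mb flank; a
centered 1 Mb total window is expressible by passing the appropriate region
and flank. Coordinates are 1-based inclusive throughout.

**Evaluation.** Plain logistic regression (IRLS, tol 1e−8, ≤100
iterations via statsmodels GLM) on the unrelated subset (greedy removal of
highest-degree individuals at kinship ≥ 0.04, with a re-add pass ensuring
maximality), reporting OR per SD with Wald 95% CI and two-sided Wald p.
Separation and non-convergence are hard errors (no Firth fallback). AUC is
the Mann–Whitney statistic (midranks for ties) of the fitted model
probabilities, with a score-only variant available. Mixed models with
kinship random effects are out of scope; the unrelated-subset route used
for AUC is extended to estimation, and results carry that note in their
metadata. Stratified analyses (sex, APOE genotype with ε2/ε2+ε2/ε3 pooled,
ancestry) drop the stratification covariate within strata and skip strata
missing an outcome class. Model ranking is AUC (desc) → OR per SD (desc) →
p (asc) → label; the three criteria needed a deterministic resolution
order and AUC-first is the recorded choice.

**Orchestration.** `run_training_data`/`run_validation_data` operate on
in-memory cohorts; `run_training`/`run_validation` wrap them with
YAML-configured file IO (explicit integer seeds required; configs are
validated by explicit field checks). Cohorts must be disjoint by sample id
(hard error). Every run writes a manifest with seeds, parameters, input
and artifact hashes; reruns are byte-identical. Validation applies the
frozen collapsed table and scaling only — the API offers no path to refit
scaling on validation data.

## Problem sizes in the shipped checks

Default tests and the acceptance script use scaled-down study sizes chosen
to keep the full statistical structure while running on a laptop: m =
120–2000 variants, cohorts of 800–20,000 samples, 2 ancestries, 4 GWAS
sources. These are the package's own simulation conditions; ORs and AUCs
they produce describe the synthetic architecture (h² 0.3–0.4 over a few
hundred causal variants), not any real cohort — with so few variants each
retained variant carries more signal than in a genome-wide score, so
synthetic ORs run higher than published AD values.

## What the synthetic results do and do not show

Passing tests demonstrate algorithmic correctness (oracle equivalence for
clumping, AUC, meta-analysis, scoring and collapse), statistical
calibration (type-I error, null p-value uniformity), recovery of known
summation weights, and the integrity of the frozen-weight transfer
contract. They do not demonstrate real-data performance: the generator has
no coalescent LD, no admixture, no genotyping error, no phenotype
misclassification, and its effect-size distribution is Gaussian rather
than the heavy-tailed mixtures real GWAS suggest.

## Known limitations

- Liability-scale ↔ logistic-scale mapping is numeric but assumes a
  Gaussian predictor and residual; extreme architectures (few huge
  effects) would bias the analytic GWAS mode.
- No sample-overlap correction in meta-analysis (sources are assumed
  non-overlapping) and no genomic control.
- Kinship handling is subtractive (unrelated subset), never model-based.
- The C+T reference panel is used as-is; no shrinkage of the LD estimate.
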