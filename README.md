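# multiprs

Multi-ancestry polygenic risk score (PRS) construction, combination and
evaluation for case/control phenotypes, built around the workflow used for
APOE-independent Alzheimer disease risk scores: several ancestry-specific
GWAS feed per-study scores, which are merged into one portable score and
carried, with frozen weights and scaling, into independent cohorts.

It is a library first (``import multiprs``), with short narrative scripts
under ``examples/`` and a thin ``multiprs`` command-line wrapper for the
file-driven steps.

## What it computes

* **C+T construction** — greedy LD clumping over a cohort reference panel
  (grid: R² ∈ {0.1, 0.2, 0.3}, windows {100, 250, 500} kb, p-thresholds
  5×10⁻⁸ … 0.5), with the winning candidate chosen by the coefficient of
  variation sd/|mean| of its association effect across k=5 random unrelated
  tuning subsets.
* **Fixed-effects meta-analysis** of harmonized summary statistics:
  β\* = Σ(β_i/se_i²)/Σ(1/se_i²), se\* = (Σ1/se_i²)^(−1/2).
* **Three combination strategies** — meta-analysis-first, unweighted
  summation PRS₁+…+PRS₄, and weighted summation w₁·PRS₁+…+w₄·PRS₄ with the
  w_k trained by logistic regression in an independent cohort (age, sex,
  ancestry, cohort, 10 PCs and APOE ε4/ε2 as covariates). The weighted
  model collapses to a single per-variant weight table that reproduces the
  combination exactly (up to centering).
* **APOE-region exclusion** — mask variants within ±1 Mb of the APOE
  coding region (GRCh38 chr19:44,905,791–44,909,393 by default) to isolate
  polygenic background from the dominant APOE signal.
* **Evaluation** — OR per 1 SD of the standardized PRS with Wald 95% CI
  and p from logistic regression on an unrelated subset (kinship < 0.04),
  Mann–Whitney AUC, stratified analyses (sex, APOE genotype, ancestry) and
  AUC→OR→p model ranking.
* **Synthetic multi-ancestry cohorts** — Balding–Nichols allele-frequency
  drift, block-LD genotypes, correlated cross-ancestry effects with an
  APOE-like locus, liability-threshold case/control status, sibling
  structure and per-study GWAS summary statistics, so the whole pipeline
  runs and is tested without access-restricted data.

## Worked example

```sh
python examples/03_full_pipeline.py
```

builds a two-ancestry study (300 variants, four GWAS sources), runs all
three strategies and validates the frozen score in a held-out cohort:

```
strategy ranking (AUC -> OR -> p):
  weighted   OR/SD= 2.91 (95% CI 2.60-3.27)  AUC=0.899  p=4.57e-74
  meta       OR/SD= 2.43 (95% CI 2.20-2.68)  AUC=0.897  p=4.56e-70
  unweighted OR/SD= 2.61 (95% CI 2.33-2.92)  AUC=0.894  p=3.15e-61
selected: weighted; summation weights: {'EADB': 1.251, 'EAS': 0.524, 'FinnGen': 1.268, 'MVP': 0.703}
validation [all    ] OR/SD= 3.27 AUC=0.899 (n=619+2381)
validation [female ] OR/SD= 2.88 AUC=0.892 (n=326+1146)
validation [male   ] OR/SD= 3.82 AUC=0.906 (n=293+1235)
```

The OR per SD is the odds ratio for one standard deviation of the
standardized score; the validation rows show the frozen collapsed weights
and scaling transferring to an independent cohort within sampling error.
(ORs are large because the synthetic architecture packs h²≈0.4 into a few
hundred variants; see `docs/methods.md`.)

Other examples: `01_simulate_cohorts.py` (generator calibration),
`02_clump_threshold_select.py` (the C+T grid and CV selection).

## Command line

```sh
multiprs simulate --seed 1 --out study/          # synthetic study to TSV/VCF
multiprs meta --in a.tsv --in b.tsv --ref ref.tsv --out meta.tsv
multiprs ct --sumstats s.tsv --ref-geno ref.tsv --tune-geno t.tsv \
            --tune-pheno p.tsv --seed 1 --out ct/
multiprs score --geno g.tsv --weights w.tsv --mask --out prs.tsv
multiprs train-sum --prs-matrix m.tsv --pheno p.tsv --out model.json
multiprs apply-sum --model model.json --prs-matrix m.tsv --out prs.tsv
multiprs evaluate --prs prs.tsv --pheno p.tsv --stratify sex,apoe --out results/
multiprs run-training --config pipeline.yaml
multiprs run-validation --config pipeline.yaml
```

Weight tables use the PGS-Catalog-compatible TSV header (CHR, POS, ID, EA,
OA, WEIGHT), so published scoring files can be applied directly.
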