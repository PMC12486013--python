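"""Simulate a small multi-ancestry study: cohorts, kinship and GWAS sumstats.

Builds a two-ancestry synthetic study (drifted allele frequencies, block LD,
a shared polygenic architecture with an APOE-like large-effect variant,
liability-threshold AD status) and prints the basic calibration numbers.
"""

import numpy as np

from multiprs import StudyDesign, simulate_study

design = StudyDesign(m_variants=300)
study = simulate_study(design, seed=1)

G_eval, phen_eval, kin_eval = study.evaluation
print(f"ancestries: {design.ancestry.labels}, variants: {design.m_variants}")
print(f"evaluation cohort: {G_eval.n_samples} samples "
      f"({dict(zip(*np.unique(G_eval.sample_ancestry, return_counts=True)))})")
print(f"case fraction: {phen_eval.table['ad_status'].mean():.3f} "
      f"(liability prevalence {design.liability.prevalence})")
print(f"related pairs with kinship >= 0.04: {len(kin_eval.pairs_at_or_above(0.04))}")
for lab, ss in study.sumstats.items():
    sig = (ss.table["p"] < 5e-8).sum()
    print(f"GWAS source {lab:8s} (n={ss.table['n'].iloc[0]:>7}): "
          f"{ss.n_variants} variants, {sig} genome-wide significant")
# The case fraction should sit near the stated prevalence; the large sources
# yield many significant variants, the small ones few — the asymmetry the
# multi-ancestry combination has to cope with.
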