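"""GWAS summary statistics: reading, QC, harmonization and fixed-effects meta-analysis.

The variant key throughout is (chrom, pos) with an allele-compatibility
check; rsID-style identifiers are carried as annotation only.  Harmonization
resolves effect-allele orientation against a reference variant index and
conservatively drops strand-ambiguous (A/T, C/G) variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohorts import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SummaryStats",
    "VariantFilterSpec",
    "read_sumstats",
    "write_sumstats",
    "qc_filter_variants",
    "harmonize_to_reference",
    "meta_analyze_fixed",
]

REQUIRED_COLUMNS = ("chrom", "pos", "id", "effect_allele", "other_allele", "beta", "se", "p", "n", "af")

#: canonical TSV header used by writers, and the default alias map of readers
TSV_COLUMNS = {
    "CHR": "chrom",
    "POS": "pos",
    "ID": "id",
    "EA": "effect_allele",
    "OA": "other_allele",
    "BETA": "beta",
    "SE": "se",
    "P": "p",
    "N": "n",
    "EAF": "af",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SummaryStats:
    """Per-variant association results for one study (or a meta-analysis)."""

    table: pd.DataFrame
    study_label: str = "study"
    ancestry_label: str | None = None

    def __post_init__(self) -> None:
        missing = set(REQUIRED_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"summary statistics missing columns: {sorted(missing)}")
        present = self.table["se"].notna() & self.table["beta"].notna()
        if (self.table.loc[present, "se"] <= 0).any():
            raise ValueError("standard errors must be positive where beta is present")
        keys = self.table[["chrom", "pos", "effect_allele", "other_allele"]]
        if keys.duplicated().any():
            raise ValueError("duplicate (chrom, pos, alleles) keys in summary statistics")

    @property
    def n_variants(self) -> int:
        return len(self.table)

    def key_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.table[["chrom", "pos"]])


@dataclass(frozen=True)
class VariantFilterSpec:
    """Variant-level QC bounds: drop MAF <= maf_min or missing rate > missing_max."""

    maf_min: float = 0.01
    missing_max: float = 0.01

    def __post_init__(self) -> None:
        for v in (self.maf_min, self.missing_max):
            if not 0.0 <= v <= 1.0:
                raise ValueError("QC bounds must lie in [0,1]")


def read_sumstats(
    path, dialect: dict[str, str] | None = None, study_label: str | None = None, ancestry_label: str | None = None
) -> SummaryStats:
    """Read a summary-statistics TSV, mapping foreign headers via ``dialect``.

    ``dialect`` maps file column names to canonical names (e.g. {"BETA":
    "beta"}); the standard header (CHR, POS, ID, EA, OA, BETA, SE, P, N,
    EAF) is always understood.  Rows whose beta or se cannot be parsed are
    dropped with a logged count.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    mapping = dict(TSV_COLUMNS)
    if dialect:
        mapping.update(dialect)
    renamed = raw.rename(columns={k: v for k, v in mapping.items() if k in raw.columns})
    missing = set(REQUIRED_COLUMNS) - set(renamed.columns)
    if missing:
        raise ValueError(f"summary statistics file {path} lacks required column(s): {sorted(missing)}")
    renamed = renamed[list(REQUIRED_COLUMNS)].copy()
    for col in ("beta", "se", "p", "af"):
        renamed[col] = pd.to_numeric(renamed[col], errors="coerce")
    renamed["pos"] = pd.to_numeric(renamed["pos"], errors="coerce").astype("Int64")
    renamed["n"] = pd.to_numeric(renamed["n"], errors="coerce")
    renamed["chrom"] = renamed["chrom"].astype(str)
    ok = renamed["beta"].notna() & renamed["se"].notna() & renamed["pos"].notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("read_sumstats(%s): dropped %d rows with unparseable beta/se", path, n_dropped)
    out = renamed[ok].reset_index(drop=True)
    out["pos"] = out["pos"].astype(np.int64)
    return SummaryStats(out, study_label=study_label or str(path), ancestry_label=ancestry_label)


def write_sumstats(ss: SummaryStats, path) -> None:
    """Write the canonical TSV header (gzip inferred from the extension)."""
    inv = {v: k for k, v in TSV_COLUMNS.items()}
    out = ss.table[list(REQUIRED_COLUMNS)].rename(columns=inv)
    out.to_csv(path, sep="\t", index=False)


def qc_filter_variants(G: GenotypeMatrix, spec: VariantFilterSpec = VariantFilterSpec()) -> GenotypeMatrix:
    """Drop variants failing MAF or missingness QC, preserving order.

    The MAF boundary is exclusionary: a variant at exactly ``maf_min`` is
    removed (MAF <= bound fails); missingness strictly above ``missing_max``
    fails.
    """
    af = G.empirical_af()
    maf = np.minimum(af, 1 - af)
    miss = np.isnan(G.dosages).mean(axis=0)
    keep = (maf > spec.maf_min) & (miss <= spec.missing_max)
    logger.info("qc_filter_variants: %d of %d variants retained", int(keep.sum()), G.n_variants)
    return G.subset_variants(np.flatnonzero(keep))


def _is_palindromic(ea: pd.Series, oa: pd.Series) -> pd.Series:
    return oa == ea.map(_COMPLEMENT)


def harmonize_to_reference(ss: SummaryStats, variant_index: pd.DataFrame) -> SummaryStats:
    """Orient study records to a reference variant index, matching on (chrom, pos).

    Swapped effect/other alleles negate beta and reflect af (1-af);
    palindromic (A/T, C/G) pairs and allele-incompatible or unmatched
    records are dropped, with counts logged by reason.  Idempotent.
    """
    ref = variant_index[["chrom", "pos", "effect_allele", "other_allele"]].copy()
    ref.columns = ["chrom", "pos", "ref_ea", "ref_oa"]
    if ref[["chrom", "pos"]].duplicated().any():
        raise ValueError("reference variant index has duplicate (chrom, pos) keys")
    t = ss.table.merge(ref, on=["chrom", "pos"], how="left")

    unmatched = t["ref_ea"].isna()
    palindromic = _is_palindromic(t["effect_allele"], t["other_allele"])
    same = (t["effect_allele"] == t["ref_ea"]) & (t["other_allele"] == t["ref_oa"])
    swapped = (t["effect_allele"] == t["ref_oa"]) & (t["other_allele"] == t["ref_ea"])
    incompatible = ~unmatched & ~palindromic & ~same & ~swapped

    keep = ~unmatched & ~palindromic & ~incompatible
    logger.info(
        "harmonize_to_reference(%s): kept=%d unmatched_dropped=%d ambiguous_dropped=%d incompatible_dropped=%d",
        ss.study_label, int(keep.sum()), int(unmatched.sum()),
        int((palindromic & ~unmatched).sum()), int(incompatible.sum()),
    )
    out = t[keep].copy()
    flip = swapped[keep]
    out.loc[flip, "beta"] = -out.loc[flip, "beta"]
    out.loc[flip, "af"] = 1.0 - out.loc[flip, "af"]
    out.loc[flip, ["effect_allele", "other_allele"]] = out.loc[flip, ["ref_ea", "ref_oa"]].to_numpy()
    out = out.drop(columns=["ref_ea", "ref_oa"]).reset_index(drop=True)
    return SummaryStats(out, study_label=ss.study_label, ancestry_label=ss.ancestry_label)


def meta_analyze_fixed(studies: list[SummaryStats], study_label: str = "meta") -> SummaryStats:
    """Inverse-variance fixed-effects meta-analysis over harmonized studies.

    Per variant present in >= 1 study: beta* = sum(beta_i/se_i^2) / sum(1/se_i^2),
    se* = (sum 1/se_i^2)^(-1/2), two-sided normal p, n* = sum(n_i), af* the
    n-weighted mean.  A single study is returned unchanged apart from the
    recomputed Wald p.
    """
    if not studies:
        raise ValueError("meta_analyze_fixed requires at least one study")
    frames = []
    for s in studies:
        f = s.table[["chrom", "pos", "id", "effect_allele", "other_allele", "beta", "se", "n", "af"]].copy()
        f = f[f["beta"].notna() & f["se"].notna()]
        frames.append(f)
    allrows = pd.concat(frames, ignore_index=True)
    key = ["chrom", "pos", "effect_allele", "other_allele"]
    # allele orientation must agree across studies after harmonization
    if allrows.groupby(["chrom", "pos"])["effect_allele"].nunique().gt(1).any():
        raise ValueError("studies are not harmonized to a common reference (allele orientation differs)")
    w = 1.0 / allrows["se"] ** 2
    allrows = allrows.assign(_w=w, _bw=allrows["beta"] * w, _afn=allrows["af"] * allrows["n"])
    agg = allrows.groupby(key, sort=False).agg(
        id=("id", "first"), _w=("_w", "sum"), _bw=("_bw", "sum"), n=("n", "sum"), _afn=("_afn", "sum")
    ).reset_index()
    beta = agg["_bw"] / agg["_w"]
    se = 1.0 / np.sqrt(agg["_w"])
    out = agg[key + ["id", "n"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["p"] = np.clip(2 * norm.sf(np.abs(beta / se)), np.nextafter(0, 1), 1.0)
    out["af"] = agg["_afn"] / agg["n"]
    out = out[list(REQUIRED_COLUMNS)].sort_values(["chrom", "pos"]).reset_index(drop=True)
    return SummaryStats(out, study_label=study_label, ancestry_label=None)
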