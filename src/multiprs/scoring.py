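"""PRS scoring: dosage-weight inner products, region masking, standardization.

A PRS for sample i is S_i = sum_j d_ij * w_j over the variants of a weight
table matched to the cohort's variant index.  Scores are reported raw or
standardized against a frozen ScalingReference (the mean/SD of the score in
a designated reference cohort), which is how a score trained in one cohort
is applied comparably in another.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohorts import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "WeightTable",
    "ScalingReference",
    "GenomicRegion",
    "PRSVector",
    "APOE_REGION_GRCH38",
    "score_prs",
    "mask_region",
    "fit_reference_stats",
    "standardize",
    "read_weight_table",
    "write_weight_table",
]

WEIGHT_COLUMNS = ("chrom", "pos", "id", "effect_allele", "other_allele", "weight")
WEIGHT_TSV_HEADER = {"CHR": "chrom", "POS": "pos", "ID": "id", "EA": "effect_allele", "OA": "other_allele", "WEIGHT": "weight"}


@dataclass
class WeightTable:
    """Per-variant scoring weights with effect-allele provenance.

    The TSV serialization (CHR, POS, ID, EA, OA, WEIGHT) is superset-
    compatible with PGS-Catalog scoring files, so published scores can be
    loaded and applied alongside natively constructed ones.
    """

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(WEIGHT_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"weight table missing columns: {sorted(missing)}")
        if not np.all(np.isfinite(self.table["weight"].to_numpy(float))):
            raise ValueError("weight table contains non-finite weights")
        if self.table[["chrom", "pos", "effect_allele", "other_allele"]].duplicated().any():
            raise ValueError("duplicate variant keys in weight table")

    @property
    def n_variants(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class ScalingReference:
    """Frozen mean/SD of a PRS in a reference cohort."""

    mean: float
    sd: float
    cohort_label: str = "reference"

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"scaling reference SD must be positive, got {self.sd}")

    def to_json(self) -> str:
        return json.dumps({"mean": self.mean, "sd": self.sd, "cohort_label": self.cohort_label})

    @classmethod
    def from_json(cls, text: str) -> "ScalingReference":
        d = json.loads(text)
        return cls(mean=float(d["mean"]), sd=float(d["sd"]), cohort_label=d.get("cohort_label", "reference"))


@dataclass(frozen=True)
class GenomicRegion:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must be <= end")


#: APOE coding region, GRCh38 coordinates (the conventional masking target)
APOE_REGION_GRCH38 = GenomicRegion("19", 44_905_791, 44_909_393, label="APOE")


@dataclass
class PRSVector:
    """Per-sample scores with provenance (weight table id, scaling chain)."""

    sample_ids: np.ndarray
    values: np.ndarray
    n_variants_used: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, float)
        self.n_variants_used = np.asarray(self.n_variants_used)
        if len(self.sample_ids) != len(self.values):
            raise ValueError("one score per sample required")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "prs": self.values, "n_variants_used": self.n_variants_used})


def score_prs(G: GenotypeMatrix, w: WeightTable, missing_policy: str = "mean_impute") -> PRSVector:
    """Compute S_i = sum_j d_ij * w_j over variants matched on (chrom, pos, alleles).

    The weight table must already be harmonized to G's variant index (same
    effect-allele orientation).  Missing dosages are mean-imputed as 2*AF
    (empirical AF; default) or the variant is omitted for that sample.
    Variants in the table absent from G are skipped and counted in the
    provenance.
    """
    if missing_policy not in ("mean_impute", "omit"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    gv = G.variants[["chrom", "pos", "effect_allele", "other_allele"]].copy()
    gv["_col"] = np.arange(len(gv))
    merged = w.table.merge(gv, on=["chrom", "pos", "effect_allele", "other_allele"], how="inner")
    n_skipped = w.n_variants - len(merged)
    if len(merged) == 0:
        raise ValueError(
            "no weight-table variants matched the genotype variant index "
            "(check harmonization / allele orientation)"
        )
    cols = merged["_col"].to_numpy()
    weights = merged["weight"].to_numpy(float)
    dos = G.dosages[:, cols]
    miss = np.isnan(dos)
    if missing_policy == "mean_impute":
        if miss.any():
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", RuntimeWarning)
                imputed = np.nanmean(dos, axis=0)  # = 2*AF, empirical
            af_cols = [c for c in G.variants.columns if c.startswith("af_")]
            if af_cols:  # variants missing in every sample fall back to the index AF
                index_af2 = 2.0 * G.variants.iloc[cols][af_cols].mean(axis=1).to_numpy()
                imputed = np.where(np.isnan(imputed), index_af2, imputed)
            imputed = np.nan_to_num(imputed, nan=0.0)
            filled = np.where(miss, imputed, dos)
        else:
            filled = dos
        values = filled @ weights
        n_used = np.full(G.n_samples, len(merged))
    else:
        filled = np.where(miss, 0.0, dos)
        values = filled @ weights
        n_used = len(merged) - miss.sum(axis=1)
    prov = {
        "weight_table": w.provenance,
        "scaling": "raw",
        "missing_policy": missing_policy,
        "n_matched": int(len(merged)),
        "n_skipped": int(n_skipped),
    }
    if n_skipped:
        logger.info("score_prs: %d weight-table variants absent from genotypes, skipped", n_skipped)
    return PRSVector(G.sample_ids, values, n_used, prov)


def mask_region(w: WeightTable, region: GenomicRegion, flank_bp: int = 1_000_000) -> WeightTable:
    """Remove variants within ``flank_bp`` of a region (inclusive boundaries).

    Variants with chrom == region.chrom and pos in [start - flank, end + flank]
    are dropped; the mask is recorded in the provenance.
    """
    t = w.table
    inside = (
        (t["chrom"].astype(str) == str(region.chrom))
        & (t["pos"] >= region.start - flank_bp)
        & (t["pos"] <= region.end + flank_bp)
    )
    prov = dict(w.provenance)
    masks = list(prov.get("masks", []))
    masks.append(
        {
            "chrom": str(region.chrom), "start": int(region.start), "end": int(region.end),
            "flank_bp": int(flank_bp), "label": region.label, "n_removed": int(inside.sum()),
        }
    )
    prov["masks"] = masks
    return WeightTable(t[~inside].reset_index(drop=True), provenance=prov)


def fit_reference_stats(prs: PRSVector, cohort_label: str = "reference") -> ScalingReference:
    """Mean and (n-1)-denominator SD of a PRS in the reference cohort."""
    if len(prs.values) < 2:
        raise ValueError("need at least two samples to fit a scaling reference")
    sd = float(np.std(prs.values, ddof=1))
    if sd == 0:
        raise ValueError("cannot fit a scaling reference to constant scores (sd = 0)")
    return ScalingReference(mean=float(np.mean(prs.values)), sd=sd, cohort_label=cohort_label)


def standardize(prs: PRSVector, ref: ScalingReference) -> PRSVector:
    """Apply (x - mean)/sd with a frozen reference; records the scaling in provenance."""
    prov = dict(prs.provenance)
    prov["scaling"] = {"mean": ref.mean, "sd": ref.sd, "cohort_label": ref.cohort_label}
    return PRSVector(prs.sample_ids, (prs.values - ref.mean) / ref.sd, prs.n_variants_used, prov)


def read_weight_table(path, provenance: dict | None = None) -> WeightTable:
    raw = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    renamed = raw.rename(columns={k: v for k, v in WEIGHT_TSV_HEADER.items() if k in raw.columns})
    missing = set(WEIGHT_COLUMNS) - set(renamed.columns)
    if missing:
        raise ValueError(f"weight table file {path} lacks column(s): {sorted(missing)}")
    out = renamed[list(WEIGHT_COLUMNS)].copy()
    out["chrom"] = out["chrom"].astype(str)
    out["pos"] = pd.to_numeric(out["pos"]).astype(np.int64)
    out["weight"] = pd.to_numeric(out["weight"])
    return WeightTable(out, provenance=provenance or {"source": str(path)})


def write_weight_table(w: WeightTable, path) -> None:
    inv = {v: k for k, v in WEIGHT_TSV_HEADER.items()}
    w.table[list(WEIGHT_COLUMNS)].rename(columns=inv).to_csv(path, sep="\t", index=False)
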