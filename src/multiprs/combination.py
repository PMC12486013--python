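"""Multi-study PRS combination: trained (PRSsum-style) and unweighted summation.

Per-study PRSs, each standardized against a frozen reference cohort, are
combined either as a plain sum (unweighted) or as sum_k w_k * PRS_k with
the w_k taken from logistic regressions of case status on each source PRS
in an independent training cohort.  The weighted combination collapses to a
single per-variant weight table (w_k * beta_jk / sd_k summed over sources),
so one exportable score reproduces the combination in any cohort.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohorts import CohortPhenotypes
from .scoring import PRSVector, ScalingReference, WeightTable, fit_reference_stats, standardize

logger = logging.getLogger(__name__)

__all__ = [
    "CombinationModel",
    "SourcePRSMatrix",
    "build_source_matrix",
    "train_combination_weights",
    "combine_weighted",
    "combine_unweighted",
    "collapse_to_variant_weights",
]


@dataclass
class SourcePRSMatrix:
    """One standardized PRS column per source study, aligned on sample ids."""

    sample_ids: np.ndarray
    columns: pd.DataFrame  # one column per source label, standardized values
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if len(self.sample_ids) != len(self.columns):
            raise ValueError("sample ids and PRS rows disagree")
        if self.columns.isna().any().any():
            raise ValueError("source PRS matrix must have no missing entries")

    @property
    def source_labels(self) -> tuple[str, ...]:
        return tuple(self.columns.columns)


@dataclass
class CombinationModel:
    """Per-source summation weights plus the scaling references to apply them."""

    source_labels: tuple[str, ...]
    weights: dict[str, float]
    weight_ses: dict[str, float]
    per_source_scaling: dict[str, ScalingReference]
    final_scaling: ScalingReference | None = None
    fit_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.weights) != set(self.source_labels):
            raise ValueError("one weight per source label required")
        for lab, ref in self.per_source_scaling.items():
            if ref.sd <= 0:
                raise ValueError(f"scaling for source {lab} has non-positive sd")

    def to_json(self) -> str:
        d = {
            "source_labels": list(self.source_labels),
            "weights": self.weights,
            "weight_ses": self.weight_ses,
            "per_source_scaling": {
                k: {"mean": v.mean, "sd": v.sd, "cohort_label": v.cohort_label}
                for k, v in self.per_source_scaling.items()
            },
            "final_scaling": None
            if self.final_scaling is None
            else {"mean": self.final_scaling.mean, "sd": self.final_scaling.sd,
                  "cohort_label": self.final_scaling.cohort_label},
            "fit_metadata": self.fit_metadata,
        }
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CombinationModel":
        d = json.loads(text)
        fs = d.get("final_scaling")
        return cls(
            source_labels=tuple(d["source_labels"]),
            weights={k: float(v) for k, v in d["weights"].items()},
            weight_ses={k: float(v) for k, v in d.get("weight_ses", {}).items()},
            per_source_scaling={
                k: ScalingReference(v["mean"], v["sd"], v.get("cohort_label", "reference"))
                for k, v in d["per_source_scaling"].items()
            },
            final_scaling=None if fs is None else ScalingReference(fs["mean"], fs["sd"], fs.get("cohort_label", "reference")),
            fit_metadata=d.get("fit_metadata", {}),
        )


def build_source_matrix(
    prs_by_source: dict[str, PRSVector], scalings: dict[str, ScalingReference]
) -> SourcePRSMatrix:
    """Standardize each source PRS by its frozen reference and align columns."""
    labels = list(prs_by_source)
    base_ids = prs_by_source[labels[0]].sample_ids
    cols = {}
    for lab in labels:
        prs = prs_by_source[lab]
        if not np.array_equal(prs.sample_ids, base_ids):
            raise ValueError(f"source {lab} is not aligned on the same samples")
        cols[lab] = standardize(prs, scalings[lab]).values
    return SourcePRSMatrix(base_ids, pd.DataFrame(cols), provenance={"scalings": {k: v.cohort_label for k, v in scalings.items()}})


def _design(ph: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Covariate design: age, sex, ancestry and cohort dummies, 10 PCs, APOE e4/e2."""
    parts = [ph["age"].to_numpy(float), ph["sex"].to_numpy(float)]
    names = ["age", "sex"]
    for cat in ("ancestry", "cohort_label"):
        if cat in ph.columns and ph[cat].nunique() > 1:
            dummies = pd.get_dummies(ph[cat], prefix=cat, drop_first=True)
            parts.extend(dummies[c].to_numpy(float) for c in dummies.columns)
            names.extend(dummies.columns)
    for j in range(1, 11):
        c = f"pc{j}"
        if c in ph.columns:
            parts.append(ph[c].to_numpy(float))
            names.append(c)
    parts += [ph["apoe_e4_count"].to_numpy(float), ph["apoe_e2_count"].to_numpy(float)]
    names += ["apoe_e4_count", "apoe_e2_count"]
    return np.column_stack(parts), names


def train_combination_weights(
    M: SourcePRSMatrix,
    phen: CohortPhenotypes,
    fit_mode: str = "marginal",
    per_source_scaling: dict[str, ScalingReference] | None = None,
    training_label: str = "training",
) -> CombinationModel:
    """Fit summation weights w_k in an independent training cohort.

    ``marginal`` (default) fits one logistic regression per source —
    status ~ PRS_k + age + sex + ancestry + cohort + 10 PCs + e4 + e2 — and
    takes the PRS_k coefficient as w_k.  ``joint`` enters all sources in a
    single regression; near-collinearity between sources is detected via
    the condition number of the standardized source block and reported in
    ``fit_metadata['warnings']``.
    """
    import statsmodels.api as sm

    if fit_mode not in ("marginal", "joint"):
        raise ValueError(f"unknown fit_mode {fit_mode!r}")
    ph = phen.aligned_to(M.sample_ids)
    y = ph["ad_status"].to_numpy(float)
    covars, cov_names = _design(ph)
    S = M.columns.to_numpy(float)
    labels = list(M.source_labels)
    warnings_list: list[str] = []

    weights: dict[str, float] = {}
    ses: dict[str, float] = {}
    if fit_mode == "marginal":
        for j, lab in enumerate(labels):
            X = np.column_stack([np.ones(len(y)), S[:, j], covars])
            res = _fit_logistic(X, y, context=f"source {lab}")
            weights[lab] = float(res.params[1])
            ses[lab] = float(res.bse[1])
    else:
        Sz = (S - S.mean(axis=0)) / S.std(axis=0)
        cond = float(np.linalg.cond(Sz.T @ Sz / len(Sz)))
        if cond > 1e8:
            warnings_list.append(f"near-collinear source PRS columns (condition number {cond:.3g})")
            logger.warning("train_combination_weights: %s", warnings_list[-1])
        X = np.column_stack([np.ones(len(y)), S, covars])
        res = _fit_logistic(X, y, context="joint source model", allow_singular=bool(warnings_list))
        for j, lab in enumerate(labels):
            weights[lab] = float(res.params[1 + j])
            ses[lab] = float(res.bse[1 + j])

    scalings = per_source_scaling or {
        lab: ScalingReference(0.0, 1.0, cohort_label="pre-standardized") for lab in labels
    }
    model = CombinationModel(
        source_labels=tuple(labels),
        weights=weights,
        weight_ses=ses,
        per_source_scaling=scalings,
        final_scaling=None,
        fit_metadata={
            "training_cohort": training_label,
            "fit_mode": fit_mode,
            "covariates": cov_names,
            "warnings": warnings_list,
        },
    )
    raw = _weighted_sum(M, model)
    model.final_scaling = ScalingReference(
        float(np.mean(raw)), float(np.std(raw, ddof=1)), cohort_label=training_label
    )
    return model


def _fit_logistic(X: np.ndarray, y: np.ndarray, context: str, allow_singular: bool = False):
    import statsmodels.api as sm

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200, tol=1e-8)
    except Exception as exc:  # singular/perfect-separation failures surface here
        if allow_singular:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit_regularized(alpha=1e-6, disp=0)
            return res
        raise RuntimeError(f"logistic fit failed for {context}: {exc}") from exc
    if not res.converged:
        raise RuntimeError(f"logistic fit did not converge for {context}")
    return res


def _weighted_sum(M: SourcePRSMatrix, model: CombinationModel) -> np.ndarray:
    if tuple(M.source_labels) != tuple(model.source_labels):
        raise ValueError(
            f"source label mismatch: matrix has {M.source_labels}, model expects {model.source_labels}"
        )
    w = np.array([model.weights[lab] for lab in model.source_labels])
    return M.columns.to_numpy(float) @ w


def combine_weighted(M: SourcePRSMatrix, model: CombinationModel) -> PRSVector:
    """S = sum_k w_k * PRS_k, standardized by the model's frozen final scaling."""
    raw = _weighted_sum(M, model)
    if model.final_scaling is None:
        raise ValueError("combination model carries no final scaling reference")
    values = (raw - model.final_scaling.mean) / model.final_scaling.sd
    prov = {"combination": "weighted", "weights": model.weights, "final_scaling": model.final_scaling.cohort_label}
    return PRSVector(M.sample_ids, values, np.zeros(len(values), dtype=int), prov)


def combine_unweighted(M: SourcePRSMatrix, final_scaling: ScalingReference | None = None) -> tuple[PRSVector, ScalingReference]:
    """Plain sum of standardized source PRSs, then standardization.

    If no frozen scaling is supplied, one is fit from this cohort and
    returned alongside the scores (constant sums raise, as sd = 0).
    """
    raw = M.columns.to_numpy(float).sum(axis=1)
    prs = PRSVector(M.sample_ids, raw, np.zeros(len(raw), dtype=int), {"combination": "unweighted"})
    ref = final_scaling or fit_reference_stats(prs, "unweighted-sum")
    return standardize(prs, ref), ref


def collapse_to_variant_weights(model: CombinationModel, source_tables: dict[str, WeightTable]) -> WeightTable:
    """Collapse the weighted combination into one per-variant table.

    Per variant j: weight_j = sum_k w_k * beta_jk / sd_k over the sources
    containing the variant, sd_k the per-source scaling sd.  Scoring a
    cohort with the collapsed table then centering equals combine_weighted
    up to an additive constant.
    """
    if set(source_tables) != set(model.source_labels):
        raise ValueError("source tables must match the model's source labels")
    pieces = []
    for lab in model.source_labels:
        t = source_tables[lab].table.copy()
        t["_w"] = model.weights[lab] * t["weight"] / model.per_source_scaling[lab].sd
        pieces.append(t[["chrom", "pos", "id", "effect_allele", "other_allele", "_w"]])
    allrows = pd.concat(pieces, ignore_index=True)
    orient = allrows.groupby(["chrom", "pos"])["effect_allele"].nunique()
    if (orient > 1).any():
        bad = orient[orient > 1].index.tolist()[:5]
        raise ValueError(f"allele-orientation conflict between source tables at {bad}")
    out = (
        allrows.groupby(["chrom", "pos", "effect_allele", "other_allele"], sort=True)
        .agg(id=("id", "first"), weight=("_w", "sum"))
        .reset_index()
    )
    out = out[["chrom", "pos", "id", "effect_allele", "other_allele", "weight"]]
    prov = {
        "method": "collapsed-weighted-sum",
        "weights": model.weights,
        "per_source_sd": {k: v.sd for k, v in model.per_source_scaling.items()},
        "sources": {k: source_tables[k].provenance for k in model.source_labels},
    }
    return WeightTable(out.sort_values(["chrom", "pos"]).reset_index(drop=True), provenance=prov)
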