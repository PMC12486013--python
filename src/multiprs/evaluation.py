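"""PRS evaluation: association models, AUC, relatedness filtering, stratification, ranking.

Association with case/control status is estimated by plain logistic
regression on an unrelated subset (kinship < 0.04 by default) and reported
as OR per 1 SD of the PRS with a Wald 95% CI; discrimination is the
Mann-Whitney AUC of the fitted model.  Plain logistic regression on the
unrelated subset stands in for kinship-random-effect mixed models
throughout: the unrelated-subset route is the standard AUC procedure, and
this package extends it to estimation (recorded in output metadata).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, t as t_dist

from .cohorts import CohortPhenotypes, KinshipTable
from .scoring import PRSVector

logger = logging.getLogger(__name__)

__all__ = [
    "EvalResult",
    "StratificationSpec",
    "select_unrelated",
    "fit_logistic_assoc",
    "fit_linear_assoc",
    "compute_auc",
    "stratify_assoc",
    "rank_models",
]

DEFAULT_KINSHIP_THRESHOLD = 0.04


@dataclass
class EvalResult:
    """OR per SD with CI and p, AUC and sample counts for one model in one stratum."""

    model_label: str
    stratum_label: str
    n_cases: int
    n_controls: int
    beta_per_sd: float
    se: float
    or_per_sd: float
    ci95: tuple[float, float]
    p: float
    auc: float | None
    covariates_used: tuple[str, ...] = ()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not lo <= self.or_per_sd <= hi:
            raise ValueError("OR must lie inside its confidence interval")
        if self.auc is not None and not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0,1]")

    def to_dict(self) -> dict:
        return {
            "model": self.model_label, "stratum": self.stratum_label,
            "n_cases": self.n_cases, "n_controls": self.n_controls,
            "beta_per_sd": self.beta_per_sd, "se": self.se, "or_per_sd": self.or_per_sd,
            "ci95_low": self.ci95[0], "ci95_high": self.ci95[1], "p": self.p, "auc": self.auc,
        }


@dataclass(frozen=True)
class StratificationSpec:
    """Stratification axis: 'sex', 'apoe_genotype' or 'ancestry'."""

    axis: str

    def __post_init__(self) -> None:
        if self.axis not in ("sex", "apoe_genotype", "ancestry"):
            raise ValueError(f"unknown stratification axis {self.axis!r}")

    def groups(self, ph: pd.DataFrame) -> pd.Series:
        if self.axis == "sex":
            return ph["sex"].map({0: "male", 1: "female", 0.0: "male", 1.0: "female"}).astype(str)
        if self.axis == "ancestry":
            return ph["ancestry"].astype(str)
        e4 = ph["apoe_e4_count"].to_numpy(int)
        e2 = ph["apoe_e2_count"].to_numpy(int)
        labels = np.select(
            [
                (e2 >= 1) & (e4 >= 1),
                (e2 >= 1) & (e4 == 0),  # e2/e2 + e2/e3 pooled
                (e4 == 0) & (e2 == 0),
                e4 == 1,
                e4 == 2,
            ],
            ["e2/e4", "e2_carrier", "e3/e3", "e3/e4", "e4/e4"],
            default="other",
        )
        return pd.Series(labels, index=ph.index)


def select_unrelated(
    samples: list, kin: KinshipTable, threshold: float = DEFAULT_KINSHIP_THRESHOLD
) -> list:
    """Greedy unrelated subset: no remaining pair with kinship >= threshold.

    While any related pair remains, the individual with the most related
    partners is dropped (ties by sample id); dropped individuals whose
    partners were all subsequently removed are re-added, so the output is
    maximal.
    """
    if threshold <= 0:
        raise ValueError("kinship threshold must be positive")
    sample_set = set(samples)
    edges = kin.pairs_at_or_above(threshold)
    adj: dict[object, set] = {}
    for a, b in zip(edges["sample_i"], edges["sample_j"]):
        if a in sample_set and b in sample_set:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
    removed: list = []
    degree = {s: len(nb) for s, nb in adj.items()}
    while degree and max(degree.values()) > 0:
        worst = min((s for s, d in degree.items() if d == max(degree.values())), key=str)
        removed.append(worst)
        for nb in adj[worst]:
            if nb in degree:
                degree[nb] -= 1
        del degree[worst]
    kept = sample_set - set(removed)
    for s in sorted(removed, key=str):  # maximality: re-add anyone with no kept partner
        if not (adj.get(s, set()) & kept):
            kept.add(s)
    return [s for s in samples if s in kept]


def _prepare_prs(values: np.ndarray) -> tuple[np.ndarray, bool]:
    sd = values.std(ddof=1) if len(values) > 1 else 0.0
    if sd == 0:
        raise ValueError("PRS has no variance; association model is undefined")
    # Only visibly raw scores are restandardized: stratum subsets of an
    # already-standardized PRS keep their cohort-level scale so the OR stays
    # "per SD of the full cohort".
    if abs(values.mean()) > 1.0 or sd > 3.0 or sd < 1.0 / 3.0:
        return (values - values.mean()) / sd, True
    return values, False


def fit_logistic_assoc(
    outcome: np.ndarray,
    prs: PRSVector | np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    model_label: str = "model",
    stratum_label: str = "all",
) -> EvalResult:
    """Maximum-likelihood logistic regression of a binary outcome on the PRS.

    Fits by IRLS (tol 1e-8, max 100 iterations); reports the PRS
    coefficient as OR per SD with a Wald 95% CI exp(beta +/- 1.96 se) and a
    two-sided Wald p.  A PRS that is visibly unstandardized is standardized
    internally and noted in the metadata.  Separation or non-convergence is
    a hard error with diagnostics.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, float)
    classes = set(np.unique(y))
    if not classes <= {0.0, 1.0} or len(classes) < 2:
        raise ValueError("outcome must contain both classes coded 0/1")
    values = prs.values if isinstance(prs, PRSVector) else np.asarray(prs, float)
    values, restandardized = _prepare_prs(values)
    cov_names: tuple[str, ...] = ()
    if covariates is None:
        X = np.column_stack([np.ones(len(y)), values])
    else:
        C = covariates.to_numpy(float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, float)
        cov_names = tuple(covariates.columns) if isinstance(covariates, pd.DataFrame) else tuple(
            f"x{i}" for i in range(C.shape[1])
        )
        X = np.column_stack([np.ones(len(y)), values, C])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100, tol=1e-8)
    except Exception as exc:
        raise RuntimeError(f"logistic association fit failed ({model_label}/{stratum_label}): {exc}") from exc
    if not res.converged:
        raise RuntimeError(f"logistic association did not converge ({model_label}/{stratum_label})")
    beta = float(res.params[1])
    se = float(res.bse[1])
    if not np.isfinite(se) or se > 1e3:
        raise RuntimeError(
            f"separation suspected ({model_label}/{stratum_label}): se={se:.3g}, beta={beta:.3g}"
        )
    p = float(2 * norm.sf(abs(beta / se)))
    fitted = np.asarray(res.fittedvalues, float)
    return EvalResult(
        model_label=model_label,
        stratum_label=stratum_label,
        n_cases=int(y.sum()),
        n_controls=int((1 - y).sum()),
        beta_per_sd=beta,
        se=se,
        or_per_sd=float(np.exp(beta)),
        ci95=(float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))),
        p=p,
        auc=None,
        covariates_used=cov_names,
        metadata={
            "prs_restandardized": restandardized,
            "fitted_probabilities": fitted,
            "association_model": "plain logistic regression (unrelated subset); no kinship random effects",
        },
    )


def fit_linear_assoc(
    outcome: np.ndarray,
    prs: PRSVector | np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> dict:
    """OLS of a continuous outcome on the PRS; effect per 1 SD with t-based CI and p."""
    import statsmodels.api as sm

    y = np.asarray(outcome, float)
    if y.std() == 0:
        raise ValueError("outcome is constant")
    values = prs.values if isinstance(prs, PRSVector) else np.asarray(prs, float)
    values, _ = _prepare_prs(values)
    if covariates is None:
        X = np.column_stack([np.ones(len(y)), values])
    else:
        C = covariates.to_numpy(float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, float)
        X = np.column_stack([np.ones(len(y)), values, C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix in linear association")
    res = sm.OLS(y, X).fit()
    beta = float(res.params[1])
    se = float(res.bse[1])
    df = int(res.df_resid)
    tcrit = float(t_dist.ppf(0.975, df))
    return {
        "beta_per_sd": beta,
        "se": se,
        "ci95": (beta - tcrit * se, beta + tcrit * se),
        "p": float(res.pvalues[1]),
        "n": len(y),
    }


def compute_auc(
    scores: np.ndarray,
    outcome: np.ndarray,
    unrelated_only: bool = False,
    kin: KinshipTable | None = None,
    sample_ids: np.ndarray | None = None,
    kinship_threshold: float = DEFAULT_KINSHIP_THRESHOLD,
) -> float:
    """Mann-Whitney AUC: P(score_case > score_control) + 0.5 P(tie).

    With ``unrelated_only`` the samples are first reduced to an unrelated
    subset (requires ``sample_ids`` and a kinship table).
    """
    s = np.asarray(scores, float)
    y = np.asarray(outcome, float)
    if unrelated_only:
        if sample_ids is None or kin is None:
            raise ValueError("unrelated_only requires sample_ids and a kinship table")
        keep = set(select_unrelated(list(sample_ids), kin, threshold=kinship_threshold))
        mask = np.array([sid in keep for sid in sample_ids])
        s, y = s[mask], y[mask]
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: one outcome class is empty after filtering")
    ranks = rankdata(s)  # midranks handle ties => + 0.5 * P(tie)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def stratify_assoc(
    phen_frame: pd.DataFrame,
    prs_values: np.ndarray,
    spec: StratificationSpec,
    covariate_columns: list[str],
    kin: KinshipTable | None = None,
    model_label: str = "model",
) -> list[EvalResult]:
    """Fit association and AUC per stratum, dropping the stratification covariate.

    Strata that lose an outcome class (or fail to fit) are skipped with a
    logged reason.
    """
    strata = spec.groups(phen_frame)
    axis_cols = {"sex": ["sex"], "apoe_genotype": ["apoe_e4_count", "apoe_e2_count"], "ancestry": ["ancestry"]}
    drop = set(axis_cols[spec.axis])
    use_cols = [c for c in covariate_columns if c not in drop]
    results: list[EvalResult] = []
    for name in sorted(strata.unique()):
        m = (strata == name).to_numpy()
        y = phen_frame.loc[m, "ad_status"].to_numpy(float)
        if len(np.unique(y)) < 2:
            logger.info("stratify_assoc: stratum %r skipped (single outcome class)", name)
            continue
        covs = phen_frame.loc[m, use_cols] if use_cols else None
        try:
            res = fit_logistic_assoc(y, prs_values[m], covs, model_label=model_label, stratum_label=str(name))
        except (RuntimeError, ValueError) as exc:
            logger.info("stratify_assoc: stratum %r skipped (%s)", name, exc)
            continue
        ids = phen_frame.loc[m, "sample_id"].to_numpy() if "sample_id" in phen_frame.columns else None
        res.auc = compute_auc(
            res.metadata["fitted_probabilities"], y,
            unrelated_only=kin is not None and ids is not None, kin=kin, sample_ids=ids,
        )
        results.append(res)
    return results


def rank_models(results: list[EvalResult], rule: tuple[str, ...] = ("auc", "or", "p")) -> list[EvalResult]:
    """Order models best-first: AUC desc, then OR per SD desc, then p asc, then label.

    The composite rule resolves the three reported criteria (largest OR,
    highest AUC, lowest p) deterministically; the full ordering is returned
    with the winner first.
    """
    if not results:
        raise ValueError("rank_models needs at least one result")
    keymap = {
        "auc": lambda r: -(r.auc if r.auc is not None else 0.5),
        "or": lambda r: -r.or_per_sd,
        "p": lambda r: r.p,
    }
    def sort_key(r: EvalResult):
        return tuple(keymap[k](r) for k in rule) + (r.model_label,)

    return sorted(results, key=sort_key)
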