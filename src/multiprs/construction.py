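"""Clumping + thresholding PRS construction with coefficient-of-variation selection.

The grid follows the conventional C+T design: greedy LD clumping at each
(r2, window) pair over a cohort LD reference, then a ladder of p-value
thresholds; each cell yields a candidate weight table whose weights are the
GWAS betas.  The winning candidate is the one whose association effect is
most stable — smallest coefficient of variation sd/|mean| — across k random
unrelated subsets of a tuning cohort (k=5 by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohorts import CohortPhenotypes, GenotypeMatrix, KinshipTable
from .scoring import WeightTable, fit_reference_stats, score_prs, standardize
from .sumstats import SummaryStats

logger = logging.getLogger(__name__)

__all__ = ["CTGridSpec", "CTCandidate", "CVSelectionReport", "ld_r2", "clump", "build_ct_grid", "cv_select"]

DEFAULT_P_LADDER = (5e-8, 1e-6, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.5)


@dataclass(frozen=True)
class CTGridSpec:
    """The C+T parameter grid: r2 thresholds x window sizes x p-value ladder."""

    r2_thresholds: tuple[float, ...] = (0.1, 0.2, 0.3)
    windows_kb: tuple[float, ...] = (100.0, 250.0, 500.0)
    p_thresholds: tuple[float, ...] = DEFAULT_P_LADDER

    def __post_init__(self) -> None:
        for r2 in self.r2_thresholds:
            if not 0.0 < r2 < 1.0:
                raise ValueError("r2 thresholds must lie in (0,1)")
        for w in self.windows_kb:
            if w <= 0:
                raise ValueError("windows must be positive")
        for p in self.p_thresholds:
            if not 0.0 < p <= 1.0:
                raise ValueError("p thresholds must lie in (0,1]")
        object.__setattr__(self, "p_thresholds", tuple(sorted(self.p_thresholds)))

    @property
    def size(self) -> int:
        return len(self.r2_thresholds) * len(self.windows_kb) * len(self.p_thresholds)


@dataclass
class CTCandidate:
    """One cell of the C+T grid."""

    weight_table: WeightTable
    params: tuple[float, float, float]  # (r2, window_kb, p_threshold)
    n_variants: int

    @property
    def label(self) -> str:
        r2, w, p = self.params
        return f"r2={r2:g}_kb={w:g}_p={p:g}"


@dataclass
class CVSelectionReport:
    """Per-candidate subset effects and the CV-minimizing selection."""

    per_candidate: pd.DataFrame  # candidate, r2, window_kb, p_threshold, n_variants,
    #                              subset betas (list), mean, sd, cv
    selected: str
    k: int
    seed: int


def ld_r2(G_reference: GenotypeMatrix, i: int, j: int) -> float:
    """Squared Pearson correlation of dosages (composite LD) between two variants."""
    x = G_reference.dosages[:, i]
    y = G_reference.dosages[:, j]
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        warnings.warn("monomorphic variant in LD computation; r2 treated as 0", stacklevel=2)
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def clump(
    ss: SummaryStats, G_reference: GenotypeMatrix, r2_threshold: float, window_kb: float
) -> list[int]:
    """Greedy LD clumping; returns row indices of ``ss.table`` ordered by (chrom, pos).

    Repeatedly take the unclumped variant with the smallest p as an index
    variant (p ties broken by chrom then pos ascending), then remove every
    unclumped variant on the same chromosome within ``window_kb`` center-to-
    center whose dosage r2 with the index is >= ``r2_threshold``.
    """
    t = ss.table
    gv = G_reference.variants[["chrom", "pos"]].copy()
    gv["_col"] = np.arange(len(gv))
    merged = t[["chrom", "pos", "p"]].reset_index().merge(gv, on=["chrom", "pos"], how="inner")
    merged = merged[merged["p"].notna()]
    if merged.empty:
        return []
    order = merged.sort_values(["p", "chrom", "pos"], kind="mergesort")
    window_bp = window_kb * 1000.0

    dos = G_reference.dosages
    centered = dos - np.nanmean(dos, axis=0)
    centered = np.nan_to_num(centered, nan=0.0)
    norms = np.sqrt((centered**2).sum(axis=0))

    chrom = order["chrom"].to_numpy()
    pos = order["pos"].to_numpy()
    col = order["_col"].to_numpy()
    row = order["index"].to_numpy()
    n = len(order)
    alive = np.ones(n, dtype=bool)
    kept_rows: list[int] = []
    for a in range(n):
        if not alive[a]:
            continue
        alive[a] = False
        kept_rows.append(int(row[a]))
        near = alive & (chrom == chrom[a]) & (np.abs(pos - pos[a]) <= window_bp)
        if not near.any():
            continue
        idx_cols = col[near]
        xi = centered[:, col[a]]
        ni = norms[col[a]]
        if ni == 0:
            continue  # monomorphic index: r2 undefined, treated as 0, clumps nothing
        denom = norms[idx_cols] * ni
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(denom > 0, (centered[:, idx_cols].T @ xi) ** 2 / denom**2, 0.0)
        drop = np.flatnonzero(near)[r2 >= r2_threshold]
        alive[drop] = False
    kept = t.loc[kept_rows, ["chrom", "pos"]].assign(_row=kept_rows).sort_values(["chrom", "pos"])
    return [int(r) for r in kept["_row"]]


def build_ct_grid(
    ss: SummaryStats, G_reference: GenotypeMatrix, grid: CTGridSpec = CTGridSpec()
) -> list[CTCandidate]:
    """Clump once per (r2, window) pair; threshold the index set at each p cutoff.

    With the default grid (3 r2 x 3 windows x 8 p thresholds) this yields 72
    candidates; empty candidates are retained with n_variants = 0.
    """
    candidates: list[CTCandidate] = []
    for r2 in grid.r2_thresholds:
        for w in grid.windows_kb:
            index_rows = clump(ss, G_reference, r2, w)
            sub = ss.table.loc[index_rows]
            for p_thr in grid.p_thresholds:
                hit = sub[sub["p"] <= p_thr]
                wt = pd.DataFrame(
                    {
                        "chrom": hit["chrom"], "pos": hit["pos"], "id": hit["id"],
                        "effect_allele": hit["effect_allele"], "other_allele": hit["other_allele"],
                        "weight": hit["beta"],
                    }
                ).reset_index(drop=True)
                prov = {
                    "source": ss.study_label, "method": "C+T",
                    "params": f"r2={r2:g},window_kb={w:g},p<={p_thr:g}",
                }
                cand = CTCandidate(WeightTable(wt, provenance=prov), (r2, w, p_thr), len(wt))
                if cand.n_variants == 0:
                    logger.info("build_ct_grid: empty candidate %s", cand.label)
                candidates.append(cand)
    return candidates


def _covariate_matrix(ph: pd.DataFrame) -> np.ndarray:
    cols = [ph["age"].to_numpy(float), ph["sex"].to_numpy(float),
            ph["apoe_e4_count"].to_numpy(float), ph["apoe_e2_count"].to_numpy(float)]
    cols += [ph[f"pc{j}"].to_numpy(float) for j in range(1, 11) if f"pc{j}" in ph.columns]
    return np.column_stack(cols)


def cv_select(
    candidates: list[CTCandidate],
    G_tune: GenotypeMatrix,
    phen: CohortPhenotypes,
    kin: KinshipTable | None = None,
    k: int = 5,
    seed: int = 0,
    kinship_threshold: float = 0.04,
) -> CVSelectionReport:
    """Select the candidate whose tuning-cohort effect is most stable across subsets.

    The tuning cohort is reduced to an unrelated set (kinship < threshold),
    split into ``k`` random equal subsets, and each candidate PRS
    (standardized over the unrelated set) is tested per subset with a
    logistic regression of case status on PRS + age + sex + APOE e4/e2 +
    PCs.  cv = sd/|mean| of the subset effects; the minimal finite cv wins
    (ties by candidate label).
    """
    import statsmodels.api as sm

    from .evaluation import select_unrelated

    if k < 2:
        raise ValueError("cv_select requires k >= 2 subsets")
    kin = kin or KinshipTable.empty()
    keep_ids = select_unrelated(list(G_tune.sample_ids), kin, threshold=kinship_threshold)
    G = G_tune.subset_samples(keep_ids)
    ph = phen.aligned_to(G.sample_ids)
    y = ph["ad_status"].to_numpy(float)
    covars = _covariate_matrix(ph)

    rng = np.random.default_rng(seed)
    fold = rng.permutation(np.arange(G.n_samples) % k)

    rows = []
    for ci, cand in enumerate(candidates):
        if cand.n_variants == 0:
            rows.append((cand.label, *cand.params, 0, [np.nan] * k, np.nan, np.nan, np.inf))
            continue
        try:
            prs = score_prs(G, cand.weight_table)
            prs = standardize(prs, fit_reference_stats(prs, "tune"))
        except ValueError:
            rows.append((cand.label, *cand.params, cand.n_variants, [np.nan] * k, np.nan, np.nan, np.inf))
            continue
        betas = []
        for f in range(k):
            m = fold == f
            X = np.column_stack([np.ones(int(m.sum())), prs.values[m], covars[m]])
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.GLM(y[m], X, family=sm.families.Binomial()).fit(maxiter=100)
                betas.append(float(res.params[1]))
            except Exception:
                betas.append(np.nan)
        betas_arr = np.array(betas)
        if np.isnan(betas_arr).any():
            mean = sd = cv = np.nan
        else:
            mean = float(betas_arr.mean())
            sd = float(betas_arr.std(ddof=1))
            cv = sd / abs(mean) if mean != 0 else np.inf
        rows.append((cand.label, *cand.params, cand.n_variants, betas, mean, sd, cv))

    report = pd.DataFrame(
        rows, columns=["candidate", "r2", "window_kb", "p_threshold", "n_variants", "subset_betas", "mean", "sd", "cv"]
    )
    finite = report[np.isfinite(report["cv"])]
    if finite.empty:
        raise ValueError("cv_select: no candidate produced a finite coefficient of variation")
    best = finite.sort_values(["cv", "candidate"], kind="mergesort").iloc[0]["candidate"]
    return CVSelectionReport(per_candidate=report, selected=str(best), k=k, seed=seed)


def candidate_by_label(candidates: list[CTCandidate], label: str) -> CTCandidate:
    for c in candidates:
        if c.label == label:
            return c
    raise KeyError(label)
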