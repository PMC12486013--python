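"""End-to-end orchestration: simulate -> construct -> combine -> evaluate -> validate.

The training flow mirrors the multi-cohort study design the package is
built around: per-source GWAS summary statistics are clumped and
thresholded against an LD reference panel, the best candidate per source is
chosen by coefficient-of-variation stability in a tuning cohort, the three
combination strategies (meta-analysis-first, unweighted summation, weighted
summation with weights trained in an independent cohort) are scored and
evaluated in the evaluation cohort, and the winning weighted model is
collapsed to a single exportable weight table with a frozen scaling
reference for validation in held-out cohorts.

Every run is deterministic under its configured seed and writes a manifest
(seeds, input hashes, artifact hashes) for byte-level reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .cohorts import (
    AncestryModel,
    CohortPhenotypes,
    EffectModel,
    GenotypeMatrix,
    KinshipTable,
    LDBlockSpec,
    LiabilityModel,
    draw_ancestral_frequencies,
    drift_frequencies,
    draw_true_effects,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_related_pairs,
    simulate_sumstats,
)
from .combination import (
    CombinationModel,
    build_source_matrix,
    collapse_to_variant_weights,
    combine_unweighted,
    combine_weighted,
    train_combination_weights,
)
from .construction import CTGridSpec, build_ct_grid, candidate_by_label, cv_select
from .evaluation import (
    EvalResult,
    StratificationSpec,
    compute_auc,
    fit_logistic_assoc,
    rank_models,
    select_unrelated,
    stratify_assoc,
)
from .scoring import (
    GenomicRegion,
    ScalingReference,
    WeightTable,
    fit_reference_stats,
    mask_region,
    score_prs,
    standardize,
    write_weight_table,
)
from .sumstats import SummaryStats, harmonize_to_reference, meta_analyze_fixed, write_sumstats

logger = logging.getLogger(__name__)

EVAL_COVARIATES = ["age", "sex", "apoe_e4_count", "apoe_e2_count"] + [f"pc{j}" for j in range(1, 11)]


# ---------------------------------------------------------------------------
# synthetic study design


@dataclass(frozen=True)
class GwasSourceSpec:
    """One training GWAS: label, ancestry of its cohort, reported sample size."""

    label: str
    ancestry: str
    n_reported: int
    n_simulated: int = 2000
    mode: str = "analytic"


@dataclass
class StudyDesign:
    """Generative conditions for a full synthetic multi-ancestry study."""

    m_variants: int = 1000
    ancestry: AncestryModel = field(default_factory=lambda: AncestryModel(("EA", "AA"), (0.01, 0.1)))
    ld: LDBlockSpec = field(default_factory=LDBlockSpec)
    effects: EffectModel = field(default_factory=lambda: EffectModel(apoe_variant=10))
    liability: LiabilityModel = field(default_factory=LiabilityModel)
    sources: tuple[GwasSourceSpec, ...] = (
        GwasSourceSpec("EADB", "EA", 80_000),
        GwasSourceSpec("FinnGen", "EA", 30_000),
        GwasSourceSpec("MVP", "AA", 20_000),
        GwasSourceSpec("EAS", "AA", 10_000),
    )
    n_reference: dict = field(default_factory=lambda: {"EA": 1000, "AA": 1000})
    n_tuning: dict = field(default_factory=lambda: {"EA": 1500, "AA": 1500})
    n_training: dict = field(default_factory=lambda: {"EA": 3000, "AA": 3000})
    n_eval: dict = field(default_factory=lambda: {"EA": 3000, "AA": 3000})
    n_validation: dict = field(default_factory=lambda: {"EA": 1500, "AA": 1500})
    n_sib_pairs_eval: int = 50


@dataclass
class StudyData:
    """All in-memory inputs of one synthetic study."""

    design: StudyDesign
    afs: np.ndarray
    effects: pd.DataFrame
    sumstats: dict[str, SummaryStats]
    reference: GenotypeMatrix
    tuning: tuple[GenotypeMatrix, CohortPhenotypes, KinshipTable]
    training: tuple[GenotypeMatrix, CohortPhenotypes, KinshipTable]
    evaluation: tuple[GenotypeMatrix, CohortPhenotypes, KinshipTable]
    validation: tuple[GenotypeMatrix, CohortPhenotypes, KinshipTable]


def simulate_study(design: StudyDesign, seed: int) -> StudyData:
    """Generate GWAS sources and all pipeline cohorts from one master seed."""
    from .cohorts import _make_variant_index

    base = int(seed) % (2**28)
    ancestral = draw_ancestral_frequencies(design.m_variants, design.ancestry, base)
    afs = drift_frequencies(ancestral, design.ancestry, base + 1)
    anc_index = {lab: k for k, lab in enumerate(design.ancestry.labels)}
    # one shared variant index: every cohort and GWAS source uses the same
    # (chrom, pos, alleles) frame, as real harmonized studies would
    variant_index = _make_variant_index(
        design.m_variants, afs, design.ancestry.labels, design.ld,
        np.random.default_rng(base + 4), "1", 1_000_000,
    )
    effects = None
    sumstats: dict[str, SummaryStats] = {}
    cohorts = {}
    names = ("reference", "tuning", "training", "evaluation", "validation")
    sizes = (design.n_reference, design.n_tuning, design.n_training, design.n_eval, design.n_validation)
    for i, (name, n_per) in enumerate(zip(names, sizes)):
        s = base + 10 + 10 * i
        G = simulate_genotypes(
            afs, design.ld, n_per, s, ancestry_labels=design.ancestry.labels,
            id_prefix=name[:3].upper(), variant_index=variant_index,
        )
        if effects is None:
            effects = draw_true_effects(G.variants, afs, design.effects, design.ancestry.labels, base + 5)
        kin = KinshipTable.empty()
        if name == "evaluation" and design.n_sib_pairs_eval > 0:
            sibs, kin = simulate_related_pairs(G, design.n_sib_pairs_eval, s + 1, id_prefix="EVASIB")
            G = GenotypeMatrix(
                np.vstack([G.dosages, sibs.dosages]), G.variants,
                np.concatenate([G.sample_ids, sibs.sample_ids]),
                np.concatenate([G.sample_ancestry, sibs.sample_ancestry]),
            )
        phen = simulate_phenotypes(
            G, effects, design.liability, s + 2, cohort_label=name,
            apoe_variant=design.effects.apoe_variant,
        )
        cohorts[name] = (G, phen, kin)

    for i, src in enumerate(design.sources):
        s = base + 200 + 10 * i
        k = anc_index[src.ancestry]
        Gg = simulate_genotypes(
            afs[k][None, :], design.ld, {src.ancestry: src.n_simulated}, s,
            ancestry_labels=(src.ancestry,), id_prefix=f"G{i}", variant_index=variant_index,
        )
        ph = simulate_phenotypes(
            Gg, effects, design.liability, s + 1, cohort_label=src.label,
            apoe_variant=design.effects.apoe_variant,
        )
        sumstats[src.label] = simulate_sumstats(
            Gg, ph, mode=src.mode, seed=s + 2, study_label=src.label,
            effects=effects, liability=design.liability,
            n_analytic=src.n_reported if src.mode == "analytic" else None,
        )

    return StudyData(
        design=design, afs=afs, effects=effects, sumstats=sumstats,
        reference=cohorts["reference"][0],
        tuning=cohorts["tuning"], training=cohorts["training"],
        evaluation=cohorts["evaluation"], validation=cohorts["validation"],
    )


# ---------------------------------------------------------------------------
# training / validation flows (in-memory layer)


@dataclass
class TrainingArtifacts:
    """Everything run_training produces, in memory."""

    source_tables: dict[str, WeightTable]
    cv_reports: dict
    combination_model: CombinationModel
    collapsed_table: WeightTable
    collapsed_scaling: ScalingReference
    strategy_prs: dict[str, np.ndarray]
    results: list[EvalResult]
    ranking: list[EvalResult]
    selected: str
    manifest: dict


def _check_disjoint(cohort_ids: dict[str, np.ndarray]) -> None:
    names = list(cohort_ids)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            overlap = set(cohort_ids[a]) & set(cohort_ids[b])
            if overlap:
                raise ValueError(
                    f"cohorts {a!r} and {b!r} share {len(overlap)} sample id(s); "
                    "overlapping individuals must be removed before training"
                )


def _evaluate_strategy(
    label: str, values: np.ndarray, G: GenotypeMatrix, phen: CohortPhenotypes, kin: KinshipTable
) -> EvalResult:
    keep = select_unrelated(list(G.sample_ids), kin)
    keep_set = set(keep)
    mask = np.array([s in keep_set for s in G.sample_ids])
    ph = phen.aligned_to(G.sample_ids[mask])
    covs = ph[[c for c in EVAL_COVARIATES if c in ph.columns]]
    res = fit_logistic_assoc(ph["ad_status"].to_numpy(float), values[mask], covs, model_label=label)
    res.auc = compute_auc(res.metadata["fitted_probabilities"], ph["ad_status"].to_numpy(float))
    return res


def run_training_data(
    sumstats: dict[str, SummaryStats],
    reference: GenotypeMatrix,
    tuning: tuple[GenotypeMatrix, CohortPhenotypes, KinshipTable],
    training: tuple[GenotypeMatrix, CohortPhenotypes, KinshipTable],
    evaluation: tuple[GenotypeMatrix, CohortPhenotypes, KinshipTable],
    grid: CTGridSpec = CTGridSpec(),
    mask: tuple[GenomicRegion, int] | None = None,
    fit_mode: str = "marginal",
    cv_k: int = 5,
    seed: int = 0,
    rank_rule: tuple[str, ...] = ("auc", "or", "p"),
) -> TrainingArtifacts:
    """Run the full training flow on in-memory cohorts.

    Strategies built: ``meta`` (meta-analysis first, then C+T), ``unweighted``
    (sum of standardized per-source PRSs) and ``weighted`` (summation with
    weights trained in the independent training cohort).  Per-source and
    final scalings are fit in the evaluation cohort, the study's reference
    cohort for standardization; the collapsed weighted table plus its frozen
    scaling are the exportable artifact for external validation.
    """
    G_tune, ph_tune, kin_tune = tuning
    G_train, ph_train, _ = training
    G_eval, ph_eval, kin_eval = evaluation
    _check_disjoint(
        {
            "tuning": G_tune.sample_ids, "training": G_train.sample_ids,
            "evaluation": G_eval.sample_ids, "reference": reference.sample_ids,
        }
    )

    harmonized = {lab: harmonize_to_reference(ss, reference.variants) for lab, ss in sumstats.items()}

    def _best_table(ss: SummaryStats, child_seed: int):
        cands = build_ct_grid(ss, reference, grid)
        report = cv_select(cands, G_tune, ph_tune, kin_tune, k=cv_k, seed=child_seed)
        best = candidate_by_label(cands, report.selected).weight_table
        if mask is not None:
            best = mask_region(best, mask[0], mask[1])
        return best, report

    source_tables: dict[str, WeightTable] = {}
    cv_reports: dict = {}
    for i, lab in enumerate(sorted(harmonized)):
        source_tables[lab], cv_reports[lab] = _best_table(harmonized[lab], seed + 1000 + i)
        logger.info("run_training: source %s -> %s (%d variants)", lab,
                    cv_reports[lab].selected, source_tables[lab].n_variants)

    meta_ss = meta_analyze_fixed(list(harmonized.values()), study_label="meta")
    meta_table, cv_reports["meta"] = _best_table(meta_ss, seed + 1999)

    # per-source PRS, scaled against the evaluation cohort (the study's reference for scaling)
    scalings: dict[str, ScalingReference] = {}
    prs_eval: dict = {}
    prs_train: dict = {}
    for lab, table in source_tables.items():
        pe = score_prs(G_eval, table)
        scalings[lab] = fit_reference_stats(pe, cohort_label="evaluation")
        prs_eval[lab] = pe
        prs_train[lab] = score_prs(G_train, table)
    M_eval = build_source_matrix(prs_eval, scalings)
    M_train = build_source_matrix(prs_train, scalings)

    model = train_combination_weights(
        M_train, ph_train, fit_mode=fit_mode, per_source_scaling=scalings, training_label="training"
    )
    raw_eval = M_eval.columns.to_numpy(float) @ np.array([model.weights[l] for l in model.source_labels])
    model.final_scaling = ScalingReference(
        float(raw_eval.mean()), float(raw_eval.std(ddof=1)), cohort_label="evaluation"
    )

    weighted = combine_weighted(M_eval, model)
    unweighted, unweighted_scaling = combine_unweighted(M_eval)
    meta_prs = score_prs(G_eval, meta_table)
    meta_scaled = standardize(meta_prs, fit_reference_stats(meta_prs, "evaluation"))

    strategy_prs = {"meta": meta_scaled.values, "unweighted": unweighted.values, "weighted": weighted.values}
    results = [
        _evaluate_strategy(lab, vals, G_eval, ph_eval, kin_eval) for lab, vals in sorted(strategy_prs.items())
    ]
    ranking = rank_models(results, rule=rank_rule)
    selected = ranking[0].model_label

    collapsed = collapse_to_variant_weights(model, source_tables)
    coll_scores = score_prs(G_eval, collapsed)
    collapsed_scaling = fit_reference_stats(coll_scores, cohort_label="evaluation")

    manifest = {
        "seed": int(seed),
        "grid": {
            "r2_thresholds": list(grid.r2_thresholds),
            "windows_kb": list(grid.windows_kb),
            "p_thresholds": list(grid.p_thresholds),
        },
        "mask": None if mask is None else {
            "chrom": mask[0].chrom, "start": mask[0].start, "end": mask[0].end,
            "label": mask[0].label, "flank_bp": mask[1],
        },
        "fit_mode": fit_mode,
        "rank_rule": list(rank_rule),
        "sources": {lab: {"selected": cv_reports[lab].selected, "n_variants": source_tables[lab].n_variants}
                    for lab in sorted(source_tables)},
        "meta": {"selected": cv_reports["meta"].selected, "n_variants": meta_table.n_variants},
        "combination_weights": {k: round(v, 12) for k, v in model.weights.items()},
        "strategies": sorted(strategy_prs),
        "selected": selected,
        "results": [
            {k: (round(v, 10) if isinstance(v, float) else v) for k, v in r.to_dict().items()}
            for r in ranking
        ],
    }
    return TrainingArtifacts(
        source_tables=source_tables, cv_reports=cv_reports, combination_model=model,
        collapsed_table=collapsed, collapsed_scaling=collapsed_scaling,
        strategy_prs=strategy_prs, results=results, ranking=ranking, selected=selected,
        manifest=manifest,
    )


def run_validation_data(
    artifacts: TrainingArtifacts,
    validation: tuple[GenotypeMatrix, CohortPhenotypes, KinshipTable],
    sex_strata: bool = True,
) -> list[EvalResult]:
    """Apply the frozen collapsed weights and scaling to a held-out cohort.

    The scaling reference is never refit here; the API deliberately offers
    no path to do so.  Returns the overall association plus sex strata.
    """
    G_val, ph_val, kin_val = validation
    scores = score_prs(G_val, artifacts.collapsed_table)
    scaled = standardize(scores, artifacts.collapsed_scaling)

    keep = set(select_unrelated(list(G_val.sample_ids), kin_val))
    mask = np.array([s in keep for s in G_val.sample_ids])
    ph = ph_val.aligned_to(G_val.sample_ids[mask])
    vals = scaled.values[mask]
    covs = ph[[c for c in EVAL_COVARIATES if c in ph.columns]]
    overall = fit_logistic_assoc(ph["ad_status"].to_numpy(float), vals, covs, model_label="validation")
    overall.auc = compute_auc(overall.metadata["fitted_probabilities"], ph["ad_status"].to_numpy(float))
    out = [overall]
    if sex_strata:
        out += stratify_assoc(
            ph.assign(sample_id=ph["sample_id"]), vals, StratificationSpec("sex"),
            [c for c in EVAL_COVARIATES if c in ph.columns], kin=None, model_label="validation",
        )
    return out


# ---------------------------------------------------------------------------
# config-driven file layer


@dataclass
class PipelineConfig:
    """Paths and parameters for a file-driven training/validation run."""

    sumstats: dict[str, str]
    reference_genotypes: str
    tuning_genotypes: str
    tuning_phenotypes: str
    tuning_kinship: str | None
    training_genotypes: str
    training_phenotypes: str
    eval_genotypes: str
    eval_phenotypes: str
    eval_kinship: str | None
    validation_genotypes: str | None
    validation_phenotypes: str | None
    validation_kinship: str | None
    out_dir: str
    seed: int
    grid: CTGridSpec = field(default_factory=CTGridSpec)
    mask: dict | None = None  # {chrom,start,end,label,flank_bp}
    fit_mode: str = "marginal"
    rank_rule: tuple[str, ...] = ("auc", "or", "p")
    cv_k: int = 5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        required = [
            "sumstats", "reference_genotypes", "tuning_genotypes", "tuning_phenotypes",
            "training_genotypes", "training_phenotypes", "eval_genotypes", "eval_phenotypes",
            "out_dir", "seed",
        ]
        missing = [k for k in required if k not in raw]
        if missing:
            raise ValueError(f"pipeline config missing required key(s): {missing}")
        if not isinstance(raw["seed"], int):
            raise ValueError("config seed must be an explicit integer (no wall-clock defaults)")
        grid_raw = raw.get("grid", {})
        grid = CTGridSpec(
            r2_thresholds=tuple(grid_raw.get("r2_thresholds", CTGridSpec().r2_thresholds)),
            windows_kb=tuple(grid_raw.get("windows_kb", CTGridSpec().windows_kb)),
            p_thresholds=tuple(grid_raw.get("p_thresholds", CTGridSpec().p_thresholds)),
        )
        return cls(
            sumstats=dict(raw["sumstats"]),
            reference_genotypes=raw["reference_genotypes"],
            tuning_genotypes=raw["tuning_genotypes"],
            tuning_phenotypes=raw["tuning_phenotypes"],
            tuning_kinship=raw.get("tuning_kinship"),
            training_genotypes=raw["training_genotypes"],
            training_phenotypes=raw["training_phenotypes"],
            eval_genotypes=raw["eval_genotypes"],
            eval_phenotypes=raw["eval_phenotypes"],
            eval_kinship=raw.get("eval_kinship"),
            validation_genotypes=raw.get("validation_genotypes"),
            validation_phenotypes=raw.get("validation_phenotypes"),
            validation_kinship=raw.get("validation_kinship"),
            out_dir=raw["out_dir"],
            seed=int(raw["seed"]),
            grid=grid,
            mask=raw.get("mask"),
            fit_mode=raw.get("fit_mode", "marginal"),
            rank_rule=tuple(raw.get("rank_rule", ("auc", "or", "p"))),
            cv_k=int(raw.get("cv_k", 5)),
        )

    def mask_tuple(self) -> tuple[GenomicRegion, int] | None:
        if self.mask is None:
            return None
        m = self.mask
        region = GenomicRegion(str(m["chrom"]), int(m["start"]), int(m["end"]), m.get("label", "mask"))
        return region, int(m.get("flank_bp", 1_000_000))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_cohort(geno_path, pheno_path, kin_path):
    G = mio.read_genotypes_tsv(geno_path) if not str(geno_path).endswith((".vcf", ".vcf.gz")) else mio.read_vcf_dosage(geno_path)
    phen = mio.read_phenotypes_tsv(pheno_path)
    kin = mio.read_kinship_tsv(kin_path) if kin_path else KinshipTable.empty()
    return G, phen, kin


def run_training(config: PipelineConfig) -> TrainingArtifacts:
    """File-driven training run: load inputs, run the flow, write artifacts + manifest."""
    from .sumstats import read_sumstats

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sumstats = {lab: read_sumstats(p, study_label=lab) for lab, p in config.sumstats.items()}
    reference = (
        mio.read_vcf_dosage(config.reference_genotypes)
        if str(config.reference_genotypes).endswith((".vcf", ".vcf.gz"))
        else mio.read_genotypes_tsv(config.reference_genotypes)
    )
    tuning = _load_cohort(config.tuning_genotypes, config.tuning_phenotypes, config.tuning_kinship)
    training = _load_cohort(config.training_genotypes, config.training_phenotypes, None)
    evaluation = _load_cohort(config.eval_genotypes, config.eval_phenotypes, config.eval_kinship)

    art = run_training_data(
        sumstats, reference, tuning, training, evaluation,
        grid=config.grid, mask=config.mask_tuple(), fit_mode=config.fit_mode,
        cv_k=config.cv_k, seed=config.seed, rank_rule=config.rank_rule,
    )

    write_weight_table(art.collapsed_table, out / "collapsed_weights.tsv")
    (out / "collapsed_scaling.json").write_text(art.collapsed_scaling.to_json())
    (out / "combination_model.json").write_text(art.combination_model.to_json())
    for lab, table in art.source_tables.items():
        write_weight_table(table, out / f"weights_{lab}.tsv")
    results_frame = pd.DataFrame([r.to_dict() for r in art.ranking])
    results_frame.to_csv(out / "evaluation_results.tsv", sep="\t", index=False)

    manifest = dict(art.manifest)
    manifest["inputs"] = {
        "sumstats": {lab: _sha256(Path(p)) for lab, p in config.sumstats.items()},
        "reference_genotypes": _sha256(Path(config.reference_genotypes)),
    }
    manifest["artifacts"] = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.suffix in (".tsv", ".json") and p.name != "manifest.json"
    }
    art.manifest = manifest
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return art


def run_validation(config: PipelineConfig, artifacts: TrainingArtifacts) -> list[EvalResult]:
    """File-driven validation run against the frozen training artifacts."""
    if not (config.validation_genotypes and config.validation_phenotypes):
        raise ValueError("config lacks validation cohort paths")
    validation = _load_cohort(
        config.validation_genotypes, config.validation_phenotypes, config.validation_kinship
    )
    results = run_validation_data(artifacts, validation)
    out = Path(config.out_dir)
    pd.DataFrame([r.to_dict() for r in results]).to_csv(out / "validation_results.tsv", sep="\t", index=False)
    return results
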