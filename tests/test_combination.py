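"""Summation-weight training, combination arithmetic and collapse equivalence."""

import numpy as np
import pandas as pd
import pytest

from multiprs import (
    CohortPhenotypes,
    ScalingReference,
    SourcePRSMatrix,
    WeightTable,
    build_source_matrix,
    collapse_to_variant_weights,
    combine_unweighted,
    combine_weighted,
    score_prs,
    train_combination_weights,
)
from multiprs._liability import gaussian_grid, logistic_slope_from_liability

from conftest import make_genotypes


def phen_from(y, n, rng, extra=None):
    t = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "ad_status": y.astype(int),
            "age": rng.normal(75, 6, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "apoe_e4_count": rng.integers(0, 2, n),
            "apoe_e2_count": 0,
            "cohort_label": "train",
            "ancestry": "EA",
        }
    )
    for j in range(1, 11):
        t[f"pc{j}"] = rng.normal(0, 0.3, n)
    if extra:
        for k, v in extra.items():
            t[k] = v
    return CohortPhenotypes(t)


def matrix_from(values: dict, n):
    ids = np.array([f"S{i}" for i in range(n)], dtype=object)
    return SourcePRSMatrix(ids, pd.DataFrame(values))


class TestTrainWeights:
    def _mixture(self, seed, n=20_000, c1=1.0, c2=0.0):
        rng = np.random.default_rng(seed)
        s1 = rng.standard_normal(n)
        s2 = rng.standard_normal(n)
        lia = c1 * s1 + c2 * s2 + rng.normal(0, np.sqrt(max(1 - c1**2 - c2**2, 0.05)), n)
        y = (lia > np.quantile(rng.normal(0, 1, 200_000) * lia.std(), 0.8)).astype(float)
        # threshold via the distributional quantile, not in-sample forcing
        y = (lia > np.sqrt(lia.var()) * 0.8416).astype(float)  # 20% prevalence
        return s1, s2, lia, y, rng

    def test_parameter_recovery_marginal_and_joint(self):
        c1, c2 = 0.5, 0.0
        s1, s2, lia, y, rng = self._mixture(100, c1=c1, c2=c2)
        M = matrix_from({"src1": s1, "src2": s2}, len(s1))
        phen = phen_from(y, len(s1), rng)
        x, wts = gaussian_grid()
        target1 = logistic_slope_from_liability(c1, x, wts, prevalence=0.2)
        for mode in ("marginal", "joint"):
            model = train_combination_weights(M, phen, fit_mode=mode)
            assert abs(model.weights["src1"] - target1) < 2 * model.weight_ses["src1"]
            assert abs(model.weights["src2"]) < 2 * model.weight_ses["src2"]

    def test_duplicated_sources_reported_in_joint_mode(self):
        s1, s2, lia, y, rng = self._mixture(101, n=2000, c1=0.5)
        M = matrix_from({"a": s1, "b": s1.copy()}, len(s1))
        model = train_combination_weights(M, phen_from(y, len(s1), rng), fit_mode="joint")
        assert any("collinear" in w for w in model.fit_metadata["warnings"])

    def test_permuted_phenotype_gives_null_weights(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            n = 3000
            s1 = rng.standard_normal(n)
            s2 = rng.standard_normal(n)
            y = rng.binomial(1, 0.2, n).astype(float)  # independent of sources
            M = matrix_from({"a": s1, "b": s2}, n)
            model = train_combination_weights(M, phen_from(y, n, rng))
            ok = all(abs(model.weights[k]) < 2 * model.weight_ses[k] for k in ("a", "b"))
            hits += ok
        assert hits >= 17  # ~95% joint coverage of two 2-se intervals

    def test_affine_rescaling_invariance(self):
        s1, s2, lia, y, rng = self._mixture(102, n=5000, c1=0.5)
        M = matrix_from({"a": s1, "b": s2}, len(s1))
        phen = phen_from(y, len(s1), rng)
        m0 = train_combination_weights(M, phen)
        # rescale source a by 3 and refit its scaling: per-SD weight must match
        prs_raw = {"a": 3 * s1 + 7, "b": s2}
        refit = {"a": ScalingReference(7.0, 3.0), "b": ScalingReference(0.0, 1.0)}
        from multiprs import PRSVector

        vecs = {
            k: PRSVector(M.sample_ids, v, np.zeros(len(v), int)) for k, v in prs_raw.items()
        }
        M2 = build_source_matrix(vecs, refit)
        m1 = train_combination_weights(M2, phen, per_source_scaling=refit)
        assert m1.weights["a"] == pytest.approx(m0.weights["a"], rel=1e-6)


class TestCombine:
    def _model(self, labels, weights, final=None):
        return __import__("multiprs").CombinationModel(
            source_labels=tuple(labels),
            weights=dict(zip(labels, weights)),
            weight_ses={k: 0.1 for k in labels},
            per_source_scaling={k: ScalingReference(0.0, 1.0) for k in labels},
            final_scaling=final or ScalingReference(0.0, 1.0),
        )

    def test_selection_weights(self):
        rng = np.random.default_rng(1)
        n = 50
        M = matrix_from({"a": rng.standard_normal(n), "b": rng.standard_normal(n)}, n)
        model = self._model(["a", "b"], [1.0, 0.0])
        out = combine_weighted(M, model)
        assert np.allclose(out.values, M.columns["a"])

    def test_equal_weights_proportional_to_unweighted(self):
        rng = np.random.default_rng(2)
        n = 200
        M = matrix_from({"a": rng.standard_normal(n), "b": rng.standard_normal(n)}, n)
        model = self._model(["a", "b"], [0.7, 0.7])
        w = combine_weighted(M, model)
        u, _ = combine_unweighted(M)
        assert abs(np.corrcoef(w.values, u.values)[0, 1] - 1.0) < 1e-12

    def test_matches_hand_linear_combination(self):
        rng = np.random.default_rng(3)
        n, k = 100, 4
        cols = {f"s{j}": rng.standard_normal(n) for j in range(k)}
        wts = rng.normal(size=k)
        M = matrix_from(cols, n)
        model = self._model(list(cols), wts)
        out = combine_weighted(M, model)
        oracle = sum(wts[j] * cols[f"s{j}"] for j in range(k))
        assert np.allclose(out.values, oracle, atol=1e-12)

    def test_label_mismatch_is_hard_error(self):
        rng = np.random.default_rng(4)
        M = matrix_from({"a": rng.standard_normal(10), "b": rng.standard_normal(10)}, 10)
        model = self._model(["a", "c"], [1.0, 1.0])
        with pytest.raises(ValueError, match="label mismatch"):
            combine_weighted(M, model)

    def test_unweighted_single_source_identity(self):
        rng = np.random.default_rng(5)
        vals = rng.standard_normal(100)
        M = matrix_from({"a": vals}, 100)
        out, ref = combine_unweighted(M)
        assert np.allclose(out.values, (vals - vals.mean()) / vals.std(ddof=1), atol=1e-12)

    def test_cancelling_sources_surface_sd_zero_error(self):
        x = np.random.default_rng(6).standard_normal(50)
        M = matrix_from({"a": x, "b": -x}, 50)
        with pytest.raises(ValueError, match="sd = 0"):
            combine_unweighted(M)

    def test_unweighted_equals_unit_weighted(self):
        rng = np.random.default_rng(7)
        M = matrix_from({"a": rng.standard_normal(80), "b": rng.standard_normal(80)}, 80)
        u, ref = combine_unweighted(M)
        model = self._model(["a", "b"], [1.0, 1.0], final=ref)
        w = combine_weighted(M, model)
        assert np.allclose(u.values, w.values, atol=1e-12)


class TestCollapse:
    def _tables(self, G, rng, k=2, subset=None):
        out = {}
        for j in range(k):
            t = G.variants[["chrom", "pos", "id", "effect_allele", "other_allele"]].copy()
            t["weight"] = rng.normal(0, 0.1, len(t))
            if subset is not None:
                t = t.iloc[subset[j]].reset_index(drop=True)
            out[f"s{j}"] = WeightTable(t, provenance={"source": f"s{j}"})
        return out

    def test_single_source_unit_weight_identity(self):
        rng = np.random.default_rng(8)
        G = make_genotypes(rng.integers(0, 3, size=(10, 6)).astype(float))
        (tbl,) = self._tables(G, rng, k=1).values()
        model = __import__("multiprs").CombinationModel(
            source_labels=("s0",), weights={"s0": 1.0}, weight_ses={"s0": 0.1},
            per_source_scaling={"s0": ScalingReference(0.0, 1.0)},
            final_scaling=ScalingReference(0.0, 1.0),
        )
        out = collapse_to_variant_weights(model, {"s0": tbl})
        merged = out.table.merge(tbl.table, on=["chrom", "pos"], suffixes=("_c", "_s"))
        assert np.allclose(merged["weight_c"], merged["weight_s"])

    def test_shared_variant_weighted_sum(self):
        rng = np.random.default_rng(9)
        G = make_genotypes(rng.integers(0, 3, size=(10, 1)).astype(float))
        tabs = self._tables(G, rng, k=2)
        model = __import__("multiprs").CombinationModel(
            source_labels=("s0", "s1"), weights={"s0": 0.5, "s1": 2.0},
            weight_ses={"s0": 0.1, "s1": 0.1},
            per_source_scaling={"s0": ScalingReference(0.0, 2.0), "s1": ScalingReference(0.0, 4.0)},
            final_scaling=ScalingReference(0.0, 1.0),
        )
        out = collapse_to_variant_weights(model, tabs)
        expect = 0.5 * tabs["s0"].table["weight"].iloc[0] / 2.0 + 2.0 * tabs["s1"].table["weight"].iloc[0] / 4.0
        assert out.table["weight"].iloc[0] == pytest.approx(expect)

    def test_orientation_conflict_is_hard_error(self):
        rng = np.random.default_rng(10)
        G = make_genotypes(rng.integers(0, 3, size=(10, 2)).astype(float))
        tabs = self._tables(G, rng, k=2)
        flipped = tabs["s1"].table.copy()
        flipped[["effect_allele", "other_allele"]] = flipped[["other_allele", "effect_allele"]].to_numpy()
        tabs["s1"] = WeightTable(flipped)
        model = __import__("multiprs").CombinationModel(
            source_labels=("s0", "s1"), weights={"s0": 1.0, "s1": 1.0},
            weight_ses={"s0": 0.1, "s1": 0.1},
            per_source_scaling={k: ScalingReference(0.0, 1.0) for k in ("s0", "s1")},
            final_scaling=ScalingReference(0.0, 1.0),
        )
        with pytest.raises(ValueError, match="orientation"):
            collapse_to_variant_weights(model, tabs)

    @pytest.mark.parametrize("seed", range(5))
    def test_collapse_equivalence_with_weighted_combination(self, seed):
        rng = np.random.default_rng(40 + seed)
        n, m = 200, 30
        G = make_genotypes(rng.integers(0, 3, size=(n, m)).astype(float))
        subset = [rng.choice(m, 20, replace=False), rng.choice(m, 20, replace=False)]
        tabs = self._tables(G, rng, k=2, subset=subset)
        prs = {k: score_prs(G, t) for k, t in tabs.items()}
        scalings = {k: ScalingReference(float(p.values.mean()), float(p.values.std(ddof=1))) for k, p in prs.items()}
        M = build_source_matrix(prs, scalings)
        wts = rng.normal(size=2)
        model = __import__("multiprs").CombinationModel(
            source_labels=("s0", "s1"), weights={"s0": wts[0], "s1": wts[1]},
            weight_ses={"s0": 0.1, "s1": 0.1}, per_source_scaling=scalings,
            final_scaling=ScalingReference(0.0, 1.0),
        )
        combined = combine_weighted(M, model)
        collapsed = collapse_to_variant_weights(model, tabs)
        direct = score_prs(G, collapsed)
        assert abs(np.corrcoef(direct.values, combined.values)[0, 1]) > 0.999999
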