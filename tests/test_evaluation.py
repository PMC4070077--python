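"""Cross-validation protocol, ranking metrics, shuffle test, candidates."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from netprio.core import GeneSetCollection, GeneUniverse
from netprio.evaluation import (
    auc,
    add_permutation_pvalues,
    candidate_analysis,
    cross_validate,
    estimate_internal_weights,
    filter_diseases,
    make_cv_plan,
    permutation_test,
    precision_at_recall,
)
from netprio.kernels import random_walk_kernel
from netprio.prioritizers import build_scorer


class TestFilterDiseases:
    def test_inclusive_boundaries(self):
        n = 250
        u = GeneUniverse(f"g{i}" for i in range(n))
        sets = GeneSetCollection(
            {
                "too_small": [f"g{i}" for i in range(4)],
                "at_min": [f"g{i}" for i in range(5)],
                "at_max": [f"g{i}" for i in range(200)],
                "too_big": [f"g{i}" for i in range(201)],
            },
            u,
        )
        kept = filter_diseases(sets)
        assert set(kept) == {"at_min", "at_max"}

    def test_empty_and_identity(self, two_gene_sets):
        assert len(filter_diseases(two_gene_sets, 100, 200)) == 0
        assert set(filter_diseases(two_gene_sets, 1, 10)) == {"D1", "D2"}


class TestAUC:
    def test_perfect_separation(self):
        s = np.array([0.9, 0.8, 0.7, 0.1])
        assert auc(s, np.array([True, True, False, False])) == 1.0

    def test_single_tie_is_half(self):
        assert auc(np.array([0.5, 0.5]), np.array([True, False])) == 0.5

    def test_degenerate_class_is_nan(self):
        assert np.isnan(auc(np.array([1.0, 2.0]), np.array([True, True])))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_counting_oracle_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        s = np.round(rng.random(40), 1)  # coarse grid forces ties
        y = rng.random(40) < 0.3
        if y.all() or not y.any():
            y[:2] = [True, False]
        pos, neg = s[y], s[~y]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        oracle = wins / (pos.size * neg.size)
        assert auc(s, y) == pytest.approx(oracle)
        assert auc(s, y) == pytest.approx(roc_auc_score(y, s))

    def test_invariant_under_monotone_transform(self, rng):
        s = rng.random(30)
        y = rng.random(30) < 0.4
        y[0], y[1] = True, False
        assert auc(np.exp(3 * s), y) == pytest.approx(auc(s, y))


class TestPrecisionAtRecall:
    def test_hand_walked_ranking(self):
        # positives at ranks 1 and 4 of 4
        s = np.array([0.9, 0.7, 0.5, 0.3])
        y = np.array([True, False, False, True])
        p = precision_at_recall(s, y, [0.5, 1.0])
        assert p == [1.0, 0.5]

    def test_all_positives_first(self):
        s = np.array([0.9, 0.8, 0.2, 0.1])
        y = np.array([True, True, False, False])
        assert precision_at_recall(s, y, [0.1, 0.5, 1.0]) == [1.0, 1.0, 1.0]

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_cutoff_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.random(25)
        y = rng.random(25) < 0.3
        if not y.any():
            y[3] = True
        levels = [0.2, 0.5, 0.8, 1.0]
        got = precision_at_recall(s, y, levels)
        order = np.argsort(-s, kind="stable")
        for r, p in zip(levels, got):
            best = None
            for cut in range(1, 26):
                topk = order[:cut]
                recall = y[topk].sum() / y.sum()
                if recall >= r:
                    best = y[topk].sum() / cut
                    break
            assert p == pytest.approx(best)


class TestCVPlan:
    def test_partition_property(self):
        u = GeneUniverse(f"g{i}" for i in range(100))
        plan = make_cv_plan(u, f=5, seed=3)
        seen = np.concatenate([plan.test_indices(t) for t in range(5)])
        assert sorted(seen.tolist()) == list(range(100))
        sizes = [plan.test_indices(t).size for t in range(5)]
        assert max(sizes) - min(sizes) <= 1

    def test_stratified_spreads_positives(self):
        u = GeneUniverse(f"g{i}" for i in range(50))
        sets = GeneSetCollection({"D": [f"g{i}" for i in range(5)]}, u)
        plan = make_cv_plan(u, f=5, seed=1, stratify_for=sets)
        folds_of_pos = plan.fold_of[:5]
        assert len(set(folds_of_pos.tolist())) == 5

    def test_too_few_folds_rejected(self):
        u = GeneUniverse(["a", "b"])
        with pytest.raises(ValueError, match=">= 2"):
            make_cv_plan(u, f=1)


class TestCrossValidate:
    def test_informative_network_scores_high(self, planted):
        col, sets, _ = planted
        kern = random_walk_kernel(col.members[0], a=2.0, q=3)
        plan = make_cv_plan(col.universe, f=5, seed=0)
        report = cross_validate(build_scorer("sav", kernel=kern), sets, plan)
        assert report["auc"].mean() > 0.8

    def test_noise_network_near_chance(self, planted):
        col, sets, _ = planted
        kern = random_walk_kernel(col.members[2], a=2.0, q=3)  # iota = 0
        plan = make_cv_plan(col.universe, f=5, seed=0)
        report = cross_validate(build_scorer("sav", kernel=kern), sets, plan)
        assert abs(report["auc"].mean() - 0.5) < 0.12

    def test_five_fold_close_to_leave_one_out(self, planted):
        col, sets, _ = planted
        kern = random_walk_kernel(col.members[0], a=2.0, q=3)
        scorer = build_scorer("sav", kernel=kern)
        auc5 = cross_validate(
            scorer, sets, make_cv_plan(col.universe, f=5, seed=1)
        )["auc"].mean()
        aucn = cross_validate(
            scorer, sets, make_cv_plan(col.universe, f=col.universe.n, seed=1)
        )["auc"].mean()
        assert abs(auc5 - aucn) < 0.05

    def test_fold_with_all_positives_warns_and_zeroes(self, caplog):
        u = GeneUniverse(f"g{i}" for i in range(10))
        sets = GeneSetCollection({"D": ["g0", "g1"]}, u)
        plan = make_cv_plan(u, f=5, seed=0)
        plan.fold_of[:] = np.arange(10) % 5
        plan.fold_of[[0, 1]] = 0  # both positives in fold 0
        scorer = lambda idx: np.ones(10)
        with caplog.at_level("WARNING"):
            report = cross_validate(scorer, sets, plan)
        assert "every positive" in caplog.text
        assert len(report) == 1


class TestInternalWeights:
    def _setup(self, planted):
        col, sets, _ = planted
        scorers = {
            name: build_scorer("sav", kernel=random_walk_kernel(m, a=2.0, q=3))
            for name, m in zip(col.names, col.members)
        }
        return col, sets, scorers

    def test_identical_networks_get_uniform_weights(self, planted):
        col, sets, _ = planted
        kern = random_walk_kernel(col.members[0], a=2.0, q=3)
        scorer = build_scorer("sav", kernel=kern)
        scorers = {"a": scorer, "b": scorer, "c": scorer}
        g = estimate_internal_weights(scorers, sets, np.arange(col.universe.n), seed=0)
        np.testing.assert_allclose(g.per_class.values, 1 / 3, atol=1e-9)

    def test_single_network_weight_is_one(self, planted):
        col, sets, scorers = self._setup(planted)
        only = {"net1": scorers["net1"]}
        g = estimate_internal_weights(only, sets, np.arange(col.universe.n), seed=0)
        np.testing.assert_allclose(g.per_class.values, 1.0)

    def test_informative_network_outweighs_noise(self, planted):
        col, sets, scorers = self._setup(planted)
        g = estimate_internal_weights(scorers, sets, np.arange(col.universe.n), seed=0)
        avg = g.averaged()
        assert avg["net1"] > avg["net3"]

    def test_no_test_label_leakage(self, planted):
        """Sentinel check: adding or removing positives inside the held-out
        fold must leave the estimated weights bit-identical."""
        col, sets, scorers = self._setup(planted)
        plan = make_cv_plan(col.universe, f=5, seed=7)
        train_idx = plan.train_indices(0)
        test_idx = plan.test_indices(0)
        g_ref = estimate_internal_weights(scorers, sets, train_idx, seed=5)
        tampered = {}
        rng = np.random.default_rng(0)
        for d in sets:
            genes = set(sets[d])
            sentinel = {col.universe.genes[i] for i in rng.choice(test_idx, 3, replace=False)}
            tampered[d] = (genes - {col.universe.genes[i] for i in test_idx}) | sentinel
        tampered_sets = GeneSetCollection(tampered, col.universe)
        g_tam = estimate_internal_weights(scorers, tampered_sets, train_idx, seed=5)
        np.testing.assert_array_equal(g_ref.per_class.values, g_tam.per_class.values)

    def test_loo_mode_runs_and_orders_networks(self, planted):
        col, sets, scorers = self._setup(planted)
        sub = {"net1": scorers["net1"], "net3": scorers["net3"]}
        g = estimate_internal_weights(
            sub, sets, np.arange(col.universe.n), internal_folds="loo", seed=0
        )
        assert g.averaged()["net1"] > g.averaged()["net3"]


class TestPermutationTest:
    def test_ratio_definition_and_add_one(self, rng):
        s = rng.random(50)
        y = rng.random(50) < 0.2
        y[0] = True
        m, p = permutation_test(s, y, n_shuffles=200, seed=1)
        assert p == m / 200
        m2, p2 = permutation_test(s, y, n_shuffles=200, seed=1, add_one=True)
        assert m2 == m and p2 == (m + 1) / 201

    def test_separated_scores_give_p_zero(self):
        n = 100
        s = np.arange(n, dtype=float)
        y = np.zeros(n, dtype=bool)
        y[-10:] = True  # positives are exactly the top scores
        m, p = permutation_test(s, y, n_shuffles=200, seed=0)
        assert m == 0 and p == 0.0

    def test_reproducible_under_seed(self, rng):
        s = rng.random(60)
        y = rng.random(60) < 0.3
        y[0] = True
        assert permutation_test(s, y, 100, seed=9) == permutation_test(s, y, 100, seed=9)


class TestCandidateAnalysis:
    def _frame(self, aucs, ps, index):
        return pd.DataFrame({"auc": aucs, "p_value": ps}, index=index)

    def test_hand_derived_percentiles(self):
        u = GeneUniverse(["a1", "a2", "u1", "u2", "u3", "u4"])
        sets = GeneSetCollection({"D": ["a1", "a2"]}, u)
        scores = {"D": np.array([0.9, 0.6, 0.8, 0.7, 0.5, 0.4])}
        report = self._frame([0.99], [0.0], ["D"])
        tab = candidate_analysis(scores, sets, report, top=2)
        assert tab["gene"].tolist() == ["u1", "u2"]
        assert tab["percentile"].tolist() == [75.0, 50.0]

    def test_top_unannotated_above_all_annotated_is_100th(self):
        u = GeneUniverse(["a1", "u1", "u2"])
        sets = GeneSetCollection({"D": ["a1"]}, u)
        scores = {"D": np.array([0.5, 0.9, 0.1])}
        report = self._frame([0.99], [0.0], ["D"])
        tab = candidate_analysis(scores, sets, report, top=1)
        assert tab["percentile"].iloc[0] == 100.0

    def test_below_support_gene_flagged_zero(self):
        u = GeneUniverse(["a1", "u1"])
        sets = GeneSetCollection({"D": ["a1"]}, u)
        scores = {"D": np.array([0.5, 0.1])}
        report = self._frame([0.99], [0.0], ["D"])
        tab = candidate_analysis(scores, sets, report, top=1)
        assert tab["percentile"].iloc[0] == 0.0
        assert bool(tab["below_support"].iloc[0])

    def test_no_disease_passes_gives_empty_table(self):
        u = GeneUniverse(["a1", "u1"])
        sets = GeneSetCollection({"D": ["a1"]}, u)
        scores = {"D": np.array([0.5, 0.1])}
        report = self._frame([0.6], [0.5], ["D"])
        tab = candidate_analysis(scores, sets, report)
        assert tab.empty


def test_add_permutation_pvalues_columns(planted):
    col, sets, _ = planted
    kern = random_walk_kernel(col.members[0], a=2.0, q=3)
    plan = make_cv_plan(col.universe, f=5, seed=0)
    report, assembled = cross_validate(
        build_scorer("sav", kernel=kern), sets, plan, return_scores=True
    )
    out = add_permutation_pvalues(report, assembled, sets, n_shuffles=50, seed=1)
    assert {"m", "p_value"} <= set(out.columns)
    assert ((out["p_value"] >= 0) & (out["p_value"] <= 1)).all()
    assert (out["p_value"] == out["m"] / 50).all()
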