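"""Fold construction, R-squared, CV driver, robustness and gene characterization."""

import numpy as np
import pandas as pd
import pytest

from cisxpred import evaluation as ev
from cisxpred.io_core import PopulationLabels


def _pops(sizes):
    ids, labels = [], []
    for pop, n in sizes.items():
        for i in range(n):
            ids.append(f"{pop}_{i}")
            labels.append(pop)
    return PopulationLabels(ids, labels)


class TestFolds:
    def test_cross_pop_holds_out_whole_populations(self):
        pops = _pops({"CEU": 10, "YRI": 8, "CHB": 6, "JPT": 6})
        fa = ev.make_cv_folds(pops, "cross_pop")
        assert len(fa.folds) == 4
        pop_map = pops.as_dict()
        for (train, test), label in zip(fa.folds, fa.fold_labels):
            assert {pop_map[i] for i in test} == {label}
            assert label not in {pop_map[i] for i in train}
            assert set(train) | set(test) == set(pops.individual_ids)

    def test_mixed_pop_partitions_with_balance(self):
        pops = _pops({"A": 50, "B": 50})
        fa = ev.make_cv_folds(pops, "mixed_pop", n_folds=5, seed=1)
        tests = [set(t) for _, t in fa.folds]
        assert all(len(t) == 20 for t in tests)
        assert set().union(*tests) == set(pops.individual_ids)
        for i, t in enumerate(tests):
            for u in tests[i + 1:]:
                assert not (t & u)

    def test_intra_pop_never_mixes_populations(self):
        pops = _pops({"A": 12, "B": 15})
        fa = ev.make_cv_folds(pops, "intra_pop", n_folds=5, seed=0)
        pop_map = pops.as_dict()
        assert len(fa.folds) == 10
        for train, test in fa.folds:
            used = {pop_map[i] for i in train} | {pop_map[i] for i in test}
            assert len(used) == 1

    def test_deterministic_given_seed(self):
        pops = _pops({"A": 21, "B": 17})
        a = ev.make_cv_folds(pops, "mixed_pop", seed=5)
        b = ev.make_cv_folds(pops, "mixed_pop", seed=5)
        assert a.folds == b.folds

    def test_single_population_cross_pop_errors(self):
        with pytest.raises(ValueError):
            ev.make_cv_folds(_pops({"A": 10}), "cross_pop")

    def test_small_population_intra_pop_errors(self):
        with pytest.raises(ValueError, match="'B'"):
            ev.make_cv_folds(_pops({"A": 10, "B": 3}), "intra_pop", n_folds=5)


class TestRSquared:
    def test_perfect(self):
        assert ev.r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_mean_prediction_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert ev.r_squared(y, np.full(3, 2.0)) == 0.0

    def test_anti_prediction_negative(self):
        assert ev.r_squared([0.0, 1.0], [1.0, 0.0]) == pytest.approx(-3.0)

    def test_shift_invariance(self, rng):
        y = rng.normal(size=20)
        p = rng.normal(size=20)
        assert ev.r_squared(y + 5, p + 5) == pytest.approx(
            ev.r_squared(y, p), abs=1e-10
        )

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            ev.r_squared([1.0, 1.0], [0.0, 2.0])


class TestRunGeneCv:
    def test_result_count_and_determinism(self, small_dataset):
        ds, _ = small_dataset
        gene = ds.expression.gene_ids[0]
        cfg = ev.RunConfig()
        res1, f1 = ev.run_gene_cv(ds, [gene], ["single", "knn", "enet"],
                                  "cross_pop", cfg, seed=2)
        assert not f1
        assert len(res1) == 2 * 3  # 2 populations x 3 models
        res2, _ = ev.run_gene_cv(ds, [gene], ["single", "knn", "enet"],
                                 "cross_pop", cfg, seed=2)
        for a, b in zip(res1, res2):
            assert a.test_r2 == b.test_r2
            assert a.predictions == b.predictions

    def test_test_predictions_cover_held_out_individuals(self, small_dataset):
        ds, _ = small_dataset
        gene = ds.expression.gene_ids[0]
        res, _ = ev.run_gene_cv(ds, [gene], ["knn"], "mixed_pop",
                                ev.RunConfig(n_folds=5), seed=0)
        covered = set()
        for r in res:
            assert not (covered & set(r.predictions))
            covered |= set(r.predictions)
        assert covered == set(ds.genotypes.individual_ids)

    def test_train_only_centering_runs(self, small_dataset):
        ds, _ = small_dataset
        gene = ds.expression.gene_ids[0]
        cfg = ev.RunConfig(center_scope="train_only")
        res, fails = ev.run_gene_cv(ds, [gene], ["single"], "mixed_pop", cfg)
        assert not fails and len(res) == 5

    def test_train_only_centering_ill_posed_for_cross_pop(self, small_dataset):
        """A held-out population has no training individuals to define its mean."""
        ds, _ = small_dataset
        gene = ds.expression.gene_ids[0]
        cfg = ev.RunConfig(center_scope="train_only")
        res, fails = ev.run_gene_cv(ds, [gene], ["single"], "cross_pop", cfg)
        assert gene in fails and not res


class TestRobustness:
    def test_fraction_example(self):
        assert ev.robustness_fraction([0.2, 0.4], [0.1, 0.1], 0.5) == 0.5

    def test_threshold_zero_counts_nonnegative(self):
        assert ev.robustness_fraction([0.2, 0.3], [0.0, 0.2], 0.0) == 1.0

    def test_identical_always_robust(self, rng):
        r2 = rng.uniform(0.06, 0.9, size=30)
        for t in (0.1, 0.5, 1.0):
            assert ev.robustness_fraction(r2, r2, t) == 1.0

    def test_monotone_in_threshold(self, rng):
        tr = rng.uniform(0, 1, size=50)
        te = rng.uniform(-0.2, 1, size=50)
        grid = np.linspace(0, 1.2, 13)
        fracs = [ev.robustness_fraction(tr, te, t) for t in grid]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_empty_gene_set_errors(self):
        with pytest.raises(ValueError, match="empty gene set"):
            ev.robustness_fraction([0.01], [0.5], 0.5)


class TestConcordance:
    def test_identity_gives_unit_correlations(self, rng):
        r2 = rng.uniform(0, 1, size=20)
        rep = ev.concordance_and_bins(r2, r2, [0, 0.5, 1.0])
        assert rep.pearson == pytest.approx(1.0)
        assert rep.spearman == pytest.approx(1.0)

    def test_negated_gives_minus_one(self):
        tr = np.array([0.1, 0.2, 0.5, 0.7])
        rep = ev.concordance_and_bins(tr, -tr, [0, 1.0])
        assert rep.pearson == pytest.approx(-1.0)

    def test_bin_means(self):
        tr = np.array([0.22, 0.25, 0.28, 0.9])
        te = np.array([0.1, 0.2, 0.3, 0.5])
        rep = ev.concordance_and_bins(tr, te, [0.2, 0.3, 1.0])
        row = rep.bins.iloc[0]
        assert row["n_genes"] == 3
        assert row["mean_train_r2"] == pytest.approx(0.25)
        assert row["mean_test_r2"] == pytest.approx(0.2)

    def test_empty_bin_reported_as_nan(self):
        rep = ev.concordance_and_bins(
            [0.1, 0.15, 0.18], [0.1, 0.1, 0.1], [0.0, 0.2, 0.4]
        )
        assert np.isnan(rep.bins.iloc[1]["mean_train_r2"])


class TestOverlap:
    def test_identical_lists(self):
        lists = {"knn": list("abcdefghij"), "enet": list("abcdefghij")}
        out = ev.model_overlap(lists, 10)
        assert out == {"enet|knn": 10, "all": 10}

    def test_disjoint_lists(self):
        out = ev.model_overlap({"a": ["g1", "g2"], "b": ["g3", "g4"]}, 2)
        assert out["a|b"] == 0 and out["all"] == 0

    def test_three_lists_match_enumeration(self, rng):
        genes = [f"g{i}" for i in range(30)]
        lists = {m: list(rng.permutation(genes)) for m in ("knn", "enet", "single")}
        n = 12
        out = ev.model_overlap(lists, n)
        tops = {m: set(v[:n]) for m, v in lists.items()}
        assert out["all"] == len(tops["knn"] & tops["enet"] & tops["single"])
        assert out["enet|knn"] == len(tops["knn"] & tops["enet"])

    def test_n_top_too_large_errors(self):
        with pytest.raises(ValueError):
            ev.model_overlap({"a": ["g1"]}, 5)


class TestCharacterize:
    def test_identical_groups_p_near_one(self, rng):
        vals = rng.normal(size=40)
        df = pd.DataFrame({"k": np.r_[vals[:20], vals[:20]]})
        mask = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        out = ev.characterize_genes(df, mask)
        assert out.iloc[0]["p_value"] > 0.9
        assert out.iloc[0]["mean_group"] == pytest.approx(out.iloc[0]["mean_rest"])

    def test_separated_groups_tiny_p(self, rng):
        df = pd.DataFrame({"x": np.r_[rng.normal(0, 1, 50), rng.normal(5, 1, 50)]})
        mask = np.r_[np.ones(50, bool), np.zeros(50, bool)]
        out = ev.characterize_genes(df, mask)
        assert out.iloc[0]["p_value"] < 1e-10

    def test_constant_feature_p_one(self):
        df = pd.DataFrame({"c": np.ones(10)})
        mask = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        assert ev.characterize_genes(df, mask).iloc[0]["p_value"] == 1.0

    def test_coefficient_of_variation_closed_form(self):
        y = np.array([2.0, 4.0])
        cv = y.std(ddof=1) / y.mean()
        assert cv == pytest.approx(np.sqrt(2) / 3, abs=1e-12)
        assert cv == pytest.approx(0.4714, abs=1e-4)

    def test_one_empty_group_errors(self):
        with pytest.raises(ValueError):
            ev.characterize_genes(pd.DataFrame({"a": [1.0, 2.0]}),
                                  np.array([True, True]))
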