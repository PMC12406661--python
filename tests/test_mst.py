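"""Best-model labelling, CART, CV fitness, GA search and the reference tree."""

import json

import numpy as np
import pytest

import vancomst as v
from vancomst import mst as M
from vancomst.metrics import ErrorTable
from vancomst.mst import TreeLeaf, TreeNode


class TestLabelling:
    def test_singleton_subset(self, planted_table):
        name = M.label_best_model(0, (2,), planted_table)
        assert name == planted_table.model_names[2]

    def test_lowest_pape_wins(self, planted_table):
        for t in range(0, len(planted_table.timeframes), 37):
            full = range(len(planted_table.registry))
            name = M.label_best_model(t, full, planted_table)
            papes = [planted_table.timeframe_mean_pape(i, t) for i in full]
            assert name == planted_table.model_names[int(np.argmin(papes))]

    def test_tie_breaks_to_registry_order(self):
        a = v.make_model("A", "5", "50")
        b = v.make_model("Aclone", "5", "50")
        config = v.SimulationConfig(n_patients=4, seed=2, models=(a,), creatinine_walk_sd=0.0)
        episodes, _ = v.generate_cohort(config)
        frames = v.build_cohort_timeframes(episodes)
        table = ErrorTable([a, b], frames)
        assert M.label_best_model(0, (0, 1), table) == "A"


class TestCART:
    def test_single_class_single_leaf(self):
        X = np.random.default_rng(0).normal(size=(30, 2))
        tree = M.fit_cart(X, np.zeros(30, dtype=int), ["egfr", "day"], ["OnlyModel"])
        assert isinstance(tree, TreeLeaf) and tree.model == "OnlyModel"

    def test_separable_boundary_recovered(self):
        rng = np.random.default_rng(1)
        egfr = np.concatenate([rng.uniform(5, 28, 60), rng.uniform(34, 120, 60)])
        labels = (egfr > 31).astype(int)
        X = np.column_stack([egfr, rng.normal(size=120)])
        tree = M.fit_cart(X, labels, ["egfr", "noise"], ["Low", "High"])
        assert isinstance(tree, TreeNode) and tree.covariate == "egfr"
        assert 28.0 <= tree.threshold <= 34.0  # inside the separating gap
        assert isinstance(tree.left, TreeLeaf) and tree.left.model == "Low"

    def test_uninformative_covariates_majority_leaf(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 2))
        labels = (rng.random(100) < 0.3).astype(int)  # independent of X
        tree = M.fit_cart(X, labels, ["a", "b"], ["Major", "Minor"],
                          max_depth=3, min_leaf_fraction=0.45)
        majority = ["Major", "Minor"][int(np.bincount(labels).argmax())]
        preds = {M.apply_mst(tree, {"a": x[0], "b": x[1]}) for x in X}
        assert preds == {majority}

    def test_depth_cap(self, planted_table):
        labels = M.label_subset(planted_table, (0, 1, 2))
        X = M._covariate_matrix(planted_table.timeframes, M.DEFAULT_SPLIT_COVARIATES)
        for depth in (1, 2, 3):
            tree = M.fit_cart(X, labels, M.DEFAULT_SPLIT_COVARIATES,
                              planted_table.model_names, max_depth=depth)
            assert tree.depth <= depth


class TestApplyAndSerialize:
    def test_missing_covariate_named(self):
        tree = TreeNode("egfr_ckd_epi", 31.0, TreeLeaf("A"), TreeLeaf("B"))
        with pytest.raises(M.MSTError, match="egfr_ckd_epi"):
            M.apply_mst(tree, {"age": 50.0})

    def test_json_round_trip(self, tmp_path):
        tree = M.reference_mst()
        path = tmp_path / "tree.json"
        M.save_tree(tree, path)
        again = M.load_tree(path)
        assert again == tree
        # serialized form uses the documented node/leaf keys
        payload = json.loads(path.read_text())
        assert set(payload) == {"covariate", "threshold", "left", "right"}


class TestReferenceTree:
    @pytest.mark.parametrize(
        "egfr, day, expected",
        [
            (20.0, 1, "Staatz"),   # very low GFR
            (60.0, 1, "Kim"),      # first treatment day, normal GFR
            (60.0, 3, "Zhou"),     # later days, regular GFR
            (130.0, 1, "Kim"),
            (130.0, 5, "Kim"),     # augmented clearance on any day
            (30.9, 4, "Staatz"),   # boundary below 31
            (31.0, 2, "Zhou"),     # boundary at 31, later day
            (124.9, 2, "Zhou"),
            (125.0, 2, "Kim"),
        ],
    )
    def test_assignment_rules(self, egfr, day, expected):
        tree = M.reference_mst()
        vector = {"egfr_ckd_epi": egfr, "treatment_day": float(day)}
        assert M.apply_mst(tree, vector) == expected

    def test_depth_and_models(self):
        tree = M.reference_mst()
        assert tree.depth == 3
        assert M.tree_models(tree) == {"Staatz", "Kim", "Zhou"}


class TestCVFitness:
    def test_mean_of_fold_means(self, planted_table):
        config = M.GAConfig(cv_folds=2, seed=4, population_size=4, generations=1)
        folds = M.episode_folds(planted_table.timeframes, 2, 4)
        fitness = M.cv_fitness((0, 1, 2), planted_table, config, folds=folds)
        # recompute the two fold means independently
        labels = M.label_subset(planted_table, (0, 1, 2))
        X = M._covariate_matrix(planted_table.timeframes, config.split_covariates)
        means = []
        for fold in folds:
            mask = np.ones(len(planted_table.timeframes), dtype=bool)
            mask[fold] = False
            tree = M.fit_cart(X[mask], labels[mask], config.split_covariates,
                              planted_table.model_names)
            papes = []
            for t in fold:
                model = M.apply_mst(tree, planted_table.timeframes[t].frozen_covariates)
                papes.extend(
                    np.abs(planted_table.ppe_values(planted_table.model_names.index(model), t))
                )
            means.append(np.mean(papes))
        assert fitness == pytest.approx(np.mean(means))

    def test_singleton_subset_fitness_is_model_cv_pape(self, planted_table):
        config = M.GAConfig(cv_folds=10, seed=0)
        folds = M.episode_folds(planted_table.timeframes, 10, 0)
        fitness = M.cv_fitness((1,), planted_table, config, folds=folds)
        means = []
        for fold in folds:
            papes = np.concatenate(
                [np.abs(planted_table.ppe_values(1, t)) for t in fold]
            )
            means.append(papes.mean())
        assert fitness == pytest.approx(np.mean(means))

    def test_folds_group_episodes(self, planted_table):
        folds = M.episode_folds(planted_table.timeframes, 10, 3)
        fold_of = {}
        for k, fold in enumerate(folds):
            for t in fold:
                ep = planted_table.timeframes[t].episode_id
                assert fold_of.setdefault(ep, k) == k  # episode never split
        assert sorted(np.concatenate(folds)) == list(range(len(planted_table.timeframes)))

    def test_too_few_timeframes_rejected(self, planted_table):
        config = M.GAConfig(cv_folds=10, seed=0)
        with pytest.raises(M.MSTError):
            M.episode_folds(planted_table.timeframes[:5], 10, 0)


class TestGA:
    def test_seed_reproducible(self, planted_registry, planted_table):
        config = M.GAConfig(population_size=10, generations=5, seed=42)
        a = M.ga_search(planted_registry, planted_table, config)
        b = M.ga_search(planted_registry, planted_table, config)
        assert a.subset == b.subset and a.fitness == b.fitness and a.tree == b.tree

    def test_singleton_registry(self, planted_table):
        reg = [planted_table.registry[0]]
        table = ErrorTable(reg, planted_table.timeframes)
        config = M.GAConfig(population_size=4, generations=2, seed=0)
        result = M.ga_search(reg, table, config)
        assert result.subset == (0,)
        assert result.fitness == pytest.approx(M.cv_fitness((0,), table, config))

    def test_matches_exhaustive_on_four_models(self, planted_cohort):
        _, episodes, _ = planted_cohort
        frames = v.build_cohort_timeframes(episodes)
        registry = v.planted_models() + v.simulate.decoy_models()[:1]
        table = ErrorTable(registry, frames)
        config = M.GAConfig(population_size=16, generations=12, seed=7)
        ga = M.ga_search(registry, table, config)
        oracle = M.exhaustive_search(registry, table, config)
        assert ga.fitness == pytest.approx(oracle.fitness, abs=1e-12)

    def test_estimator_api(self, planted_registry, planted_table):
        tool = v.ModelSelectionTool(
            registry=planted_registry, population_size=10, generations=5, random_state=3
        ).fit(planted_table)
        assert set(tool.subset_names_) <= set(planted_table.model_names)
        preds = tool.predict(planted_table.timeframes[:4])
        assert all(p in tool.subset_names_ for p in preds)
        assert 0.0 <= tool.assignment_rate() <= 100.0
        cloned = type(tool)(**tool.get_params())
        assert cloned.get_params()["random_state"] == 3


class TestAssignmentRate:
    def test_perfect_and_zero(self, planted_table):
        labels = M.label_subset(planted_table, (0, 1, 2))
        # single-leaf tree predicting the most common best model
        common = int(np.bincount(labels).argmax())
        leaf = TreeLeaf(planted_table.model_names[common])
        rate = M.mst_assignment_rate(leaf, (common,), planted_table)
        assert rate == 100.0  # labels restricted to the same singleton subset
        wrong = TreeLeaf("RenalSteep")
        zero = M.mst_assignment_rate(wrong, (0,), planted_table)
        assert zero == 0.0

    def test_separable_fixture_reaches_100(self, planted_table):
        labels = M.label_subset(planted_table, (0, 1, 2))
        X = M._covariate_matrix(planted_table.timeframes, M.DEFAULT_SPLIT_COVARIATES)
        tree = M.fit_cart(X, labels, M.DEFAULT_SPLIT_COVARIATES,
                          planted_table.model_names, max_depth=3)
        rate = M.mst_assignment_rate(tree, (0, 1, 2), planted_table)
        assert rate > 80.0  # noisy labels; the tree recovers the bulk
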