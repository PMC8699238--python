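import numpy as np
import pandas as pd
import pytest

import focimeta as fm
from focimeta.classify import random_search_evaluate
from focimeta.contrast import make_contingency
from focimeta.exceptions import ConfigError, ValidationError


class TestEncoding:
    def test_onehot_rows(self):
        foci = pd.DataFrame({"cluster_id": ["a", "b", "a"], "label": [1, 0, 1]})
        X, y = fm.encode_onehot(foci)
        assert X.values.tolist() == [[1, 0], [0, 1], [1, 0]]
        assert list(y) == [1, 0, 1]

    def test_exactly_one_indicator_per_row(self, rng):
        foci = pd.DataFrame({
            "cluster_id": rng.choice(list("abcde"), size=100),
            "label": rng.integers(0, 2, size=100),
        })
        X, _ = fm.encode_onehot(foci)
        assert X.shape[1] == foci["cluster_id"].nunique()
        assert (X.sum(axis=1) == 1).all()

    def test_single_cluster_rejected(self):
        foci = pd.DataFrame({"cluster_id": ["a", "a"], "label": [1, 0]})
        with pytest.raises(ValidationError):
            fm.encode_onehot(foci)

    def test_dataset_from_contingency_round_trip(self, rng):
        counts = rng.integers(1, 20, size=(4, 2))
        table = make_contingency(list("abcd"), counts[:, 0], counts[:, 1])
        X, y = fm.dataset_from_contingency(table)
        assert len(y) == counts.sum()
        back = fm.build_contingency(X.idxmax(axis=1), y)
        pd.testing.assert_frame_equal(back.sort_index(), table.sort_index())

    def test_separable_two_cluster_expansion(self):
        table = make_contingency(["a", "b"], [2, 0], [0, 2])
        X, y = fm.dataset_from_contingency(table)
        assert len(y) == 4
        assert (X["a"].to_numpy() == y).all()


class TestProportionScoreAuc:
    def test_uniform_proportions_are_chance(self):
        table = make_contingency(["a", "b"], [10, 30], [10, 30])
        assert fm.proportion_score_auc(table) == pytest.approx(0.5)

    def test_perfect_separation(self):
        table = make_contingency(["a", "b"], [5, 0], [0, 5])
        assert fm.proportion_score_auc(table) == pytest.approx(1.0)

    def test_matches_quadratic_pair_enumeration_oracle(self, rng):
        counts = rng.integers(0, 15, size=(5, 2)) + [1, 1]
        table = make_contingency(list("abcde"), counts[:, 0], counts[:, 1])
        scores, labels = [], []
        for _, rec in table.iterrows():
            p = rec["label1"] / (rec["label1"] + rec["label0"])
            scores += [p] * (rec["label1"] + rec["label0"])
            labels += [1] * rec["label1"] + [0] * rec["label0"]
        pos = [s for s, l in zip(scores, labels) if l == 1]
        neg = [s for s, l in zip(scores, labels) if l == 0]
        oracle = sum(1.0 if a > b else 0.5 if a == b else 0.0
                     for a in pos for b in neg) / (len(pos) * len(neg))
        assert fm.proportion_score_auc(table) == pytest.approx(oracle, abs=1e-12)


class TestCrossval:
    def test_separable_limit(self):
        table = make_contingency(["a", "b"], [50, 0], [0, 50])
        X, y = fm.dataset_from_contingency(table)
        report = fm.crossval_evaluate(X, y, seed=0)
        assert report.auc == pytest.approx(1.0)
        assert report.logloss < 0.1

    def test_cv_auc_bounded_by_proportion_oracle(self, rng):
        for _ in range(3):
            counts = rng.integers(5, 40, size=(6, 2))
            table = make_contingency([f"c{i}" for i in range(6)],
                                     counts[:, 0], counts[:, 1])
            X, y = fm.dataset_from_contingency(table)
            report = fm.crossval_evaluate(X, y, seed=1)
            assert report.auc <= fm.proportion_score_auc(table) + 0.01

    def test_metrics_invariant_to_row_order(self, retained_table, rng):
        X, y = fm.dataset_from_contingency(retained_table)
        perm = rng.permutation(len(y))
        a = fm.crossval_evaluate(X, y, seed=0)
        b = fm.crossval_evaluate(np.asarray(X)[perm], np.asarray(y)[perm], seed=0)
        assert (a.auc, a.auc_pr, a.logloss) == (b.auc, b.auc_pr, b.logloss)

    def test_model_menu_and_unknown_spec(self, retained_table):
        X, y = fm.dataset_from_contingency(retained_table)
        for spec in ("random_forest", "logistic"):
            report = fm.crossval_evaluate(X, y, spec, seed=0)
            assert 0.0 <= report.auc <= 1.0 and report.logloss >= 0.0
        with pytest.raises(ConfigError):
            fm.make_classifier("h2o_automl")

    def test_stratification_error_on_tiny_class(self):
        table = make_contingency(["a", "b"], [2, 1], [30, 30])
        X, y = fm.dataset_from_contingency(table)
        with pytest.raises(ValidationError):
            fm.crossval_evaluate(X, y, n_folds=5, seed=0)

    def test_random_search_stays_bounded(self, retained_table):
        X, y = fm.dataset_from_contingency(retained_table)
        report = random_search_evaluate(X, y, n_draws=4, seed=0)
        assert report.auc <= fm.proportion_score_auc(retained_table) + 0.01
        assert report.params


class TestFeatureImportance:
    def test_scaled_max_is_one_and_constant_indicator_zero(self, retained_table):
        X, y = fm.dataset_from_contingency(retained_table)
        X = X.copy()
        X["never_set"] = 0
        model = fm.make_classifier("gradient_boosted_trees", seed=0)
        model.fit(np.asarray(X, float), y)
        imp = fm.feature_importance(model, list(X.columns))
        assert imp["scaled_importance"].max() == pytest.approx(1.0)
        assert imp.loc["never_set", "importance"] == 0.0

    def test_top_feature_is_largest_residual_cluster(self, retained_table,
                                                     brand_contrast):
        X, y = fm.dataset_from_contingency(retained_table)
        model = fm.make_classifier("gradient_boosted_trees", seed=0)
        model.fit(np.asarray(X, float), y)
        imp = fm.feature_importance(model, list(X.columns))
        residuals = brand_contrast.report_.loc[retained_table.index,
                                               "residual_label1"].abs()
        assert imp.index[0] == residuals.idxmax()

    def test_logistic_has_no_gain_importance(self, retained_table):
        X, y = fm.dataset_from_contingency(retained_table)
        model = fm.make_classifier("logistic", seed=0)
        model.fit(np.asarray(X, float), y)
        with pytest.raises(ConfigError):
            fm.feature_importance(model, list(X.columns))
        imp = fm.feature_importance(model, list(X.columns), X=X, y=y,
                                    method="permutation")
        assert imp["scaled_importance"].max() <= 1.0

    def test_planted_biased_cluster_ranks_first(self):
        # one strongly label-biased planted cluster among neutral ones: its
        # indicator should top the importance ranking in >= 90% of seeds
        from focimeta.synthetic import PlantedCluster, SyntheticSpec
        n_seeds, hits = 20, 0
        for seed in range(n_seeds):
            spec = SyntheticSpec(
                n_studies_label1=4, n_studies_label0=4, foci_per_study=(40, 40),
                clusters=(
                    PlantedCluster((40, 0, 0), 5.0, 0.45, 0.05),
                    PlantedCluster((-40, 0, 0), 5.0, 0.15, 0.15),
                    PlantedCluster((0, 60, 0), 5.0, 0.15, 0.15),
                ),
                seed=100 + seed)
            foci, truth = fm.generate(spec)
            model = fm.fit_kmeans(foci[["x", "y", "z"]].to_numpy(), k=4, seed=seed)
            foci = foci.copy()
            foci["cluster_id"] = [f"cl_{i}" for i in model.assignments]
            # fitted cluster closest to the biased plant
            biased = np.argmin(np.linalg.norm(model.centroids - [40, 0, 0], axis=1))
            X, y = fm.encode_onehot(foci)
            gbt = fm.make_classifier("gradient_boosted_trees", seed=seed)
            gbt.fit(np.asarray(X, float), y)
            imp = fm.feature_importance(gbt, list(X.columns))
            hits += imp.index[0] == f"cl_{biased}"
        assert hits >= 18
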