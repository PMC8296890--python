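"""Feature building, splitting, training, permutation null and attributions."""

import numpy as np
import pytest

from adalert.errors import ConfigError, DataError
from adalert.model import (
    FeatureMatrix,
    ModelConfig,
    build_feature_matrix,
    cv_balanced_accuracy,
    feature_attributions,
    grid_search_cv,
    metrics_from_confusion,
    permutation_test,
    stratified_split,
    train_and_evaluate,
)
from adalert.screening import AlertMatchMatrix, DoseRule, screen_library
from adalert.synthetic import SyntheticConfig, generate_drug_set

from conftest import make_drug

FAST_PARAMS = {"max_depth": 2, "learning_rate": 0.1, "n_estimators": 50}
FAST_CONFIG = ModelConfig(grid={k: [v] for k, v in FAST_PARAMS.items()}, seed=11)


def synthetic_features(n_pos=50, n_neg=350, seed=0, amine=(0.45, 0.12)):
    """Feature matrix straight from the generator's planted indicators."""
    config = SyntheticConfig(
        n_pos=n_pos,
        n_neg=n_neg,
        alert_prevalence={"aryl_amine_primary": amine, "alkene": (0.2, 0.2),
                          "phenol": (0.15, 0.15)},
        seed=seed,
    )
    drugs, truth = generate_drug_set(config)
    X = np.column_stack([truth.dose_high.astype(np.int8), truth.indicators.astype(np.int8)])
    return FeatureMatrix(
        drug_ids=[d.drug_id for d in drugs],
        feature_names=["high_dose", *truth.alert_ids],
        X=X,
        y=truth.labels,
    )


class TestBuildFeatureMatrix:
    def test_dose_first_then_alert_columns(self, toy_panel, builtin):
        sub = builtin.subset(["n_benzene", "phenol"])
        matrix = screen_library(toy_panel, sub)
        fm = build_feature_matrix(toy_panel, matrix, DoseRule())
        assert fm.feature_names == ["high_dose", "n_benzene", "phenol"]
        assert fm.X.shape == (3, 3)
        aniline = fm.X[fm.drug_ids.index("aniline")]
        assert aniline.tolist() == [1, 1, 0]  # dose 150, amine alert, no phenol
        benzene = fm.X[fm.drug_ids.index("benzene")]
        assert benzene.tolist() == [1, 0, 0]

    def test_all_zero_drug_row(self, builtin):
        drugs = [make_drug("inert", "CCCC", 10.0, False), make_drug("x", "Nc1ccccc1", 10.0, True)]
        matrix = screen_library(drugs, builtin.subset(["phenol"]))
        fm = build_feature_matrix(drugs, matrix)
        assert fm.X[fm.drug_ids.index("inert")].tolist() == [0, 0]

    def test_empty_alert_set_rejected(self, toy_panel):
        matrix = AlertMatchMatrix(
            drug_ids=[d.drug_id for d in toy_panel], alert_ids=[],
            matches=np.zeros((3, 0), dtype=bool),
        )
        with pytest.raises(DataError):
            build_feature_matrix(toy_panel, matrix)


class TestStratifiedSplit:
    def test_study_sizes_and_class_balance(self):
        fm = synthetic_features(n_pos=50, n_neg=357)
        train, test = stratified_split(fm, fraction=0.8, seed=1)
        assert (train.n, test.n) == (325, 82)
        assert train.y.sum() == 40 and test.y.sum() == 10
        assert not set(train.drug_ids) & set(test.drug_ids)
        assert sorted(train.drug_ids + test.drug_ids) == sorted(fm.drug_ids)

    def test_same_seed_reproduces_partition(self):
        fm = synthetic_features()
        a = stratified_split(fm, fraction=0.8, seed=5)
        b = stratified_split(fm, fraction=0.8, seed=5)
        assert a[0].drug_ids == b[0].drug_ids and a[1].drug_ids == b[1].drug_ids

    def test_degenerate_fraction_rejected(self):
        fm = synthetic_features()
        with pytest.raises(ConfigError):
            stratified_split(fm, fraction=1.0, seed=0)


class TestMetricsFromConfusion:
    def test_reported_test_confusion(self):
        # the unique 10-positive/72-negative confusion matrix consistent with
        # sens 40%, spec 97%, NPV 92%, balanced accuracy 69%, MCC 47%
        m = metrics_from_confusion(tp=4, fn=6, fp=2, tn=70)
        assert round(m.sensitivity * 100) == 40
        assert round(m.specificity * 100) == 97
        assert round(m.npv * 100) == 92
        assert round(m.balanced_accuracy * 100) == 69
        assert round(m.mcc * 100) == 47

    def test_perfect_classifier(self):
        m = metrics_from_confusion(tp=5, fn=0, fp=0, tn=5)
        assert m.balanced_accuracy == 1.0 and m.mcc == 1.0

    def test_constant_classifier(self):
        m = metrics_from_confusion(tp=0, fn=5, fp=0, tn=5)
        assert m.balanced_accuracy == 0.5 and m.mcc == 0.0

    def test_balanced_accuracy_identity_enforced(self):
        for cells in [(4, 6, 2, 70), (1, 0, 3, 9), (7, 7, 7, 7)]:
            m = metrics_from_confusion(*cells)
            assert m.balanced_accuracy == pytest.approx(
                (m.sensitivity + m.specificity) / 2, abs=1e-15
            )


class TestGridSearch:
    def test_single_point_grid_returned(self):
        fm = synthetic_features(n_pos=40, n_neg=160)
        result = grid_search_cv(fm, FAST_CONFIG)
        assert result.best_params == FAST_PARAMS
        assert len(result.table) == 1

    def test_separable_data_scores_high(self):
        # perfectly separable: the amine alert is present in every positive only
        fm = synthetic_features(n_pos=40, n_neg=160, amine=(1.0, 0.0))
        result = grid_search_cv(fm, FAST_CONFIG)
        assert result.best_score > 0.9

    def test_shuffled_labels_score_near_chance(self):
        fm = synthetic_features(n_pos=40, n_neg=160, amine=(1.0, 0.0))
        rng = np.random.default_rng(3)
        shuffled = FeatureMatrix(fm.drug_ids, fm.feature_names, fm.X, rng.permutation(fm.y))
        result = grid_search_cv(shuffled, FAST_CONFIG)
        assert abs(result.best_score - 0.5) < 0.12


class TestTrainEvaluate:
    def test_strong_signal_beats_chance_and_auc_defined(self):
        fm = synthetic_features(seed=4)
        train, test = stratified_split(fm, fraction=0.8, seed=4)
        model, metrics = train_and_evaluate(train, test, FAST_PARAMS, FAST_CONFIG)
        assert metrics.balanced_accuracy > 0.55
        assert 0.0 <= metrics.auc <= 1.0

    def test_overlapping_sets_rejected(self):
        fm = synthetic_features()
        with pytest.raises(DataError):
            train_and_evaluate(fm, fm, FAST_PARAMS, FAST_CONFIG)

    def test_pipeline_deterministic_for_fixed_seed(self):
        def run():
            fm = synthetic_features(seed=9)
            train, test = stratified_split(fm, fraction=0.8, seed=9)
            search = grid_search_cv(train, FAST_CONFIG)
            model, metrics = train_and_evaluate(train, test, search.best_params, FAST_CONFIG)
            attrib = feature_attributions(model, test)
            return metrics, attrib.values.copy()

        (m1, a1), (m2, a2) = run(), run()
        assert m1 == m2
        assert np.array_equal(a1, a2)


class TestPermutationTest:
    def test_null_centered_and_signal_detected(self):
        fm = synthetic_features(n_pos=50, n_neg=350, seed=2)
        config = ModelConfig(
            grid=FAST_CONFIG.grid, seed=2, n_permutations=20, n_cv_repetitions=20
        )
        result = permutation_test(fm, FAST_PARAMS, config)
        assert abs(result.mean_permuted - 0.5) < 0.05
        assert result.mean_cv > result.mean_permuted
        assert result.p_value < 0.05

    def test_too_few_repetitions_rejected(self):
        fm = synthetic_features()
        config = ModelConfig(n_permutations=1, n_cv_repetitions=10)
        with pytest.raises(ConfigError):
            permutation_test(fm, FAST_PARAMS, config)

    def test_minority_class_smaller_than_folds_rejected(self):
        fm = synthetic_features(n_pos=50, n_neg=350)
        small = fm.take(np.concatenate([np.where(fm.y == 1)[0][:3], np.where(fm.y == 0)[0]]))
        with pytest.raises(DataError):
            cv_balanced_accuracy(small, FAST_PARAMS, ModelConfig(k_folds=5), fold_seed=0)


class TestAttributions:
    def test_local_accuracy(self):
        fm = synthetic_features(seed=6)
        train, test = stratified_split(fm, fraction=0.8, seed=6)
        model, _ = train_and_evaluate(train, test, FAST_PARAMS, FAST_CONFIG)
        attrib = feature_attributions(model, test)
        raw = model.predict(test.frame, raw_score=True)
        assert np.allclose(attrib.base_value + attrib.values.sum(axis=1), raw, atol=1e-6)

    def test_dose_only_signal_ranks_dose_first(self):
        # alerts carry no class signal; only the dose flag is informative
        config = SyntheticConfig(
            n_pos=60,
            n_neg=240,
            alert_prevalence={"alkene": (0.2, 0.2), "phenol": (0.15, 0.15)},
            p_highdose_pos=0.9,
            p_highdose_neg=0.1,
            seed=12,
        )
        drugs, truth = generate_drug_set(config)
        fm = FeatureMatrix(
            drug_ids=[d.drug_id for d in drugs],
            feature_names=["high_dose", *truth.alert_ids],
            X=np.column_stack([truth.dose_high.astype(np.int8),
                               truth.indicators.astype(np.int8)]),
            y=truth.labels,
        )
        train, test = stratified_split(fm, fraction=0.8, seed=12)
        model, _ = train_and_evaluate(train, test, FAST_PARAMS, FAST_CONFIG)
        attrib = feature_attributions(model, test)
        assert attrib.ranking().iloc[0]["feature"] == "high_dose"

    def test_feature_mismatch_rejected(self):
        fm = synthetic_features(seed=6)
        train, test = stratified_split(fm, fraction=0.8, seed=6)
        model, _ = train_and_evaluate(train, test, FAST_PARAMS, FAST_CONFIG)
        narrower = FeatureMatrix(
            test.drug_ids, ["high_dose", "aryl_amine_primary"], test.X[:, :2], test.y
        )
        with pytest.raises(DataError):
            feature_attributions(model, narrower)
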