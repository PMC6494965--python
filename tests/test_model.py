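"""Cross-validation protocol, metrics, importance and validation statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from abcscreen.fingerprints import FingerprintMatrix, filter_constant_keys
from abcscreen.model import (
    CVConfig,
    LearnerSpec,
    PredictionSet,
    call_substrates,
    confusion_and_metrics,
    load_model,
    marginalized_cv,
    permutation_importance,
    rank_auc,
    reduced_learners,
    roc_pr_curves,
    select_best_params,
    spearman_permutation_test,
    stratified_folds,
    train_final_model,
)


def brute_force_auc(scores, labels):
    """All-pairs comparison oracle: ties count 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _preds_with_counts(tp, tn, fp, fn):
    """Construct a prediction set realizing exact confusion counts at 0.5."""
    probs = [0.9] * tp + [0.1] * tn + [0.9] * fp + [0.1] * fn
    labels = [1] * tp + [0] * tn + [0] * fp + [1] * fn
    ids = [f"d{i}" for i in range(len(probs))]
    return PredictionSet(ids, np.array(probs), labels=np.array(labels))


class TestStratifiedFolds:
    def test_screen_sized_example(self):
        """376 drugs with 119 positives into 10 folds: 37-38 drugs, 11-12 positives."""
        y = np.r_[np.ones(119, int), np.zeros(257, int)]
        folds = stratified_folds(y, 10, seed=0)
        sizes = np.bincount(folds, minlength=10)
        pos = np.array([y[folds == f].sum() for f in range(10)])
        assert set(sizes) <= {37, 38}
        assert set(pos) <= {11, 12}

    def test_small_balanced_case_exact(self):
        y = np.array([1, 0] * 5)
        folds = stratified_folds(y, 5, seed=1)
        for f in range(5):
            assert y[folds == f].sum() == 1 and (folds == f).sum() == 2

    def test_partition_property(self):
        y = np.random.default_rng(0).integers(0, 2, size=101)
        folds = stratified_folds(y, 7, seed=3)
        assert folds.shape == y.shape
        assert set(folds) == set(range(7))

    def test_deterministic_given_seed(self):
        y = np.r_[np.ones(30, int), np.zeros(60, int)]
        assert np.array_equal(stratified_folds(y, 5, 9), stratified_folds(y, 5, 9))
        assert not np.array_equal(stratified_folds(y, 5, 9), stratified_folds(y, 5, 10))

    def test_class_smaller_than_n_folds_rejected(self):
        y = np.r_[np.ones(3, int), np.zeros(50, int)]
        with pytest.raises(ValueError, match="fewer"):
            stratified_folds(y, 5, seed=0)

    def test_agrees_with_sklearn_on_fold_balance(self):
        from sklearn.model_selection import StratifiedKFold

        y = np.r_[np.ones(40, int), np.zeros(93, int)]
        ours = stratified_folds(y, 10, seed=4)
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=4)
        sk_pos = sorted(y[test].sum() for _, test in skf.split(np.zeros_like(y), y))
        our_pos = sorted(y[ours == f].sum() for f in range(10))
        assert our_pos == sk_pos


class TestMarginalizedCV:
    def test_duplicated_grid_point_equals_single_for_deterministic_learner(self, planted_dataset):
        matrix, labels, _ = planted_dataset
        retained = filter_constant_keys(matrix)
        cv = CVConfig(n_repeats=1, seed=2)
        single = marginalized_cv(retained, labels, LearnerSpec("knn", ({"n_neighbors": 5},)), cv)
        doubled = marginalized_cv(
            retained, labels, LearnerSpec("knn", ({"n_neighbors": 5}, {"n_neighbors": 5})), cv
        )
        assert np.allclose(single.probabilities, doubled.probabilities)

    def test_one_probability_per_drug_in_unit_interval(self, planted_dataset):
        matrix, labels, _ = planted_dataset
        retained = filter_constant_keys(matrix)
        preds = marginalized_cv(
            retained, labels, LearnerSpec("knn", ({"n_neighbors": 7},)), CVConfig(n_repeats=2, seed=0)
        )
        assert len(preds.probabilities) == retained.n_drugs
        assert np.all((preds.probabilities >= 0) & (preds.probabilities <= 1))

    def test_deterministic_given_seed(self, planted_dataset):
        matrix, labels, _ = planted_dataset
        retained = filter_constant_keys(matrix)
        spec = LearnerSpec("gbm", ({"n_estimators": 50, "max_depth": 1},))
        cv = CVConfig(n_repeats=1, seed=5)
        p1 = marginalized_cv(retained, labels, spec, cv)
        p2 = marginalized_cv(retained, labels, spec, cv)
        assert np.array_equal(p1.probabilities, p2.probabilities)

    def test_planted_signal_beats_chance(self, planted_dataset):
        matrix, labels, _ = planted_dataset
        retained = filter_constant_keys(matrix)
        preds = marginalized_cv(
            retained, labels, reduced_learners()["gbm"], CVConfig(n_repeats=2, seed=7)
        )
        assert rank_auc(preds.probabilities, preds.labels) > 0.65


class TestMetrics:
    @pytest.mark.parametrize(
        "counts, precision, recall, accuracy",
        [
            ((42, 232, 25, 77), 0.627, 0.353, 0.729),
            ((62, 195, 62, 57), 0.500, 0.521, 0.684),
            ((61, 211, 46, 58), 0.570, 0.513, 0.723),
        ],
    )
    def test_confusion_arithmetic_reference_rows(self, counts, precision, recall, accuracy):
        s = confusion_and_metrics(_preds_with_counts(*counts))
        assert (s.tp, s.tn, s.fp, s.fn) == counts
        assert round(s.precision, 3) == precision
        assert round(s.recall, 3) == recall
        assert round(s.accuracy, 3) == accuracy

    def test_perfect_predictions(self):
        s = confusion_and_metrics(_preds_with_counts(5, 5, 0, 0))
        assert (s.precision, s.recall, s.accuracy, s.auc) == (1.0, 1.0, 1.0, 1.0)

    def test_no_positive_labels_reports_missing_recall(self):
        preds = PredictionSet(["a", "b"], np.array([0.2, 0.8]), labels=np.array([0, 0]))
        with pytest.warns(UserWarning, match="recall"):
            s = confusion_and_metrics(preds)
        assert s.recall is None and s.auc is None

    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1], 0.75),
            ([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], 1.0),
            ([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1], 0.5),
        ],
    )
    def test_rank_auc_reference_values(self, scores, labels, expected):
        assert rank_auc(np.array(scores), np.array(labels)) == pytest.approx(expected)

    def test_rank_auc_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            assert rank_auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels))

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        scores = rng.random(50)
        labels = rng.integers(0, 2, size=50)
        a1 = rank_auc(scores, labels)
        a2 = rank_auc(np.exp(3 * scores) + 1, labels)
        assert a1 == pytest.approx(a2)

    def test_roc_pr_rejects_single_class(self):
        preds = PredictionSet(["a", "b"], np.array([0.2, 0.8]), labels=np.array([1, 1]))
        with pytest.raises(ValueError, match="class"):
            roc_pr_curves(preds)

    def test_roc_pr_curve_auc_consistency(self, planted_dataset):
        matrix, labels, _ = planted_dataset
        rng = np.random.default_rng(8)
        y = labels.to_numpy()
        scores = 0.5 * y + 0.5 * rng.random(y.size)
        preds = PredictionSet(list(matrix.drug_ids), scores, labels=y)
        out = roc_pr_curves(preds)
        assert out["auc"] == pytest.approx(brute_force_auc(scores, y))
        assert len(out["roc"]["fpr"]) == len(out["roc"]["tpr"])


@pytest.fixture(scope="module")
def fitted(planted_dataset):
    matrix, labels, _ = planted_dataset
    retained = filter_constant_keys(matrix)
    spec = reduced_learners()["gbm"]
    model = train_final_model(retained, labels, spec, dict(spec.grid[0]), seed=1)
    return retained, labels, model


class TestFinalModel:
    def test_params_outside_grid_rejected(self, planted_dataset):
        matrix, labels, _ = planted_dataset
        spec = reduced_learners()["gbm"]
        with pytest.raises(ValueError, match="grid"):
            train_final_model(matrix, labels, spec, {"n_estimators": 999, "max_depth": 1})

    def test_predictions_in_unit_interval(self, fitted):
        retained, _, model = fitted
        preds = model.predict_proba(retained)
        assert np.all((preds.probabilities >= 0) & (preds.probabilities <= 1))

    def test_serialization_roundtrip(self, fitted, tmp_path):
        retained, _, model = fitted
        path = tmp_path / "model.joblib"
        model.save(path)
        reloaded = load_model(path)
        assert np.array_equal(
            model.predict_proba(retained).probabilities,
            reloaded.predict_proba(retained).probabilities,
        )
        assert reloaded.params == model.params

    def test_key_mismatch_rejected(self, fitted):
        _, _, model = fitted
        other = FingerprintMatrix(["x"], [1, 2], np.array([[1, 0]], dtype=np.uint8))
        with pytest.raises(ValueError, match="key_ids"):
            model.predict_proba(other)

    def test_training_optimism(self, planted_dataset):
        """In-sample AUC exceeds out-of-fold AUC for a flexible learner."""
        matrix, labels, _ = planted_dataset
        retained = filter_constant_keys(matrix)
        spec = LearnerSpec("gbm", ({"n_estimators": 100, "max_depth": 2},))
        preds_oof = marginalized_cv(retained, labels, spec, CVConfig(n_repeats=1, seed=3))
        model = train_final_model(retained, labels, spec, dict(spec.grid[0]), seed=3)
        train_auc = rank_auc(model.predict_proba(retained).probabilities, labels.to_numpy())
        oof_auc = rank_auc(preds_oof.probabilities, preds_oof.labels)
        assert train_auc > oof_auc

    def test_select_best_params_breaks_ties_to_smaller_capacity(self):
        grid = ({"n_estimators": 50}, {"n_estimators": 200})
        assert select_best_params(grid, {0: 0.7, 1: 0.7}) == {"n_estimators": 50}
        assert select_best_params(grid, {0: 0.6, 1: 0.7}) == {"n_estimators": 200}


class TestPermutationImportance:
    def test_constant_feature_scores_zero(self, planted_dataset):
        matrix, labels, _ = planted_dataset
        # add a constant column as key 166 replacement
        bits = matrix.bits.copy()
        bits[:, -1] = 1
        m = FingerprintMatrix(list(matrix.drug_ids), list(matrix.key_ids), bits)
        spec = reduced_learners()["gbm"]
        model = train_final_model(m, labels, spec, dict(spec.grid[0]), seed=2)
        scores = permutation_importance(model, m, labels, n_permutations=5, seed=0)
        last = [s for s in scores if s.key_id == m.key_ids[-1]][0]
        assert last.score == 0.0

    def test_single_feature_equal_to_label_dominates(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=200)
        bits = y[:, None].astype(np.uint8)
        m = FingerprintMatrix([f"d{i}" for i in range(200)], [1], bits)
        labels = pd.Series(y, index=m.drug_ids)
        spec = LearnerSpec("gbm", ({"n_estimators": 50, "max_depth": 1},))
        model = train_final_model(m, labels, spec, dict(spec.grid[0]), seed=0)
        scores = permutation_importance(model, m, labels, n_permutations=10, seed=0)
        assert scores[0].score > 5.0  # shuffling collapses accuracy to chance

    def test_planted_keys_rank_highly(self, planted_dataset):
        from tests.conftest import PLANTED_KEYS

        matrix, labels, _ = planted_dataset
        retained = filter_constant_keys(matrix)
        spec = LearnerSpec("gbm", ({"n_estimators": 100, "max_depth": 2},))
        model = train_final_model(retained, labels, spec, dict(spec.grid[0]), seed=4)
        scores = permutation_importance(model, retained, labels, n_permutations=10, seed=4)
        top10 = {s.key_id for s in scores if s.rank <= 10}
        planted = {k for k, _ in PLANTED_KEYS}
        assert len(top10 & planted) >= 4

    def test_ranks_are_a_permutation(self, planted_dataset):
        matrix, labels, _ = planted_dataset
        retained = filter_constant_keys(matrix)
        spec = reduced_learners()["gbm"]
        model = train_final_model(retained, labels, spec, dict(spec.grid[0]), seed=5)
        scores = permutation_importance(model, retained, labels, n_permutations=3, seed=5)
        assert sorted(s.rank for s in scores) == list(range(1, len(retained.key_ids) + 1))


class TestCallsAndSpearman:
    def test_call_threshold_behavior(self):
        preds = PredictionSet(["a", "b", "c"], np.array([0.16, 0.5, 0.05]))
        assert call_substrates(preds).tolist() == [1, 1, 0]
        assert call_substrates(preds, threshold=0.5).tolist() == [0, 1, 0]

    def test_lowering_threshold_never_removes_calls(self):
        rng = np.random.default_rng(2)
        preds = PredictionSet([f"d{i}" for i in range(50)], rng.random(50))
        hi = call_substrates(preds, threshold=0.5)
        lo = call_substrates(preds, threshold=0.15)
        assert np.all(lo >= hi)

    def test_monotone_vectors_give_rho_plus_minus_1(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        rho, _ = spearman_permutation_test(x, [2.0, 4.0, 6.0, 8.0, 10.0], n_perm=100, seed=0)
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_permutation_test(x, [5.0, 4.0, 3.0, 2.0, 1.0], n_perm=100, seed=0)
        assert rho == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_permutation_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_permutation_p_matches_exhaustive_enumeration(self):
        """n=7 fixture: Monte-Carlo p within binomial error of the exact p."""
        from scipy import stats

        rng = np.random.default_rng(3)
        x = rng.random(7)
        y = rng.random(7)
        rho, p_mc = spearman_permutation_test(x, y, n_perm=20_000, seed=1)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        zx = (rx - rx.mean()) / rx.std()
        zy = (ry - ry.mean()) / ry.std()
        count = total = 0
        for perm in itertools.permutations(range(7)):
            r_star = float(np.mean(zx * zy[list(perm)]))
            count += abs(r_star) >= abs(rho) - 1e-12
            total += 1
        p_exact = count / total
        se = math.sqrt(p_exact * (1 - p_exact) / 20_000)
        assert abs(p_mc - p_exact) < max(4 * se, 5e-3)

    def test_deterministic_given_seed(self):
        x = [0.1, 0.9, 0.4, 0.6, 0.2, 0.8]
        y = [1.0, 0.2, 0.5, 0.7, 0.9, 0.1]
        assert spearman_permutation_test(x, y, seed=7) == spearman_permutation_test(x, y, seed=7)
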