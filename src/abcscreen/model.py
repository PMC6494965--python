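"""Substrate-likeness modeling: marginalized cross-validation and metrics.

The protocol: stratified ten-fold cross-validation, repeated (100 times at
full scale) to average over fold-assignment randomness; within every fold a
model is trained at each point of a meta-parameter grid and the withheld
drugs' probabilities are averaged over the entire grid ("marginalized"
rather than selecting a per-fold best). Five learner families are supported
(k-NN, L1/L2 logistic regression, linear SVM, gradient boosting, small
feed-forward neural nets), all backed by scikit-learn; this module owns the
splitting, marginalization, metric, importance and thresholding logic.

AUC is the normalized Mann-Whitney rank statistic with ties counted 1/2.
Confusion counts threshold the averaged probability at 0.5 (one call per
drug); substrate calls for new compounds use a lower threshold (default
0.15) because high-precision/low-recall models under-call at 0.5.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import stats

from ._util import derive_seed, sha256_of, spawn_rng
from .fingerprints import FingerprintMatrix

__all__ = [
    "CVConfig",
    "LearnerSpec",
    "PredictionSet",
    "PerformanceSummary",
    "ImportanceScore",
    "FittedModel",
    "default_learners",
    "reduced_learners",
    "stratified_folds",
    "marginalized_cv",
    "grid_point_aucs",
    "rank_auc",
    "confusion_and_metrics",
    "roc_pr_curves",
    "train_final_model",
    "load_model",
    "permutation_importance",
    "call_substrates",
    "spearman_permutation_test",
]

METHODS = ("knn", "logistic_l1l2", "svm", "gbm", "nnet")


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation protocol settings."""

    n_folds: int = 10
    n_repeats: int = 100
    stratified: bool = True
    seed: int = 0
    threshold_confusion: float = 0.5
    threshold_call: float = 0.15

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError(f"n_folds must be >= 2, got {self.n_folds}")
        if self.n_repeats < 1:
            raise ValueError(f"n_repeats must be >= 1, got {self.n_repeats}")
        for name in ("threshold_confusion", "threshold_call"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass(frozen=True)
class LearnerSpec:
    """A learner family plus its meta-parameter grid.

    Grids are ordered from smaller to larger model capacity so deterministic
    tie-breaks favor the simpler model.
    """

    method: str
    grid: tuple[dict[str, Any], ...]

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}, expected one of {METHODS}")
        if len(self.grid) == 0:
            raise ValueError(f"empty meta-parameter grid for {self.method}")
        object.__setattr__(self, "grid", tuple(dict(g) for g in self.grid))


def default_learners() -> dict[str, LearnerSpec]:
    """Five-learner panel with moderate meta-parameter grids."""
    return {
        "knn": LearnerSpec("knn", tuple({"n_neighbors": k} for k in (3, 5, 7, 11))),
        "logistic_l1l2": LearnerSpec(
            "logistic_l1l2",
            tuple(
                {"penalty": p, "C": c}
                for p in ("l1", "l2")
                for c in (0.01, 0.1, 1.0, 10.0)
            ),
        ),
        "svm": LearnerSpec("svm", tuple({"C": c} for c in (0.01, 0.1, 1.0, 10.0))),
        "gbm": LearnerSpec(
            "gbm",
            tuple(
                {"n_estimators": n, "max_depth": d}
                for d in (1, 2, 3)
                for n in (50, 100, 200)
            ),
        ),
        "nnet": LearnerSpec("nnet", tuple({"hidden": h} for h in (2, 4, 8))),
    }


def reduced_learners() -> dict[str, LearnerSpec]:
    """Small grids for fast runs (testing / demo scale)."""
    return {
        "knn": LearnerSpec("knn", ({"n_neighbors": 5}, {"n_neighbors": 11})),
        "logistic_l1l2": LearnerSpec(
            "logistic_l1l2", ({"penalty": "l1", "C": 1.0}, {"penalty": "l2", "C": 1.0})
        ),
        "svm": LearnerSpec("svm", ({"C": 1.0},)),
        "gbm": LearnerSpec(
            "gbm",
            (
                {"n_estimators": 50, "max_depth": 1},
                {"n_estimators": 100, "max_depth": 2},
            ),
        ),
        "nnet": LearnerSpec("nnet", ({"hidden": 4},)),
    }


def _make_estimator(method: str, params: dict[str, Any], seed: int):
    if method == "knn":
        from sklearn.neighbors import KNeighborsClassifier

        return KNeighborsClassifier(n_neighbors=params["n_neighbors"])
    if method == "logistic_l1l2":
        from sklearn.linear_model import LogisticRegression

        return LogisticRegression(
            penalty=params["penalty"],
            C=params["C"],
            solver="liblinear",
            max_iter=2000,
            random_state=seed,
        )
    if method == "svm":
        from sklearn.svm import SVC

        return SVC(
            kernel="linear", C=params["C"], probability=True, random_state=seed
        )
    if method == "gbm":
        from sklearn.ensemble import GradientBoostingClassifier

        return GradientBoostingClassifier(
            n_estimators=params["n_estimators"],
            max_depth=params["max_depth"],
            random_state=seed,
        )
    if method == "nnet":
        from sklearn.neural_network import MLPClassifier

        return MLPClassifier(
            hidden_layer_sizes=(params["hidden"],),
            max_iter=500,
            random_state=seed,
        )
    raise ValueError(f"unknown method {method!r}")


def _positive_proba(estimator, X: np.ndarray) -> np.ndarray:
    proba = estimator.predict_proba(X)
    pos_col = list(estimator.classes_).index(1)
    return proba[:, pos_col]


@dataclass
class PredictionSet:
    """Per-drug substrate probabilities (averaged over grid and repeats)."""

    drug_ids: list[str]
    probabilities: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.shape != (len(self.drug_ids),):
            raise ValueError("one probability per drug required")
        if np.any((self.probabilities < 0) | (self.probabilities > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != self.probabilities.shape:
                raise ValueError("labels must match probabilities in length")

    def to_frame(self, threshold_call: float = 0.15) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"drug_id": self.drug_ids, "probability": self.probabilities}
        )
        frame["call"] = np.where(
            self.probabilities >= threshold_call, "substrate", "non-substrate"
        )
        if self.labels is not None:
            frame["label"] = self.labels
        return frame


@dataclass(frozen=True)
class PerformanceSummary:
    """Confusion counts and threshold-free metrics at one decision threshold."""

    tp: int
    tn: int
    fp: int
    fn: int
    precision: float | None
    recall: float | None
    accuracy: float
    auc: float | None

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass(frozen=True)
class ImportanceScore:
    key_id: int
    score: float
    rank: int


# ---------------------------------------------------------------------------
# folds and cross-validation


def stratified_folds(labels: np.ndarray | pd.Series, n_folds: int, seed: int) -> np.ndarray:
    """Deterministic stratified partition into ``n_folds`` test folds.

    Within each class, samples are shuffled and dealt round-robin, starting
    each class at the currently smallest folds, so per-fold class counts
    differ from proportional allocation by at most 1 and total fold sizes
    stay balanced.
    """
    y = np.asarray(labels)
    n = y.size
    if n_folds < 2:
        raise ValueError(f"n_folds must be >= 2, got {n_folds}")
    classes, counts = np.unique(y, return_counts=True)
    short = classes[counts < n_folds]
    if short.size:
        raise ValueError(
            f"classes {short.tolist()} have fewer than n_folds={n_folds} samples"
        )
    rng = spawn_rng(seed, 7_001)
    assignment = np.empty(n, dtype=int)
    fold_sizes = np.zeros(n_folds, dtype=int)
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        order = np.argsort(fold_sizes, kind="stable")
        for j, sample in enumerate(idx):
            f = order[j % n_folds]
            assignment[sample] = f
            fold_sizes[f] += 1
    return assignment


def _plain_folds(n: int, n_folds: int, seed: int) -> np.ndarray:
    rng = spawn_rng(seed, 7_002)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    assignment[perm] = np.arange(n) % n_folds
    return assignment


def marginalized_cv(
    matrix: FingerprintMatrix,
    labels: pd.Series | np.ndarray,
    learner: LearnerSpec,
    cv: CVConfig,
    return_grid_scores: bool = False,
) -> PredictionSet | tuple[PredictionSet, dict[int, float]]:
    """Out-of-fold probabilities averaged over the meta-parameter grid.

    For every repeat and fold, one model per grid point is trained on the
    non-withheld drugs and scores the withheld drugs; each drug's final
    probability is the mean of its out-of-fold scores across all grid points
    and repeats. All randomness derives from ``cv.seed`` expanded per
    (repeat, fold, grid point), so results are reproducible and independent
    of execution order.

    With ``return_grid_scores=True`` additionally returns the out-of-fold
    AUC per grid point (probabilities averaged over repeats only), used to
    pick "best" meta-parameters for final-model training.
    """
    y = labels.to_numpy() if isinstance(labels, pd.Series) else np.asarray(labels)
    y = y.astype(int)
    if y.size != matrix.n_drugs:
        raise ValueError(f"{matrix.n_drugs} drugs but {y.size} labels")
    X = matrix.bits.astype(np.float64)
    n_grid = len(learner.grid)
    acc = np.zeros((n_grid, y.size), dtype=float)

    for repeat in range(cv.n_repeats):
        fold_seed = derive_seed(cv.seed, 11, repeat)
        if cv.stratified:
            folds = stratified_folds(y, cv.n_folds, fold_seed)
        else:
            folds = _plain_folds(y.size, cv.n_folds, fold_seed)
        for f in range(cv.n_folds):
            test = folds == f
            train = ~test
            for g, params in enumerate(learner.grid):
                est_seed = derive_seed(cv.seed, 13, repeat, f, g)
                est = _make_estimator(learner.method, params, est_seed)
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")  # MLP convergence at small grids
                        est.fit(X[train], y[train])
                        acc[g, test] += _positive_proba(est, X[test])
                except Exception as exc:  # pragma: no cover - learner failure path
                    raise RuntimeError(
                        f"learner {learner.method} failed at grid point {params} "
                        f"(repeat {repeat}, fold {f}): {exc}"
                    ) from exc
    per_grid = acc / cv.n_repeats  # each drug scored once per repeat per grid point
    probabilities = per_grid.mean(axis=0)
    preds = PredictionSet(list(matrix.drug_ids), probabilities, labels=y)
    if return_grid_scores:
        grid_aucs = {g: rank_auc(per_grid[g], y) for g in range(n_grid)}
        return preds, grid_aucs
    return preds


def grid_point_aucs(
    matrix: FingerprintMatrix,
    labels: pd.Series | np.ndarray,
    learner: LearnerSpec,
    cv: CVConfig,
) -> dict[int, float]:
    """Out-of-fold AUC per grid point (convenience wrapper)."""
    _, scores = marginalized_cv(matrix, labels, learner, cv, return_grid_scores=True)
    return scores


# ---------------------------------------------------------------------------
# metrics


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U statistic, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(scores)  # average ranks handle ties as 1/2
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def confusion_and_metrics(preds: PredictionSet, threshold: float = 0.5) -> PerformanceSummary:
    """Confusion counts at a probability threshold plus precision/recall/accuracy/AUC.

    A drug is called positive when its averaged probability >= threshold.
    With no positive labels, recall (and AUC) are undefined and reported as
    None with a warning.
    """
    if preds.labels is None:
        raise ValueError("labels required to compute a confusion matrix")
    y = preds.labels
    calls = (preds.probabilities >= threshold).astype(int)
    tp = int(np.sum((calls == 1) & (y == 1)))
    tn = int(np.sum((calls == 0) & (y == 0)))
    fp = int(np.sum((calls == 1) & (y == 0)))
    fn = int(np.sum((calls == 0) & (y == 1)))
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    if (tp + fn) == 0:
        warnings.warn("no positive labels: recall and AUC undefined", stacklevel=2)
        recall = None
        auc = None
    else:
        recall = tp / (tp + fn)
        auc = rank_auc(preds.probabilities, y) if tn + fp > 0 else None
    accuracy = (tp + tn) / y.size
    return PerformanceSummary(tp, tn, fp, fn, precision, recall, accuracy, auc)


def roc_pr_curves(preds: PredictionSet) -> dict[str, Any]:
    """ROC and precision-recall point lists plus the rank-statistic AUC."""
    if preds.labels is None:
        raise ValueError("labels required for ROC/PR curves")
    y = preds.labels
    if len(np.unique(y)) < 2:
        raise ValueError("ROC/PR curves need both classes present")
    from sklearn.metrics import precision_recall_curve, roc_curve

    fpr, tpr, roc_thresholds = roc_curve(y, preds.probabilities)
    precision, recall, pr_thresholds = precision_recall_curve(y, preds.probabilities)
    return {
        "roc": {"fpr": fpr.tolist(), "tpr": tpr.tolist(), "thresholds": roc_thresholds.tolist()},
        "pr": {
            "precision": precision.tolist(),
            "recall": recall.tolist(),
            "thresholds": pr_thresholds.tolist(),
        },
        "auc": rank_auc(preds.probabilities, y),
    }


# ---------------------------------------------------------------------------
# final model


@dataclass
class FittedModel:
    """A trained estimator plus the metadata needed to reuse it safely."""

    estimator: Any
    method: str
    params: dict[str, Any]
    seed: int
    key_ids: list[int]
    training_hash: str

    def predict_proba(self, matrix: FingerprintMatrix) -> PredictionSet:
        if matrix.key_ids != self.key_ids:
            raise ValueError(
                "matrix key_ids do not match the model's training keys; "
                "restrict the matrix to the retained training keys first"
            )
        probs = _positive_proba(self.estimator, matrix.bits.astype(np.float64))
        return PredictionSet(list(matrix.drug_ids), probs)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        joblib.dump(self.estimator, path)
        meta = {
            "method": self.method,
            "params": self.params,
            "seed": self.seed,
            "key_ids": self.key_ids,
            "training_hash": self.training_hash,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> FittedModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    return FittedModel(
        estimator=joblib.load(path),
        method=meta["method"],
        params=meta["params"],
        seed=meta["seed"],
        key_ids=list(meta["key_ids"]),
        training_hash=meta["training_hash"],
    )


def train_final_model(
    matrix: FingerprintMatrix,
    labels: pd.Series | np.ndarray,
    learner: LearnerSpec,
    best_params: dict[str, Any],
    seed: int = 0,
) -> FittedModel:
    """Fit one model on all drugs at the chosen meta-parameters.

    ``best_params`` must be a grid point of the learner (by convention the
    one with highest mean out-of-fold AUC; ties favor the earlier, smaller-
    capacity grid entry).
    """
    if dict(best_params) not in [dict(g) for g in learner.grid]:
        raise ValueError(f"params {best_params} not in the {learner.method} grid")
    y = labels.to_numpy() if isinstance(labels, pd.Series) else np.asarray(labels)
    y = y.astype(int)
    est_seed = derive_seed(seed, 17)
    est = _make_estimator(learner.method, dict(best_params), est_seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(matrix.bits.astype(np.float64), y)
    return FittedModel(
        estimator=est,
        method=learner.method,
        params=dict(best_params),
        seed=seed,
        key_ids=list(matrix.key_ids),
        training_hash=sha256_of(matrix.bits) + ":" + sha256_of(y),
    )


def select_best_params(grid: Sequence[dict[str, Any]], grid_aucs: dict[int, float]) -> dict[str, Any]:
    """Highest mean out-of-fold AUC; ties resolved toward the earlier grid entry."""
    best = max(range(len(grid)), key=lambda g: (grid_aucs[g], -g))
    return dict(grid[best])


# ---------------------------------------------------------------------------
# importance, calls, validation statistics


def permutation_importance(
    model: FittedModel,
    matrix: FingerprintMatrix,
    labels: pd.Series | np.ndarray,
    n_permutations: int = 30,
    seed: int = 0,
) -> list[ImportanceScore]:
    """Permutation feature importance: mean accuracy drop / SE of the drops.

    For each feature, the column is shuffled ``n_permutations`` times across
    the whole set; the drop from baseline accuracy (probability threshold
    0.5) is averaged and normalized by its standard error. Features the
    model ignores score ~0. Ranks are 1..n_features, descending by score.
    """
    if n_permutations < 2:
        raise ValueError(f"n_permutations must be >= 2, got {n_permutations}")
    y = labels.to_numpy() if isinstance(labels, pd.Series) else np.asarray(labels)
    y = y.astype(int)
    X = matrix.bits.astype(np.float64)
    baseline = np.mean((_positive_proba(model.estimator, X) >= 0.5).astype(int) == y)
    scores = []
    for j, key_id in enumerate(matrix.key_ids):
        rng = spawn_rng(seed, 19, j)
        drops = np.empty(n_permutations)
        Xp = X.copy()
        for t in range(n_permutations):
            Xp[:, j] = X[rng.permutation(y.size), j]
            acc = np.mean((_positive_proba(model.estimator, Xp) >= 0.5).astype(int) == y)
            drops[t] = baseline - acc
        mean = drops.mean()
        sd = drops.std(ddof=1)
        se = sd / np.sqrt(n_permutations)
        score = 0.0 if mean == 0.0 else float(mean / max(se, 1e-12))
        scores.append((key_id, score))
    order = sorted(range(len(scores)), key=lambda i: -scores[i][1])
    ranks = np.empty(len(scores), dtype=int)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    return [
        ImportanceScore(key_id=k, score=s, rank=int(ranks[i]))
        for i, (k, s) in enumerate(scores)
    ]


def call_substrates(preds: PredictionSet, threshold: float = 0.15) -> np.ndarray:
    """Binary substrate calls: probability >= threshold.

    The default 0.15 is deliberately below 0.5: a conservative, high-
    precision model leaves true substrates in the 0.15-0.5 band, and
    lowering the threshold recovers them at little false-positive cost.
    """
    return (preds.probabilities >= threshold).astype(int)


def spearman_permutation_test(
    predicted: Sequence[float],
    observed: Sequence[float],
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman rho with a two-sided label-shuffling permutation p-value.

    p = (1 + #{permutations with |rho*| >= |rho|}) / (1 + n_perm).
    """
    x = np.asarray(list(predicted), dtype=float)
    y = np.asarray(list(observed), dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with >= 3 entries")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: Spearman correlation undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    rng = spawn_rng(seed, 23)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    # Spearman rho is Pearson on ranks; precompute standardized ranks once
    zx = (rx - rx.mean()) / rx.std()
    zy = (ry - ry.mean()) / ry.std()
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(y.size)
        r_star = float(np.mean(zx * zy[perm]))
        if abs(r_star) >= abs(rho) - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return rho, p


def performance_table(
    summaries: dict[str, PerformanceSummary], path: str | Path | None = None
) -> pd.DataFrame:
    """Per-method performance table (Method, TP, TN, FP, FN, Precision, Recall, Accuracy, AUC)."""
    rows = []
    for method, s in summaries.items():
        rows.append(
            {
                "Method": method,
                "TP": s.tp,
                "TN": s.tn,
                "FP": s.fp,
                "FN": s.fn,
                "Precision": s.precision,
                "Recall": s.recall,
                "Accuracy": s.accuracy,
                "AUC": s.auc,
            }
        )
    frame = pd.DataFrame(rows)
    if path is not None:
        frame.to_csv(path, sep="\t", index=False, float_format="%.3f")
    return frame
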