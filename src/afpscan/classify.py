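"""SVM training, prediction and the ACC/SN/SP/AUC/MCC evaluation suite.

Features are standardized with training-set statistics, an RBF-kernel SVM is
tuned over a (C, gamma) grid by mean cross-validated AUC, and evaluation
reports sensitivity, specificity, accuracy, the Matthews correlation
coefficient and a pair-counting AUC (tied scores count one half).  Trained
models serialize to JSON: scaler statistics, hyperparameters and the fitted
support data are enough to reproduce decision values exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .containers import FeatureTable

__all__ = [
    "TrainedClassifier",
    "ConfusionMatrix",
    "EvalReport",
    "default_grid",
    "fast_grid",
    "stratified_split",
    "train_svm",
    "decision_values",
    "auc_score",
    "evaluate",
    "cross_validate",
]


def default_grid() -> list[tuple[float, float]]:
    """Full (C, gamma) search grid: C in 2^-5..2^9, gamma in 2^-15..2^3."""
    cs = [2.0 ** e for e in range(-5, 10, 2)]
    gammas = [2.0 ** e for e in range(-15, 4, 2)]
    return [(c, g) for c in cs for g in gammas]


def fast_grid() -> list[tuple[float, float]]:
    """Coarse 3 x 3 grid for the inner loops of incremental selection."""
    cs = [2.0 ** e for e in (0, 3, 6)]
    gammas = [2.0 ** e for e in (-7, -5, -3)]
    return [(c, g) for c in cs for g in gammas]


@dataclass
class ConfusionMatrix:
    """Counts with the antifreeze class as positive."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def _safe_div(num: float, den: float) -> float:
    return num / den if den else float("nan")


def _mcc(c: ConfusionMatrix) -> float:
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


@dataclass
class EvalReport:
    """Metrics for one evaluation context ("cv" or "test")."""

    confusion: ConfusionMatrix
    acc: float
    sn: float
    sp: float
    auc: float
    mcc: float
    context: str = "test"
    decision_scores: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "context": self.context,
            "confusion": {
                "tp": self.confusion.tp,
                "fn": self.confusion.fn,
                "tn": self.confusion.tn,
                "fp": self.confusion.fp,
            },
            "acc": self.acc,
            "sn": self.sn,
            "sp": self.sp,
            "auc": self.auc,
            "mcc": self.mcc,
        }


def auc_score(truth, scores) -> float:
    """Pair-counting AUC: P(random positive outscores random negative), ties 1/2.

    Computed via the Mann-Whitney statistic with average ranks, which equals
    exhaustive pair counting exactly.  Single-class truth returns NaN.
    """
    truth = np.asarray(truth, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((truth == 1).sum())
    n_neg = int((truth == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    rank_sum = ranks[truth == 1].sum()
    return (rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def evaluate(truth, scores, threshold: float = 0.0, context: str = "test") -> EvalReport:
    """Threshold signed scores and compute the full metric suite.

    MCC is defined as 0 whenever a marginal of the confusion matrix is empty
    (constant predictions); AUC is NaN when only one class is present.
    """
    truth = np.asarray(truth, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if truth.shape != scores.shape:
        raise ValueError("truth and scores must have equal length")
    predicted = (scores > threshold).astype(int)
    confusion = ConfusionMatrix(
        tp=int(((predicted == 1) & (truth == 1)).sum()),
        fn=int(((predicted == 0) & (truth == 1)).sum()),
        tn=int(((predicted == 0) & (truth == 0)).sum()),
        fp=int(((predicted == 1) & (truth == 0)).sum()),
    )
    return EvalReport(
        confusion=confusion,
        acc=_safe_div(confusion.tp + confusion.tn, confusion.total),
        sn=_safe_div(confusion.tp, confusion.tp + confusion.fn),
        sp=_safe_div(confusion.tn, confusion.tn + confusion.fp),
        auc=auc_score(truth, scores),
        mcc=_mcc(confusion),
        context=context,
        decision_scores=scores,
    )


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def stratified_split(
    table: FeatureTable, train_fraction: float = 0.8, seed: int = 0
) -> tuple[FeatureTable, FeatureTable]:
    """Per-class random split: floor(fraction * n_class) to train, rest to test."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in (0, 1):
        members = np.flatnonzero(table.labels == cls)
        if members.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 samples; cannot split")
        members = rng.permutation(members)
        n_train = int(train_fraction * members.size)
        train_idx.append(members[:n_train])
        test_idx.append(members[n_train:])
    train_idx = np.sort(np.concatenate(train_idx))
    test_idx = np.sort(np.concatenate(test_idx))
    return table.subset_rows(train_idx), table.subset_rows(test_idx)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainedClassifier:
    """A fitted RBF-SVM with its standardizer, reproducible from JSON.

    Decision values are computed from the stored support vectors directly
    (``sum_i dual_coef_i * K(sv_i, x) + intercept``), so a round-tripped
    model scores identically to the freshly fitted one.
    """

    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    kernel: str
    C: float
    gamma: float
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    feature_indices: np.ndarray
    decision_threshold: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if len(self.scaler_mean) != len(self.feature_indices):
            raise ValueError("scaler statistics must match the feature subset")

    def to_json(self, path) -> None:
        payload = {
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_std": self.scaler_std.tolist(),
            "kernel": self.kernel,
            "C": self.C,
            "gamma": self.gamma,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "feature_indices": self.feature_indices.tolist(),
            "decision_threshold": self.decision_threshold,
            "seed": self.seed,
        }
        with open(path, "w") as out:
            json.dump(payload, out)

    @classmethod
    def from_json(cls, path) -> "TrainedClassifier":
        with open(path) as handle:
            payload = json.load(handle)
        return cls(
            scaler_mean=np.asarray(payload["scaler_mean"]),
            scaler_std=np.asarray(payload["scaler_std"]),
            kernel=payload["kernel"],
            C=payload["C"],
            gamma=payload["gamma"],
            support_vectors=np.asarray(payload["support_vectors"]),
            dual_coef=np.asarray(payload["dual_coef"]),
            intercept=payload["intercept"],
            feature_indices=np.asarray(payload["feature_indices"], dtype=int),
            decision_threshold=payload["decision_threshold"],
            seed=payload["seed"],
        )


def _standardize_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std == 0, 1.0, std)
    return mean, std


def _fit_svc(X: np.ndarray, y: np.ndarray, C: float, gamma: float) -> SVC:
    svc = SVC(C=C, gamma=gamma, kernel="rbf")
    svc.fit(X, y)
    return svc


def _cv_auc(X: np.ndarray, y: np.ndarray, C: float, gamma: float,
            folds: int, seed: int) -> float:
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    for fit_idx, val_idx in splitter.split(X, y):
        mean, std = _standardize_stats(X[fit_idx])
        svc = _fit_svc((X[fit_idx] - mean) / std, y[fit_idx], C, gamma)
        scores[val_idx] = svc.decision_function((X[val_idx] - mean) / std)
    return auc_score(y, scores)


def train_svm(
    train: FeatureTable,
    grid: list[tuple[float, float]] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    feature_indices=None,
) -> TrainedClassifier:
    """Tune (C, gamma) by mean CV AUC, then refit on the full training table.

    Ties resolve toward smaller C, then smaller gamma.  Deterministic for a
    fixed seed and data.
    """
    if train.n_minority == 0:
        raise ValueError("training data lacks the positive (antifreeze) class")
    if train.n_majority == 0:
        raise ValueError("training data lacks the negative (non-antifreeze) class")
    if min(train.n_minority, train.n_majority) < cv_folds:
        raise ValueError(f"need at least {cv_folds} samples in each class for tuning")
    grid = grid if grid is not None else default_grid()
    if not grid:
        raise ValueError("empty hyperparameter grid")

    if feature_indices is None:
        feature_indices = np.arange(train.n_features)
    feature_indices = np.asarray(feature_indices, dtype=int)
    X = train.matrix[:, feature_indices]
    y = train.labels

    best = None
    for C, gamma in sorted(grid):
        score = _cv_auc(X, y, C, gamma, cv_folds, seed)
        if best is None or score > best[0] + 1e-12:
            best = (score, C, gamma)
    _, C, gamma = best

    mean, std = _standardize_stats(X)
    svc = _fit_svc((X - mean) / std, y, C, gamma)
    return TrainedClassifier(
        scaler_mean=mean,
        scaler_std=std,
        kernel="rbf",
        C=C,
        gamma=gamma,
        support_vectors=svc.support_vectors_,
        dual_coef=svc.dual_coef_.ravel(),
        intercept=float(svc.intercept_[0]),
        feature_indices=feature_indices,
        seed=seed,
    )


def decision_values(model: TrainedClassifier, table: FeatureTable | np.ndarray) -> np.ndarray:
    """Signed decision score per row; label 1 is predicted when score > threshold."""
    X = table.matrix if isinstance(table, FeatureTable) else np.asarray(table, dtype=float)
    if isinstance(table, FeatureTable):
        if X.shape[1] == len(model.feature_indices):
            pass  # already sliced to the model's feature subset
        elif X.shape[1] > int(model.feature_indices.max()):
            X = X[:, model.feature_indices]
        else:
            raise ValueError("table lacks the model's feature columns")
    elif X.shape[1] != len(model.feature_indices):
        raise ValueError("array width does not match the model's feature subset")
    Xs = (X - model.scaler_mean) / model.scaler_std
    kernel = rbf_kernel(Xs, model.support_vectors, gamma=model.gamma)
    return kernel @ model.dual_coef + model.intercept


def predict(model: TrainedClassifier, table) -> np.ndarray:
    return (decision_values(model, table) > model.decision_threshold).astype(int)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def cross_validate(
    table: FeatureTable,
    folds: int = 5,
    seed: int = 0,
    feature_indices=None,
    C: float = 1.0,
    gamma: float = 2.0 ** -5,
    resample_inside: bool = False,
    resample_plan=None,
    mwmote_params=None,
) -> EvalReport:
    """Stratified k-fold CV with pooled out-of-fold decision values.

    With ``resample_inside`` MWMOTE is applied to each fold's training
    portion only, keeping the held-out fold free of synthetic rows; fold
    membership is fixed by the seed before any oversampling.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if min(table.n_minority, table.n_majority) < folds:
        raise ValueError("fold count exceeds the size of a class")
    if feature_indices is None:
        feature_indices = np.arange(table.n_features)
    feature_indices = np.asarray(feature_indices, dtype=int)

    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.empty(table.n_samples)
    for fold, (fit_idx, val_idx) in enumerate(splitter.split(table.matrix, table.labels)):
        fold_train = table.subset_rows(fit_idx)
        if resample_inside:
            from .resampling import ResamplePlan, mwmote_oversample

            plan = resample_plan or ResamplePlan()
            fold_plan = ResamplePlan(
                target_ratio=plan.target_ratio,
                n_synthetic=plan.n_synthetic,
                seed=(plan.seed * folds + fold) % 2**31,
            )
            fold_train = mwmote_oversample(fold_train, fold_plan, mwmote_params)
        X_fit = fold_train.matrix[:, feature_indices]
        mean, std = _standardize_stats(X_fit)
        svc = _fit_svc((X_fit - mean) / std, fold_train.labels, C, gamma)
        X_val = table.matrix[np.ix_(val_idx, feature_indices)]
        scores[val_idx] = svc.decision_function((X_val - mean) / std)
    return evaluate(table.labels, scores, context="cv")
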