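"""Ensemble mRMR feature ranking and parsimonious incremental selection.

Features are discretized into three states (below mean - sd, within one sd,
above mean + sd), scored by plug-in mutual information with the class label,
and ranked greedily by the mRMR difference criterion: each pick maximizes
relevance minus mean redundancy with the already-selected features.  An
ensemble of stratified bootstrap resamples is aggregated by mean rank
position (Borda style) into a consensus order.  Incremental selection then
adds ranked features one at a time and keeps the model preceding the first
one whose independent-test performance decreases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "discretize",
    "mutual_information",
    "mrmr_rank",
    "ensemble_rank",
    "incremental_select",
    "select_k",
    "RankedFeatures",
    "SelectionResult",
]

#: scores within this distance of the step maximum are treated as tied and
#: resolved toward the lower feature index (guards against last-bit noise in
#: otherwise identical mutual-information sums).
TIE_TOLERANCE = 1e-9


def discretize(values, n_states: int = 3) -> np.ndarray:
    """Discretize a numeric vector into 3 states split at mean +/- sd.

    Constant vectors map to a single state (all zeros).  Only the three-state
    scheme is provided; it is the classic convention for mutual-information
    scoring of continuous features.
    """
    if n_states != 3:
        raise ValueError("only the 3-state (mean +/- sd) scheme is supported")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot discretize an empty vector")
    if np.ptp(values) == 0:
        return np.zeros(values.size, dtype=int)
    mu, sd = values.mean(), values.std()
    return np.digitize(values, [mu - sd, mu + sd]).astype(int)


def _discretize_matrix(matrix: np.ndarray) -> np.ndarray:
    mu = matrix.mean(axis=0)
    sd = matrix.std(axis=0)
    lo = mu - sd
    hi = mu + sd
    states = (matrix >= lo[None, :]).astype(int) + (matrix >= hi[None, :]).astype(int)
    states[:, np.ptp(matrix, axis=0) == 0] = 0
    return states


def mutual_information(a, b) -> float:
    """Plug-in mutual information (nats) between two discrete vectors."""
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if a.size == 0:
        raise ValueError("vectors must be non-empty")
    return float(_batch_mi(a, b.reshape(-1, 1))[0])


def _batch_mi(a: np.ndarray, B: np.ndarray) -> np.ndarray:
    """MI (nats) between vector ``a`` and every column of matrix ``B``."""
    n, n_cols = B.shape
    sa = int(a.max()) + 1
    sb = int(B.max()) + 1
    codes = (a[:, None] * sb + B) + (sa * sb) * np.arange(n_cols)[None, :]
    counts = np.bincount(codes.reshape(-1), minlength=sa * sb * n_cols)
    joint = counts.reshape(n_cols, sa, sb) / n
    pa = joint.sum(axis=2, keepdims=True)
    pb = joint.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (pa * pb))
    return np.nansum(terms, axis=(1, 2))


@dataclass
class RankedFeatures:
    """A consensus (or single-run) mRMR ordering of feature indices.

    ``relevance`` is per feature index (MI with the label); ``mrmr_score`` is
    aligned with ``order`` and holds the greedy score at the selection step
    for a single run, or the negated mean rank for an ensemble.
    """

    order: np.ndarray
    relevance: np.ndarray
    mrmr_score: np.ndarray
    n_ensemble: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        if len(np.unique(self.order)) != len(self.order):
            raise ValueError("ranking contains duplicate feature indices")

    def top(self, k: int) -> np.ndarray:
        return self.order[:k]

    def to_dict(self) -> dict:
        return {
            "order": self.order.tolist(),
            "relevance": np.asarray(self.relevance).tolist(),
            "mrmr_score": np.asarray(self.mrmr_score).tolist(),
            "n_ensemble": self.n_ensemble,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "RankedFeatures":
        return cls(
            order=np.asarray(payload["order"], dtype=int),
            relevance=np.asarray(payload["relevance"], dtype=float),
            mrmr_score=np.asarray(payload["mrmr_score"], dtype=float),
            n_ensemble=payload.get("n_ensemble", 1),
            seed=payload.get("seed"),
        )


def _tied_argmax(scores: np.ndarray, valid: np.ndarray) -> int:
    masked = np.where(valid, scores, -np.inf)
    best = masked.max()
    return int(np.flatnonzero(masked >= best - TIE_TOLERANCE)[0])


def mrmr_rank(table: FeatureTable, K: int | None = None) -> RankedFeatures:
    """Greedy mRMR ranking with the difference (relevance - mean redundancy) criterion.

    The first pick maximizes MI with the label; each later pick maximizes
    MI(feature; label) minus the mean MI with the already-selected features.
    Exact score ties resolve to the lower feature index.
    """
    n_features = table.n_features
    K = n_features if K is None else K
    if K > n_features:
        raise ValueError(f"K={K} exceeds the {n_features} available features")
    if table.n_minority == 0 or table.n_majority == 0:
        raise ValueError("mRMR requires both classes in the labels")

    states = _discretize_matrix(table.matrix)
    relevance = _batch_mi(table.labels, states)

    order = np.empty(K, dtype=int)
    step_scores = np.empty(K)
    valid = np.ones(n_features, dtype=bool)
    redundancy_sum = np.zeros(n_features)
    scores = relevance.copy()
    for step in range(K):
        pick = _tied_argmax(scores, valid)
        order[step] = pick
        step_scores[step] = scores[pick]
        valid[pick] = False
        if step + 1 < K:
            redundancy_sum += _batch_mi(states[:, pick], states)
            scores = relevance - redundancy_sum / (step + 1)
    return RankedFeatures(order=order, relevance=relevance, mrmr_score=step_scores)


def _stratified_bootstrap(table: FeatureTable, rng: np.random.Generator) -> FeatureTable:
    index = []
    for cls in (0, 1):
        members = np.flatnonzero(table.labels == cls)
        index.append(rng.choice(members, size=members.size, replace=True))
    return table.subset_rows(np.concatenate(index))


def ensemble_rank(
    table: FeatureTable,
    n_ensemble: int = 20,
    K: int | None = None,
    seed: int = 0,
) -> RankedFeatures:
    """Consensus mRMR ranking over stratified bootstrap resamples.

    Each resample draws rows with replacement within each class, is ranked by
    :func:`mrmr_rank` to depth ``K``, and rankings are aggregated by mean
    rank position (features absent from a resample's top-K count as K+1).
    Final order is ascending mean rank, ties toward the lower index.
    """
    if n_ensemble < 1:
        raise ValueError("n_ensemble must be >= 1")
    n_features = table.n_features
    K = n_features if K is None else K
    rng = np.random.default_rng(seed)
    rank_sum = np.zeros(n_features)
    relevance_sum = np.zeros(n_features)
    for _ in range(n_ensemble):
        resample = _stratified_bootstrap(table, rng)
        ranking = mrmr_rank(resample, K=K)
        positions = np.full(n_features, K + 1, dtype=float)
        positions[ranking.order] = np.arange(1, K + 1)
        rank_sum += positions
        relevance_sum += ranking.relevance
    mean_rank = rank_sum / n_ensemble
    order = np.lexsort((np.arange(n_features), mean_rank))[:K]
    return RankedFeatures(
        order=order,
        relevance=relevance_sum / n_ensemble,
        mrmr_score=-mean_rank[order],
        n_ensemble=n_ensemble,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Incremental (parsimonious) selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Outcome of the sequential feature-addition procedure."""

    k_selected: int
    selected_indices: np.ndarray
    per_k_metrics: pd.DataFrame
    monitor: str

    def to_dict(self) -> dict:
        return {
            "k_selected": int(self.k_selected),
            "selected_indices": np.asarray(self.selected_indices).tolist(),
            "monitor": self.monitor,
            "per_k_metrics": self.per_k_metrics.to_dict(orient="records"),
        }


def select_k(monitor_values, require_all: bool = False, extra_series=None) -> int:
    """The stopping rule: keep the model preceding the first strict decrease.

    ``monitor_values[k-1]`` is the monitored independent-test metric of the
    top-k model.  Returns ``k - 1`` for the smallest ``k >= 2`` whose value
    strictly decreases versus ``k - 1``; if no decrease occurs, returns the
    largest k evaluated.  With ``require_all`` the decrease must be
    simultaneous in every series of ``extra_series`` as well.
    """
    monitor_values = list(monitor_values)
    if not monitor_values:
        raise ValueError("no monitored values")
    extra = [list(s) for s in (extra_series or [])]
    for k in range(2, len(monitor_values) + 1):
        decreased = monitor_values[k - 1] < monitor_values[k - 2]
        if require_all:
            decreased = decreased and all(s[k - 1] < s[k - 2] for s in extra)
        if decreased:
            return k - 1
    return len(monitor_values)


def incremental_select(
    ranking: RankedFeatures,
    train: FeatureTable,
    test: FeatureTable,
    K_max: int = 200,
    monitor: str = "auc",
    require_all_decrease: bool = False,
    cv_folds: int = 5,
    seed: int = 0,
    grid=None,
    cv_table: FeatureTable | None = None,
    resample_inside: bool = False,
    resample_plan=None,
    mwmote_params=None,
    stop_early: bool = True,
) -> SelectionResult:
    """Sequentially add ranked features; stop before the first test-set drop.

    For each k the top-k features are used to tune and train an SVM on
    ``train`` (module :mod:`afpscan.classify`); five-fold CV metrics on
    ``cv_table`` (default: the training table) and metrics on the
    independent ``test`` table are recorded.  Passing the raw training
    partition as ``cv_table`` with ``resample_inside`` keeps CV folds free
    of leaked synthetic rows.  The monitored test metric decides the
    stopping point per :func:`select_k`.  When no decrease occurs up to
    ``K_max`` the full ``K_max``-feature model is retained (logged).
    """
    from . import classify

    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    if K_max > len(ranking.order):
        raise ValueError("K_max exceeds the ranking depth")
    if monitor not in ("auc", "acc", "sn", "sp"):
        raise ValueError(f"unknown monitor metric {monitor!r}")
    if cv_table is None:
        cv_table = train

    rows = []
    monitor_test = []
    extra = {"auc": [], "acc": [], "sn": []}
    for k in range(1, K_max + 1):
        idx = ranking.order[:k]
        model = classify.train_svm(
            train, grid=grid, cv_folds=cv_folds, seed=seed, feature_indices=idx
        )
        cv_report = classify.cross_validate(
            cv_table,
            folds=cv_folds,
            seed=seed,
            feature_indices=idx,
            C=model.C,
            gamma=model.gamma,
            resample_inside=resample_inside,
            resample_plan=resample_plan,
            mwmote_params=mwmote_params,
        )
        test_report = classify.evaluate(
            test.labels, classify.decision_values(model, test), context="test"
        )
        rows.append(
            {
                "k": k,
                "cv_auc": cv_report.auc,
                "cv_acc": cv_report.acc,
                "cv_sn": cv_report.sn,
                "cv_sp": cv_report.sp,
                "test_auc": test_report.auc,
                "test_acc": test_report.acc,
                "test_sn": test_report.sn,
                "test_sp": test_report.sp,
            }
        )
        metric = {"auc": test_report.auc, "acc": test_report.acc,
                  "sn": test_report.sn, "sp": test_report.sp}
        monitor_test.append(metric[monitor])
        for name in extra:
            extra[name].append(metric.get(name, test_report.auc))
        if stop_early and k >= 2:
            decreased = monitor_test[-1] < monitor_test[-2]
            if require_all_decrease:
                decreased = all(extra[m][-1] < extra[m][-2] for m in ("auc", "acc", "sn"))
            if decreased:
                break

    k_selected = select_k(
        monitor_test,
        require_all=require_all_decrease,
        extra_series=[extra[m] for m in ("auc", "acc", "sn")] if require_all_decrease else None,
    )
    if k_selected == len(monitor_test) == K_max:
        logger.info("no test-set decrease up to K_max=%d; retaining all", K_max)
    return SelectionResult(
        k_selected=k_selected,
        selected_indices=ranking.order[:k_selected],
        per_k_metrics=pd.DataFrame(rows),
        monitor=monitor,
    )
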