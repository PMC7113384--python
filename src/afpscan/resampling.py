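"""MWMOTE: majority-weighted minority oversampling for imbalanced protein data.

Implements the Majority Weighted Minority Oversampling TEchnique from first
principles.  The method (a) discards minority samples surrounded entirely by
majority samples, (b) identifies the borderline-majority set near the
minority class, (c) collects the informative minority samples close to that
border, (d) weights each informative sample by closeness and density factors
with respect to the borderline-majority set, and (e) generates synthetic
minority samples by interpolating between an informative sample and a member
of its own minority cluster, so no synthetic point leaves the convex hull of
an observed minority cluster.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist
from sklearn.neighbors import NearestNeighbors

from .containers import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "MwmoteParams",
    "ResamplePlan",
    "required_synthetic_count",
    "informative_weights",
    "cluster_minority",
    "mwmote_oversample",
]


@dataclass(frozen=True)
class MwmoteParams:
    """Tuning constants of the MWMOTE weighting chain.

    k1
        neighborhood size for the minority-noise filter (over all samples).
    k2
        majority neighbors per minority point defining the borderline set.
    k3
        minority neighbors per borderline-majority point defining the
        informative set; ``None`` means ``floor(n_minority / 2)``.
    c_threshold, c_max
        cap and rescale ceiling of the closeness factor (Cf(th) and CMAX).
    cluster_cut_multiplier
        Cp: multiplies the mean nearest-minority-neighbor distance to set the
        average-linkage dendrogram cut.
    """

    k1: int = 5
    k2: int = 3
    k3: int | None = None
    c_threshold: float = 5.0
    c_max: float = 2.0
    cluster_cut_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if self.k1 < 1 or self.k2 < 1 or (self.k3 is not None and self.k3 < 1):
            raise ValueError("neighborhood sizes must be positive")
        if self.c_threshold <= 0 or self.c_max <= 0 or self.cluster_cut_multiplier <= 0:
            raise ValueError("closeness/cluster constants must be positive")

    def resolved_k3(self, n_minority: int) -> int:
        k3 = self.k3 if self.k3 is not None else max(1, n_minority // 2)
        return min(k3, n_minority)


@dataclass(frozen=True)
class ResamplePlan:
    """Target class balance for one oversampling run."""

    target_ratio: float = 0.78
    n_synthetic: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_ratio <= 1:
            raise ValueError("target_ratio must lie in (0, 1]")
        if self.n_synthetic is not None and self.n_synthetic < 0:
            raise ValueError("n_synthetic must be non-negative")


def required_synthetic_count(n_minority: int, n_majority: int, target_ratio: float) -> int:
    """Number of synthetic minority rows needed to reach the target ratio."""
    if n_minority < 1 or n_majority < 1:
        raise ValueError("both classes must be non-empty")
    if target_ratio <= 0:
        raise ValueError("target_ratio must be positive")
    return max(0, math.ceil(target_ratio * n_majority) - n_minority)


def informative_weights(
    minority: np.ndarray, majority: np.ndarray, params: MwmoteParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Informative minority indices and their selection probabilities.

    Returns ``(informative, probabilities)`` where ``informative`` indexes
    rows of ``minority`` and ``probabilities`` sums to 1.  If the noise
    filter removes every minority point (or the informative set comes out
    empty) the method degrades to uniform sampling over all minority points
    rather than failing.
    """
    params = params or MwmoteParams()
    minority = np.asarray(minority, dtype=float)
    majority = np.asarray(majority, dtype=float)
    n_min = minority.shape[0]
    if n_min < 2:
        raise ValueError("informative_weights needs at least 2 minority points")
    n_maj = majority.shape[0]
    dim = minority.shape[1]

    # (a) drop minority points whose k1-neighborhood (over all points,
    # excluding self) contains no minority point.
    all_points = np.vstack([minority, majority])
    k1 = min(params.k1, all_points.shape[0] - 1)
    nn_all = NearestNeighbors(n_neighbors=k1 + 1).fit(all_points)
    _, neigh = nn_all.kneighbors(minority)
    filtered = []
    for i in range(n_min):
        others = neigh[i][neigh[i] != i][:k1]
        if (others < n_min).any():
            filtered.append(i)

    if not filtered or n_maj == 0:
        logger.warning(
            "MWMOTE noise filter removed every minority point; "
            "falling back to uniform sampling over all minority rows"
        )
        informative = np.arange(n_min)
        return informative, np.full(n_min, 1.0 / n_min)

    # (b) borderline-majority set: union of k2 nearest majority neighbors.
    k2 = min(params.k2, n_maj)
    nn_maj = NearestNeighbors(n_neighbors=k2).fit(majority)
    _, maj_neigh = nn_maj.kneighbors(minority[filtered])
    borderline = np.unique(maj_neigh.reshape(-1))

    # (c) informative-minority set: union of k3 nearest minority neighbors of
    # each borderline-majority point.
    k3 = params.resolved_k3(n_min)
    nn_min = NearestNeighbors(n_neighbors=k3).fit(minority)
    _, min_neigh = nn_min.kneighbors(majority[borderline])
    informative = np.unique(min_neigh.reshape(-1))
    if informative.size == 0:
        logger.warning("MWMOTE informative set empty; falling back to uniform sampling")
        informative = np.arange(n_min)
        return informative, np.full(n_min, 1.0 / n_min)

    # (d) closeness x density weights.
    dist = cdist(majority[borderline], minority[informative]) / dim
    with np.errstate(divide="ignore"):
        inv = np.where(dist > 0, 1.0 / dist, np.inf)
    closeness = np.minimum(inv, params.c_threshold) * (params.c_max / params.c_threshold)
    row_sums = closeness.sum(axis=1, keepdims=True)
    density = closeness / row_sums
    weights = (closeness * density).sum(axis=0)
    total = weights.sum()
    if total <= 0:
        probabilities = np.full(informative.size, 1.0 / informative.size)
    else:
        probabilities = weights / total
    return informative, probabilities


def cluster_minority(minority: np.ndarray, params: MwmoteParams | None = None) -> np.ndarray:
    """Average-linkage clustering of minority points, cut at Cp x mean NN distance.

    Returns a 0-based cluster label per point.
    """
    params = params or MwmoteParams()
    minority = np.asarray(minority, dtype=float)
    n = minority.shape[0]
    if n < 1:
        raise ValueError("cluster_minority needs at least one point")
    if n == 1:
        return np.zeros(1, dtype=int)
    nn = NearestNeighbors(n_neighbors=2).fit(minority)
    dists, _ = nn.kneighbors(minority)
    threshold = params.cluster_cut_multiplier * dists[:, 1].mean()
    tree = linkage(minority, method="average", metric="euclidean")
    labels = fcluster(tree, t=threshold, criterion="distance")
    return labels - 1


def mwmote_oversample(
    table: FeatureTable,
    plan: ResamplePlan | None = None,
    params: MwmoteParams | None = None,
) -> FeatureTable:
    """Append MWMOTE synthetic minority rows until the target ratio is met.

    Each synthetic sample is ``x + alpha * (y - x)`` with ``x`` drawn from the
    informative minority set by its selection probability, ``y`` drawn
    uniformly from ``x``'s minority cluster and ``alpha ~ Uniform(0, 1)``.
    Original rows are untouched and keep their order; synthetic rows carry
    label 1 and a set synthetic flag.  Deterministic given ``plan.seed``.
    """
    plan = plan or ResamplePlan()
    params = params or MwmoteParams()
    n_min, n_maj = table.n_minority, table.n_majority
    if n_min == 0 or n_maj == 0:
        raise ValueError("MWMOTE needs both classes present in the table")
    if plan.n_synthetic is not None:
        n_synthetic = plan.n_synthetic
    else:
        n_synthetic = required_synthetic_count(n_min, n_maj, plan.target_ratio)
    if n_synthetic == 0:
        return table

    minority = table.matrix[table.labels == 1]
    majority = table.matrix[table.labels == 0]
    if n_min == 1:
        informative = np.zeros(1, dtype=int)
        probabilities = np.ones(1)
    else:
        informative, probabilities = informative_weights(minority, majority, params)
    clusters = cluster_minority(minority, params)
    members_of = {c: np.flatnonzero(clusters == c) for c in np.unique(clusters)}

    rng = np.random.default_rng(plan.seed)
    picks = rng.choice(informative, size=n_synthetic, p=probabilities)
    rows = np.empty((n_synthetic, table.n_features))
    for s, x_idx in enumerate(picks):
        members = members_of[clusters[x_idx]]
        y_idx = int(rng.choice(members))
        alpha = rng.uniform()
        x, y = minority[x_idx], minority[y_idx]
        rows[s] = x + alpha * (y - x)
    ids = [f"synthetic_{i:05d}" for i in range(n_synthetic)]
    logger.info(
        "MWMOTE: generated %d synthetic minority rows (ratio %.4f -> %.4f)",
        n_synthetic,
        n_min / n_maj,
        (n_min + n_synthetic) / n_maj,
    )
    return table.append_rows(ids, rows, np.ones(n_synthetic), np.ones(n_synthetic))
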