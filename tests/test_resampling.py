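"""MWMOTE oversampling: weight chain, clustering and interpolation contracts."""

import math

import numpy as np
import pytest

from afpscan.containers import FeatureTable
from afpscan.resampling import (
    MwmoteParams,
    ResamplePlan,
    cluster_minority,
    informative_weights,
    mwmote_oversample,
    required_synthetic_count,
)
from tests.conftest import random_table


# ---------------------------------------------------------------------------
# Synthetic-count arithmetic
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "n_min,n_maj,ratio,expected",
    [
        (10, 100, 0.5, 40),
        (50, 100, 0.5, 0),
        (318, 5938, 0.78, 4314),
        (1, 1, 1.0, 0),
    ],
)
def test_required_synthetic_count_examples(n_min, n_maj, ratio, expected):
    assert required_synthetic_count(n_min, n_maj, ratio) == expected


def test_required_synthetic_count_grid_matches_ceiling_formula():
    for n_min in (1, 7, 50, 318):
        for n_maj in (10, 100, 5938):
            for ratio in (0.1, 0.5, 0.78, 1.0):
                expected = max(0, math.ceil(ratio * n_maj) - n_min)
                assert required_synthetic_count(n_min, n_maj, ratio) == expected


def test_required_synthetic_count_rejects_bad_input():
    with pytest.raises(ValueError):
        required_synthetic_count(0, 10, 0.5)
    with pytest.raises(ValueError):
        required_synthetic_count(10, 10, 0.0)


# ---------------------------------------------------------------------------
# Informative weights
# ---------------------------------------------------------------------------

def brute_force_weights(minority, majority, params: MwmoteParams):
    """Literal re-computation of the MWMOTE weighting chain with loops."""
    n_min = len(minority)
    all_points = np.vstack([minority, majority])

    def knn(query, points, k, exclude=None):
        dists = np.linalg.norm(points - query, axis=1)
        order = [i for i in np.argsort(dists, kind="stable") if i != exclude]
        return order[:k]

    filtered = []
    for i in range(n_min):
        neighbors = knn(minority[i], all_points, params.k1, exclude=i)
        if any(j < n_min for j in neighbors):
            filtered.append(i)
    if not filtered:
        return list(range(n_min)), np.full(n_min, 1.0 / n_min)

    borderline = set()
    for i in filtered:
        borderline.update(knn(minority[i], majority, min(params.k2, len(majority))))
    borderline = sorted(borderline)

    k3 = params.resolved_k3(n_min)
    informative = set()
    for y in borderline:
        informative.update(knn(majority[y], minority, k3))
    informative = sorted(informative)

    dim = minority.shape[1]
    scale = params.c_max / params.c_threshold

    def closeness(y, x):
        d = np.linalg.norm(majority[y] - minority[x]) / dim
        raw = params.c_threshold if d == 0 else min(1.0 / d, params.c_threshold)
        return raw * scale

    weights = np.zeros(len(informative))
    for y in borderline:
        total = sum(closeness(y, x) for x in informative)
        for pos, x in enumerate(informative):
            cf = closeness(y, x)
            weights[pos] += cf * (cf / total)
    return informative, weights / weights.sum()


@pytest.mark.parametrize("seed", range(4))
def test_informative_weights_match_brute_force_chain(seed):
    rng = np.random.default_rng(seed)
    minority = rng.normal(0, 1, size=(8, 3))
    majority = rng.normal(2.5, 1, size=(12, 3))
    params = MwmoteParams(k1=4, k2=2, k3=3)
    informative, probs = informative_weights(minority, majority, params)
    oracle_informative, oracle_probs = brute_force_weights(minority, majority, params)
    assert informative.tolist() == list(oracle_informative)
    assert np.allclose(probs, oracle_probs, atol=1e-10)


def test_boundary_minority_points_outweigh_interior_ones():
    rng = np.random.default_rng(7)
    interior = rng.normal([-4, 0], 0.3, size=(8, 2))
    boundary = rng.normal([-0.8, 0], 0.3, size=(8, 2))
    minority = np.vstack([interior, boundary])
    majority = rng.normal([2, 0], 0.5, size=(30, 2))
    informative, probs = informative_weights(minority, majority, MwmoteParams(k1=6))
    weight = np.zeros(len(minority))
    weight[informative] = probs
    assert weight[8:].min() > weight[:8].max()


def test_probabilities_are_a_distribution(rng):
    minority = rng.normal(size=(10, 4))
    majority = rng.normal(size=(25, 4))
    _, probs = informative_weights(minority, majority)
    assert probs.min() >= 0
    assert probs.sum() == pytest.approx(1.0)


def test_all_noise_minority_falls_back_to_uniform():
    # Two isolated minority points surrounded by a tight majority cloud.
    rng = np.random.default_rng(3)
    minority = np.array([[10.0, 10.0], [-10.0, -10.0]])
    majority = np.vstack(
        [rng.normal(10, 0.01, size=(6, 2)), rng.normal(-10, 0.01, size=(6, 2))]
    )
    informative, probs = informative_weights(minority, majority, MwmoteParams(k1=3))
    assert informative.tolist() == [0, 1]
    assert np.allclose(probs, [0.5, 0.5])


# ---------------------------------------------------------------------------
# Minority clustering
# ---------------------------------------------------------------------------

def brute_force_average_linkage(points, threshold):
    """Naive agglomerative clustering oracle: merge closest pair while <= cut."""
    clusters = [[i] for i in range(len(points))]

    def avg_dist(a, b):
        return np.mean(
            [np.linalg.norm(points[i] - points[j]) for i in a for j in b]
        )

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = avg_dist(clusters[i], clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        if best[0] > threshold:
            break
        d, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    labels = np.empty(len(points), dtype=int)
    for c, members in enumerate(clusters):
        labels[members] = c
    return labels


def _as_partitions(labels):
    groups = {}
    for i, c in enumerate(labels):
        groups.setdefault(c, set()).add(i)
    return sorted(map(frozenset, groups.values()), key=min)


def test_two_far_pairs_give_two_clusters():
    points = np.array([[0, 0], [0, 0.1], [50, 50], [50, 50.1]])
    labels = cluster_minority(points)
    assert labels[0] == labels[1]
    assert labels[2] == labels[3]
    assert labels[0] != labels[2]


def test_identical_points_form_one_cluster():
    labels = cluster_minority(np.ones((5, 3)))
    assert len(set(labels)) == 1


def test_single_point_is_a_singleton_cluster():
    assert cluster_minority(np.zeros((1, 2))).tolist() == [0]


@pytest.mark.parametrize("seed", range(5))
def test_clustering_matches_agglomerative_oracle(seed):
    rng = np.random.default_rng(seed)
    points = rng.normal(size=(10, 2))
    params = MwmoteParams()
    nn_dists = [
        min(np.linalg.norm(points[i] - points[j]) for j in range(10) if j != i)
        for i in range(10)
    ]
    threshold = params.cluster_cut_multiplier * np.mean(nn_dists)
    labels = cluster_minority(points, params)
    oracle = brute_force_average_linkage(points, threshold)
    assert _as_partitions(labels) == _as_partitions(oracle)


# ---------------------------------------------------------------------------
# Oversampling contracts
# ---------------------------------------------------------------------------

def test_target_already_met_is_a_no_op(rng):
    table = random_table(rng, n_pos=10, n_neg=20)
    plan = ResamplePlan(target_ratio=0.5, seed=0)
    assert mwmote_oversample(table, plan) is table


def test_degenerate_identical_minority_reproduces_the_point(rng):
    X = np.vstack([np.full((2, 3), 7.0), rng.normal(size=(10, 3))])
    table = FeatureTable(
        [f"s{i}" for i in range(12)], X, [1, 1] + [0] * 10,
        feature_names=["a", "b", "c"],
    )
    out = mwmote_oversample(table, ResamplePlan(target_ratio=0.5, seed=1))
    synthetic = out.matrix[out.synthetic_flags == 1]
    assert len(synthetic) == 3
    assert np.allclose(synthetic, 7.0)


def _convex_pair_exists(s, minority, clusters, atol=1e-8):
    for c in np.unique(clusters):
        members = np.flatnonzero(clusters == c)
        for x in members:
            for y in members:
                d = minority[y] - minority[x]
                denom = d @ d
                if denom == 0:
                    if np.allclose(s, minority[x], atol=atol):
                        return True
                    continue
                alpha = (s - minority[x]) @ d / denom
                if -1e-9 <= alpha <= 1 + 1e-9 and np.allclose(
                    s, minority[x] + alpha * d, atol=atol
                ):
                    return True
    return False


def test_synthetic_rows_are_in_cluster_convex_combinations(rng):
    table = random_table(rng, n_pos=12, n_neg=40, n_features=4, separation=1.0)
    plan = ResamplePlan(target_ratio=0.6, seed=5)
    out = mwmote_oversample(table, plan)
    minority = table.matrix[table.labels == 1]
    clusters = cluster_minority(minority)
    synthetic = out.matrix[out.synthetic_flags == 1]
    assert len(synthetic) == 24 - 12
    for s in synthetic:
        assert _convex_pair_exists(s, minority, clusters)
    # original rows untouched, order preserved
    assert np.array_equal(out.matrix[: table.n_samples], table.matrix)
    assert out.sample_ids[: table.n_samples] == table.sample_ids
    assert out.labels[out.synthetic_flags == 1].all()


def test_achieved_ratio_lands_in_the_contract_band(rng):
    table = random_table(rng, n_pos=9, n_neg=37, n_features=3)
    for ratio in (0.3, 0.5, 0.78):
        out = mwmote_oversample(table, ResamplePlan(target_ratio=ratio, seed=2))
        assert ratio <= out.minority_ratio <= ratio + 1 / table.n_majority + 1e-12


def test_seed_determinism_and_divergence(rng):
    table = random_table(rng, n_pos=8, n_neg=30, n_features=5)
    a = mwmote_oversample(table, ResamplePlan(target_ratio=0.5, seed=11))
    b = mwmote_oversample(table, ResamplePlan(target_ratio=0.5, seed=11))
    c = mwmote_oversample(table, ResamplePlan(target_ratio=0.5, seed=12))
    assert np.array_equal(a.matrix, b.matrix)
    assert not np.array_equal(a.matrix, c.matrix)


def test_synthetic_stays_in_cluster_bounding_box(rng):
    table = random_table(rng, n_pos=15, n_neg=50, n_features=4)
    out = mwmote_oversample(table, ResamplePlan(target_ratio=0.5, seed=3))
    minority = table.matrix[table.labels == 1]
    clusters = cluster_minority(minority)
    lo = minority.min(axis=0) - 1e-9
    hi = minority.max(axis=0) + 1e-9
    synthetic = out.matrix[out.synthetic_flags == 1]
    assert (synthetic >= lo).all() and (synthetic <= hi).all()
    del clusters


def test_single_class_table_is_rejected(rng):
    table = random_table(rng, n_pos=0, n_neg=10)
    with pytest.raises(ValueError):
        mwmote_oversample(table, ResamplePlan(target_ratio=0.5))
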