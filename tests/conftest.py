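import numpy as np
import pytest

from afpscan.alphabet import AA_ORDER
from afpscan.containers import FeatureTable, PssmProfile


def random_profile(rng: np.random.Generator, length: int = 12) -> PssmProfile:
    residues = "".join(np.array(list(AA_ORDER))[rng.integers(0, 20, size=length)])
    scores = rng.integers(-6, 7, size=(length, 20))
    return PssmProfile(id=f"p{rng.integers(1e6)}", residues=residues, scores=scores)


def random_table(
    rng: np.random.Generator,
    n_pos: int = 10,
    n_neg: int = 20,
    n_features: int = 6,
    separation: float = 0.0,
) -> FeatureTable:
    """Small labelled table; positive class optionally shifted on feature 0."""
    n = n_pos + n_neg
    labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    X = rng.normal(size=(n, n_features))
    X[labels == 1, 0] += separation
    return FeatureTable(
        sample_ids=[f"s{i}" for i in range(n)],
        matrix=X,
        labels=labels,
        feature_names=[f"f{i}" for i in range(n_features)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
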