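"""The 400-dimensional evolutionary encoding of PSSM profiles.

Rows of a profile sharing the same query residue are summed into a 20 x 20
matrix whose (X, Z) entry accumulates the log-odds scores for replacing query
residue X by residue Z across all X positions; flattening row-major over the
canonical amino-acid order yields the 400-feature vector.  The encoding is
position-free and additive over sequence segments.  No length normalization
is applied by default (the features are raw occurrence sums, so longer
proteins have larger-magnitude vectors); pass ``normalize_by_length=True`` to
divide by sequence length, and leave scale handling to the classifier's
standardizer otherwise.
"""

from __future__ import annotations

import numpy as np

from .alphabet import AA_INDEX, FEATURE_NAMES, N_AMINO_ACIDS, feature_index, feature_label
from .containers import FeatureTable, PssmProfile

__all__ = [
    "aggregate_pssm",
    "encode_profile",
    "encode_dataset",
    "feature_index",
    "feature_label",
]


def aggregate_pssm(profile: PssmProfile) -> np.ndarray:
    """Sum profile rows by query residue into a 20 x 20 substitution matrix.

    Entry (X, Z) is the sum over positions carrying residue X of the score in
    column Z.  Residues absent from the sequence leave an all-zero row.
    """
    matrix = np.zeros((N_AMINO_ACIDS, N_AMINO_ACIDS), dtype=float)
    row_idx = np.fromiter((AA_INDEX[aa] for aa in profile.residues), dtype=int)
    np.add.at(matrix, row_idx, profile.scores.astype(float))
    return matrix


def encode_profile(profile: PssmProfile, normalize_by_length: bool = False) -> np.ndarray:
    """Flatten the aggregated 20 x 20 matrix into the 400-feature vector."""
    vector = aggregate_pssm(profile).reshape(-1)
    if normalize_by_length:
        vector = vector / profile.length
    return vector


def encode_dataset(
    profiles: list[PssmProfile], labels, normalize_by_length: bool = False
) -> FeatureTable:
    """Encode a list of profiles into one FeatureTable, preserving order."""
    if len(profiles) == 0:
        raise ValueError("cannot encode an empty profile list")
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(profiles):
        raise ValueError(
            f"{len(profiles)} profiles but {len(labels)} labels"
        )
    matrix = np.vstack([encode_profile(p, normalize_by_length) for p in profiles])
    return FeatureTable(
        sample_ids=[p.id for p in profiles],
        matrix=matrix,
        labels=labels,
        feature_names=FEATURE_NAMES,
    )
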