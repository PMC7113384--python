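"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import AA_ORDER, FEATURE_NAMES


@dataclass(frozen=True)
class ProteinSequence:
    """A named amino-acid sequence, possibly still containing ambiguous letters."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has an empty residue string")


@dataclass
class PssmProfile:
    """A query sequence together with its n x 20 log-odds substitution-score matrix.

    ``scores[i, j]`` is the log-odds score of residue ``column_order[j]``
    replacing the query residue at position ``i``; negative values mean the
    replacement is rarer than chance (the query residue is conserved there).
    """

    id: str
    residues: str
    scores: np.ndarray
    column_order: str = AA_ORDER

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"PSSM {self.id!r}: scores must be n x 20, got {self.scores.shape}"
            )
        if self.scores.shape[0] != len(self.residues):
            raise ValueError(
                f"PSSM {self.id!r}: {self.scores.shape[0]} score rows but "
                f"{len(self.residues)} residues"
            )
        if sorted(self.column_order) != sorted(AA_ORDER):
            raise ValueError(f"PSSM {self.id!r}: invalid column order")

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PssmGenerationSettings:
    """How the upstream PSI-BLAST profile search is (or was) invoked."""

    iterations: int = 3
    e_value: float = 0.0001
    database: str = "swissprot"

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.e_value <= 0:
            raise ValueError("e_value must be positive")

    def command_template(self) -> str:
        """The documented (never executed here) PSI-BLAST invocation."""
        return (
            f"psiblast -query {{query.fasta}} -db {self.database} "
            f"-num_iterations {self.iterations} -evalue {self.e_value} "
            f"-out_ascii_pssm {{query_id}}.pssm"
        )


class FeatureTable:
    """Samples x features matrix with binary labels and synthetic-row provenance.

    The canonical shape is samples x 400 substitution features, but any
    feature subset is allowed (ranked-feature work operates on slices).
    Label 1 marks the antifreeze (minority) class; ``synthetic_flags`` mark
    rows produced by oversampling rather than observed data.
    """

    def __init__(
        self,
        sample_ids,
        matrix,
        labels,
        synthetic_flags=None,
        feature_names=None,
    ) -> None:
        self.sample_ids = list(sample_ids)
        self.matrix = np.asarray(matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        self.labels = np.asarray(labels, dtype=int)
        if synthetic_flags is None:
            synthetic_flags = np.zeros(len(self.labels), dtype=int)
        self.synthetic_flags = np.asarray(synthetic_flags, dtype=int)
        if feature_names is None:
            if self.matrix.shape[1] != len(FEATURE_NAMES):
                raise ValueError(
                    "feature_names required when the table is not 400-wide"
                )
            feature_names = list(FEATURE_NAMES)
        self.feature_names = list(feature_names)

        n = self.matrix.shape[0]
        if not (len(self.sample_ids) == n == len(self.labels) == len(self.synthetic_flags)):
            raise ValueError("sample_ids, matrix rows, labels and flags must align")
        if len(self.feature_names) != self.matrix.shape[1]:
            raise ValueError("feature_names must match matrix width")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0 = non-antifreeze, 1 = antifreeze)")
        if not np.isin(self.synthetic_flags, (0, 1)).all():
            raise ValueError("synthetic_flags must be binary")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_minority(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_majority(self) -> int:
        return int((self.labels == 0).sum())

    @property
    def minority_ratio(self) -> float:
        if self.n_majority == 0:
            raise ZeroDivisionError("no majority rows")
        return self.n_minority / self.n_majority

    # -- slicing --------------------------------------------------------
    def subset_rows(self, index) -> "FeatureTable":
        index = np.asarray(index)
        return FeatureTable(
            [self.sample_ids[i] for i in index],
            self.matrix[index],
            self.labels[index],
            self.synthetic_flags[index],
            self.feature_names,
        )

    def subset_features(self, index) -> "FeatureTable":
        index = np.asarray(index, dtype=int)
        return FeatureTable(
            self.sample_ids,
            self.matrix[:, index],
            self.labels,
            self.synthetic_flags,
            [self.feature_names[i] for i in index],
        )

    def append_rows(self, sample_ids, matrix, labels, synthetic_flags) -> "FeatureTable":
        return FeatureTable(
            self.sample_ids + list(sample_ids),
            np.vstack([self.matrix, np.asarray(matrix, dtype=float)]),
            np.concatenate([self.labels, np.asarray(labels, dtype=int)]),
            np.concatenate([self.synthetic_flags, np.asarray(synthetic_flags, dtype=int)]),
            self.feature_names,
        )

    # -- interop --------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.matrix, columns=self.feature_names)
        frame.insert(0, "synthetic", self.synthetic_flags)
        frame.insert(0, "label", self.labels)
        frame.insert(0, "sample_id", self.sample_ids)
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureTable":
        for col in ("sample_id", "label"):
            if col not in frame.columns:
                raise ValueError(f"feature table is missing the {col!r} column")
        reserved = {"sample_id", "label", "synthetic"}
        feature_cols = [c for c in frame.columns if c not in reserved]
        if not feature_cols:
            raise ValueError("feature table has no feature columns")
        synthetic = (
            frame["synthetic"].to_numpy()
            if "synthetic" in frame.columns
            else np.zeros(len(frame), dtype=int)
        )
        return cls(
            frame["sample_id"].astype(str).tolist(),
            frame[feature_cols].to_numpy(dtype=float),
            frame["label"].to_numpy(dtype=int),
            synthetic,
            feature_cols,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.feature_names == other.feature_names
            and np.array_equal(self.labels, other.labels)
            and np.array_equal(self.synthetic_flags, other.synthetic_flags)
            and np.allclose(self.matrix, other.matrix, rtol=0, atol=1e-12)
        )

    def __repr__(self) -> str:
        return (
            f"FeatureTable(n_samples={self.n_samples}, n_features={self.n_features}, "
            f"n_minority={self.n_minority}, n_majority={self.n_majority})"
        )
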