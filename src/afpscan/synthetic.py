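"""Synthetic PSSM profiles and feature tables with a planted class signal.

The generator emulates the structure that separates antifreeze from
non-antifreeze proteins in substitution-score space: for a small set of
planted (query residue X, replacement residue Z) pairs, the X -> Z
replacement score is depressed in the positive class (the residue is
conserved: replacements are rarer than chance) and elevated in the negative
class.  The five canonical pairs are C-A, W-M, G-A, R-S and R-R — the
replacements of Cys, Trp and Gly by Ala/Met/Ala that antifreeze proteins
avoid, and the Ser/Arg replacements of Arg that they favour — plus two
configurable extras for a total of seven planted features.

Everything else is uniform background: residues are drawn uniformly over the
20-letter alphabet and background scores uniformly over a symmetric integer
range, so unplanted features carry no label information.  Real PSI-BLAST
profiles have positional autocorrelation and alignment-depth structure that
this generator deliberately omits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alphabet import AA_INDEX, AA_ORDER, feature_index
from .containers import FeatureTable, ProteinSequence, PssmProfile
from .pssm_io import write_fasta, write_pssm

__all__ = [
    "SimulationConfig",
    "SimulatedTable",
    "simulate_pssm_profiles",
    "simulate_feature_table",
    "write_fixture_dir",
    "DEFAULT_PLANTED_PAIRS",
]

#: the five high-signal substitution pairs plus two conservative extras.
DEFAULT_PLANTED_PAIRS: tuple[tuple[str, str], ...] = (
    ("C", "A"),
    ("W", "M"),
    ("G", "A"),
    ("R", "S"),
    ("R", "R"),
    ("E", "D"),
    ("K", "Q"),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic data set.

    ``delta`` is the per-position substitution-score shift at planted pairs:
    positives get ``-delta`` (replacement suppressed, query residue
    conserved), negatives ``+delta``.  ``noise_sd`` is the standard deviation
    of the Gaussian jitter added on top (rounded back to integers so profiles
    stay valid PSSMs).
    """

    n_pos: int = 200
    n_neg: int = 800
    length_range: tuple[int, int] = (50, 300)
    planted_pairs: tuple[tuple[str, str], ...] = DEFAULT_PLANTED_PAIRS
    delta: float = 8.0
    noise_sd: float = 2.0
    background_score_range: tuple[int, int] = (-5, 5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("both classes need at least one sample")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid length_range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.delta != 0 and not self.planted_pairs:
            raise ValueError("a nonzero delta requires at least one planted pair")
        for x, z in self.planted_pairs:
            if x not in AA_INDEX or z not in AA_INDEX:
                raise ValueError(f"planted pair ({x}, {z}) uses a non-standard residue")

    @property
    def planted_indices(self) -> list[int]:
        return [feature_index(x, z) for x, z in self.planted_pairs]


@dataclass
class SimulatedTable:
    """A simulated feature table plus the provenance of its planted signal."""

    table: FeatureTable
    planted_indices: list[int]
    config: SimulationConfig


def simulate_pssm_profiles(
    config: SimulationConfig,
) -> tuple[list[PssmProfile], np.ndarray]:
    """Draw labelled synthetic PSSM profiles; positives first, then negatives.

    Deterministic for a fixed config (including seed).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    s_lo, s_hi = config.background_score_range
    profiles: list[PssmProfile] = []
    labels = np.concatenate(
        [np.ones(config.n_pos, dtype=int), np.zeros(config.n_neg, dtype=int)]
    )
    aa = np.array(list(AA_ORDER))
    for i, label in enumerate(labels):
        length = int(rng.integers(lo, hi + 1))
        residues = aa[rng.integers(0, 20, size=length)]
        scores = rng.integers(s_lo, s_hi + 1, size=(length, 20)).astype(float)
        shift = -config.delta if label == 1 else config.delta
        for x, z in config.planted_pairs:
            rows = np.flatnonzero(residues == x)
            if rows.size:
                noise = rng.normal(0.0, config.noise_sd, size=rows.size)
                scores[rows, AA_INDEX[z]] += np.rint(shift + noise)
        prefix = "pos" if label == 1 else "neg"
        profiles.append(
            PssmProfile(
                id=f"{prefix}_{i:05d}",
                residues="".join(residues),
                scores=scores.astype(int),
            )
        )
    return profiles, labels


def simulate_feature_table(config: SimulationConfig) -> SimulatedTable:
    """Shortcut generator: 400-column tables with class-shifted planted columns.

    Planted columns are Gaussian with class means -delta/2 (positives) and
    +delta/2 (negatives) and sd ``noise_sd``; every other column is standard
    normal noise.  Much faster than simulating and encoding full profiles,
    with the same planted-index bookkeeping.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_pos + config.n_neg
    labels = np.concatenate(
        [np.ones(config.n_pos, dtype=int), np.zeros(config.n_neg, dtype=int)]
    )
    X = rng.normal(0.0, 1.0, size=(n, 400))
    planted = config.planted_indices
    centers = np.where(labels == 1, -config.delta / 2.0, config.delta / 2.0)
    for j in planted:
        X[:, j] = centers + rng.normal(0.0, config.noise_sd, size=n)
    ids = [
        f"{'pos' if label == 1 else 'neg'}_{i:05d}" for i, label in enumerate(labels)
    ]
    table = FeatureTable(sample_ids=ids, matrix=X, labels=labels)
    return SimulatedTable(table=table, planted_indices=list(planted), config=config)


def write_fixture_dir(config: SimulationConfig, out_dir) -> dict:
    """Emit FASTA + per-sequence PSSM files + a truth JSON for a config.

    Returns the truth payload (labels, planted pairs/indices, seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pssm_dir = out_dir / "pssm"
    pssm_dir.mkdir(exist_ok=True)
    profiles, labels = simulate_pssm_profiles(config)
    sequences = [ProteinSequence(p.id, p.residues) for p in profiles]
    write_fasta(sequences, out_dir / "sequences.fasta")
    for profile in profiles:
        write_pssm(profile, pssm_dir / f"{profile.id}.pssm")
    truth = {
        "labels": {p.id: int(label) for p, label in zip(profiles, labels)},
        "planted_pairs": [list(pair) for pair in config.planted_pairs],
        "planted_indices": config.planted_indices,
        "delta": config.delta,
        "noise_sd": config.noise_sd,
        "seed": config.seed,
    }
    with (out_dir / "truth.json").open("w") as handle:
        json.dump(truth, handle, indent=2)
    return truth
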