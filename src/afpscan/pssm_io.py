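"""Reading and validating FASTA sequences, PSI-BLAST ASCII PSSMs and feature tables.

The PSSM dialect handled here is the plain-text matrix PSI-BLAST emits via
``-out_ascii_pssm``: a couple of header lines, a 40-letter column header, then
one row per query position holding the position number, the query residue,
20 integer log-odds scores, 20 integer weighted percentages and two trailing
per-position statistics.  Only the log-odds block is used by the evolutionary
encoding by default; the percentage block can be selected for experimentation.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .alphabet import AA_INDEX, AA_ORDER, AMBIGUOUS_RESIDUES
from .containers import FeatureTable, ProteinSequence, PssmGenerationSettings, PssmProfile

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "write_fasta",
    "filter_ambiguous",
    "read_pssm",
    "write_pssm",
    "load_profiles",
    "read_feature_table",
    "write_feature_table",
    "psiblast_command",
]


def read_fasta(path) -> list[ProteinSequence]:
    """Parse a FASTA file into ``ProteinSequence`` records, order preserved.

    Residues are uppercased.  A record with an empty sequence raises a
    ``ValueError`` naming its header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    sequences = []
    for rec in records:
        residues = str(rec.seq).upper()
        if not residues:
            raise ValueError(f"FASTA record {rec.id!r} has an empty sequence")
        sequences.append(ProteinSequence(id=rec.id, residues=residues))
    return sequences


def write_fasta(sequences: list[ProteinSequence], path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as out:
        for seq in sequences:
            out.write(f">{seq.id}\n")
            for start in range(0, len(seq.residues), width):
                out.write(seq.residues[start : start + width] + "\n")


def filter_ambiguous(
    sequences: list[ProteinSequence],
) -> tuple[list[ProteinSequence], list[ProteinSequence]]:
    """Split sequences into (retained, rejected) by the ambiguous-letter rule.

    A sequence is rejected iff it contains at least one of X, B, U or O;
    order is preserved within both lists.
    """
    retained, rejected = [], []
    for seq in sequences:
        if AMBIGUOUS_RESIDUES.intersection(seq.residues):
            rejected.append(seq)
        else:
            retained.append(seq)
    return retained, rejected


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

def _find_header(lines: list[str]):
    """Locate the 40-letter column header; return (line index, letters)."""
    for i, line in enumerate(lines):
        tokens = line.split()
        if len(tokens) >= 40 and all(len(t) == 1 and t.isalpha() for t in tokens[:40]):
            return i, [t.upper() for t in tokens[:40]]
    raise ValueError("no PSSM column header (40 amino-acid letters) found")


def read_pssm(path, profile_id: str | None = None, block: str = "log_odds") -> PssmProfile:
    """Parse one PSI-BLAST ASCII PSSM file into a ``PssmProfile``.

    ``block`` selects which 20-column block to keep: ``"log_odds"`` (default,
    the signed substitution scores) or ``"percent"`` (the weighted observed
    percentages).  Columns are reordered to the canonical order if the file
    header declares a different one.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PSSM file not found: {path}")
    if block not in ("log_odds", "percent"):
        raise ValueError(f"unknown PSSM block {block!r}")
    lines = path.read_text().splitlines()
    header_idx, letters = _find_header(lines)
    offset = 0 if block == "log_odds" else 20
    block_letters = letters[offset : offset + 20]
    for letter in block_letters:
        if letter not in AA_INDEX:
            raise ValueError(f"unrecognized amino acid {letter!r} in PSSM header")
    if sorted(block_letters) != sorted(AA_ORDER):
        raise ValueError("PSSM header does not list the 20 standard amino acids")

    residues: list[str] = []
    rows: list[list[int]] = []
    for line in lines[header_idx + 1 :]:
        tokens = line.split()
        if not tokens:
            continue
        if not tokens[0].lstrip("-").isdigit():
            break  # footer statistics (Lambda/K) or free text
        if len(tokens) < 2 or not (len(tokens[1]) == 1 and tokens[1].isalpha()):
            raise ValueError(f"malformed PSSM row at position token {tokens[0]}")
        residue = tokens[1].upper()
        if residue not in AA_INDEX:
            raise ValueError(
                f"unrecognized residue {residue!r} at PSSM position {tokens[0]}"
            )
        numeric = tokens[2:]
        # Trailing information-content / relative-weight floats are optional.
        int_tokens = []
        for tok in numeric:
            if tok.lstrip("-").isdigit():
                int_tokens.append(tok)
            else:
                break
        if len(int_tokens) != 40:
            raise ValueError(
                f"PSSM row {len(rows)} (position {tokens[0]}): expected 40 integer "
                f"score columns, found {len(int_tokens)}"
            )
        residues.append(residue)
        rows.append([int(t) for t in int_tokens[offset : offset + 20]])
    if not rows:
        raise ValueError(f"PSSM file {path} contains no score rows")

    import numpy as np

    scores = np.asarray(rows, dtype=int)
    # Reorder file columns into the canonical order.
    perm = [block_letters.index(aa) for aa in AA_ORDER]
    scores = scores[:, perm]
    return PssmProfile(
        id=profile_id if profile_id is not None else path.stem,
        residues="".join(residues),
        scores=scores,
    )


def write_pssm(profile: PssmProfile, path) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect ``read_pssm`` accepts.

    The percentage block is filled with zeros; only the log-odds block is
    meaningful for synthetic profiles.
    """
    path = Path(path)
    letters = "  ".join(AA_ORDER)
    with path.open("w") as out:
        out.write("\n")
        out.write("Last position-specific scoring matrix computed\n")
        out.write(f"            {letters}   {letters}\n")
        for i, (residue, row) in enumerate(zip(profile.residues, profile.scores), start=1):
            scores = " ".join(f"{int(v):4d}" for v in row)
            zeros = " ".join("   0" for _ in range(20))
            out.write(f"{i:5d} {residue} {scores}  {zeros}  0.00 0.00\n")
        out.write("\n")


def load_profiles(
    sequences: list[ProteinSequence], pssm_dir, strict_residues: bool = True
) -> tuple[list[PssmProfile], list[str]]:
    """Pair filtered sequences with their PSSM files by basename.

    Returns (profiles, skipped_ids).  A missing PSSM file is treated like an
    upstream profile-search failure: the sequence is skipped with a logged
    warning.  A residue-string mismatch between FASTA and PSSM is an error
    (neither source is silently trusted over the other).
    """
    pssm_dir = Path(pssm_dir)
    profiles, skipped = [], []
    for seq in sequences:
        pssm_path = pssm_dir / f"{seq.id}.pssm"
        if not pssm_path.exists():
            logger.warning("no PSSM for sequence %s; excluded from the data set", seq.id)
            skipped.append(seq.id)
            continue
        profile = read_pssm(pssm_path, profile_id=seq.id)
        if strict_residues and profile.residues != seq.residues:
            raise ValueError(
                f"sequence {seq.id!r}: FASTA residues disagree with the PSSM rows"
            )
        profiles.append(profile)
    return profiles, skipped


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, path) -> None:
    """Serialize a feature table to CSV (sample_id, label, synthetic, features)."""
    if table.n_samples == 0:
        raise ValueError("refusing to write an empty feature table")
    table.to_frame().to_csv(path, index=False)


def read_feature_table(path) -> FeatureTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    frame = pd.read_csv(path)
    return FeatureTable.from_frame(frame)


def psiblast_command(settings: PssmGenerationSettings | None = None) -> str:
    """The documented PSI-BLAST invocation used to produce input PSSMs.

    The profile search itself is out of scope here (it needs the external
    sequence database); this template records how the expected inputs are made.
    """
    return (settings or PssmGenerationSettings()).command_template()
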