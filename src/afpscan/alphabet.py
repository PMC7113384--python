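"""Canonical amino-acid ordering and the 400-dimensional substitution-feature index.

The column order is the one PSI-BLAST prints in its ASCII PSSM output:
A R N D C Q E G H I L K M F P S T W Y V.  Every feature of the evolutionary
encoding is a (query residue X, replacement residue Z) pair, laid out
row-major over that order, so feature ``20*pos(X) + pos(Z)`` is labelled
``"X-Z"``.
"""

from __future__ import annotations

AA_ORDER: str = "ARNDCQEGHILKMFPSTWYV"
"""Canonical PSI-BLAST column order of the 20 standard amino acids."""

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA_ORDER)}

AMBIGUOUS_RESIDUES: frozenset[str] = frozenset("XBUO")
"""Letters that mark a sequence as ambiguous and exclude it from encoding."""

N_AMINO_ACIDS: int = 20
N_FEATURES: int = N_AMINO_ACIDS * N_AMINO_ACIDS


def feature_index(x: str, z: str) -> int:
    """Flat index (0-399) of the substitution feature X-Z.

    ``x`` is the query residue, ``z`` the replacement residue observed in
    related sequences.  Raises ``ValueError`` for non-standard letters.
    """
    try:
        return N_AMINO_ACIDS * AA_INDEX[x.upper()] + AA_INDEX[z.upper()]
    except KeyError as exc:
        raise ValueError(f"not a standard amino acid: {exc.args[0]!r}") from None


def feature_label(index: int) -> str:
    """Human-readable "X-Z" label of a flat feature index."""
    if not 0 <= index < N_FEATURES:
        raise ValueError(f"feature index out of range [0, {N_FEATURES}): {index}")
    return f"{AA_ORDER[index // N_AMINO_ACIDS]}-{AA_ORDER[index % N_AMINO_ACIDS]}"


FEATURE_NAMES: list[str] = [f"{x}-{z}" for x in AA_ORDER for z in AA_ORDER]
"""All 400 feature labels in flat-index order."""
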