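"""Small shared sequence utilities and alphabets."""

from __future__ import annotations

import numpy as np

PROTEIN_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET = frozenset(PROTEIN_LETTERS) | {"X", "*"}
DNA_LETTERS = "ACGT"
DNA_ALPHABET = frozenset(DNA_LETTERS) | {"N"}
GAP = "-"

AA_INDEX = {aa: i for i, aa in enumerate(PROTEIN_LETTERS)}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_aa_indices(seq: str) -> np.ndarray:
    """Map a protein string to indices into the 20-letter alphabet.

    Residues outside the canonical 20 (X, *) map to -1 and are ignored
    by downstream scoring.
    """
    return np.array([AA_INDEX.get(c, -1) for c in seq], dtype=np.int64)


def validate_alphabet(seq: str, alphabet: str, *, allow_gap: bool = True) -> list[tuple[int, str]]:
    """Return (1-based position, character) for every out-of-alphabet character."""
    allowed = PROTEIN_ALPHABET if alphabet == "protein" else DNA_ALPHABET
    if allow_gap:
        allowed = allowed | {GAP}
    return [(i + 1, c) for i, c in enumerate(seq) if c not in allowed]
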