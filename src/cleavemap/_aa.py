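"""Amino-acid alphabet, subsite labels and small numeric helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np

#: The 20 canonical amino acids, alphabetical by one-letter code.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Residues that occur in database entries but are not canonical
#: (ambiguity codes and the rare translated residues).
NON_CANONICAL: frozenset[str] = frozenset("BZXUO")

#: Padding character used when a subsite falls outside the protein.
PAD: str = "-"


def subsite_labels(upstream: int = 6, downstream: int = 5) -> list[str]:
    """Schechter–Berger subsite labels, N- to C-terminal.

    ``upstream`` non-prime subsites (P<upstream>..P1) followed by
    ``downstream`` prime subsites (P1'..P<downstream>').  The enzyme cleaves
    the bond between P1 and P1'.
    """
    return [f"P{i}" for i in range(upstream, 0, -1)] + [
        f"P{i}'" for i in range(1, downstream + 1)
    ]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of printed percentage
    tables), unlike banker's rounding used by the builtin."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def validate_composition(composition: dict[str, float], tol: float = 1e-9) -> np.ndarray:
    """Check a residue→frequency map and return it as a vector over
    :data:`AMINO_ACIDS`.

    Raises ``ValueError`` on unknown residues, negative entries, or a total
    differing from 1 by more than ``tol``.
    """
    vec = np.zeros(len(AMINO_ACIDS))
    for res, freq in composition.items():
        if res not in AA_INDEX:
            raise ValueError(f"unknown residue in composition: {res!r}")
        if freq < 0:
            raise ValueError(f"negative frequency for residue {res}: {freq}")
        vec[AA_INDEX[res]] = freq
    total = float(vec.sum())
    if abs(total - 1.0) > tol:
        raise ValueError(f"composition frequencies sum to {total}, expected 1")
    return vec


def is_canonical(sequence: str) -> bool:
    """True if every residue is one of the 20 canonical amino acids."""
    return all(res in AA_INDEX for res in sequence)
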