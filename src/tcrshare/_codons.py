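"""Standard genetic code helpers shared by the recombination model.

The codon table itself comes from Biopython-independent hardcoding of the
standard nuclear code is deliberately avoided: the table is derived once from
``Bio.Data.CodonTable`` so the package cannot drift from the standard code.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
NT_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}

_STANDARD = CodonTable.unambiguous_dna_by_name["Standard"]

#: codon (string over ACGT) -> single-letter amino acid, '*' for stop
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = "*"

#: amino acid letter (incl. '*') -> tuple of codons encoding it
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] = AA_TO_CODONS[_aa] + (_codon,)

AMINO_ACIDS = "".join(sorted(set(CODON_TO_AA.values()) - {"*"}))


def translate(nt: str) -> str:
    """Translate an in-frame nucleotide string (length divisible by 3)."""
    if len(nt) % 3 != 0:
        raise ValueError(f"sequence length {len(nt)} is not a multiple of 3")
    return "".join(CODON_TO_AA[nt[i : i + 3]] for i in range(0, len(nt), 3))


@lru_cache(maxsize=1)
def codon_index_to_aa_code() -> np.ndarray:
    """uint8 array of length 64: codon index (16a+4b+c, ACGT=0..3) -> aa byte."""
    out = np.zeros(64, dtype=np.uint8)
    for codon, aa in CODON_TO_AA.items():
        idx = 16 * NT_INDEX[codon[0]] + 4 * NT_INDEX[codon[1]] + NT_INDEX[codon[2]]
        out[idx] = ord(aa)
    return out


@lru_cache(maxsize=1)
def aa_codon_arrays() -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    """Flat integer codon table for the numba p_gen kernel.

    Returns ``(codons_flat, offsets, aa_index)`` where codons for amino acid
    with index ``a`` are rows ``codons_flat[offsets[a]:offsets[a+1]]`` (each a
    length-3 int8 row over ACGT=0..3).
    """
    letters = AMINO_ACIDS + "*"
    aa_index = {aa: i for i, aa in enumerate(letters)}
    rows: list[list[int]] = []
    offsets = [0]
    for aa in letters:
        for codon in AA_TO_CODONS[aa]:
            rows.append([NT_INDEX[c] for c in codon])
        offsets.append(len(rows))
    return (
        np.asarray(rows, dtype=np.int8),
        np.asarray(offsets, dtype=np.int64),
        aa_index,
    )
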