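"""Standard genetic code helpers and the Kyte-Doolittle hydropathy scale.

Plant mitochondria use the standard code, so it is fixed here.
"""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]

CODONS = [a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"]

AA = {}
for _c in CODONS:
    AA[_c] = "*" if _c in _TABLE.stop_codons else _TABLE.forward_table[_c]


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon; '*' for stops, 'X' if ambiguous."""
    codon = codon.upper().replace("U", "T")
    return AA.get(codon, "X")


def is_synonymous(codon_a: str, codon_b: str) -> bool:
    return translate_codon(codon_a) == translate_codon(codon_b)


# Kyte & Doolittle hydropathy (dimensionless; positive = hydrophobic)
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def hydropathy(aa: str) -> float | None:
    return KYTE_DOOLITTLE.get(aa)
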