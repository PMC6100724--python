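"""Codon usage tables and deterministic reverse translation.

Reverse translation for oligo design is deterministic: each amino acid is
encoded by the single most frequent codon in the E. coli K-12 usage table
below.  The full ranked synonym list is kept so that a codon can be swapped
for its next-ranked synonym when a restriction-site motif must be removed
from an insert.
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

# Relative synonymous codon usage fractions for E. coli K-12 (per amino
# acid, fractions within each synonym family).  Values are the commonly
# tabulated K-12 figures rounded to two decimals; only the ranking matters
# for design output.
ECOLI_K12_USAGE: dict[str, dict[str, float]] = {
    "A": {"GCG": 0.33, "GCC": 0.26, "GCA": 0.23, "GCT": 0.18},
    "R": {"CGC": 0.40, "CGT": 0.38, "CGG": 0.10, "CGA": 0.06, "AGA": 0.04, "AGG": 0.02},
    "N": {"AAC": 0.51, "AAT": 0.49},
    "D": {"GAT": 0.63, "GAC": 0.37},
    "C": {"TGC": 0.54, "TGT": 0.46},
    "Q": {"CAG": 0.66, "CAA": 0.34},
    "E": {"GAA": 0.68, "GAG": 0.32},
    "G": {"GGC": 0.37, "GGT": 0.35, "GGG": 0.15, "GGA": 0.11},
    "H": {"CAT": 0.57, "CAC": 0.43},
    "I": {"ATT": 0.49, "ATC": 0.39, "ATA": 0.11},
    "L": {"CTG": 0.47, "TTA": 0.14, "TTG": 0.13, "CTT": 0.12, "CTC": 0.10, "CTA": 0.04},
    "K": {"AAA": 0.74, "AAG": 0.26},
    "M": {"ATG": 1.00},
    "F": {"TTT": 0.58, "TTC": 0.42},
    "P": {"CCG": 0.49, "CCA": 0.20, "CCT": 0.18, "CCC": 0.13},
    "S": {"AGC": 0.25, "TCT": 0.17, "AGT": 0.16, "TCC": 0.15, "TCA": 0.14, "TCG": 0.14},
    "T": {"ACC": 0.40, "ACG": 0.25, "ACT": 0.19, "ACA": 0.17},
    "W": {"TGG": 1.00},
    "Y": {"TAT": 0.59, "TAC": 0.41},
    "V": {"GTG": 0.35, "GTT": 0.28, "GTC": 0.20, "GTA": 0.17},
}

#: ranked synonymous codons per amino acid, most frequent first
RANKED_CODONS: dict[str, list[str]] = {
    aa: sorted(usage, key=lambda c: (-usage[c], c)) for aa, usage in ECOLI_K12_USAGE.items()
}

#: one codon per amino acid — the design default
TOP_CODON: dict[str, str] = {aa: ranked[0] for aa, ranked in RANKED_CODONS.items()}

AMINO_ACIDS = frozenset(ECOLI_K12_USAGE)


def reverse_translate(aa_seq: str, codon_table: dict[str, str] | None = None) -> str:
    """Encode a peptide as DNA using one fixed codon per residue.

    Raises ``KeyError`` naming the residue if it is absent from the table
    (e.g. X or a stop).
    """
    table = TOP_CODON if codon_table is None else codon_table
    try:
        return "".join(table[aa] for aa in aa_seq)
    except KeyError as exc:
        raise KeyError(f"no codon configured for residue {exc.args[0]!r}") from None


def translate(nt_seq: str) -> str:
    """Translate DNA with the standard genetic code; stops become ``*``.

    Codons containing N or other ambiguity codes raise ``ValueError``.
    """
    if len(nt_seq) % 3 != 0:
        raise ValueError(f"length {len(nt_seq)} not a multiple of 3")
    fwd = standard_dna_table.forward_table
    out = []
    for i in range(0, len(nt_seq), 3):
        codon = nt_seq[i : i + 3].upper()
        if codon in standard_dna_table.stop_codons:
            out.append("*")
        elif codon in fwd:
            out.append(fwd[codon])
        else:
            raise ValueError(f"untranslatable codon {codon!r} at nt {i}")
    return "".join(out)


def translates_to(nt_seq: str, aa_seq: str) -> bool:
    """True iff ``nt_seq`` translates exactly to ``aa_seq`` (no ambiguity)."""
    try:
        return translate(nt_seq) == aa_seq
    except ValueError:
        return False


def reverse_complement(nt_seq: str) -> str:
    return str(Seq(nt_seq).reverse_complement())
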