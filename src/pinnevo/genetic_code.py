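"""Universal genetic code tables used throughout the package.

The codon state space is the 61 sense codons of the standard (universal)
code, in lexicographic order over the ACGT alphabet; every array in this
package assumes that ordering.  Stop codons (TAA, TAG, TGA) are excluded
from the state space; they may only appear as the final codon of an
unaligned CDS.
"""

from __future__ import annotations

import itertools

import numpy as np

NUCLEOTIDES = "ACGT"

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in _CODON_TABLE.items() if aa == "*")

#: the 61 sense codons in lexicographic (ACGT) order
SENSE_CODONS = tuple(
    "".join(c)
    for c in itertools.product(NUCLEOTIDES, repeat=3)
    if "".join(c) not in STOP_CODONS
)
N_CODONS = len(SENSE_CODONS)  # 61

CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

#: amino acid (one-letter) encoded by each sense codon, aligned with SENSE_CODONS
CODON_AA = tuple(_CODON_TABLE[c] for c in SENSE_CODONS)

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"  # PAML ordering, used by the JTT tables
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: amino-acid index (into AMINO_ACIDS) of each sense codon
CODON_AA_INDEX = np.array([AA_INDEX[a] for a in CODON_AA], dtype=np.intp)

# transitions are A<->G and C<->T
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def is_transition(n1: str, n2: str) -> bool:
    """True if the unordered nucleotide pair (n1, n2) is a transition."""
    return ({n1, n2} <= _PURINES) or ({n1, n2} <= _PYRIMIDINES)


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon; '*' for stop, 'X' if ambiguous.

    A codon containing '-' in all three positions translates to '-';
    any other gap/N content translates to 'X'.
    """
    codon = codon.upper()
    if codon == "---":
        return "-"
    aa = _CODON_TABLE.get(codon)
    return aa if aa is not None else "X"


def translate(seq: str) -> str:
    """Translate an in-frame nucleotide string codon by codon."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    return "".join(translate_codon(seq[i : i + 3]) for i in range(0, len(seq), 3))


def codons_of(seq: str) -> list[str]:
    """Split an in-frame nucleotide string into codons."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def synonymous_codons(aa: str) -> list[str]:
    """Sense codons encoding ``aa``, in lexicographic order."""
    return [c for c, a in zip(SENSE_CODONS, CODON_AA) if a == aa]
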