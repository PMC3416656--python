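"""Standard genetic code tables on the RNA alphabet.

All codon bookkeeping in this package uses RNA codons (U, not T), since
codon-usage tables in this field are conventionally printed with U-ended
codons. The 59 "informative" codons are those of amino acids with two or
more synonymous codons: Met (AUG), Trp (UGG) and the three stop codons
carry no synonymous-choice information and are excluded from RSCU, Nc and
third-position composition statistics.
"""

from __future__ import annotations

from Bio.Data import CodonTable

RNA_BASES = ("A", "C", "G", "U")

_standard = CodonTable.unambiguous_rna_by_id[1]

#: codon -> one-letter amino acid, sense codons only
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_standard.stop_codons)

ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in RNA_BASES for b in RNA_BASES for c in RNA_BASES
)

SENSE_CODONS: tuple[str, ...] = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

#: one-letter amino acid -> sorted tuple of its synonymous codons
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] = AA_TO_CODONS[_aa] + (_codon,)

#: degeneracy (family size) per amino acid
DEGENERACY: dict[str, int] = {aa: len(cods) for aa, cods in AA_TO_CODONS.items()}

#: amino acids with >= 2 synonymous codons (excludes Met and Trp)
SYNONYMOUS_AA: tuple[str, ...] = tuple(
    sorted(aa for aa, k in DEGENERACY.items() if k >= 2)
)

#: the 59 codons of multi-codon families, in (amino acid, codon) sort order
INFORMATIVE_CODONS: tuple[str, ...] = tuple(
    codon for aa in SYNONYMOUS_AA for codon in AA_TO_CODONS[aa]
)

#: degeneracy class -> amino acids in it (2-, 3-, 4- and 6-fold classes)
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {}
for _aa in SYNONYMOUS_AA:
    _k = DEGENERACY[_aa]
    DEGENERACY_CLASSES.setdefault(_k, ())
    DEGENERACY_CLASSES[_k] = DEGENERACY_CLASSES[_k] + (_aa,)

AA_THREE_TO_ONE: dict[str, str] = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
AA_ONE_TO_THREE: dict[str, str] = {v: k for k, v in AA_THREE_TO_ONE.items()}

assert len(INFORMATIVE_CODONS) == 59
assert sorted(DEGENERACY_CLASSES) == [2, 3, 4, 6]


def rna(seq: str) -> str:
    """Normalize a nucleotide string to upper-case RNA (T -> U)."""
    return seq.upper().replace("T", "U")


def dna(seq: str) -> str:
    """Convert an RNA string back to DNA (U -> T) for output writers."""
    return seq.upper().replace("U", "T")
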