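"""Standard bacterial/archaeal genetic code (NCBI translation table 11).

All indices in this package operate on the 61 sense codons of this table
(stops TAA/TAG/TGA; single-codon families ATG=Met and TGG=Trp). The codon
assignments are taken from Biopython's codon tables rather than hard-coded.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[11]

BASES = "ACGT"

#: stop codons of the bacterial code
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: codon -> one-letter amino acid, for the 61 sense codons
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

#: the 61 sense codons in lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: amino acid -> tuple of synonymous codons (lexicographic)
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    FAMILIES.setdefault(_aa, ())
FAMILIES = {
    aa: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa) for aa in FAMILIES
}

#: codon -> family size (degeneracy n_i)
DEGENERACY: dict[str, int] = {
    c: len(FAMILIES[CODON_TO_AA[c]]) for c in SENSE_CODONS
}

#: family sizes represented in the code and the number of families per size,
#: used by Wright's effective-number-of-codons estimator.
#: size 1: Met, Trp; size 2: nine families; size 3: Ile; size 4: five; size 6: three.
FAMILIES_BY_SIZE: dict[int, tuple[str, ...]] = {}
for _aa, _codons in FAMILIES.items():
    FAMILIES_BY_SIZE.setdefault(len(_codons), ())
FAMILIES_BY_SIZE = {
    k: tuple(aa for aa, cs in sorted(FAMILIES.items()) if len(cs) == k)
    for k in sorted(FAMILIES_BY_SIZE)
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def anticodon_for(codon: str) -> str:
    """The exact Watson-Crick anticodon read 5'->3' that decodes `codon`."""
    return reverse_complement(codon)


SINGLE_CODON_AAS: frozenset[str] = frozenset(
    aa for aa, cs in FAMILIES.items() if len(cs) == 1
)
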