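"""Canonical mitochondrial gene nomenclature and the invertebrate mitochondrial code.

The 37-gene animal mitochondrial complement: 13 protein-coding genes (PCGs),
22 tRNAs and 2 rRNAs.  tRNA-Leu and tRNA-Ser each occur twice and are split
into isotypes by anticodon: trnL1 reads CUN codons (anticodon UAG), trnL2
reads UUR (anticodon UAA); trnS1 reads AGN (anticodon GCU/UCU in insects),
trnS2 reads UCN (anticodon UGA).

Translation is fixed to NCBI table 5 (invertebrate mitochondrial), under
which ATA codes Met, TGA codes Trp and AGA/AGG code Ser, leaving 62 sense
codons and the two stops TAA/TAG.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

PCG_NAMES = (
    "atp6", "atp8", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
)

TRNA_NAMES = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
    "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
    "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
)

RRNA_NAMES = ("rrnS", "rrnL")

CANONICAL_GENES = PCG_NAMES + TRNA_NAMES + RRNA_NAMES
CONTROL_REGION = "control_region"

AMINO_ACID_ONE_TO_THREE = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe",
    "G": "Gly", "H": "His", "I": "Ile", "K": "Lys", "L": "Leu",
    "M": "Met", "N": "Asn", "P": "Pro", "Q": "Gln", "R": "Arg",
    "S": "Ser", "T": "Thr", "V": "Val", "W": "Trp", "Y": "Tyr",
}
AMINO_ACID_THREE_TO_ONE = {v: k for k, v in AMINO_ACID_ONE_TO_THREE.items()}


def gene_category(name: str) -> str:
    """Return the feature category for a canonical gene id."""
    if name in PCG_NAMES:
        return "PCG"
    if name in TRNA_NAMES:
        return "tRNA"
    if name in RRNA_NAMES:
        return "rRNA"
    if name == CONTROL_REGION:
        return "control_region"
    raise ValueError(f"not a canonical gene id: {name!r}")


# --- gene-name synonym table -------------------------------------------------
# Keys are uppercased, stripped of whitespace/punctuation variants at lookup
# time.  Leu/Ser tRNAs are only resolvable here when the label itself carries
# the isotype; otherwise the anticodon decides (see normalize below).

_PCG_SYNONYMS = {
    "ATP6": "atp6", "ATPASE6": "atp6", "ATPASESUBUNIT6": "atp6",
    "ATPSYNTHASEF0SUBUNIT6": "atp6", "ATPSYNTHASESUBUNIT6": "atp6",
    "ATP8": "atp8", "ATPASE8": "atp8", "ATPASESUBUNIT8": "atp8",
    "ATPSYNTHASEF0SUBUNIT8": "atp8", "ATPSYNTHASESUBUNIT8": "atp8",
    "COB": "cob", "CYTB": "cob", "CYB": "cob", "CYTOCHROMEB": "cob",
    "CYTOCHROMEBAPOENZYME": "cob",
    "COX1": "cox1", "COI": "cox1", "CO1": "cox1", "COXI": "cox1",
    "CYTOCHROMECOXIDASESUBUNIT1": "cox1", "CYTOCHROMECOXIDASESUBUNITI": "cox1",
    "COX2": "cox2", "COII": "cox2", "CO2": "cox2", "COXII": "cox2",
    "CYTOCHROMECOXIDASESUBUNIT2": "cox2", "CYTOCHROMECOXIDASESUBUNITII": "cox2",
    "COX3": "cox3", "COIII": "cox3", "CO3": "cox3", "COXIII": "cox3",
    "CYTOCHROMECOXIDASESUBUNIT3": "cox3",
    "CYTOCHROMECOXIDASESUBUNITIII": "cox3",
}
for _i in (1, 2, 3, 4, 5, 6):
    _PCG_SYNONYMS[f"NAD{_i}"] = f"nad{_i}"
    _PCG_SYNONYMS[f"ND{_i}"] = f"nad{_i}"
    _PCG_SYNONYMS[f"NADH{_i}"] = f"nad{_i}"
    _PCG_SYNONYMS[f"NADHDEHYDROGENASESUBUNIT{_i}"] = f"nad{_i}"
_PCG_SYNONYMS.update({
    "NAD4L": "nad4l", "ND4L": "nad4l", "NADHDEHYDROGENASESUBUNIT4L": "nad4l",
})

_RRNA_SYNONYMS = {
    "RRNS": "rrnS", "12S": "rrnS", "12SRRNA": "rrnS", "12SRIBOSOMALRNA": "rrnS",
    "SRRNA": "rrnS", "SSU": "rrnS", "SMALLSUBUNITRIBOSOMALRNA": "rrnS",
    "RRNSMALL": "rrnS", "MTSSU": "rrnS",
    "RRNL": "rrnL", "16S": "rrnL", "16SRRNA": "rrnL", "16SRIBOSOMALRNA": "rrnL",
    "LRRNA": "rrnL", "LSU": "rrnL", "LARGESUBUNITRIBOSOMALRNA": "rrnL",
    "RRNLARGE": "rrnL", "MTLSU": "rrnL",
}

_CR_SYNONYMS = {
    "CONTROLREGION": CONTROL_REGION, "CR": CONTROL_REGION,
    "DLOOP": CONTROL_REGION, "ATRICHREGION": CONTROL_REGION,
    "ATRICH": CONTROL_REGION, "PUTATIVECONTROLREGION": CONTROL_REGION,
}

# tRNA amino-acid letter -> canonical id (unambiguous isotypes only)
_TRNA_BY_AA = {
    "A": "trnA", "C": "trnC", "D": "trnD", "E": "trnE", "F": "trnF",
    "G": "trnG", "H": "trnH", "I": "trnI", "K": "trnK", "M": "trnM",
    "N": "trnN", "P": "trnP", "Q": "trnQ", "R": "trnR", "T": "trnT",
    "V": "trnV", "W": "trnW", "Y": "trnY",
}

# Anticodon (RNA or DNA alphabet, 5'->3') -> isotype for the duplicated tRNAs.
# trnL1 serves CUN codons, trnL2 serves UUR; trnS1 serves AGN, trnS2 UCN.
LEU_SER_ANTICODONS = {
    "UAG": "trnL1", "UAA": "trnL2",
    "GCU": "trnS1", "UCU": "trnS1", "GCT": "trnS1", "TCT": "trnS1",
    "UGA": "trnS2",
    "TAG": "trnL1", "TAA": "trnL2", "TGA": "trnS2",
}


# --- invertebrate mitochondrial genetic code (NCBI table 5) ------------------

_BASES = "TCAG"


@lru_cache(maxsize=None)
def codon_table5():
    """Biopython CodonTable for NCBI translation table 5."""
    return CodonTable.unambiguous_dna_by_id[5]


@lru_cache(maxsize=None)
def sense_codons() -> tuple[str, ...]:
    """The 62 sense codons of table 5, in TCAG order."""
    stops = set(codon_table5().stop_codons)
    return tuple(
        a + b + c
        for a in _BASES for b in _BASES for c in _BASES
        if a + b + c not in stops
    )


@lru_cache(maxsize=None)
def stop_codons() -> frozenset[str]:
    return frozenset(codon_table5().stop_codons)


@lru_cache(maxsize=None)
def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon; '*' for a stop."""
    codon = codon.upper().replace("U", "T")
    if codon in stop_codons():
        return "*"
    return codon_table5().forward_table[codon]


@lru_cache(maxsize=None)
def synonymous_families() -> dict[str, tuple[str, ...]]:
    """Amino acid -> tuple of its sense codons under table 5.

    Family sizes: twelve 2-fold, six 4-fold, Leu 6-fold, Ser 8-fold.
    """
    fam: dict[str, list[str]] = {}
    for codon in sense_codons():
        fam.setdefault(translate_codon(codon), []).append(codon)
    return {aa: tuple(codons) for aa, codons in sorted(fam.items())}


@lru_cache(maxsize=None)
def family_of(codon: str) -> tuple[str, ...]:
    """Synonymous family (tuple of codons) a sense codon belongs to."""
    return synonymous_families()[translate_codon(codon)]


# --- ancestral insect mitochondrial gene order -------------------------------
# The pancrustacean ground pattern (as in Drosophila yakuba), majority-strand
# orientation, listed from trnI.  Includes the tRNA clusters trnI-trnQ-trnM
# and trnW-trnC-trnY.  Strand +1 = majority strand.

ANCESTRAL_INSECT_ORDER: tuple[tuple[str, int], ...] = (
    ("trnI", +1), ("trnQ", -1), ("trnM", +1), ("nad2", +1),
    ("trnW", +1), ("trnC", -1), ("trnY", -1),
    ("cox1", +1), ("trnL2", +1), ("cox2", +1), ("trnK", +1), ("trnD", +1),
    ("atp8", +1), ("atp6", +1), ("cox3", +1), ("trnG", +1), ("nad3", +1),
    ("trnA", +1), ("trnR", +1), ("trnN", +1), ("trnS1", +1), ("trnE", +1),
    ("trnF", -1), ("nad5", -1), ("trnH", -1), ("nad4", -1), ("nad4l", -1),
    ("trnT", +1), ("trnP", -1), ("nad6", +1), ("cob", +1), ("trnS2", +1),
    ("nad1", -1), ("trnL1", -1), ("rrnL", -1), ("trnV", -1), ("rrnS", -1),
)

assert len(ANCESTRAL_INSECT_ORDER) == 37
assert {g for g, _ in ANCESTRAL_INSECT_ORDER} == set(CANONICAL_GENES)
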