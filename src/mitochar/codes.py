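"""Vertebrate mitochondrial genetic code (NCBI transl_table 2) helpers.

Under this code AGA/AGG are stop codons, ATA encodes Met and TGA encodes
Trp, so there are 60 sense codons and 4 stops.  Leu and Ser are each
6-fold degenerate families that span two codon boxes; family membership
here always follows amino-acid identity.
"""
from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

MITO_TABLE = unambiguous_dna_by_id[2]

STOP_CODONS: frozenset[str] = frozenset(MITO_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(MITO_TABLE.forward_table))
ALL_CODONS: tuple[str, ...] = tuple(sorted(set(SENSE_CODONS) | STOP_CODONS))

NUCLEOTIDES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "-": "-"}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

# canonical protein-coding gene names in vertebrate mitogenome order
PCG_NAMES = (
    "ND1", "ND2", "COX1", "COX2", "ATP8", "ATP6", "COX3",
    "ND3", "ND4L", "ND4", "ND5", "ND6", "CYTB",
)

_GENE_ALIASES = {
    "COI": "COX1", "COXI": "COX1", "CO1": "COX1",
    "COII": "COX2", "COXII": "COX2", "CO2": "COX2",
    "COIII": "COX3", "COXIII": "COX3", "CO3": "COX3",
    "COB": "CYTB", "CYB": "CYTB", "CYT B": "CYTB",
    "ATPASE6": "ATP6", "ATPASE8": "ATP8",
    "NAD1": "ND1", "NAD2": "ND2", "NAD3": "ND3", "NAD4": "ND4",
    "NAD4L": "ND4L", "NAD5": "ND5", "NAD6": "ND6",
}


def normalize_gene_name(name: str) -> str:
    """Map common protein-coding gene aliases (COI, cob, ...) onto canonical names."""
    key = name.strip().upper().replace("-", "").replace("_", "")
    return _GENE_ALIASES.get(key, name.strip().upper() if key in PCG_NAMES else name.strip())


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def translate_codon(codon: str) -> str:
    """Amino acid (1-letter) for a codon; '*' for a stop.  Raises on ambiguity."""
    codon = codon.upper()
    if codon in STOP_CODONS:
        return "*"
    try:
        return MITO_TABLE.forward_table[codon]
    except KeyError:
        raise ValueError(f"cannot translate codon {codon!r} under the vertebrate mito code")


def is_stop(codon: str) -> bool:
    return codon.upper() in STOP_CODONS


def is_transition(a: str, b: str) -> bool:
    return _TRANSITION.get(a.upper()) == b.upper()


def _build_families() -> dict[str, tuple[str, ...]]:
    fams: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        fams.setdefault(translate_codon(codon), []).append(codon)
    return {aa: tuple(sorted(cods)) for aa, cods in fams.items()}


AA_FAMILIES: dict[str, tuple[str, ...]] = _build_families()
FAMILY_OF: dict[str, tuple[str, ...]] = {
    codon: AA_FAMILIES[translate_codon(codon)] for codon in ALL_CODONS
}
FAMILY_SIZE: dict[str, int] = {codon: len(fam) for codon, fam in FAMILY_OF.items()}
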