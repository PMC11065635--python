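"""Standard genetic-code constants shared across the package.

The 61 sense codons and 3 stop codons come from the standard (NCBI table 1)
genetic code via Biopython; codon order is fixed (lexicographic) so that
usage vectors from different runs align positionally.
"""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import reverse_complement

_TABLE = unambiguous_dna_by_id[1]

STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.stop_codons))
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

assert len(SENSE_CODONS) == 61 and len(STOP_CODONS) == 3

SENSE_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: three-letter amino-acid codes used in gtRNAdb-style tRNA gene names
AA_THREE = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}
CODON_TO_AA3: dict[str, str] = {c: AA_THREE[a] for c, a in CODON_TO_AA.items()}


def anticodon_to_codon(anticodon: str) -> str:
    """Watson-Crick cognate codon of an anticodon: its reverse complement.

    This is the only codon/anticodon pairing the package ever infers; wobble
    and near-cognate decoding are deliberately out of scope.

    >>> anticodon_to_codon("TAT")
    'ATA'
    >>> anticodon_to_codon("TCT")
    'AGA'
    """
    anticodon = anticodon.upper()
    if len(anticodon) != 3 or any(b not in "ACGT" for b in anticodon):
        raise ValueError(f"anticodon must be a 3-mer over ACGT, got {anticodon!r}")
    return reverse_complement(anticodon)


def codon_to_anticodon(codon: str) -> str:
    """Inverse of :func:`anticodon_to_codon` (reverse complement again)."""
    return anticodon_to_codon(codon)
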