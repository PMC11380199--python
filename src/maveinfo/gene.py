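"""Total possible missense information of a gene.

Each possible missense variant is a binary pathogenic/benign question and
so carries one bit of classification information; the total missense
information of a gene, in bits, is therefore the number of distinct
single-nucleotide missense substitutions its coding sequence admits.  The
total serves as the finish line against which a MAVE's information yield
can be expressed as a percentage.

Every sense codon admits exactly 9 single-base substitutions (3 positions
x 3 alternative bases), each of which is missense, nonsense or
synonymous.  When only the protein sequence is available the per-residue
missense count is averaged over the codons encoding that amino acid
("codon-averaged" mode, fractional totals); given the actual coding
sequence the per-codon counts are exact ("cds" mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

from Bio.Data import CodonTable as _BioCodonTable

__all__ = [
    "CodonSubstitutionCounts",
    "GeneInfoSummary",
    "standard_codon_table",
    "codon_substitution_counts",
    "amino_acid_average_missense",
    "gene_total_missense_bits",
    "gene_total_missense_bits_from_cds",
    "percent_information",
    "CANONICAL_AMINO_ACIDS",
]

logger = logging.getLogger(__name__)

RNA_BASES = "ACGU"
STOP = "*"
CANONICAL_AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


def standard_codon_table() -> dict[str, str]:
    """The standard genetic code as RNA codon -> amino acid (stop = ``*``)."""
    table = _BioCodonTable.unambiguous_rna_by_id[1]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = STOP
    assert len(code) == 64
    return code


@dataclass(frozen=True)
class CodonSubstitutionCounts:
    """Classification of the 9 single-base substitutions of a sense codon."""

    codon: str
    missense: int
    nonsense: int
    synonymous: int

    @property
    def total(self) -> int:
        return self.missense + self.nonsense + self.synonymous


@dataclass(frozen=True)
class GeneInfoSummary:
    """Total possible missense information of one protein/gene.

    ``total_missense_bits`` may be fractional under codon averaging; the
    nearest integer is exposed separately for display alongside printed
    gene totals.
    """

    gene: str
    length_aa: int
    total_missense_bits: float
    per_residue: tuple[float, ...]
    mode: str = "codon_averaged"

    @property
    def display_bits(self) -> int:
        return round(self.total_missense_bits)

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "length_aa": self.length_aa,
            "total_missense_bits": self.total_missense_bits,
            "display_bits": self.display_bits,
            "mode": self.mode,
        }


def _normalise_codon(codon: str) -> str:
    codon = codon.strip().upper().replace("T", "U")
    if len(codon) != 3 or any(base not in RNA_BASES for base in codon):
        raise ValueError(f"invalid codon {codon!r}")
    return codon


def codon_substitution_counts(
    codon: str, table: dict[str, str] | None = None
) -> CodonSubstitutionCounts:
    """Count missense/nonsense/synonymous single-base changes of a codon.

    DNA spelling (T) is accepted and converted to RNA.  Stop codons are
    rejected: the enumeration is defined for sense codons only.

    >>> codon_substitution_counts("AUG")
    CodonSubstitutionCounts(codon='AUG', missense=9, nonsense=0, synonymous=0)
    """
    code = table if table is not None else standard_codon_table()
    codon = _normalise_codon(codon)
    aa = code[codon]
    if aa == STOP:
        raise ValueError(f"{codon} is a stop codon; substitution counts are "
                         "defined for sense codons only")
    missense = nonsense = synonymous = 0
    for pos in range(3):
        for base in RNA_BASES:
            if base == codon[pos]:
                continue
            alt_aa = code[codon[:pos] + base + codon[pos + 1:]]
            if alt_aa == STOP:
                nonsense += 1
            elif alt_aa == aa:
                synonymous += 1
            else:
                missense += 1
    return CodonSubstitutionCounts(codon, missense, nonsense, synonymous)


@lru_cache(maxsize=None)
def _average_missense_map() -> dict[str, float]:
    code = standard_codon_table()
    by_aa: dict[str, list[str]] = {}
    for codon, aa in code.items():
        if aa != STOP:
            by_aa.setdefault(aa, []).append(codon)
    return {
        aa: sum(codon_substitution_counts(c, code).missense for c in codons)
        / len(codons)
        for aa, codons in by_aa.items()
    }


def amino_acid_average_missense(
    aa: str, table: dict[str, str] | None = None
) -> float:
    """Mean missense count over all codons encoding an amino acid.

    Single-codon amino acids return their codon's count exactly (Met 9.0,
    Trp 7.0).  Non-canonical symbols (X, B, Z, U, O, ...) raise
    ``ValueError``.
    """
    aa = aa.strip().upper()
    if aa not in CANONICAL_AMINO_ACIDS:
        raise ValueError(f"non-canonical amino acid {aa!r}")
    if table is None:
        return _average_missense_map()[aa]
    code = table
    codons = [c for c, a in code.items() if a == aa]
    if not codons:
        raise ValueError(f"no codons encode {aa!r} in the supplied table")
    return sum(codon_substitution_counts(c, code).missense for c in codons) / len(
        codons
    )


def _clean_protein(seq: str, on_noncanonical: str) -> str:
    seq = "".join(seq.split()).upper().rstrip(STOP)
    if on_noncanonical not in ("error", "skip"):
        raise ValueError("on_noncanonical must be 'error' or 'skip'")
    bad = [a for a in seq if a not in CANONICAL_AMINO_ACIDS]
    if bad:
        if on_noncanonical == "error":
            raise ValueError(
                f"non-canonical amino acid(s) {sorted(set(bad))} in sequence; "
                "pass on_noncanonical='skip' to drop them"
            )
        logger.warning(
            "skipping %d non-canonical residue(s): %s", len(bad), sorted(set(bad))
        )
        seq = "".join(a for a in seq if a in CANONICAL_AMINO_ACIDS)
    return seq


def gene_total_missense_bits(
    protein_seq: str,
    gene: str = "",
    table: dict[str, str] | None = None,
    on_noncanonical: str = "error",
) -> GeneInfoSummary:
    """Codon-averaged total missense information of a protein sequence.

    Sums, over residues, the mean number of single-nucleotide missense
    substitutions of the codons encoding each amino acid.  The initiator
    methionine is included.  Stop-gained substitutions count as nonsense
    and are excluded from the missense total (truncating variants are
    conventionally assumed pathogenic and sit outside the missense
    information budget).

    >>> gene_total_missense_bits("MW").total_missense_bits
    16.0
    """
    seq = _clean_protein(protein_seq, on_noncanonical)
    if not seq:
        raise ValueError("empty protein sequence")
    if table is None:
        avg = _average_missense_map()
        per_residue = tuple(avg[a] for a in seq)
    else:
        per_residue = tuple(amino_acid_average_missense(a, table) for a in seq)
    return GeneInfoSummary(
        gene=gene,
        length_aa=len(seq),
        total_missense_bits=sum(per_residue),
        per_residue=per_residue,
        mode="codon_averaged",
    )


def gene_total_missense_bits_from_cds(
    cds: str,
    gene: str = "",
    table: dict[str, str] | None = None,
) -> GeneInfoSummary:
    """Exact total missense information from a coding nucleotide sequence.

    The CDS must be a whole number of codons; a trailing stop codon is
    allowed and ignored.  Unlike codon averaging this uses each codon's
    actual substitution counts, so totals are integers.
    """
    code = table if table is not None else standard_codon_table()
    seq = "".join(cds.split()).upper().replace("T", "U")
    if not seq:
        raise ValueError("empty coding sequence")
    if len(seq) % 3:
        raise ValueError(f"CDS length {len(seq)} is not a multiple of 3")
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    if code.get(codons[-1]) == STOP:
        codons = codons[:-1]
    per_residue = tuple(
        float(codon_substitution_counts(c, code).missense) for c in codons
    )
    return GeneInfoSummary(
        gene=gene,
        length_aa=len(codons),
        total_missense_bits=sum(per_residue),
        per_residue=per_residue,
        mode="cds",
    )


def percent_information(mave_bits: float, total_bits: float) -> float:
    """A MAVE's yield as a percentage of the gene's total missense bits.

    >>> round(percent_information(813.2, 12351), 2)
    6.58
    """
    if not total_bits > 0.0:
        raise ValueError(f"total_bits must be > 0, got {total_bits!r}")
    return 100.0 * mave_bits / total_bits
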