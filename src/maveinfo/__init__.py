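"""maveinfo: information-content scoring of clinical variant evidence.

Converts probabilities of pathogenicity to bits of classification
information, scores the total information yield of multiplexed assays of
variant effect (MAVEs), computes a gene's total possible missense
information by genetic-code enumeration, and quantifies the apparent
information effect of classification-guideline rule changes.
"""

from importlib import resources as _resources

from .calculus import (
    DEFAULT_STRENGTH_ODDS,
    EvidenceCodeError,
    EvidenceOdds,
    EvidenceOddsTable,
    combine_odds,
    entropy,
    evidence_to_odds,
    information_content,
    posterior,
)
from .gene import (
    CodonSubstitutionCounts,
    GeneInfoSummary,
    amino_acid_average_missense,
    codon_substitution_counts,
    gene_total_missense_bits,
    gene_total_missense_bits_from_cds,
    percent_information,
    standard_codon_table,
)
from .guidelines import (
    InfoChangeCurve,
    RuleChangeAudit,
    default_prior_grid,
    info_change_curve,
    plot_info_change_curves,
    rule_change_audit,
)
from .io import (
    VariantTableError,
    read_protein_fasta,
    read_variant_table,
    write_per_variant_tsv,
    write_report_json,
    write_variant_table,
)
from .scoring import (
    FunctionalClassMap,
    InfoResult,
    MaveScoreReport,
    VariantEvidenceRecord,
    fold_increase,
    mave_information_score,
    variant_info_delta,
)
from .synthetic import SyntheticMaveSpec, generate_synthetic_mave, random_protein

__version__ = "0.1.0"


def bundled_fasta(gene: str):
    """Path to a bundled reference protein FASTA (``TP53`` or ``PTEN``).

    These are the canonical UniProt sequences (P04637, P60484) shipped
    with the package so gene-total computations work offline.
    """
    names = {"TP53": "TP53_P04637.fasta", "PTEN": "PTEN_P60484.fasta"}
    key = gene.upper()
    if key not in names:
        raise KeyError(f"no bundled FASTA for {gene!r}; available: {sorted(names)}")
    return _resources.files("maveinfo.data") / names[key]


__all__ = [name for name in dir() if not name.startswith("_")]
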