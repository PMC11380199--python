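"""Per-variant information deltas and aggregate MAVE information scores.

The information yield of a multiplexed assay of variant effect (MAVE) is
the sum, over assayed variants, of the change in classification
information attributable to the assay's evidence.  For each variant the
posterior probability of pathogenicity is computed twice — once from the
prior and the pre-existing evidence codes, once with the MAVE-derived
evidence multiplied in — and the delta of information content between the
two states is the assay's contribution in bits.  Deltas can be negative:
evidence that conflicts with the prior state moves the posterior toward
0.5 and loses certainty.

Two accounting modes are supported.  *Relative* mode scores each variant
at its stated prior (default 0.1) and so measures the change against the
existing state of knowledge.  *Absolute* mode forces the prior to 0.5 —
no prior information — under which every evidence item contributes
non-negative bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .calculus import (
    EvidenceOddsTable,
    combine_odds,
    information_content,
    posterior,
)

__all__ = [
    "VariantEvidenceRecord",
    "FunctionalClassMap",
    "InfoResult",
    "MaveScoreReport",
    "variant_info_delta",
    "mave_information_score",
    "fold_increase",
    "FUNCTIONAL_CLASSES",
]

FUNCTIONAL_CLASSES = ("normal", "intermediate", "abnormal")

#: Posterior thresholds used for the "VUS reclassified" accounting that
#: conventional MAVE utility reports are based on.
LIKELY_PATHOGENIC_POSTERIOR = 0.90
LIKELY_BENIGN_POSTERIOR = 0.10


@dataclass(frozen=True)
class FunctionalClassMap:
    """Per-assay mapping from functional class to an evidence-code label.

    ``None`` (or ``"none"``) means the class carries no evidence (odds 1);
    intermediate scores typically map to none.  Examples: the BRCA1
    saturation-editing assay treats functionally normal as strong benign
    (BS3) and loss of function as strong pathogenic (PS3); the TP53
    classifier output was weighted benign moderate / pathogenic strong.
    """

    normal: str | None = "BS3"
    intermediate: str | None = None
    abnormal: str | None = "PS3"

    def code_for(self, functional_class: str) -> str | None:
        cls = functional_class.strip().lower()
        if cls not in FUNCTIONAL_CLASSES:
            raise ValueError(
                f"unknown functional class {functional_class!r}; "
                f"expected one of {FUNCTIONAL_CLASSES}"
            )
        return getattr(self, cls)


@dataclass(frozen=True)
class VariantEvidenceRecord:
    """One variant's prior, pre-existing evidence, and MAVE evidence.

    Parameters
    ----------
    variant_id : str
        HGVS-style identifier or any free label.
    gene : str
        Gene symbol (used only for reporting).
    prior : float
        Prior probability of pathogenicity; 0.1 by default, the value
        conventionally used with the Bayesian ACMG/AMP framework.
    baseline_codes : sequence of str
        Evidence codes applied before the MAVE (e.g. ``PM2_supporting``).
    mave_code : str, optional
        Evidence code assigned from the MAVE; takes precedence over
        ``functional_class`` when both are present.
    functional_class : str, optional
        ``normal`` / ``intermediate`` / ``abnormal``; resolved to a code
        through a :class:`FunctionalClassMap`.
    is_vus : bool, optional
        Whether the variant was of uncertain significance before the MAVE
        (used for VUS-only accounting).
    single_substitution : bool
        False flags amino-acid changes needing more than one nucleotide
        substitution; such records are excluded from scoring.
    annotations : dict
        Unrecognised input columns, preserved verbatim.
    """

    variant_id: str
    gene: str = ""
    prior: float = 0.1
    baseline_codes: tuple[str, ...] = ()
    mave_code: str | None = None
    functional_class: str | None = None
    is_vus: bool | None = None
    single_substitution: bool = True
    annotations: Mapping = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.prior <= 1.0:
            raise ValueError(
                f"prior for {self.variant_id!r} must be in [0, 1], got {self.prior!r}"
            )
        object.__setattr__(self, "baseline_codes", tuple(self.baseline_codes))
        if self.functional_class is not None:
            cls = self.functional_class.strip().lower()
            if cls not in FUNCTIONAL_CLASSES:
                raise ValueError(
                    f"unknown functional class {self.functional_class!r} "
                    f"for {self.variant_id!r}"
                )
            object.__setattr__(self, "functional_class", cls)

    def mave_evidence_code(self, class_map: FunctionalClassMap | None) -> str | None:
        """The evidence code the MAVE contributes for this record."""
        if self.mave_code is not None:
            return self.mave_code
        if self.functional_class is not None:
            cmap = class_map if class_map is not None else FunctionalClassMap()
            return cmap.code_for(self.functional_class)
        raise ValueError(
            f"record {self.variant_id!r} has neither mave_code nor functional_class"
        )


@dataclass(frozen=True)
class InfoResult:
    """Information state of one variant before and after MAVE evidence."""

    variant_id: str
    posterior_before: float
    posterior_after: float
    info_before: float
    info_after: float
    delta_bits: float


@dataclass(frozen=True)
class MaveScoreReport:
    """Aggregate information score of a MAVE over a set of variants.

    ``total_bits`` sums per-variant deltas in the requested mode;
    ``vus_only_bits`` restricts the sum to variants flagged VUS whose
    posterior crosses a likely-pathogenic/likely-benign boundary (the
    conventional "variants reclassified" accounting); ``absolute_bits``
    is the prior-0.5 total regardless of mode.
    """

    gene: str
    n_variants: int
    total_bits: float
    vus_only_bits: float
    absolute_bits: float
    mode: str
    per_variant: tuple[InfoResult, ...]
    n_excluded_multi_substitution: int = 0

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "n_variants": self.n_variants,
            "mode": self.mode,
            "total_bits": self.total_bits,
            "vus_only_bits": self.vus_only_bits,
            "absolute_bits": self.absolute_bits,
            "n_excluded_multi_substitution": self.n_excluded_multi_substitution,
        }


def variant_info_delta(
    record: VariantEvidenceRecord,
    class_map: FunctionalClassMap | None = None,
    table: EvidenceOddsTable | None = None,
    prior: float | None = None,
) -> InfoResult:
    """Information change for one variant with vs without its MAVE evidence.

    The before-state combines the prior with ``baseline_codes`` only; the
    after-state additionally multiplies in the MAVE odds.  ``prior``
    overrides the record's own prior (used for absolute accounting).

    >>> rec = VariantEvidenceRecord("BRCA1 c.5120T>C", prior=0.1,
    ...                             baseline_codes=("PM2_supporting",),
    ...                             mave_code="BS3")
    >>> round(variant_info_delta(rec).delta_bits, 3)
    0.602
    """
    table = table if table is not None else EvidenceOddsTable()
    p0 = record.prior if prior is None else prior
    baseline_odds = combine_odds(table.odds_for(c) for c in record.baseline_codes)
    mave_odds = table.odds_for(record.mave_evidence_code(class_map))
    post_before = posterior(baseline_odds, p0)
    post_after = posterior(baseline_odds * mave_odds, p0)
    info_before = information_content(post_before)
    info_after = information_content(post_after)
    return InfoResult(
        variant_id=record.variant_id,
        posterior_before=post_before,
        posterior_after=post_after,
        info_before=info_before,
        info_after=info_after,
        delta_bits=info_after - info_before,
    )


def _crosses_classification_boundary(
    result: InfoResult,
    likely_pathogenic: float,
    likely_benign: float,
) -> bool:
    return (
        result.posterior_after >= likely_pathogenic
        or result.posterior_after <= likely_benign
    )


def mave_information_score(
    records: Sequence[VariantEvidenceRecord],
    class_map: FunctionalClassMap | None = None,
    table: EvidenceOddsTable | None = None,
    mode: str = "relative",
    likely_pathogenic: float = LIKELY_PATHOGENIC_POSTERIOR,
    likely_benign: float = LIKELY_BENIGN_POSTERIOR,
) -> MaveScoreReport:
    """Total information score of a MAVE over a list of variant records.

    Parameters
    ----------
    records : sequence of VariantEvidenceRecord
        Must be non-empty.  Records flagged as multi-nucleotide
        substitutions are excluded from all totals and counts.
    mode : {"relative", "absolute"}
        Relative sums deltas at each record's stated prior; absolute
        recomputes every delta at prior 0.5 (no prior information), under
        which contributions are non-negative.

    Notes
    -----
    Variants whose evidence resolves to odds 1 (e.g. intermediate
    functional scores) contribute 0 bits but are counted in
    ``n_variants``, mirroring how assays report intermediate calls.
    """
    if mode not in ("relative", "absolute"):
        raise ValueError(f"mode must be 'relative' or 'absolute', got {mode!r}")
    records = list(records)
    if not records:
        raise ValueError("cannot score an empty record list")
    scored = [r for r in records if r.single_substitution]
    n_excluded = len(records) - len(scored)
    if not scored:
        raise ValueError("no single-substitution records to score")

    forced_prior = 0.5 if mode == "absolute" else None
    per_variant = []
    vus_only = 0.0
    absolute = 0.0
    for rec in scored:
        result = variant_info_delta(rec, class_map, table, prior=forced_prior)
        per_variant.append(result)
        # VUS-only accounting always follows the stated priors, like the
        # reclassification counts it reproduces.
        rel = (
            result
            if forced_prior is None
            else variant_info_delta(rec, class_map, table)
        )
        if rec.is_vus and _crosses_classification_boundary(
            rel, likely_pathogenic, likely_benign
        ):
            vus_only += rel.delta_bits
        abs_result = (
            result
            if forced_prior == 0.5
            else variant_info_delta(rec, class_map, table, prior=0.5)
        )
        absolute += abs_result.delta_bits

    genes = {r.gene for r in scored if r.gene}
    return MaveScoreReport(
        gene=genes.pop() if len(genes) == 1 else ";".join(sorted(genes)),
        n_variants=len(scored),
        total_bits=math.fsum(r.delta_bits for r in per_variant),
        vus_only_bits=vus_only,
        absolute_bits=absolute,
        mode=mode,
        per_variant=tuple(per_variant),
        n_excluded_multi_substitution=n_excluded,
    )


def fold_increase(total_bits: float, vus_only_bits: float) -> float | None:
    """Ratio of a MAVE's full information yield to its VUS-only yield.

    Returns ``None`` when ``vus_only_bits`` is not positive (the ratio is
    then not computable, and reporting infinity would overstate it).

    >>> round(fold_increase(813.2, 36.9), 1)
    22.0
    """
    if not vus_only_bits > 0.0:
        return None
    return total_bits / vus_only_bits
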