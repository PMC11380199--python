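"""Deterministic synthetic MAVE cohorts and protein sequences.

The generator emulates the composition of real MAVE result tables: a
fixed number of functionally normal / intermediate / abnormal calls, a
shared prior, and pre-existing evidence codes sprinkled across variants
at configurable frequencies (e.g. PM2_supporting on rare variants).  It
produces :class:`~maveinfo.scoring.VariantEvidenceRecord` lists directly,
so every scoring and audit path can be exercised without any external
download.  Identical spec + seed gives identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .scoring import FunctionalClassMap, VariantEvidenceRecord

__all__ = ["SyntheticMaveSpec", "generate_synthetic_mave", "random_protein"]

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Rough human proteome amino-acid frequencies, used for synthetic
#: protein sequences (order matches _AMINO_ACIDS).
_AA_FREQ = np.array(
    [
        0.070, 0.023, 0.047, 0.071, 0.036, 0.066, 0.026, 0.043, 0.057, 0.100,
        0.021, 0.036, 0.063, 0.048, 0.056, 0.083, 0.054, 0.060, 0.012, 0.028,
    ]
)


@dataclass(frozen=True)
class SyntheticMaveSpec:
    """Recipe for a synthetic MAVE result table.

    Defaults mirror the TP53 cohort composition (5070 normal, 2823
    abnormal calls from a combined-assay classifier, prior 0.1, benign
    moderate / pathogenic strong weights); pass other counts and maps to
    emulate other assays.
    """

    n_normal: int = 5070
    n_intermediate: int = 0
    n_abnormal: int = 2823
    class_map: FunctionalClassMap = field(
        default_factory=lambda: FunctionalClassMap(normal="BM", abnormal="PS")
    )
    prior: float = 0.1
    baseline_code_frequency: Mapping[str, float] = field(default_factory=dict)
    gene: str = "SYNTH"
    random_seed: int = 0

    def __post_init__(self):
        for name in ("n_normal", "n_intermediate", "n_abnormal"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.prior <= 1.0:
            raise ValueError(f"prior must be in [0, 1], got {self.prior!r}")
        for code, freq in self.baseline_code_frequency.items():
            if not 0.0 <= freq <= 1.0:
                raise ValueError(
                    f"baseline frequency for {code!r} must be in [0, 1]"
                )

    @property
    def n_total(self) -> int:
        return self.n_normal + self.n_intermediate + self.n_abnormal


def generate_synthetic_mave(spec: SyntheticMaveSpec) -> list[VariantEvidenceRecord]:
    """Generate a synthetic variant-record list from a spec.

    Functional classes are assigned to meet the spec's exact counts and
    then shuffled; baseline codes are sampled independently per variant
    at the configured frequencies.  Deterministic for a fixed
    ``random_seed``.
    """
    rng = np.random.default_rng(spec.random_seed)
    classes = (
        ["normal"] * spec.n_normal
        + ["intermediate"] * spec.n_intermediate
        + ["abnormal"] * spec.n_abnormal
    )
    order = rng.permutation(len(classes))
    codes = sorted(spec.baseline_code_frequency)
    records = []
    for row, idx in enumerate(order):
        baseline = tuple(
            code
            for code in codes
            if rng.random() < spec.baseline_code_frequency[code]
        )
        records.append(
            VariantEvidenceRecord(
                variant_id=f"{spec.gene}_v{row + 1:05d}",
                gene=spec.gene,
                prior=spec.prior,
                baseline_codes=baseline,
                functional_class=classes[idx],
                is_vus=True,
            )
        )
    return records


def random_protein(length: int, seed: int = 0) -> str:
    """A random protein sequence with human-like amino-acid frequencies."""
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    aa = rng.choice(list(_AMINO_ACIDS), size=length, p=_AA_FREQ / _AA_FREQ.sum())
    return "".join(aa)
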