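"""Apparent-information effect of classification-rule strengths and changes.

Classification committees (ACMG/AMP, ClinGen VCEPs) periodically change
the strength assigned to an evidence rule.  Because information content
is a nonlinear function of the posterior, the apparent information a rule
contributes depends strongly on the prior: pathogenic evidence applied at
a low prior drags the posterior toward 0.5 and *loses* information, and
symmetrically for benign evidence at high priors.  Sweeping a rule's odds
across the prior range makes this visible; auditing a rule change over a
set of variants quantifies its gene-wide apparent-information effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calculus import EvidenceOddsTable, information_content, posterior
from .scoring import (
    FunctionalClassMap,
    VariantEvidenceRecord,
    variant_info_delta,
)

__all__ = [
    "InfoChangeCurve",
    "RuleChangeAudit",
    "info_change_curve",
    "rule_change_audit",
    "default_prior_grid",
    "plot_info_change_curves",
]


def default_prior_grid() -> np.ndarray:
    """199 priors at 0.005 spacing on the open interval (0, 1).

    The endpoints are excluded: at prior 0 or 1 the baseline already holds
    a full bit and no evidence can change it.
    """
    return np.round(np.arange(1, 200) * 0.005, 10)


@dataclass(frozen=True)
class InfoChangeCurve:
    """Information change of one evidence category across priors."""

    code: str
    odds: float
    priors: np.ndarray
    delta_bits: np.ndarray

    @property
    def argmax_prior(self) -> float:
        """Prior at which this evidence yields its largest information gain.

        Reported empirically; for strong evidence the maximum can sit away
        from 0.5.
        """
        return float(self.priors[int(np.argmax(self.delta_bits))])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "category": self.code,
                "prior": self.priors,
                "delta_bits": self.delta_bits,
            }
        )


@dataclass(frozen=True)
class RuleChangeAudit:
    """Per-variant and aggregate effect of swapping one rule for another.

    Each entry is the difference (new minus old) in the variant's MAVE
    information delta when its assay evidence is scored under ``new_code``
    instead of ``old_code``.
    """

    old_code: str
    new_code: str
    variant_ids: tuple[str, ...]
    delta_of_deltas: tuple[float, ...]

    @property
    def total_bits(self) -> float:
        return float(sum(self.delta_of_deltas))

    @property
    def mean_bits(self) -> float:
        return self.total_bits / len(self.delta_of_deltas)

    def to_dict(self) -> dict:
        return {
            "old_code": self.old_code,
            "new_code": self.new_code,
            "n_variants": len(self.delta_of_deltas),
            "total_bits": self.total_bits,
            "mean_bits": self.mean_bits,
        }


def info_change_curve(
    code: str,
    priors: Sequence[float] | None = None,
    table: EvidenceOddsTable | None = None,
) -> InfoChangeCurve:
    """Sweep one evidence category's information change across priors.

    For each prior p the curve records I(posterior(odds, p)) - I(p).
    Grid points touching 0 or 1 exactly are rejected.

    >>> curve = info_change_curve("PS", priors=[0.5])
    >>> round(float(curve.delta_bits[0]), 2)
    0.71
    """
    table = table if table is not None else EvidenceOddsTable()
    odds = table.odds_for(code)
    grid = default_prior_grid() if priors is None else np.asarray(priors, float)
    if grid.size == 0:
        raise ValueError("prior grid is empty")
    if np.any(grid <= 0.0) or np.any(grid >= 1.0):
        raise ValueError("priors must lie strictly inside (0, 1)")
    delta = information_content(posterior(odds, grid)) - information_content(grid)
    return InfoChangeCurve(code=code, odds=odds, priors=grid, delta_bits=delta)


def rule_change_audit(
    records: Sequence[VariantEvidenceRecord],
    old_code: str,
    new_code: str,
    table: EvidenceOddsTable | None = None,
) -> RuleChangeAudit:
    """Audit the apparent-information effect of a rule-strength change.

    Every record's MAVE evidence is re-scored with ``old_code`` and with
    ``new_code`` (baseline codes and priors untouched); the audit reports
    the per-variant difference in delta-bits plus the sum and mean.
    Identical codes give exact zeros.
    """
    table = table if table is not None else EvidenceOddsTable()
    records = list(records)
    if not records:
        raise ValueError("cannot audit an empty record list")
    # resolve eagerly so unknown codes fail before any scoring
    table.odds_for(old_code)
    table.odds_for(new_code)
    old_map = FunctionalClassMap(normal=old_code, intermediate=old_code,
                                 abnormal=old_code)
    new_map = FunctionalClassMap(normal=new_code, intermediate=new_code,
                                 abnormal=new_code)
    ids, diffs = [], []
    for rec in records:
        forced_old = _with_code(rec, old_code)
        forced_new = _with_code(rec, new_code)
        if old_code == new_code:
            diff = 0.0
        else:
            diff = (
                variant_info_delta(forced_new, new_map, table).delta_bits
                - variant_info_delta(forced_old, old_map, table).delta_bits
            )
        ids.append(rec.variant_id)
        diffs.append(diff)
    return RuleChangeAudit(
        old_code=old_code,
        new_code=new_code,
        variant_ids=tuple(ids),
        delta_of_deltas=tuple(diffs),
    )


def _with_code(
    rec: VariantEvidenceRecord, code: str
) -> VariantEvidenceRecord:
    from dataclasses import replace

    return replace(rec, mave_code=code, functional_class=None)


def plot_info_change_curves(
    codes: Sequence[str] = ("PVS", "PS", "PM", "PP", "BP", "BM", "BS", "BVS"),
    table: EvidenceOddsTable | None = None,
    ax=None,
):
    """Plot information-change curves for several evidence categories.

    Returns the matplotlib axes; intended for the ``rule-curve`` CLI
    subcommand's optional figure output.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    for code in codes:
        curve = info_change_curve(code, table=table)
        ax.plot(curve.priors, curve.delta_bits, label=code)
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.set_xlabel("prior probability of pathogenicity")
    ax.set_ylabel("information change (bits)")
    ax.legend(fontsize=8, ncol=2)
    return ax
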