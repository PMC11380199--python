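"""Conversions between probability of pathogenicity, entropy, information
content, and odds of pathogenicity.

Clinical variant classification is, at bottom, a binary question: a variant
is pathogenic or benign for the disease linked to its gene.  The certainty
of that call can be expressed as a probability of pathogenicity ``p`` and
converted to classification information measured in bits:

* binary entropy ``S(p) = -p*log2(p) - (1-p)*log2(1-p)`` measures the
  remaining uncertainty (1 bit at p = 0.5, 0 bits at p in {0, 1});
* information content ``I(p) = 1 - S(p)`` measures the certainty already
  accumulated (0 bits at even odds, 1 bit at complete certainty).

Evidence items in the Bayesian adaptation of the ACMG/AMP guidelines carry
odds-of-pathogenicity multipliers (likelihood ratios).  Independent items
combine by multiplication, and a combined odds ``O`` updates a prior via

    posterior = O * prior / ((O - 1) * prior + 1)

which is Bayes' rule written on the probability scale.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "entropy",
    "information_content",
    "posterior",
    "combine_odds",
    "evidence_to_odds",
    "EvidenceOdds",
    "EvidenceOddsTable",
    "EvidenceCodeError",
    "DEFAULT_STRENGTH_ODDS",
    "STRENGTHS",
]

#: Evidence strength categories, strongest first.
STRENGTHS = ("very_strong", "strong", "moderate", "supporting")

#: Default pathogenic odds per strength category (Tavtigian-style Bayesian
#: adaptation of the ACMG/AMP guidelines).  Benign odds are the reciprocals.
DEFAULT_STRENGTH_ODDS: Mapping[str, float] = {
    "very_strong": 350.0,
    "strong": 18.7,
    "moderate": 4.33,
    "supporting": 2.08,
}


class EvidenceCodeError(KeyError):
    """Raised when an evidence-code label cannot be resolved to odds."""


def _validate_probability(p, name: str = "p"):
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0) or np.any(np.isnan(arr)):
        raise ValueError(f"{name} must lie in [0, 1], got {p!r}")
    return arr


def entropy(p):
    """Binary Shannon entropy of a probability of pathogenicity, in bits.

    Accepts a scalar or array-like; values outside [0, 1] raise
    ``ValueError``.  The limit convention 0*log2(0) = 0 is applied, so
    p = 0 and p = 1 return exactly 0 without floating-point warnings.
    """
    arr = _validate_probability(p)
    out = np.zeros_like(arr)
    interior = (arr > 0.0) & (arr < 1.0)
    q = arr[interior]
    out[interior] = -q * np.log2(q) - (1.0 - q) * np.log2(1.0 - q)
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def information_content(p):
    """Classification information in bits: ``1 - entropy(p)``.

    Symmetric under p <-> 1-p; 0 at p = 0.5 and 1 at p in {0, 1}.
    """
    return 1.0 - entropy(p)


def posterior(odds, prior):
    """Posterior probability of pathogenicity from combined odds and a prior.

    Evaluates ``odds*prior / ((odds-1)*prior + 1)``, the probability-scale
    form of Bayes' rule with a likelihood ratio ``odds``.  A prior of 0 or
    1 is a fixed point regardless of the evidence.

    Parameters
    ----------
    odds : float
        Combined odds of pathogenicity; must be > 0.
    prior : float
        Prior probability of pathogenicity in [0, 1].
    """
    odds_arr = np.asarray(odds, dtype=float)
    if np.any(odds_arr <= 0.0) or np.any(np.isnan(odds_arr)):
        raise ValueError(f"odds must be > 0, got {odds!r}")
    prior_arr = _validate_probability(prior, "prior")
    raw = odds_arr * prior_arr / ((odds_arr - 1.0) * prior_arr + 1.0)
    # priors of exactly 0/1 are fixed points; enforce despite rounding in
    # the denominator, and keep the result inside [0, 1]
    out = np.clip(np.where(prior_arr == 1.0, 1.0, raw), 0.0, 1.0)
    scalar = np.isscalar(odds) and np.isscalar(prior)
    return float(out) if scalar or out.ndim == 0 else out


def combine_odds(odds_list: Iterable[float]) -> float:
    """Combine independent evidence items by multiplying their odds.

    An empty list means no evidence and returns 1.0.  Non-positive entries
    raise ``ValueError``.
    """
    product = 1.0
    for o in odds_list:
        if not o > 0.0:
            raise ValueError(f"odds must be > 0, got {o!r}")
        product *= float(o)
    return product


@dataclass(frozen=True)
class EvidenceOdds:
    """An evidence-code label resolved to its odds-of-pathogenicity."""

    code: str
    odds: float

    def __post_init__(self):
        if not self.odds > 0.0:
            raise ValueError(f"odds must be > 0, got {self.odds!r}")


# Base-code prefix -> (direction, default strength).  Direction "P" means
# pathogenic (odds > 1), "B" benign (reciprocal odds).  BA1 is the
# stand-alone benign frequency criterion, weighted very strong; BM/BVS are
# not formal ACMG/AMP categories but appear in strength-sweep analyses.
_CODE_PREFIXES = {
    "PVS": ("P", "very_strong"),
    "PS": ("P", "strong"),
    "PM": ("P", "moderate"),
    "PP": ("P", "supporting"),
    "BVS": ("B", "very_strong"),
    "BA": ("B", "very_strong"),
    "BS": ("B", "strong"),
    "BM": ("B", "moderate"),
    "BP": ("B", "supporting"),
}

_CODE_RE = re.compile(r"^(PVS|PS|PM|PP|BVS|BA|BS|BM|BP)(\d*)$", re.IGNORECASE)

#: Labels treated as "no evidence" (odds exactly 1).
_NO_EVIDENCE = {"", ".", "none", "na"}


class EvidenceOddsTable:
    """Mapping from evidence-code labels to odds of pathogenicity.

    The table stores one pathogenic odds value per strength category
    (``very_strong`` > ``strong`` > ``moderate`` > ``supporting`` > 1);
    benign odds are the reciprocals.  Codes are matched case-insensitively
    and an explicit strength suffix after ``_`` (e.g. ``PM2_supporting``)
    overrides the code's default strength.  Individual code labels may be
    pinned to exact odds via ``code_overrides`` (e.g. the rounded 18.8 a
    study reports for PS3).

    Parameters
    ----------
    strength_odds : mapping, optional
        Pathogenic odds per strength category; defaults to the Tavtigian
        values (350, 18.7, 4.33, 2.08).
    code_overrides : mapping, optional
        Exact odds for specific full code labels, bypassing strength
        resolution.
    """

    def __init__(
        self,
        strength_odds: Mapping[str, float] | None = None,
        code_overrides: Mapping[str, float] | None = None,
    ):
        merged = dict(DEFAULT_STRENGTH_ODDS)
        if strength_odds:
            for key, value in strength_odds.items():
                key = key.lower().replace(" ", "_")
                if key not in STRENGTHS:
                    raise ValueError(
                        f"unknown strength {key!r}; expected one of {STRENGTHS}"
                    )
                if not value > 1.0:
                    raise ValueError(
                        f"pathogenic odds for {key!r} must be > 1, got {value!r}"
                    )
                merged[key] = float(value)
        ordered = [merged[s] for s in STRENGTHS]
        if not all(a > b for a, b in zip(ordered, ordered[1:])):
            raise ValueError(
                "pathogenic odds must decrease from very_strong to supporting"
            )
        self._strength_odds = merged
        self._code_overrides = {
            code.upper(): float(odds) for code, odds in (code_overrides or {}).items()
        }
        for code, odds in self._code_overrides.items():
            if not odds > 0.0:
                raise ValueError(f"override odds for {code} must be > 0")

    @classmethod
    def from_dict(cls, config: Mapping) -> "EvidenceOddsTable":
        """Build a table from a config mapping.

        Recognised keys: ``strength_odds`` (category -> pathogenic odds)
        and ``code_overrides`` (code label -> exact odds).  A flat mapping
        of category -> odds is also accepted.
        """
        if "strength_odds" in config or "code_overrides" in config:
            return cls(config.get("strength_odds"), config.get("code_overrides"))
        return cls(strength_odds=config)

    @classmethod
    def from_yaml(cls, path) -> "EvidenceOddsTable":
        import yaml

        with open(path) as handle:
            config = yaml.safe_load(handle)
        if not isinstance(config, Mapping):
            raise ValueError(f"odds-table config {path} must be a mapping")
        return cls.from_dict(config)

    def to_dict(self) -> dict:
        return {
            "strength_odds": dict(self._strength_odds),
            "code_overrides": dict(self._code_overrides),
        }

    def strength_odds(self, strength: str, direction: str = "P") -> float:
        """Odds for a strength category; benign direction is the reciprocal."""
        odds = self._strength_odds[strength]
        return odds if direction == "P" else 1.0 / odds

    def odds_for(self, code: str) -> float:
        """Resolve an evidence-code label to its odds of pathogenicity.

        ``None``, ``""``, ``"."`` and ``"none"`` resolve to 1 (no
        evidence).  Unknown labels raise :class:`EvidenceCodeError`.
        """
        if code is None:
            return 1.0
        label = str(code).strip()
        if label.lower() in _NO_EVIDENCE:
            return 1.0
        upper = label.upper()
        if upper in self._code_overrides:
            return self._code_overrides[upper]
        base, _, suffix = label.partition("_")
        match = _CODE_RE.match(base)
        if not match:
            known = sorted(_CODE_PREFIXES) + sorted(self._code_overrides)
            raise EvidenceCodeError(
                f"unknown evidence code {code!r}; known prefixes/codes: {known}"
            )
        direction, strength = _CODE_PREFIXES[match.group(1).upper()]
        if suffix:
            suffix = suffix.lower().replace(" ", "_")
            if suffix not in STRENGTHS:
                raise EvidenceCodeError(
                    f"unknown strength suffix {suffix!r} in {code!r}; "
                    f"expected one of {STRENGTHS}"
                )
            strength = suffix
        return self.strength_odds(strength, direction)

    def __repr__(self) -> str:  # pragma: no cover
        odds = ", ".join(f"{s}={self._strength_odds[s]}" for s in STRENGTHS)
        return f"EvidenceOddsTable({odds}, overrides={self._code_overrides})"


def evidence_to_odds(code: str, table: EvidenceOddsTable | None = None) -> EvidenceOdds:
    """Resolve one evidence-code label against an odds table.

    >>> evidence_to_odds("PM").odds
    4.33
    >>> round(evidence_to_odds("BS").odds, 4)
    0.0535
    """
    table = table if table is not None else EvidenceOddsTable()
    return EvidenceOdds(code=code, odds=table.odds_for(code))
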