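# Methods

## Model

Classification of a missense variant is treated as a binary outcome
(pathogenic/benign) for a gene with a single defined gene–disease
relationship; reduced penetrance and multi-outcome phenotypes are out of
scope, as they are in the classification frameworks this builds on. The
state of knowledge about a variant is a probability of pathogenicity `p`,
and its certainty is scored as information content `I(p) = 1 − S(p)` with
`S` the binary Shannon entropy in bits. `0·log₂0 = 0` by limit convention,
so `p = 0` and `p = 1` return exactly 1 bit without floating-point
warnings. Probabilities are validated, not clamped: out-of-range inputs
raise, because silent clamping could hide upstream errors in evidence
combination.

Evidence enters through the Bayesian adaptation of the ACMG/AMP criteria:
each code carries an odds-of-pathogenicity (likelihood ratio), independent
codes combine by multiplication, and the posterior is
`O·prior / ((O−1)·prior + 1)`. Priors of exactly 0 or 1 are enforced as
fixed points (the naive expression can round past 1 for priors near 1) and
the result is kept inside [0, 1].

## Odds table

Default strengths are the Tavtigian-framework values: very strong 350,
strong 18.7, moderate 4.33, supporting 2.08, with benign odds the exact
reciprocals. Published analyses often print rounded instances (4.3, 18.8,
0.0535, 0.053); all worked-example checks in the test suite pass with
either choice at the ±0.005 tolerance used throughout, and individual
codes can be pinned to exact values via `code_overrides` (YAML-configurable
per run). Evidence codes are case-insensitive; a strength suffix after
`_` (`PM2_supporting`) overrides the code's default strength; `none`/`.`
mean odds 1. The supporting-level odds 2.08 is the value that reproduces
the published PM2-supporting posterior of 0.188 at prior 0.1.

## MAVE scoring

A variant record holds a prior (default 0.1, the value conventionally used
with this framework; overridable per record and globally), pre-existing
evidence codes, and the MAVE's evidence — either a code directly or a
functional class (`normal`/`intermediate`/`abnormal`) resolved through a
per-assay class map (e.g. BS3/PS3 for the BRCA1 saturation-editing assay,
benign-moderate/pathogenic-strong for the TP53 classifier output). The
per-variant delta is `I(posterior with MAVE odds) − I(posterior without)`;
negative deltas are reported as-is, since conflicting evidence genuinely
loses certainty. Intermediate calls map to odds 1, contribute 0 bits, and
stay in the variant count. Records flagged as requiring more than one
nucleotide substitution are excluded from totals.

Aggregate reports carry three totals: *relative* (deltas at stated priors),
*absolute* (priors forced to 0.5, under which every item contributes
non-negatively), and *VUS-only*. The VUS-only rule — needed to compute the
fold-increase over reclassification-based accounting — is not spelled out
in the literature being reproduced, so it is made explicit and
configurable here: sum deltas over records flagged VUS whose posterior
(with the MAVE evidence, at the stated prior) reaches the likely-pathogenic
(≥ 0.90) or likely-benign (≤ 0.10) band. `fold_increase` returns `None`
when the VUS-only denominator is non-positive rather than reporting an
infinite ratio.

## Gene totals

Each sense codon has nine single-base neighbours, classified against the
standard genetic code (from Biopython) as missense, nonsense, or
synonymous; the three counts always sum to 9. Totals computed from protein
sequence use the mean missense count over the codons encoding each residue
("codon-averaged", generally fractional; e.g. Leu 5.5, Arg 17/3, Met 9),
which is the convention that reproduces published gene totals computed
from UniProt protein sequences; an exact CDS mode is provided when the
nucleotide sequence is known. A "possible missense variant" is a
nucleotide-level substitution event — two substitutions yielding the same
amino-acid change count twice — consistent with per-codon totals of 9 and
with the magnitude of published gene totals. Stop-gained changes count as
nonsense and are excluded from missense bits (truncating variants are
conventionally assumed pathogenic and sit outside the missense budget).
The initiator methionine is included. Non-canonical symbols are rejected
by default (`on_noncanonical="skip"` drops them with a logged warning).
Input in DNA spelling is converted to RNA internally.

Canonical TP53 (UniProt P04637, 393 aa) and PTEN (P60484, 403 aa)
sequences are bundled so gene totals work offline; their codon-averaged
totals are 2570.92 and 2720.75 bits. No BRCA1 sequence is bundled.

## Guideline analysis

`info_change_curve` sweeps `I(posterior(odds, p)) − I(p)` over a prior
grid; the default grid is 199 points at 0.005 spacing on the open interval
(0, 1), excluding the endpoints where the baseline already holds a full
bit. Curves for reciprocal categories are exact mirror images under
`(odds → 1/odds, p → 1−p)`. Pathogenic evidence loses information at low
priors and benign evidence at high priors (movement toward 0.5); at prior
0.5 every category's gain is non-negative and ordered by strength. The
prior that maximises a curve is reported empirically rather than assumed
to be 0.5 — for strong evidence the arg-max sits off-centre (PS peaks near
prior 0.61 with the default odds). `rule_change_audit` re-scores each
record's assay evidence under an old and a new code and reports
per-variant, summed, and mean differences.

## Synthetic data

The generator emulates the composition of real MAVE result tables: exact
per-class counts (defaults mirror the TP53 cohort, 5070 normal / 2823
abnormal at prior 0.1 with benign-moderate/pathogenic-strong weights),
optional baseline codes sampled independently per variant at configured
frequencies, and full determinism under a fixed seed. It emulates class
composition and evidence structure only — not functional-score
distributions, assay noise, score–threshold calibration, or real variant
identifiers — so passing tests demonstrate correct information accounting
for given evidence assignments, not the validity of any assay's
score-to-evidence mapping (which this package deliberately takes as
input). Synthetic protein sequences use rough human-proteome amino-acid
frequencies.

Scoring-pipeline checks run on cohorts of tens to a few thousand records
(the largest, the 3893-variant BRCA1 composition, reproduces the published
813.2-bit total to 0.03%); the full suite completes in a few seconds.

## Numerical choices and limitations

- All probability/bit comparisons against published worked examples use
  ±0.005 absolute tolerance, absorbing the rounding of printed odds.
- Totals are accumulated with `math.fsum`; additivity and permutation
  invariance hold to 1e−9 on cohorts of hundreds of records.
- Tie-break in curve arg-max: first maximum on the grid.
- The method measures *apparent* information under the chosen odds table
  and priors; it cannot know the true pathogenicity message, and it
  inherits the Bayesian point-value framework's assumption of evidence
  independence. Score-to-evidence calibration, non-missense variants,
  splice/UTR effects, and multi-nucleotide substitutions are out of scope.
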