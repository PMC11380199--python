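# maveinfo

Information-content scoring for clinical variant classification.

Variant classification for a gene with a clear gene–disease relationship is a
binary question — pathogenic or benign — answered with partial certainty. The
conventional utility metric for a multiplexed assay of variant effect (MAVE)
is the number of variants reclassified out of "uncertain significance", which
discards all the evidence that moved a variant's probability without crossing
a category boundary. `maveinfo` implements the alternative: measure a study's
yield in *bits* of classification information, so evidence counts whether or
not it reclassifies anything.

The package is for clinical genomicists, MAVE groups, and guideline
committees (ACMG/AMP, ClinGen VCEPs) who want to quantify assay utility or
the gene-wide effect of a rule-strength change.

## The math

For a probability of pathogenicity *p*, the binary entropy

&nbsp;&nbsp;&nbsp;&nbsp;S(p) = −p·log₂(p) − (1−p)·log₂(1−p)

measures the remaining uncertainty, and the information content

&nbsp;&nbsp;&nbsp;&nbsp;I(p) = 1 − S(p)

measures accumulated certainty: 0 bits at p = 0.5, 1 bit at p ∈ {0, 1}. One
bit equals completely classifying one variant starting from no information.

Evidence codes carry odds-of-pathogenicity multipliers (the Bayesian
adaptation of the ACMG/AMP criteria: very strong 350, strong 18.7, moderate
4.33, supporting 2.08; benign codes take reciprocals). Independent items
multiply, and combined odds O update a prior by

&nbsp;&nbsp;&nbsp;&nbsp;posterior = O·prior / ((O−1)·prior + 1).

A MAVE's information score sums, over assayed variants,
I(posterior with assay evidence) − I(posterior without it); deltas can be
negative when new evidence conflicts with the prior state. A gene's total
possible missense information is the number of single-nucleotide missense
substitutions its sequence admits (each codon has 9 single-base neighbours,
classified missense/nonsense/synonymous by the genetic code; from protein
sequence the counts are averaged over each amino acid's codons).

## Worked example

The BRCA1 variant c.5120T>C is absent from population databases
(PM2 at supporting strength) and was called functionally normal (BS3) by a
saturation-editing assay:

```bash
maveinfo score-variant --variant-id "BRCA1 c.5120T>C" --prior 0.1 \
    --baseline-codes PM2_supporting --mave-code BS3
```

```json
{
  "delta_bits": 0.6015904216546393,
  "info_after": 0.9049010836457763,
  "info_before": 0.303310661991137,
  "posterior_after": 0.01220800563446414,
  "posterior_before": 0.18772563176895307,
  "variant_id": "BRCA1 c.5120T>C"
}
```

Population evidence alone gives posterior 0.188 (0.303 bits); adding the
benign functional call drives the posterior to 0.012 (0.905 bits), a gain of
0.602 bits. By contrast, a loss-of-function call (PS3) on the same baseline
swings the posterior from 0.188 to 0.812 — a large probability change but
zero information change, because the mirrored posterior is no closer to
certainty. Reclassification counting would credit only the first variant;
both are reported here.

Gene-wide totals come from FASTA (canonical TP53 and PTEN sequences are
bundled):

```bash
maveinfo gene-total src/maveinfo/data/TP53_P04637.fasta
```

reports 2570.92 codon-averaged bits (display value 2571) over 393 residues —
the denominator for expressing an assay's yield as a percentage of the
gene's total missense information (`percent_information`). The other
subcommands are `score-mave` (aggregate a variant table, relative or
absolute-prior-0.5 accounting, VUS-only subtotal and fold-increase),
`rule-curve` (information change of each evidence strength across priors),
and `simulate` (deterministic synthetic MAVE tables).

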