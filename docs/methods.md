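# Methods

## The count model and test

Each gene's read count in one library is taken as Poisson: reads are a
large random sample of the transcript pool and any one gene occupies a
small fraction of it, so the per-gene count `x` has law
`p(x) = e^-λ λ^x / x!` with λ the gene's expected transcript copy
number in that library. Comparing one library against another without
replicates, we condition on the count observed in library 1. With
library totals `N1`, `N2` and counts `x`, `y`, integrating the flat
prior over λ gives the Audic–Claverie conditional law

    p(y|x) = (N2/N1)^y · (x+y)!/(x!·y!) · (1+N2/N1)^-(x+y+1),

a negative-binomial distribution with `x+1` successes and success
probability `N1/(N1+N2)`. Significance is two-sided by tail doubling:
with `S = Σ_{i=0..y} p(i|x)`, the p-value is `2S` when `S ≤ 0.5` and
`2(1−S)` otherwise, i.e. `2·min(S, 1−S)` capped at 1.

The differential-transcription call combines a strict fold rule with a
significance gate: the library-size-normalised ratio
`(x/N1)/(y/N2)` must exceed the threshold (default 2.0, strict — a
ratio of exactly 2 is not called) in either direction, and the
Benjamini–Hochberg FDR must clear α (default 0.05). The original
screen's rule was fold-only; setting `use_fdr=False, alpha=1.0`
reproduces that behaviour, but with one library per group a fold-only
rule floods the call set with low-count noise, so the FDR gate is the
default. "Up-regulated" means a higher normalised level in group 1
(the optimized-condition library).

### Zeros and the pseudocount

A pseudocount (default 0.5) is added to *both* counts of a gene, and
only when either count is zero. Applying it unconditionally would
shrink every fold estimate; applying it one-sidedly would bias the
direction. Genes observed in both libraries are therefore untouched,
and a gene seen in only one library gets a finite, conservative fold.

## Candidate screening

Candidates are the genes with `is_de` true and direction up whose
annotation intersects a whitelist of esterase/lipase terms: 13 KEGG
K-numbers (K16815, K14788, K01051, K01050, K02332, K13333, K01956,
K03927, K14675, K09252, K17648, K12389, K01049) and 7 GO accessions
(GO:0016042, GO:0016787, GO:0016829, GO:0080030, GO:0009395,
GO:0004806, GO:0004372). Matching is exact accession equality — no
GO-graph ancestor propagation — because the whitelist is itself a flat
list of leaf annotations; a `kegg_ko` of `NA` simply falls back to GO
terms. The whitelist is replaceable via a JSON/YAML file with `kegg`
and `go` keys. Output is sorted by descending fold change with
lexicographic gene-id tie-breaks, so repeated runs are byte-identical.
Up-regulated genes with no annotation record are excluded from the
candidate list but counted (`n_unannotated_`), since silent loss of
unannotated genes is the kind of thing one wants in the run log.

Annotation coverage is plain arithmetic — `100·annotated/total`
rounded half-up to two decimals, matching printed-report precision.

## Assay analytics

Standard curves are ordinary least squares of detector response on
concentration, with replicate responses averaged per concentration
level first (so unbalanced replication cannot tilt the line) and at
least three distinct levels required. Quantification inverts the line;
concentrations driven slightly negative by blank drift are clipped to
zero rather than raised as errors. Conversion ratio is defined as mol
ester formed per mol acid initially supplied, ×100 — the only
definition consistent with reporting a "conversion ratio of the
substrate" when the acid is the limiting, measured input. Fold
improvement is the after/before ratio of conversion percentages;
relative activity scales a pH or temperature profile to percent of its
maximum (uncertainties scaled identically); residual activity and
substrate-preference folds are treated/control ratios. Reported
values are rounded half-up to two decimals; machine outputs keep full
precision, and rounding happens nowhere else.

No blank subtraction is applied by default; `analyze_assay` can
subtract the enzyme-free (NG) sample's ester concentration per ester
when asked (`subtract_control=True`, CLI `--subtract-control`), since
assay reports do not always state whether printed conversions are
blank-corrected.

## The synthetic-data generator

`simulate_counts` emulates the pooled two-condition design: per-gene
baseline expression drawn from a gamma distribution (shape 0.5, mean
40 by default — a long-tailed expression profile in which a minority
of genes carry most reads), group-1 rates multiplied by a uniform
[fold_min, fold_max] factor for a `de_fraction` minority, and counts
drawn Poisson with means scaled so each library's total concentrates
on its target size (N1 = N2 = 10^6 by default, 24,319 genes — the
unigene count of the assembled transcriptome being emulated). Planted
candidates (default 23) are DE genes given whitelist annotations, with
their baseline floored so the group-2 expectation is at least 50
reads; `whitelist_fraction` of the null genes receive decoy whitelist
terms. One seed drives three named substreams (rates, counts,
annotations), so regenerating one layer does not scramble the others.

What it does *not* emulate, and what passing tests therefore do not
show: biological replicates and overdispersion (real RNA-seq counts
are overdispersed relative to Poisson — the `overdispersion` knob
mixes gamma noise into the means precisely to demonstrate that the
test then becomes anti-conservative); mapping ambiguity and
multi-mapping loss; annotation errors; and length/GC biases. Note
also that because rates are renormalised to library totals, planting
a large DE fraction at high folds compositionally deflates every null
gene in group 1 — a faithful property of pooled designs that surfaces
as down-fold false positives when `de_fraction` is pushed far above
the default.

`simulate_assay` draws one calibration line per ester (slope uniform
in 80–120 response units/mM, intercept 0–10), emits a triplicate
dilution series (0.5–10 mM) and one assay response at the reading
implied by the ester's true conversion, with Gaussian detector noise.
Noise-free tables invert exactly; noisy ones are unbiased.

## Numerical choices

- All factorial terms go through `scipy.special.gammaln`; the pmf is
  assembled in log space and exponentiated, finite for `x+y` up to at
  least 10^7.
- The cumulative uses the negative-binomial CDF (regularised
  incomplete beta) rather than term summation; the upper tail uses the
  survival function directly so neither branch loses precision to
  subtraction.
- At `x = y` with `N1 = N2` the cumulative is exactly one half (in the
  first `2x+1` Bernoulli trials of the underlying scheme, either
  majority is equally likely), so the two-sided p-value is returned as
  exactly 1.0 there; the incomplete-beta route alone drifts by ~1e-16
  at large x.
- Extreme divergences underflow `2·min(S, 1−S)` to zero; results are
  floored at the smallest positive normal float so p-values stay in
  (0, 1] and BH adjustment is well-defined.
- Correctness of the log-space path is pinned against an
  exact-rational oracle (`fractions.Fraction`) to 1e-10 relative error
  over `x, y ≤ 50` and library ratios 1/3–3, and the pmf is checked to
  sum to 1 within 1e-9.
- Reported percentages and folds round half-up (ties away from zero)
  via decimal arithmetic, matching printed-report conventions;
  banker's rounding would turn 2.145 into 2.14.

## Problem sizes

The simulation-based checks use 5,000 null genes at 10^6 reads per
library for calibration, 24,319 genes with 23 planted candidates for
shortlist recovery, and 120 Monte-Carlo replicates for assay-bias
checks — sizes at which binomial/Monte-Carlo standard errors are small
enough for 3·SE bounds to be meaningful while a full run stays in
seconds.

## Known limitations

- The test assumes Poisson sampling and one pooled library per group;
  it has no dispersion parameter and will overstate significance on
  replicated or overdispersed data. For replicated designs use a
  negative-binomial framework instead (DESeq2/edgeR-class models).
- The candidate screen reproduces a stated rule (up-regulated ∩
  whitelist); it cannot reproduce any manual curation applied on top
  of such a rule in real studies.
- The whitelist is a flat accession list; enzymes annotated only with
  ancestor or sibling GO terms will be missed by design.
- Conversion ratios assume the measured ester derives solely from its
  paired acid; cross-esterification in mixed-substrate reactions is
  not modelled.
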