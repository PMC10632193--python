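# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `derseg`, together with what the synthetic-data
generator does and does not emulate.

## Coverage profiles and the differential signal

All internal coordinates are 0-based half-open; conversions to 1-based
inclusive happen only when writing or reading GFF3. Alignments are
filtered uniformly everywhere (profiles and counting): unmapped,
secondary, supplementary and QC-fail records are dropped; duplicates are
kept by default (`drop_duplicates` removes them). Under
`pairing_mode="fragment"` a properly paired pair is one alignment unit
spanning the outermost template ends and counted once, anchored on the
leftmost mate; `"read"` treats mates independently. Strand is inferred
from mate 1 (`fr`: read strand equals transcript strand; `rf`: opposite;
`unstranded` is accepted with a warning and everything lands on the `+`
profile). Spliced alignments contribute only their aligned blocks to
full-length coverage; end profiles use the outermost aligned bases, i.e.
soft-clipped bases do not shift the 5′/3′ definition (the alternative —
clip-inclusive ends — would shift ends by the clip length and is not
implemented).

The default per-base coverage is the shifted geometric mean of the 5′ and
3′ end counts, `Q+1 = sqrt((Q5'+1)(Q3'+1))`; it is exactly the identity
when both end profiles agree and responds at both transcript ends. The
differential signal is `Y_i = mean_r log2(Q_i1r+1) − mean_r log2(Q_i2r+1)`
with the reference condition in the second term. Because adding a
constant to `Y` does not move the changepoints of the penalized
least-squares optimum, depth normalization (the offset
`ρ = mean log2 s_1r − mean log2 s_2r`, reported for information) is not
applied to `Y`. This shift argument is exact for the penalized objective
and approximate for the data only insofar as the `+1` offsets distort
log-ratios at very low counts.

## Segmentation

`Y` is segmented under the Gaussian piecewise-constant-mean model with
common variance. The penalized objective is

    sum_j sum_{i in seg j} (Y_i − μ_j)^2 + D · β,
    β = λ · σ̂² · log(n),    λ = 2 by default.

Choices and rationale:

- **Log base.** Natural log. The penalty scale literature is stated in
  nats; any other base is absorbed by λ. Configurable only through λ.
- **Variance.** σ̂² is the unbiased sample variance of `Y` over the whole
  analyzed strand, estimated once per strand — even though `Y` contains
  signal, which inflates σ̂² and thus the penalty (conservative in the
  number of segments). A difference-based robust alternative
  (`variance="mad_diff"`, median absolute successive difference scaled to
  the Gaussian) is available behind a non-default flag.
- **Solver.** FPOP maintains the optimal cost of the data up to position
  t as a piecewise quadratic in the last segment's mean. Every piece
  carries the start index of its last segment; the changepoint candidate
  at time t is the constant `F_t + β`, which replaces every region of the
  mean axis where it strictly undercuts the envelope. Quadratics are kept
  in coefficient form; crossing points come from discriminants, and
  candidate intervals narrower than 1e-9 are merged into their neighbor.
  The algorithm is exact in exact arithmetic; the tolerance only guards
  floating-point degeneracies. An O(n²) optimal-partitioning dynamic
  program over the same objective, plus exhaustive enumeration of all
  2^(n−1) segmentations at small n, serve as independent oracles in the
  tests.
- **Ties.** Equal-cost comparisons resolve toward the most recent
  changepoint candidate, in both the solver and the oracle. Consequently
  β = 0 returns the maximal zero-cost segmentation (every residual-free
  split taken). Ties have measure zero for continuous data and only
  matter for degenerate inputs.
- **Degenerate inputs.** n = 1 returns the trivial segmentation. A
  constant profile (σ̂² = 0) returns a single segment with a warning and
  never divides by the variance.

A 10^6-base profile segments in roughly 10–20 s on one CPU in this pure
Python implementation; the exhaustive and O(n²) oracles are restricted to
n ≤ 12 and a few thousand respectively.

## Counting

A unit is counted on every same-strand segment it overlaps by ≥ 1 base,
so boundary-spanning reads contribute to both neighbors; counts are raw.
`multi_overlap=False` assigns each unit only to its largest-overlap
segment (earliest on ties) for sensitivity analyses. Since segmentation
segments tile the window, every retained overlapping read is counted at
least once.

## Differential testing

Counts for segment k, sample j follow NB(mean `s_j · q_{k,g(j)}`,
variance `μ + α_k μ²`).

- **Size factors** are median-of-ratios over segments with all-positive
  counts, rescaled to geometric mean 1. When no all-positive row exists
  the default is an explicit error advising `fallback="poscounts"`, which
  builds the pseudo-reference from positive counts only.
- **Dispersion** is estimated per segment by maximizing the Cox–Reid
  adjusted profile likelihood (adjustment −½ log det X'WX, here
  −½(log I₁ + log I₂)) over a 30-point log-spaced grid (1e-8 … 20)
  followed by one parabolic refinement in log-α; the group means are
  profiled out by Newton steps on the log scale, vectorized across
  segments. Rows whose maximum sits at the bottom of the grid are
  reported as 0 (under-dispersed); all-zero rows are undefined and
  untestable.
- **Trend moderation.** Per-segment maximum likelihood underestimates α
  at few replicates, which inflates Wald statistics and breaks p-value
  calibration — most dramatically for rows whose estimate collapses to 0
  and would be tested as Poisson. A mean-dispersion trend
  `α(μ) = a0 + a1/μ` is fitted by least squares over all defined
  estimates (zeros included) and used as a **lower bound**: below-trend
  estimates are raised to the trend, above-trend estimates are kept.
  This restores near-uniform null p-values at 3–4 replicates per group
  while leaving genuinely high-dispersion segments untouched. No
  shrinkage from above, LFC shrinkage, independent filtering or outlier
  replacement is performed; every simplification relative to full
  empirical-Bayes machinery is deliberate and tested.
- **Wald test.** The two-group NB GLM with log link and offsets log s is
  fitted per segment (Newton on each group's log mean); the statistic is
  the fitted log2 ratio over its standard error from expected Fisher
  information, with a two-sided normal reference. A group with all-zero
  counts drives its mean to the parameter bound (no pseudocounts are
  added); the test still returns a p-value, flagged `boundary`. The same
  fit is cross-checked against an independent GLM implementation in the
  tests.
- **Multiplicity.** BH step-up over tested segments of both strands
  pooled (one experiment, one family; m excludes untestable rows). The
  post-hoc FDP bound uses Simes thresholds `t_k = α k / m` calibrated on
  that same family:
  `v̄(S) = min_k [#{i∈S : p_i ≥ t_k} + k − 1]` clipped to [0, |S|], and
  `FDP(S) ≤ v̄/|S|` simultaneously over all selections at confidence
  1 − α. Parametric thresholds only; permutation-based calibration of the
  threshold family is a possible extension, not implemented.
- **DER calling.** Candidates are tested segments with |log2FC| >
  log2(1.5) (fitted, unshrunk values). "Largest set" is operationalized
  as the longest prefix in ascending-p order (ties by genomic start)
  whose bound is ≤ the 5% target — a deterministic rule verified against
  exhaustive prefix search in the tests.

## Annotation labels

The nearest annotation(s) are found by minimal distance with strand
ignored (distance 0 on any overlap); classification of each pair is then
strand-aware. Opposite-strand overlap is `antisense` regardless of
geometry (precedence choice). Same-strand overlap: `inside` when the DER
is contained (shared endpoints count as inside — no crossing),
`overlapping_5prime`/`overlapping_3prime` when exactly one boundary is
crossed (5′/3′ defined on the annotation's strand), `overlapping_both`
otherwise. Disjoint neighbors get `upstream`/`downstream` on the
annotation's strand; a strand mismatch for disjoint pairs is recorded in
a separate flag rather than a class. Distance ties produce one label per
tying annotation. Gene records are used by default; the feature-type
filter and identifier attribute are configurable.

## Synthetic data

The generator draws per-base 5′-end counts NB(mean, α) with mean
`depth_factor · baseline · 2^effect·[condition 1]` (Poisson at α = 0) and
writes constant-length single-end reads whose 5′ ends reproduce those
counts exactly; the 3′ profile is the 5′ profile shifted by
read_length − 1, so the geometric coverage mode is exercised
non-trivially. Everything is deterministic given the scenario seed.

Reference scenarios (the conditions under which the acceptance checks
run):

- **Recovery:** 10 kb window, baselines 10 (+) and 4 (−) reads/base,
  three planted DERs (+1, −1 on `+`; +2 on `−`), dispersion 0.05, 2 vs 2
  replicates, read length 10 nt. The short read length keeps the
  read-length smear of the 3′-end profile (and hence the boundary
  blur of the geometric coverage) well inside a ±10-base tolerance;
  it is typical of small-RNA libraries.
- **Blank:** 5 kb window, baselines 5 and 2 reads/base, dispersion 0.05,
  ten same-condition replicates resampled into two-group designs; every
  DER called in such a design is a false positive.
- **Count-level simulations** for testing the DEA alone use segment means
  drawn log-normal(4, 1), dispersion 0.05, 10% non-null segments at
  ±1.5 log2-FC with 4 vs 4 replicates (bound coverage / FDR), and 3 vs 3
  with no effect for null calibration; 100–500 segments per dataset.

What the generator does **not** model: sequencing error, GC and
positional bias, fragment-length variation, paired-end layouts, spliced
reads, and replicate-level batch effects. Passing tests therefore
demonstrate correctness of the algorithms under the stated statistical
model, not robustness to every artifact of real libraries; the
paired-end and spliced code paths are exercised separately on
hand-crafted alignments.

## Known limitations

- The Gaussian constant-variance model for `Y` is an approximation;
  variance in fact depends on local coverage (low-coverage bases have
  noisier log-ratios). The penalty absorbs this only on average.
- Wald tests at 2 replicates per group remain anti-conservative even
  with trend moderation; the blank-experiment calibration quantifies the
  practical effect at the pipeline level.
- The FDP bound assumes positively dependent (PRDS-like) p-values, as
  Simes-based procedures do.
- Single-window analyses only; whole-genome runs iterate user-supplied
  regions, and the multiplicity family is per analysis.
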