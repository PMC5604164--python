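# Methods

## Integration model

The package treats every probe measurement in every sample as one *data
point* for its target locus and estimates a locus's reference expression
as the plain mean of its data points after a three-stage normalization.
The model's assumptions are deliberately minimal: expression is measured
multiplicatively (microarray-like), platform and sample effects are
global scale/shape distortions removable by rank-based normalization,
and multiple probes for one locus are exchangeable measurements of the
same transcript abundance. No background correction, log transformation
or batch-effect model is applied; the pipeline is intended for
integrating many small heterogeneous studies where per-study modeling is
impractical.

### Thresholding

Values ≤ 0 become 0.95 × the sample's minimum positive value. The factor
keeps "below detection" readings strictly below every detected value
while leaving ratios between pools defined. The operation is idempotent;
a sample with no positive value is rejected as unusable.

### Intra-sample normalization

Each value becomes 100·v/mean(sample), so every sample has mean exactly
100 and the final per-locus values sit on a genome-mean ≡ 100 scale.

### Scaled quantile normalization

Classical quantile normalization requires equal-length samples. For
unequal lengths we adopt a rank-interpolation contract: with N the
largest sample length, sample j's r-th smallest value (r = 0…n_j−1) sits
at scaled position r·(N−1)/(n_j−1) on the grid 0…N−1 (a single-value
sample sits at the grid midpoint). The reference distribution is, at
each grid position, the mean over samples of each sample's value
linearly interpolated at that position; each value is then replaced by
the reference linearly interpolated at its own scaled position. Ties
within a sample receive the mean of their positions' reference values so
equal inputs map to equal outputs.

Properties enforced by tests: within-sample rank order is preserved;
with equal-length samples the result is exactly classical quantile
normalization (sort/mean/unsort oracle); the transform is deterministic.
Nearest-neighbour rank matching would be an alternative to linear
interpolation; the choice is isolated inside
`normalization.scaled_quantile_normalize` so it can be swapped without
touching the rest of the pipeline.

### Aggregation

value = mean of data points; sd_percent = 100 × SD(n−1)/mean, reported
as 0 for a single data point (no spread is estimable); data points and
distinct contributing samples are counted exactly.

## Segment maps

Windows of 500 kb with a 250 kb shift tile each chromosome
(windows [k·shift+1, k·shift+window], k = 0, 1, … while the window start
does not pass the last gene end); single-gene mode uses 12.5 kb / 6.25 kb
— below 20% of the 67 kb mean human protein-coding gene size, so a
window call is effectively a gene call. A locus belongs to every window
containing its **start** coordinate — deterministic, counts every locus
the same number of times (twice, past the first half-window), and
independent of gene length. Strand is ignored throughout.

Extreme loci are those at or beyond the empirical 2.5%/97.5% quantiles
(linear interpolation) of the genome-wide per-locus scalar — absolute
values in single maps, A/B ratios in differential maps. If the two
thresholds coincide (degenerate data) nothing is flagged.

Each non-empty window is tested in both tails with the hypergeometric
distribution: with M valued loci genome-wide of which m are extreme in
one direction, and k loci in the window of which x are extreme,
p = P(X ≥ x), X ~ Hypergeom(M, m, k). The window's reported p is the
smaller tail, carrying that tail's direction; this matches reporting a
single q per segment. Multiple-comparison correction is
Benjamini–Hochberg across all non-empty windows of one map (Bonferroni
is available via `correction="bonferroni"`); q is clamped to ≥ p. A call
requires q < 0.05 and ≥ `min_extreme` (default 3) extreme loci of the
called sign.

**Single-gene "prevails" rule.** With `min_extreme = 1` a window may
contain several loci; the call is retained only when the most-expressed
extreme locus of the called sign contributes more than 50% (configurable)
of the window's summed expression. The rule applies to both directions:
an underexpressed gene sharing its window with a well-expressed
neighbour cannot "prevail" and loses the call, which is the intended
conservative behaviour.

**Differential support filter.** In differential maps, a called segment
is demoted when any of its extreme loci has fewer than 5 data points in
either pool — single-platform artifacts with thin support are the main
source of spurious extreme ratios.

Overlapping windows are tested independently and never merged; reported
maps may therefore contain partially overlapping called segments.

## Downstream statistics

*Housekeeping screen*: value > 100 (above the genome mean), data points
≥ ⌈n_samples/2⌉, SD ≤ 30% of the mean; output sorted by ascending SD%.
The data-point bound uses the ceiling so that an odd sample count rounds
up (35 samples ⇒ 18).

*Phenotype association*: loci are filtered (≥ 5 data points in both
pools; SD < 200% in any pool whose value exceeds 50 — high spread is
tolerated near the detection floor; EST clusters `Hs.*` and `LOC*` IDs
excluded when ranking "known genes"), sorted by descending A/B ratio;
the top 25 vs next 25 form a 2×2 table of phenotype flags tested with a
**two-sided** Fisher's exact test. Two-sided is deliberate: on the
bundled thyroid table ([[8,17],[1,24]]) the two-sided p is 0.023 versus
0.012 one-sided, and the two-sided value is the published one.

*Between-map correlation*: Pearson on raw paired per-locus values, p
from the t distribution with n−2 d.f. Raw (not log) scale is used
throughout for comparability with the published correlations; note this
makes r top-gene-dominated (see Limitations).

## qPCR validation

Observed ratio OR = base^(Ct_ref − Ct_target) with base = 2 (100%
amplification efficiency; the base is exposed for sensitivity analysis
since practical efficiencies of 90–110% are accepted). Expected ratio
ER = map value of target / map value of reference. `validate()`
correlates raw (ER, OR) pairs over the panel, including the reference's
anchor pair (1, 1), and excludes (with reporting) genes undetectable by
PCR or absent from the map.

## Synthetic data generator

The generator emulates what the integration pipeline must survive:
multiple platforms with heterogeneous probe counts (defaults: coverage
0.95 with 1–4 probes/gene and coverage 0.60 with 1–2), per-probe
log-normal affinity constants (σ = 0.5), per-platform (σ = 0.5) and
per-sample (σ = 0.3) scale factors, multiplicative log-normal
measurement noise (σ = 0.3 natural-log, ≈ 31% CV), and a 1% fraction of
non-positive raw values. Base expression is log-normal (median 50,
log-sd 1.0 — a realistic 3-decade dynamic range). Planted features with
recorded ground truth: clusters of consecutive loci within one 500 kb
window multiplied by a fold (default 20) in condition A; housekeeping
genes with high mean (≈ 1.5 log-sd above the median) and 5% CV on all
platforms; hard on/off sex-biased genes (off factor 0.01, emulating
XIST/chrY behaviour); tissue-fold genes; and phenotype flags drawn with
probability decaying exponentially in tissue-fold rank so the
association test has planted signal. Annotations place genes with
exponential sizes (mean 67 kb, the mean human protein-coding gene size)
and gaps (mean 33 kb), giving roughly one locus per 100 kb so 500 kb
windows hold a handful of loci. Sample sexes alternate in platform-sized
blocks so sex is balanced across platforms rather than confounded with
them.

What the generator does **not** emulate: probe-sequence effects,
spatial array artifacts, cross-hybridization, correlated biological
covariation between neighbouring genes, and real platform-specific
response curves. Passing recovery tests therefore demonstrates that the
pipeline's statistics behave as designed under its own model, not that
the model captures every failure mode of real arrays.

## Problem sizes and study conditions

Tests and the acceptance script use 400–800 genes on 3–5 chromosomes
with 2 platforms; 10 samples per pool for recovery/housekeeping runs and
4 per pool for null-calibration runs; 20 seeds for every stochastic
property; sex-stratified maps use 6 male vs ~8 female samples. These are
scaled-down but structurally faithful versions of a realistic
meta-analysis (tens of samples, tens of thousands of loci), sized so the
whole suite runs in minutes on one core.

## Numerical choices

- Quantiles use numpy's default linear interpolation; loci exactly at a
  threshold are included in the tail.
- SD uses the n−1 denominator everywhere.
- BH q-values are clamped to be ≥ the raw p (monotonicity guarantee for
  the `q ≥ p` record invariant).
- Written tables render values at 2 decimals (p/q at 6 significant
  digits); write→read→write round trips are byte-identical.
- All generator randomness flows through `numpy.random.default_rng(seed)`;
  results are bit-for-bit reproducible per seed.

## Known limitations

- Raw-scale Pearson correlations are dominated by the most-expressed
  genes; a single discordant top gene moves r substantially. Log-scale
  correlation would be more robust but is not what the published
  comparisons report.
- The hypergeometric test treats loci as exchangeable; real co-regulated
  clusters violate independence under the null, making calls near
  co-expressed families anti-conservative in principle.
- BH across all non-empty windows is conservative in single-gene mode
  (thousands of windows, each with few loci); single-gene calls are
  reliable mainly through the prevails rule plus the data-point filter,
  and callers wanting the permissive behaviour can restrict the tested
  window set.
- Probe→locus ambiguity must be resolved upstream: a probe mapped to two
  symbols is rejected at load rather than split or duplicated.
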