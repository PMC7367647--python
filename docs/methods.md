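# Methods

## Coordinate frame

All coordinates are 0-based, half-open. The genome is tiled into fixed
200 kb bins (`bin_size` configurable), chromosome by chromosome in build
order; the last bin of each chromosome is the remainder. hg19 chromosome
sizes are packaged as data. Interval-to-bin membership uses the bin
*midpoint*, so a boundary that is not bin-aligned can never assign one bin
to two adjacent intervals. The packaged 29-segment liver-cancer panel is
bin-aligned (every boundary is a multiple of 200 kb); its two chr8 short-arm
segments (8pter−, 8p−) and the 200 kb gap between 10cen+ and 10q− are kept
exactly as published.

## Coverage model

A fragment is counted once, into the bin containing the leftmost mapped
coordinate of read 1 (or of the read itself for unpaired data). With
~300 bp cfDNA fragments and 200 kb bins, anchor choice is numerically
negligible, but it is fixed for reproducibility. Default filters: MAPQ ≥ 30,
duplicates excluded, proper pairs required. The coverage unit used
downstream is *relative coverage* — bin count divided by total usable
fragments — so per-sample depth differences cancel between samples and
controls, and the normalization is invariant under uniform depth scaling.
Screening-grade samples require ≥ 10 M usable fragments (QC-enforced,
overridable).

A GC correction (LOWESS of coverage against per-bin GC, divide-and-rescale)
is provided but **off by default**: the control-panel Z-score already
absorbs any bin-wise bias shared between samples and controls, and the
reference workflow this package implements applies none.

## Reference panel and Z-scores

The reference panel stores the per-bin mean and sample (n−1) standard
deviation of relative coverage over ≥ 2 healthy controls. A sample's
per-bin Z is `(x - mean) / sd`. Bins are masked (excluded from all
downstream statistics, not interpolated) when the control sd is zero at
float precision or the control mean falls below 10% of the genome-wide
median bin mean — without this, centromeric/telomeric dropout bins produce
infinities. Controls define the panel once; a sample is never normalized
against a panel containing itself. Sex chromosomes, when present, get
Z-scores but are excluded from screening by default, since mixed-sex
control panels would create sex-linked artifacts.

With *n* controls the empirical null of a bin Z is slightly heavier than
N(0,1) (variance ≈ (1 + 1/n)·(n−1)/(n−3) from mean- and sd-estimation
error; ~8% at n = 41). Leave-one-out tests assert |mean z| < 0.1 and
sd(z) ∈ [0.8, 1.2]; the idealized-null calibration of the 2.702 cutoff is
checked on exactly-standard-normal bins.

## Circular binary segmentation

For one chromosome's vector of unmasked bin Z-scores, the change-point
statistic of an arc (i, j] — the vector treated circularly — is the
pooled-variance two-sample t statistic between the bins inside the arc and
those outside. |t| is symmetric between a set and its complement, so
wrap-around arcs are redundant and the search space is all contiguous arcs
with both parts ≥ `min_width` (default 2) bins; the maximum is found by an
O(n²) vectorized scan. Near-ties (complementary arcs travel different
floating-point paths) are broken toward the smallest (i, j).

Significance is assessed by permutation: shuffle the sub-vector, recompute
the maximal arc statistic, and set

p = (1 + #{max |T*| **strictly greater than** |T_obs|}) / (n_perm + 1).

The strict inequality is deliberate: for discrete or noiseless inputs many
permutations *tie* the observed maximum (e.g. any permutation of a
two-level vector that happens to leave the levels contiguous), and
counting ties would make even a perfect split non-significant on short
vectors. For continuous data ties have probability zero, so the null
calibration — verified by simulation: rejection rate at α = 0.05 inside
the binomial CI — is unaffected. A degenerate sub-vector (max T = 0, i.e.
constant) is never split. Defaults: α = 0.05, n_perm = 10 000, with the
seed recorded in output metadata; inside the recursion an early-stopping
rule abandons a permutation run once enough exceedances have accumulated
to guarantee p ≥ α (this cannot change any accept/reject decision).

An accepted arc contributes at most two breakpoints (one when an arc
endpoint coincides with the sub-vector boundary); recursion continues on
the parts until no significant split remains, with a depth cap. Each
segment records the log10 permutation p of the split that created it
(0 for an unsplit chromosome) — note this per-sample quantity is bounded
below by log10(1/(n_perm+1)) and is *not* comparable to cohort-level
segment significance values, which can be far smaller. No smoothing,
outlier shrinking, or undo-splits pruning is applied; these are extension
points deliberately left out. Segment bp coordinates snap to the outer
boundaries of their terminal bins.

## Segment scoring and the screen

A panel segment spanning n usable bins is scored by Stouffer aggregation:
seg_mean = mean(z_b), Z = seg_mean · √n. Under the null each bin Z is
≈ N(0,1), so the segment Z is again ≈ N(0,1) *regardless of segment
length* — this is what lets one fixed cutoff (2.702, the ROC-optimized
screening threshold) apply to segments ranging from 13 to nearly 1000
bins, whereas the per-bin segment mean alone would be scale-dependent and
far below the cutoff even for real events. The cutoff is inclusive
(|Z| ≥ 2.702 is altered) and two-sided by default (`absolute` mode); a
`matched` mode requires the Z to cross the cutoff in the segment's
annotated gain/loss direction. A sample screens positive with ≥ 1 altered
segment; altered counts are also binned into the reporting categories
">=3" / "2" / "1" / "0". Segments with no usable bins are excluded and
reported as uncallable, never silently scored 0.

Screening normally uses the fixed 29-segment panel (the validation-phase
procedure); a `from-cbs` mode instead thresholds the sample's own CBS
segments, emulating the discovery phase. Longitudinal tracking orders
per-segment (timepoint, Z, call) triples without interpolation.

## Cohort statistics

Sensitivity and specificity are reported as exact integer ratios alongside
percentages. The ROC statistic per sample is max |panel segment Z|
(configurable); the curve sweeps observed values with ties grouped, AUC is
the trapezoid area (equal to the Mann-Whitney concordance probability —
asserted in tests against a hand-written U-statistic oracle), and the
optimal cutoff maximizes Youden's J with ties broken toward the smaller
cutoff. The exact Fisher 2×2 test reports the two-sided p (sum of
noncentral-hypergeometric point probabilities ≤ observed), the
conditional-MLE odds ratio (root of E_ψ[A] = a, found by bracketed
root-finding on the Fisher noncentral hypergeometric mean), and the exact
95% CI from inverting the one-sided tests at 2.5% per side; zero-cell
tables yield open one-sided intervals. The conditional MLE — not the
sample cross-product ratio — is the estimand exact-test software reports,
and is what reproduces the published 5.50 for the tumor-size table whose
cross-product ratio is 5.65. No multiple-testing correction is applied
across covariate tables, matching the source analysis. Missing covariate
values are tabulated as "NA" and excluded from tests, never imputed.

The packaged cohort summaries carry one documented inconsistency from the
source publication: the post-surgery follow-up category row sums to 10
positives of 29 samples while the running text twice states 9 of 29
(31.0%); the text ratio is treated as canonical for rate arithmetic and
the category row is preserved as printed.

## Simulator

The generator models plasma as a diploid admixture: with tumor fraction
tf and per-bin tumor copy number c_b, expected relative coverage is
∝ baseline_b · (1 + tf · (c_b/2 − 1)) · gc_bias_b, normalized to sum to
one. Counts are negative-binomial around depth · weight with dispersion
k = 50 by default (variance = μ + μ²/k; real cfDNA bins are overdispersed
relative to Poisson), or exactly multinomial in the k → ∞ mode used for
oracle math. Defaults mirror the screening study conditions: 10 M
fragments, 200 kb bins, uniform baseline; cohort simulation gives controls
tf = 0 and draws case events per panel segment at the panel's published
discovery frequencies, with earlier menu entries taking precedence if
drawn events would overlap.

What the simulator does **not** emulate: mappability/GC structure in the
baseline (available only via explicit per-bin vectors), fragment-length
and end-motif biology, subclonal heterogeneity, and within-sample
correlation of bin noise. Passing recovery tests therefore demonstrate
the statistical machinery under the stated noise model, not performance
on real plasma libraries. On reduced genome frames (e.g. chr1+chr8) the
sum-to-one closure of relative coverage makes large events visibly depress
neutral arms; on the full autosome frame the effect is much smaller but
never exactly zero.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately scaled problems chosen to
exercise every code path with tight Monte-Carlo error: CBS oracle
equivalence on 1000 random vectors of length ≤ 40 against exhaustive
enumeration; permutation-null calibration on 500 Gaussian chromosomes of
50 bins (n_perm = 199); leave-one-out calibration on 21 simulated controls
over a 600-bin frame; null call-rate calibration on ≥ 10 000 segment draws;
event recovery on seeded 30-control + 20-case cohorts over the chr1+chr8
frame at full 10 M depth. Stochastic assertions use binomial confidence
bands around the theoretical value; fixed seeds make every run
reproducible. Float-degenerate inputs (constant vectors, zero-variance
bins, all-masked segments) are handled by explicit guards rather than
tolerance-free arithmetic.

## Known limitations

- The 29-segment panel and the 2.702 cutoff are liver-cancer-specific and
  hg19-specific; no liftover is provided.
- Per-sample CBS logP values are permutation-bounded and not comparable to
  cohort-level significance.
- The screen is binary at a fixed cutoff; no tumor-fraction estimate is
  produced (ichorCNA-style quantification is out of scope).
- Sensitivity at tumor fractions well below ~1% is limited by bin-count
  overdispersion, not by depth alone.
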