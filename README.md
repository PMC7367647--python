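# plasmacin

Chromosomal-instability (CIN) screening of plasma cell-free DNA from
low-pass whole-genome sequencing.

Tumors shed DNA into the bloodstream, and that DNA carries the tumor's
copy-number profile. At arm-level resolution this footprint is detectable
at very shallow sequencing depth: ~10 M read pairs counted into fixed
200 kb bins are enough to see whole-arm gains and losses at tumor
fractions of a few percent. `plasmacin` implements the complete analysis
path for this kind of liquid-biopsy screen, with primary liver cancer as
the packaged application:

1. **Coverage** — count usable fragments per 200 kb bin of hg19 from an
   alignment file (or load a precomputed count table), with MAPQ,
   duplicate and proper-pair filters and depth QC.
2. **Normalization** — convert a sample's per-bin relative coverage
   *x<sub>b</sub>* into a Z-score against a panel of healthy controls:

   *z<sub>b</sub>* = (*x<sub>b</sub>* − mean<sub>controls</sub>(*x<sub>b</sub>*)) / sd<sub>controls</sub>(*x<sub>b</sub>*)

3. **Segmentation** — from-scratch circular binary segmentation (CBS):
   recursively split each chromosome at the arc maximizing the two-sample
   t statistic between arc and complement, accepting a split when its
   permutation p-value is below α = 0.05.
4. **Scoring & screening** — aggregate bin Z-scores over a packaged panel
   of 29 recurrently altered liver-cancer segments (1q+, 8q+, 17p−, …) by
   Stouffer's rule, *Z* = mean(*z*) · √*n*; a segment is altered when
   |*Z*| ≥ 2.702 (the ROC-optimized cutoff), and a sample screens
   **positive** with at least one altered segment.
5. **Cohort statistics** — sensitivity/specificity with exact ratios,
   ROC/AUC with Youden-optimal cutoff, exact Fisher 2×2 tests with
   conditional-MLE odds ratios, covariate cross-tabulations, and
   longitudinal per-segment Z tracking for post-surgery follow-up.
6. **Simulator** — seeded negative-binomial generator of bin-count
   profiles and whole cohorts with known copy-number truth, so every
   stage is testable without patient data.

## Worked example

`examples/01_simulate_and_screen.py` simulates a 20%-tumor-fraction case
carrying 1q and 8q gains plus 30 healthy controls on a chr1+chr8 frame,
builds the reference, and screens the case:

```
sample case_000: POSITIVE screen, 4 altered segments (category >=3)
  1p-      n_bins= 725 seg_mean= -0.334 Z=    -8.98 ALTERED
  1q+      n_bins= 519 seg_mean= +0.323 Z=    +7.35 ALTERED
  8q+      n_bins= 512 seg_mean= +0.304 Z=    +6.89 ALTERED
  8p-      n_bins= 177 seg_mean= -0.322 Z=    -4.28 ALTERED
  8pter-   n_bins=  34 seg_mean= -0.283 Z=    -1.65
```

Each Z is standard normal for a healthy sample, so the simulated gains
stand out by many standard deviations and the sample screens positive.
(The neutral arms drift negative here because relative coverage sums to
one; on the full autosome frame that closure effect is far smaller.)

The other examples cover CBS on a synthetic chromosome, cohort-level
ROC/AUC, and the bundled published cohort summaries. A thin CLI wraps the
same library: `plasmacin count | reference | segment | screen | simulate |
cohort-stats | demo` (see `plasmacin --help`; `plasmacin demo --outdir d`
runs a seeded 30-control + 5-case toy pipeline end to end).

## Layout

- `src/plasmacin/` — the library (`genome`, `coverage`, `normalization`,
  `segmentation`, `scoring`, `cohort`, `simulate`, `cli`)
- `src/plasmacin/data/` — hg19 chromosome sizes, the 29-segment panel,
  published cohort count summaries
- `docs/methods.md` — model, assumptions, parameter choices, limitations
- `examples/` — narrative scripts, one per capability
- `tests/` — pytest suite (unit, property-based, end-to-end)
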