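# Methods

## Scope and model

`divscan` implements the downstream analysis of a small case/control
whole-genome resequencing design: per-site allele frequencies feed a
windowed differentiation scan, window read counts feed a copy-number
analysis, per-base depth feeds a region presence test, and annotated
gene lists feed an over-representation test. The cohort model throughout
is two labeled pools of diploid samples (defaults: 2 cases, 6 controls);
no pedigree, linkage or haplotype structure is used anywhere, so none is
simulated.

## Windowed Fst / ZFst scan

* **Estimator.** Hudson's two-population estimator in per-site
  numerator/denominator form, combined per window as a ratio of sums.
  This choice is deliberate for tiny pools: at n = 4 alleles per group,
  averaging per-site ratios is badly behaved, while the ratio-of-sums
  form is the standard recommendation for windowed scans. A
  Weir–Cockerham per-site form (haploid allele-count version, r = 2) is
  available via `estimator="wc"`; both give Fst = 1 at fixed
  differences. Sites with fewer than 2 called alleles in either group
  are skipped; sites monomorphic and identical in both groups contribute
  (0, 0).
* **Windows.** Non-overlapping tiles of `window_size` (default
  150,000 bp) laid from coordinate 1 with 1-based inclusive ends, so a
  window spans exactly `window_size` bases. Windows with no usable SNP
  are absent; windows with fewer than `min_snps` (default 10) SNPs or a
  zero summed denominator are kept in the table but excluded from the
  Z-transform. `min_snps` exists because a one-SNP window can otherwise
  dominate the standardized tail.
* **ZFst and the top 1%.** ZFst standardizes window Fst over retained
  windows (sd with n − 1). The candidate threshold is the k-th largest
  ZFst with k = max(1, ⌊top_fraction · n⌋); ties at the threshold are
  all flagged. "Top 1%" has no unique definition; the order-statistic
  rule with inclusive ties is the one used here and tested.
* **Annotation.** A gene is reported for a window when their 1-based
  inclusive intervals share at least one base.

## CNV calling and Vst

* **Normalization.** `normalized_cn[w, s] = 2 · counts[w, s] /
  median_w(counts[·, s])` puts every sample's genome-wide median at
  diploid. The median (not mean) keeps large CNVs from shifting their
  own baseline. Optional GC correction divides each window by its GC
  decile bin's median over 2, re-centering every bin at CN 2.
* **Initial calls.** Maximal runs of ≥ `min_windows` (default 3)
  consecutive windows in which *any* sample is ≥ 2.75 (gain) or ≤ 1.25
  (loss). The thresholds sit beyond half-copy deviations at the
  default 100× window depth (Poisson noise sd ≈ 0.2 CN units) and are
  exposed as configuration. Calls are delimited on window starts; a
  run's interval is first-window start to last-window end.
* **Merging.** Adjacent same-chromosome calls merge when the gap is
  strictly less than 20% of their combined length *and* the Pearson
  correlation of their per-sample mean copy-number vectors is
  significant at p < 0.01 (two-sided, n = samples). Merging sweeps
  left-to-right to a fixed point; with fewer than 3 samples the
  correlation test is undefined and the distance rule decides alone
  (logged). Constant profiles have undefined correlation and do not
  merge. The merged span (gap windows included) supplies the region's
  estimates.
* **Genotyping.** Per-sample copy number is the mean normalized CN over
  the region's windows, rounded half-away-from-zero (2.5 → 3; stated
  because 2.5 is a live boundary), then coded 0→D, 1→Ad, 2→AA, 3→AB,
  4→BB, ≥5→M.
* **Vst.** Per-sample intensity is the mean over windows of
  log₂(CN/2), with CN floored at 0.05 before the log so homozygous
  deletions stay finite. Vt is the population variance (divide by N) of
  all samples' intensities; Vs the *size-weighted* mean within-group
  variance, (n₁V₁ + n₂V₂)/N. Size weighting is chosen because the law
  of total variance then guarantees Vst ∈ [0, 1]; an unweighted mean
  (offered via `weighted=False`) can leave the unit interval with
  unequal group sizes, and a test documents this. Vst is invariant to
  constant shifts and to swapping the group labels.
* **Candidate filter.** length > 2000 bp and Vst > 0.25, both strict.
  Sex chromosomes and unplaced scaffolds are excluded from candidate
  reporting by default (X dosage confounds with sex in a mixed cohort);
  a flag re-includes them.

## Region presence test

Per-base depth over the queried interval is normalized by the sample's
genome-wide mean depth computed *excluding* the interval — on a small
simulated genome a true deletion would otherwise dilute its own
baseline. Verdicts: ratio < 0.05 "absent" (the operational form of
"essentially zero" coverage), < 0.75 "heterozygous loss", else
"present". The heterozygous band is this package's addition (a
single-copy carrier sits near 0.5); both thresholds are configurable.
Verdicts are monotone in depth by construction. A helper computes
interval lengths under both the inclusive (end − start + 1) and
difference (end − start) conventions, since both appear in genomic
coordinate reporting and differ by one.

## SNP accounting

Site filters: depth strictly greater than 4 ("reads > 4") and quality
≥ 20 (inclusive) — the operators differ on purpose and are tested at
their boundaries. The depth filter is applied per site (site-level
INFO/DP); a per-sample reading of the same rule would need genotype-level
depths, which the minimal VCF does not carry. Classification uses
unordered ref/alt pairs; A/G and C/T are transitions. Report percentages
round to one decimal.

## Enrichment

Upper-tail hypergeometric p per term (P(X ≥ k) for k observed query
genes in a term of size K, query n, background N), BH step-up across
all tested terms, significance flags at raw and adjusted p < 0.05. BH
is the FDR procedure of choice absent any stated alternative; only
over-representation is tested. The background defaults to the union of
the term sets and is configurable; query genes outside it are dropped
with a log line. Ortholog mapping between species is a user
responsibility — the term map is an input.

## Synthetic cohorts

The generator emulates the study conditions the pipeline assumes:

* 2 cases vs 6 controls; genotypes binomial(2, p) under within-group
  Hardy–Weinberg from a shared Beta(0.8, 0.8) baseline frequency
  (U-shaped site spectrum). Planted sweep intervals override the two
  groups' frequencies independently; a fixed difference (1.0 vs 0.0) is
  the maximal signal. Sites are independent — no linkage — because every
  consuming statistic uses site frequencies only.
* Window counts are Poisson with mean `mean_depth_per_sample · CN/2`
  (default 100 reads per 800 bp window) on the same 800/400 sliding
  grid the CNV stage reads; counts are generated directly at window
  level rather than via simulated reads, matching what the consumers
  parse. Optional GC bias draws a per-window GC fraction Beta(5, 5) and
  multiplies depth by 0.6 + 0.8·GC.
* The per-base deletion track uses a separate `track_mean_depth`
  (default 15, a mid-range per-base coverage for this kind of study)
  so one config can drive both the window matrix and the track without
  a units clash; affected samples scale by `residual_depth_fraction`
  inside the interval.
* VCF is minimal VCFv4.2 (GT format, INFO/DP, QUAL fixed at 60 with an
  optional low-QUAL fraction for filter tests, no file date). One
  master seed drives labeled sub-streams (CRC32 of a stream label mixed
  into a SeedSequence), so identical (config, seed) pairs are
  byte-identical and each file is reproducible in isolation.
* Validation rejects planted intervals that leave the genome or overlap
  each other on a chromosome, naming the offending pair.

What the generator does **not** model: sequencing error, mapping bias,
linkage disequilibrium, overdispersed coverage, batch effects. Passing
recovery tests therefore demonstrates correctness of the statistics and
plumbing under their own assumptions, not robustness to real-data
artefacts.

## Problem sizes and determinism

The shipped tests and the acceptance script run at desk scale, chosen so
every stochastic check has comfortable statistical margin: sweep
recovery uses 20 replicates of ~300 × 150 kb windows (~18k SNPs each),
CNV pattern recovery 20 replicates of a 200 kb chromosome at 100×,
the enrichment null calibration 1000 replicates of 50 size-100 terms in
a 1000-gene background (achieved type-I rate ≈ 0.046 against the
nominal 0.05), and the deletion fixture one 40 kb chromosome at 10×.
All randomness flows from explicit seeds; reruns are byte-identical.

## Known limitations

* The Fst estimator at 2 diploids per group has high per-site variance;
  only window-level ratios are interpretable, and the scan reports
  relative (top-tail) rather than absolute significance.
* Absolute copy numbers beyond ~4 compress in the genotype codes (M);
  the caller is not designed for high-copy repeats.
* The merge rule's fixed-point sweep is order-dependent in principle;
  equivalence with an all-pairs brute-force merge is verified over
  randomized instances rather than proven.
* The presence test assumes roughly uniform mappability across the
  queried interval; a real low-mappability region would mimic loss.
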