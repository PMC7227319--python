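# Methods

## Model

Each target CpG (a *model locus*, covered by EPIC but not by the 450K chip)
gets its own regression on the beta values of 1–3 *feature loci* (CpGs on
both chips). The default family is a logistic curve on the beta scale,

    beta_i = sigmoid(w_i · x + b_i),

treated as a fractional-response binomial GLM: the observed betas (clipped to
[1e-6, 1 − 1e-6]) enter the binomial deviance directly, and the fit is by
iteratively reweighted least squares (tolerance 1e-8 on the max coefficient
change, at most 100 iterations). This choice reduces to ordinary logistic
regression when the responses are binary, keeps predictions in (0, 1) by
construction, and matches the interpretation of a beta value as a methylation
probability. The objective is convex, so the solution does not depend on
initialization; refits from different tolerances agree to ~1e-8. An ordinary
least-squares family is provided for comparison; its predictions are clipped
to [0, 1] at predict time, never at fit time.

Feature selection is deliberately minimal and is computed on training samples
only:

* **co-methylated locus** — the feature locus maximizing cross-sample Pearson
  correlation with the target, searched genome-wide with no distance cap
  (co-methylated partners are frequently distal, so a window restriction
  discards signal). Pairs with fewer than `min_samples = 30`
  pairwise-complete observations or zero variance on the overlap are
  ineligible.
* **nearest neighbour** — the same-chromosome feature locus at minimal
  base-pair distance, optionally capped (e.g. 2 kb), in which case a locus
  may have no neighbour.
* **sequence match** — maximal Pearson correlation between 340-dimensional
  k-mer frequency vectors of the 200 bp flanking windows (all 1- to 4-mers,
  4 + 16 + 64 + 256 = 340; each k-block is normalized by the count of valid
  windows of that k, windows containing N are dropped). The flanking window
  convention is [pos − 200, pos + 201] (1-based inclusive, the CpG
  dinucleotide at [pos, pos + 1]), clipped at chromosome ends without
  padding; the window includes the CpG itself.

All argmax selections are deterministic: exact score ties break by smallest
genomic distance to the target (when coordinates are available), then by
lexicographically smallest probe ID. The vectorized correlation scan uses the
same one-pass masked-sums formula as the scalar routine, so chunked and naive
scans are bit-identical.

The default feature mode uses the co-methylated locus alone. Every additional
feature requires one more non-missing input per sample, so the number of
predictable (locus, sample) cells is non-increasing in the feature count;
with typical array missingness the loss is substantial, which is why the
single-feature model is the shipped default despite a marginal accuracy gain
from extra features.

## Cross-validation, metrics and categories

Samples with a complete (target, features) row — at least
`min_fit_samples = 30` of them — are partitioned into 5 seeded folds
(uniform random permutation, no stratification). Out-of-fold predictions are
pooled and summarized once per locus: Pearson R, RMSE, MAE on the continuous
scale, and sensitivity, specificity, accuracy, MCC and AUC after binarizing
at beta > 0.5 (observed status is truth; SE = TP/(TP+FN), SP = TN/(TN+FP)).
AUC is the Mann–Whitney rank statistic with midrank tie handling. When the
observed statuses are a single class, the undefined classification metrics
are reported as missing (NaN), never silently zero; categorization uses RMSE
only, so such models remain usable. The shipped coefficients are refit on all
complete training rows; the category comes from the pooled CV RMSE:
super_high < 0.05 ≤ high < 0.1 ≤ medium < 0.15 ≤ low.

## Preprocessing

Beta matrices are quantile-normalized before analysis, within-cohort: the
reference curve is the mean of sorted per-sample values over probes complete
in every sample. Samples with missing entries are ranked on their non-missing
values and mapped onto the reference by linear interpolation of quantile
positions; tied values receive the mean of the reference quantiles at their
tied ranks (average-rank convention). For complete data this is ordinary
quantile normalization — idempotent, and every output column has the same
sorted values. Prediction inputs are normalized independently per matrix
(`pretimeth predict --normalize`); no joint renormalization across chips is
performed.

## Differential methylation

Per probe, Welch's unequal-variance t-test compares the two sample groups
(each needs ≥ 2 non-missing values and a finite pooled variance; other probes
are skipped and excluded from the multiple-testing family). p-values get
Benjamini–Hochberg step-up correction over the probes actually tested. A DML
requires both q < 0.05 and |Δβ| > 0.1, where Δβ is the signed group1 − group2
mean difference (group1 carries tumor semantics; direction is *hypo* when the
group1 mean is lower). Gene-region annotation uses 5'→3' priority
(TSS200 > TSS1500 > 5'UTR > 1stExon > Body > 3'UTR > Intergenic) for
per-probe summaries, but DMG membership intentionally uses the raw per-gene
(gene, category) pairs: prioritization collapses multi-gene probes, while the
promoter definition (TSS200 ∪ TSS1500 ∪ 5'UTR ∪ 1stExon) is per gene. Batch
correction is out of scope; the CLI accepts pre-corrected matrices.

## Synthetic studies

The generator plants known structure so every stage has a checkable truth:

* feature-locus betas are i.i.d. from 0.4·Beta(0.5, 8) + 0.4·Beta(8, 0.5) +
  0.2·Beta(2, 2), the bimodal-plus-intermediate marginal typical of array
  data;
* each model locus follows sigmoid(w·x + b) on its planted partner plus
  Gaussian noise on the beta scale, clipped to [0, 1] (RMSE is evaluated on
  the beta scale, so noise is added there too). Default slopes are
  w ~ U(1.5, 2.5) with b = −w/2, keeping the noiseless response in roughly
  [0.18, 0.82] so clipping does not materially censor the noise and the
  planted sd remains recoverable from CV RMSE;
* per-locus noise sds cycle through {0.02, 0.07, 0.12, 0.2}, one level per
  accuracy tier;
* manifest coordinates exercise all neighbour-search regimes (partner within
  2 kb, distal on the same chromosome, different chromosome); flanking
  sequences of model loci are mutated copies (per-base rate 0.05) of their
  partner's window, other sequence is i.i.d. uniform;
* missingness is uniform at random at a configurable rate; grouped fixtures
  plant a mean shift of ±δ/2 per group on the first `n_effect_loci` probes
  with noise sd 0.05 around locus means drawn from U(0.35, 0.65).

What the generator does **not** emulate: probe-type chemistry and dye bias,
detection p-values, spatially structured co-methylation blocks, batch
effects, cell-type composition, and realistic LD-like correlation among
non-partner loci. Passing tests therefore demonstrate correctness of the
algorithms and calibration of the statistics under the stated model, not
performance on real arrays.

## Problem sizes and numerical choices

Tests and the acceptance script run planted studies at desk scale — tens of
loci, 40–260 samples, 1000 probes for the null-calibration study — chosen so
the statistical assertions (noise-floor recovery within ±0.02, type-I rate in
[0.03, 0.07], tier recovery ≥ 90%) have comfortable margins under their
binomial/χ² sampling noise. Degenerate inputs are rejected loudly: constant
features, rank-deficient designs, < 30 complete pairs, samples with no
observed values, p-values outside [0, 1], negative RMSE. Model files are JSON
lines with a schema-version header; coefficients round-trip at full double
precision.

## Known limitations

* Fractional-response logistic fitting assumes a monotone single-index link;
  loci whose relationship to their best partner is non-monotone will land in
  low tiers rather than being modelled better.
* The min-30-sample floors make small cohorts unusable by design.
* Quantile normalization with heavy missingness leans on the complete-probe
  reference curve; with very few complete probes the curve is noisy (and with
  none, the operation refuses to run).
* Cross-chip application assumes the feature-locus measurements are
  comparable after per-matrix quantile normalization; systematic platform
  shifts are not modelled.
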