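# Methods

## Model and assumptions

The screen is a logistic regression on binary mutation indicators over a
fixed panel of clonal-hematopoietic (CH) mutations:
`logit(p) = β₀ + Σ βᵢ xᵢ` with `xᵢ = 1[VAFᵢ > cutoff]`. Each coefficient is
a log odds-ratio (LOR) for carriage of one mutation, controlling for the
rest of the panel. The model assumes mutation indicators act additively on
the log-odds scale; no interactions, no per-cohort terms. Batch effects are
addressed by design (multi-cohort splits, unweighted batch-average model
selection), not by covariates — formal batch-correction methods are out of
scope.

The fit minimizes the class-weighted, L2-penalized negative log-likelihood

```
Σᵢ w_{yᵢ} [ −yᵢ ln pᵢ − (1−yᵢ) ln(1−pᵢ) ] + (λ/2)‖β‖² ,
```

intercept unpenalized. The optimizer is scikit-learn's deterministic
L-BFGS solver (`C = 1/λ`); the objective above, not the solver, is the
contract, and a statsmodels GLM cross-check on unpenalized toy data guards
it in the test suite. The `converged` flag is set from the iteration count
reaching the solution within `max_iter`; the inf-norm of the objective
gradient at the solution is recorded on the model (`grad_inf_norm`) for
diagnostics rather than used as the flag, because the solver's internal
scaled stopping rule does not map one-to-one onto a raw gradient threshold.

## Discovery cascade

Three stages, in order: protein-altering consequence filter; blood VAF
strictly inside the open CH window (default (0.02, 0.25)) with any called
tumor presence in the same patient; then four pathogenicity criteria
(tumor-cohort frequency > 0.05, population frequency < 1e-4, expression in
≥ 1% of cells of at least one immune cell type among B / T / NKT /
monocyte-macrophage, SIFT < 0.05 **and** PolyPhen > 0.446). All
comparisons are strict, so values exactly at a threshold fail. Tumor-side
presence requires only a called variant (VAF > 0) because a tumor VAF
threshold is not part of the selection logic; it is configurable
(`PanelConfig.tumor_vaf_min`). Tumor-cohort frequency counts distinct
carriers at any called VAF, not only carriers inside the CH window (also
configurable by filtering the call table first). A missing annotation is an
error, never treated as a failed criterion — silently defaulting population
frequency to zero would inflate the panel.

## Synthetic cohort generator

The generator emulates the structure of a multi-cohort exome study:

* **Variant classes.** `germline_common` (population frequency 0.01–0.5,
  VAF ~ truncated Normal(0.5, 0.03) on (0.3, 0.7) in both tissues),
  `somatic_private` (tumor VAF U(0.05, 0.40), blood detection at most in
  the ctDNA range < 1%), `ch_passenger` and `ch_pathogenic` (blood and
  tumor VAF U(0.021, 0.249), strictly inside the open CH window so
  boundary comparisons are unambiguous). Blood and tumor VAFs of a CH clone
  are drawn independently within the window; how they co-vary in real
  clones is unknown, and no claim is made.
* **Planted panel.** Exactly `panel_size` variants satisfy all four
  pathogenicity criteria by construction; among the CH passengers at least
  one fails each criterion individually, so each filter has a
  discriminating test case (this forces `panel_size ≤ n_variants − 4`).
  Panel carriage in the cancer class is U(0.12, 0.45) — comfortably above
  the 5% tumor-frequency criterion so that sampling noise at a few hundred
  patients cannot push an empirical frequency below threshold — and the
  non-cancer prevalence is derived from a per-mutation LOR of ±U(0.5, 2.5),
  mirroring the large carriage-fraction differences reported for real
  panels. Under class-conditional independence these prevalences imply an
  exact logistic model whose coefficients are those LORs; `beta0_true` is
  the equal-prior Bayes intercept.
* **Depth censoring.** Observed VAF is `alt/depth` with
  `alt ~ Binomial(depth, VAF)`, zeroed below `min_alt_reads = 3` (a common
  caller floor). Cohort mean depths span 36–457×, the range of the
  18-cohort demo topology; at 36× a 3% clone is detected with probability
  ≈ 0.09, at 457× ≈ 1.0, which reproduces the depth-driven batch effect.

What the generator does **not** emulate: read-level errors, alignment and
calling artifacts, germline contamination of somatic calls, correlated
mutation carriage, demographic structure, or protocol differences beyond
mean depth. Because all 98 planted effects are nonzero and independent, the
panel is collectively almost fully separating: test accuracy on the demo
conditions sits near 100%, so passing end-to-end tests demonstrates the
machinery (recovery, selection, bookkeeping, calibration), not the
real-data operating point of any published screen.

## Study design and statistics

* **Splits.** Development cohorts split with held-out fractions rounding
  up: `n_test = ceil(n·0.25)`, then `n_val = ceil((n−n_test)·0.25)`; this
  is the unique rounding consistent with every published development-cohort
  triple (e.g. 163 → 91/31/41, 4 → 2/1/1). Non-development cohorts are
  wholly test. Cohorts are label-pure; mixed-label cohorts are rejected
  rather than supported.
* **Model selection.** Grid over 31 cutoffs × hyperparameter options,
  scored by unweighted batch-average validation accuracy. Ties break
  toward fewer nonzero coefficients, then the lexicographically smallest
  configuration key. Configurations that fail to fit are logged and
  skipped. The winning configuration is refit on train + validation with
  the identical objective before testing.
* **Proportion CIs.** Wald normal approximation
  `p̂ ± z₀.₉₇₅ √(p̂(1−p̂)/n)` with the exact quantile 1.959964 (the rounded
  1.96 does not reproduce published bounds to two decimals), clipped to
  [0, 1].
* **Coefficient inference.** Row bootstrap (samples with replacement,
  B = 1000 by default), refit per resample; SE is the resample standard
  deviation, `z = β̂/SE`, CI `β̂ ± 1.96·SE`, two-sided normal p-value.
  Single-class resamples are redrawn and counted; more than B/2 redraws
  aborts. P-values are reported raw (a Benjamini–Hochberg column is
  emitted alongside but does not drive the significance flag).
* **AUC.** Tie-corrected Mann–Whitney rank statistic, equal to
  `P(score_cancer > score_noncancer) + ½P(tie)` over all pairs.

## Problem sizes

Defaults are chosen to mirror the study shape while staying desk-scale: a
500-variant catalog with 98 planted panel mutations, 600 discovery
patients, and the 18-cohort screening topology (1,992 samples; 648 train /
221 validation / 1,123 test). The default grid is 31 cutoffs × 2 class
weightings = 62 logistic fits; the full pipeline runs in well under a
minute on one CPU. Bootstrap-heavy steps in tests and the acceptance script
use B = 120–300 resamples; the library default remains B = 1000.

## Known limitations

* Strict-threshold semantics mean values exactly at a cutoff (e.g. VAF
  exactly 0.02) are excluded; real pipelines may want inclusive bounds.
* The bootstrap SE is undefined for coefficients pinned to zero by strong
  regularization; z is reported as 0 (with SE 0) in that degenerate case.
* The ">50% degenerate resamples" abort can only trigger under extreme
  class imbalance; with both classes present at n ≥ 3 the single-class
  resample probability is bounded near 0.37.
* The VCF reader is a convenience mapping (AF/DP fields, tumor-first
  sample order); the canonical interchange format is the MAF-like TSV.
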