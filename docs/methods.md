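# Methods

## Data model and preprocessing

A profile matrix holds clone x serum spot intensities. Raw scanner
output is integer-valued on [0, 255] with every clone spotted in
duplicate; cells where no spot could be quantified are NA. The matrix
moves through four monotone stages:

1. **raw_duplicates → averaged.** Duplicate spots are averaged per
   clone; a cell is the mean of its available duplicates and stays NA
   only when both are missing.
2. **averaged → filtered.** Clones with strictly more than `max_na`
   (default 10) NA values across sera are excluded. The strict reading
   ("more than ten") means a clone with exactly 10 NAs is retained.
3. **Imputation.** Clones that survive the filter carry at most
   `max_na` NAs. Each is filled with the clone's mean intensity over
   sera of the same treatment cohort — the choice that leaves per-clone
   reactivity frequencies unbiased. If an entire cohort is missing for a
   clone, the clone's overall mean is used.
4. **filtered → normalized.** Standard quantile normalization: each
   column (array) is mapped onto the across-array mean of order
   statistics, so every array shares one intensity distribution and
   array-level scale/offset effects vanish; within-array rank order is
   untouched.

With 1,827 clones and 308 exclusions, 1,519 clones remain. (The source
counts for this design quote 1,520 reactive clones against
1,827 − 308 = 1,519; the two printed numbers cannot both be exact. The
pipeline reports whatever its filter produces and does not force either
count.)

**Tie handling in quantile normalization.** On an 8-bit integer scale
ties are pervasive. Tied entries within a column receive the mean of the
reference values over their tied rank span. Consequences worth knowing:
with ties, different columns can end up with slightly different sorted
value vectors (each column averages over its own tie spans), and the
transform is no longer exactly idempotent. On continuous (tie-free) data
the defining properties hold exactly: all columns share one sorted
vector, ranks are preserved, and normalizing twice equals normalizing
once, which is what the property tests assert.

**TSV dialect.** Tab-separated, UTF-8, header row, clone IDs in the
first column, NA as empty field. Readers accept decimal commas (as
printed in some source tables) and normalize them to points. A
`.meta.json` sidecar records the stage so round-trips are lossless.

## Seroreactivity profiling

A clone is *reactive* with a serum when its normalized intensity is
strictly above the threshold (default 50). Per-group reactivity
frequencies are kept as exact integer counts (reactive sera / group
size) so decile binning never suffers floating-point edge effects. The
histogram bins follow the printed-label convention
(0.00–10.00, 10.01–20.00, …): bin *k* covers ((k−1)/10, k/10] with 0
included in the first bin, computed in integer arithmetic as
⌈10·reactive/n⌉. The high-reactivity overlap report lists in-frame
clones with frequency strictly above the cutoff (default 0.9) in either
group, with the clone's frequency in the other group alongside.

## Clone informativeness (ROC/AUC)

For one clone with WT intensities *x* and NB intensities *y*, a decision
threshold *h* sweeps over all distinct pooled values (plus a sentinel
beyond the maximum). At each *h*: WT sera with value ≥ *h* are true
positives, otherwise false negatives; NB sera with value ≥ *h* are false
positives, otherwise true negatives. The AUC is the trapezoidal area
under the (FPR, TPR) curve. By the standard ROC identity this equals the
pair-counting statistic P(X > Y) + ½·P(X = Y); the test suite verifies
the equivalence to 1e−12 against an exhaustive pair loop, and both
routes are kept in the API (`clone_auc` is the sweep, `rank_auc` the
rank-sum cross-check).

Clones with AUC < 0.3 are called NB-reactive and AUC > 0.7 WT-reactive;
both are *informative*. The cut-offs are raw AUC rules, deliberately not
multiplicity-adjusted; Benjamini–Hochberg q-values are reported next to
the raw two-sided Mann–Whitney p-values for modern context. The p-value
is exact — complete enumeration of all C(n₁+n₂, n₁) group assignments,
which handles ties correctly — when both groups have ≤ 8 sera, and the
normal approximation with tie and continuity correction otherwise. (The
attribution of p-values to AUCs assumes the rank-sum test, since the AUC
is its rescaled statistic; no other test fits the reported pairing.)
Fold change is the ratio of group mean intensities (NB/WT), computed on
normalized intensities by default, NA when the WT mean is zero.

The AUC decile distribution uses lower-closed bins [0, 0.1) … [0.9, 1.0]
with the top bin closed — the only partition consistent with decile
labels at both ends of the scale.

## Classification

A linear-kernel SVM (C = 1, no inner tuning — no hyperparameter search
is part of the procedure; no feature scaling beyond quantile
normalization) classifies sera on the filtered, normalized clone set.
Performance is estimated by 20 repetitions of stratified 10-fold
cross-validation; stratification guarantees both classes in every
training split for the unbalanced 30-vs-53 regime. Within each
repetition every serum is predicted exactly once and the confusion
counts are pooled; accuracy, sensitivity and specificity are averaged
over repetitions with 95% CIs computed as mean ± 1.96·sd/√20 — the
simplest reading of a CI on repeated CV. PPV, NPV and likelihood ratios
come from the confusion counts pooled over all repetitions
(prevalence-bearing), with the conventions LR+ = sens/(1−spec) (= +∞ at
perfect specificity) and LR− = (1−sens)/spec (NA at zero specificity).
The positive class is WT, matching the ROC convention; swapping it swaps
sensitivity↔specificity and PPV↔NPV exactly.

Note on published likelihood ratios for this study design: printed
sens/spec pairs reproduce the negative likelihood ratios to 3 d.p.
((1−0.870)/0.867 = 0.150; (1−0.817)/0.860 = 0.213), but the printed
positive likelihood ratios do not equal sens/(1−spec) of the printed
rounded rates (0.870/0.133 = 6.54 vs 6.525 printed) — presumably they
were computed on unrounded internal values. The package therefore
asserts only the LR− arithmetic.

**Permutation (overtraining) runs.** Each of the 20 null runs permutes
the class labels once (class sizes preserved) and executes one full
stratified 10-fold CV; the run's pooled accuracy estimates chance
performance. The empirical p-value for an observed accuracy is
(1 + #{null ≥ observed}) / (runs + 1), so 1/21 ≈ 0.048 is the smallest
attainable value with 20 runs.

## Synthetic cohort generator

The generator defines the test bed and its defaults are the study
conditions: 1,827 clones (509 in-frame) in duplicate, 30 group-A (NB)
vs 53 group-B (WT) sera, 16 planted A-reactive markers with a +80
intensity shift, 308 clones planted to fail the NA filter.

Latent model, per clone *c* and serum *s*:

* prevalence p_c ~ Beta(κm, κ(1−m)) with mean m = 0.5 and concentration
  κ = 8 — unimodal around 50%, matching the observed hump-shaped
  reactivity-frequency histogram;
* baseline b_c = 50 + σ_serum·Φ⁻¹(p_c), so that
  P(latent intensity > 50) = p_c by construction;
* latent intensity = b_c + effect·1[c planted, s in group A] +
  N(0, σ_serum) + array offset N(0, σ_array);
* duplicate spots are two draws latent + N(0, σ_dup), rounded and
  clipped to [0, 255].

Free parameters without a stated empirical value were fixed once at
field-realistic magnitudes: σ_serum = 25 (gives prevalences a broad
unimodal spread on the 0–255 scale), σ_dup = 5 (duplicate spots of one
array agree closely), σ_array = 8 (modest array-to-array offset — the
magnitude of inter-array technical variation is a simulator parameter,
not an empirically derived one; quantile normalization removes it
regardless). Planted effects are mean shifts, not variance changes,
matching how differential seroreactivity is described (fold changes of
group means).

Missingness: a clone's spot pair is unreadable on a given array with
probability `na_rate` (default 0.01); counts are Binomial(n_sera,
na_rate) capped at `max_na` for background clones, while the
`n_excluded_target` planted clones draw a count uniformly above
`max_na` — so the exclusion filter removes exactly the planted number.
The cap essentially never binds at the default rate (P ≈ 10⁻¹⁴ of a
Binomial(83, 0.01) draw exceeding 10), and the empirical NA rate matches
`na_rate` within sampling error. Planted markers are never NA-excluded
clones, and all planted markers are in-frame.

What the generator does **not** emulate: spot morphology and scanner
artifacts, clone-clone correlation (real antigens share epitopes;
simulated clones are independent), serum-level covariates (age, stage,
MYCN status), heavy-tailed or saturated intensity distributions, and
batch structure beyond a single additive array offset. Passing tests on
synthetic cohorts therefore demonstrate that the *pipeline mechanics*
are correct under the assumed model, not that real sera would reach any
particular accuracy.

## Numerical and design choices

* Binarization, NA filtering and overlap cut-offs are strict
  inequalities (> 50, > 10 NAs, > 0.9), following the literal wording
  of the corresponding rules; boundary cases are pinned by unit tests.
* Reactivity decile bins are computed in integer arithmetic; AUC decile
  bins floor the value at one decimal with the top bin closed.
* All simulation, fold-assignment and permutation randomness derives
  from explicit integer seeds (numpy `SeedSequence`); every reported
  object is bit-identical under a fixed seed.
* Degenerate inputs fail loudly: empty groups, absent classes, NAs at
  normalization time, < 2 sera per group, n_folds < 2.

## Problem sizes used in the checks

Property tests run on small matrices (tens of clones/sera) where
brute-force oracles are exhaustive. End-to-end checks use the full study
geometry (1,827 clones x 83 sera): marker recovery aggregates 10
independent cohorts; classification checks run the complete 20x10-fold
CV plus 20 permutation runs on one cohort each for the planted and the
no-effect case.

## Known limitations

* The repetition-level 95% CI (mean ± 1.96·sd/√20) captures only
  fold-assignment variability. On a single dataset it is an order of
  magnitude narrower than the dataset-level sampling spread of CV
  accuracy, so it should not be read as a CI for generalization
  performance — on no-effect cohorts the CV accuracy lands anywhere in
  roughly 0.56–0.67 while its repetition CI spans ~±0.01 and typically
  excludes the majority-class rate (53/83 ≈ 0.639). The permuted-label
  null, whose run-to-run spread does reflect label randomness, is the
  reliable chance reference and agrees with observed null accuracy
  within 2 sd.
* Exact p-values switch to the normal approximation above 8 sera per
  group; for the study-sized groups (30 vs 53) the approximation error
  is negligible relative to the 0.3/0.7 AUC decision rule.
* With ties, quantile normalization is only approximately idempotent
  (see above).
* Fold changes on quantile-normalized intensities are compressed
  relative to raw-scale fold changes; the scale is configurable but the
  default is normalized, so cross-study comparison of fold changes
  should be done with care.
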