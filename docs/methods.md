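# Methods

## The model

`oralage` treats integer-age regression as an ensemble of classification
problems. Given an age range [lo, hi] (default 1–80, chosen to bracket the
6–78-year span typical of population saliva cohorts) and a bin width *N*,
the range is partitioned *N* times into contiguous inclusive bins: scheme 1
starts a full width-*N* bin at lo; scheme *k* (k ≥ 2) opens with the partial
bin [lo, lo+k−2], continues with full bins, and closes with whatever partial
bin reaches hi. Only the first and last bins of a scheme may be narrower
than *N*; every scheme exactly partitions the range, so each age maps to
exactly one bin per scheme.

One classifier per scheme is trained on the same feature matrix, its labels
being the bins its scheme assigns to the training ages. Members are trained
only on their *occupied* bins (bins containing at least one training
sample) — classification algorithms cannot emit unseen classes, and this
guarantees a predicted bin always maps back to a real age interval. A scheme
in which all training ages fall into one bin is unlearnable and aborts the
fit with the scheme named.

Prediction: each member predicts a bin; each integer age in that bin gets
one vote; the prediction is the age with the most votes. The tie rule —
youngest age wins — is applied once, to the final tally, via the first-index
argmax over ascending ages. Predictions are therefore always integers inside
the configured range. Vote tallies are exposed (`predict_tally`) because the
vote profile's shape is itself informative about prediction confidence.

Ages are required to be integers; non-integer ages are rejected, not
rounded, because the voting mechanism enumerates integer ages. Training ages
outside the range abort rather than clip — the range is a modelling
commitment, and widening it is cheap (edge experiments show modest range
extension beyond the observed ages can help, since edge bins otherwise have
fewer overlapping neighbours).

### Base learners

Members are pluggable behind a fit/predict contract: KNN, LDA, logistic
regression, Gaussian naive Bayes, MLP, random forest, SVM and XGBoost
classifiers, all sharing one hyperparameter set across the *N* members
(tuning per member would multiply cost *N*-fold for little gain, as the
members' problems are near-identical). The default is XGBoost
(100 trees, depth 3, learning rate 0.1, no subsampling), the combination
that pairs best with binarized tables; defaults are deliberately small and
any grid belongs in configuration. Direct-regression baselines (KNN, MLP,
random forest, SVR, XGBoost) share the registry; their real-valued
predictions are scored unrounded to avoid quantizing the comparison.

Every stochastic step defaults to seed 8. Identical seed + data reproduces
identical members and predictions (XGBoost and sklearn are deterministic on
one thread).

## Data representations

Four representations of a count table are supported: presence/absence
(1 iff count > 0), per-sample relative abundance (all-zero samples are left
all-zero with a warning rather than producing NaNs), log2(rel. abundance +
pseudocount) and CLR. The pseudocount (default 1e-6) is added to relative
abundances, not counts, matching the stated order of operations of the
processing chain this implements; CLR uses natural log — centering makes the
base a global scale factor, and natural log is the compositional-data
convention (the log2 transform, by contrast, is named for its base).

## SNR feature scoring

The per-feature score is between-group mean square over within-group mean
square across age groups (defaults: young 0–29, middle 30–64, old ≥ 65;
configurable for other cohorts) — numerically the one-way ANOVA F statistic,
verified against an independent oracle to 1e-9. A feature with zero
within-group variation (e.g. an ASV present in every sample after
binarization) has an undefined score, reported as `None`; the
undefined/zero decision uses a relative threshold (within-SS ≤ n·(1e-9 ×
feature scale)²) so it is invariant to feature rescaling and robust to
floating-point accumulation on constant features. Summaries report mean SNR
over defined features only, the count of features with SNR > 1, pairwise
per-feature win counts, and two-sided Wilcoxon signed-rank p-values paired
by feature across transforms; features undefined under a transform are
excluded pairwise, not globally, and identical profiles return p = 1 by
convention (the signed-rank statistic is undefined at zero differences).

## Stability selection

LASSO regression of raw integer age on features, repeated with seeds
1..n_seeds (default 100); each run picks its penalty by 10-fold
cross-validated minimum MSE with fold assignment controlled by the run's
seed, and counts features with nonzero coefficients. Features selected in
≥ 50% of runs (inclusive; a `strict` flag gives the strictly-greater
variant) are kept. The CV-minimum penalty, rather than a one-standard-error
rule, matches the intent of retaining a generous stable set for a
downstream learner that does its own regularization. Features are not
standardized before the solver (solver default); on binarized tables all
features share a scale anyway.

## Evaluation protocol

* **Hold-out split**: 3 validation samples drawn from each of the strata
  20–29, 30–39, 40–49, 50–59, ≥ 60, restricted to ages represented by ≥ 2
  individuals (so no age vanishes from training); remainder trains. On a
  150-sample cohort this yields 135/15.
* **Bin-width tuning**: k-fold (default 10) CV MAE per width over a grid
  (default 1–64); ties break toward the smaller width for determinism;
  widths infeasible in some fold (single occupied bin) are marked NaN and
  skipped, not fatal.
* **Reporting**: overall MAE plus a 20–59 (inclusive) subgroup MAE, since
  discretized-target ensembles degrade at the extremes of the age range.
* **Paired comparison**: two-sided Wilcoxon signed-rank on per-sample
  absolute errors, paired by sample id.
* **k-fold CV harness**: stability selection runs inside each fold on the
  training portion only; a poisoned-test-label construction test asserts the
  absence of leakage.
* **Sex covariate**: an appended `sex_dummy` feature row (female = 0,
  male = 1); samples with missing sex are an error and must be excluded
  upstream.

## Synthetic cohorts

The generator emulates a saliva 16S cohort at reduced feature count: ages
uniform over 6–78 (or histogram-matched via `age_counts`), presence of each
signal feature following a logistic curve in age (slope ±0.08 logit/year by
default, half rising and half falling, around a 30% baseline prevalence),
noise features at baseline independent of age, and counts conditional on
presence drawn negative-binomially scaled to a 20 000-read mean depth. The
age signal deliberately lives in presence/absence — the regime the method
targets — with an `abundance_signal` mode for exercising the log2/CLR paths.
It does **not** emulate taxonomic or phylogenetic structure, feature
correlations, compositional closure, or sequencing error; passing tests
demonstrate the machinery recovers a planted occupancy signal, not field
performance on real cohorts.

## Problem sizes used in tests

Test and verification sizes are chosen to exercise the full pipeline at
desk scale: the synthetic-recovery check uses cohorts of n = 300 with 200
features (20 signal, slope 0.08), 20-seed stability selection, and a
16-member XGBoost ensemble over 5 generator seeds, requiring MAE ≥ 20%
below the constant mean-age baseline in at least 4 of 5; the
planted-feature selection check uses n = 150 with 200 features and 20
selection seeds; the SNR-vs-F oracle runs 100 random 3-group tables of 50
features. Larger sizes change runtimes, not conclusions.

## Known limitations

* Vote profiles are hard counts; no calibrated intervals or soft voting
  from class probabilities.
* Accuracy degrades at the youngest/oldest extremes (fewer overlapping
  bins, fewer samples) — the subgroup MAE exists to make this visible.
* The binarized representation carries no information about taxa present in
  every sample; when many such features exist, the CLR/log2 paths are the
  fallback.
* The 9:1 stratified split presumes each stratum holds ≥ 3 eligible
  samples; thinner cohorts must use the generic fraction split or k-fold CV.
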