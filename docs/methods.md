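# Methods

This note documents the modelling choices behind `kdscreen`: the pipeline
stages, the synthetic cohort generator that stands in for the private
hospital data, the numerical conventions, and the limits of what the test
suite demonstrates.

## The screening problem

The target setting is rare-disease screening from routine laboratory
tables: a binary label (1 = disease-positive, the minority) and a fixed
schema of 22 features — sex, age, month of visit; 17 blood-panel values
(CBC/differential, acute-phase markers, transaminases, chemistry); urinary
white cells and a pyuria flag. Class imbalance is severe (≈ 1:64), and the
clinically relevant operating points are sensitivity floors: the model
must catch 80–95% of true cases, and is judged by the precision and
specificity it retains there.

## Pipeline stages

### Clustering-based undersampling

k-means++ (D² seeding, Lloyd iterations) partitions the training cohort;
per-cluster class counts drive a discard rule: pure-negative clusters are
removed, and clusters with more than `max_neg_per_pos` (default 200)
negatives per positive lose their negatives. Positives are always
retained (a policy flag restores the literal whole-cluster discard).

Numerical conventions, fixed for determinism:

- assignment ties break toward the lowest cluster index;
- a cluster emptied during iteration is re-seeded from the point farthest
  from its assigned centroid;
- iteration stops when the largest centroid movement falls below `tol`
  (default 1e-4) or after `max_iter` (default 100) rounds;
- the ratio comparison is strict (`>`), so a cluster exactly at the
  boundary is retained.

Non-Euclidean metrics (Manhattan, cosine) swap only the assignment
distance; centroid updates remain coordinate means. This is a pragmatic
approximation — true k-medians or spherical k-means would change the
update step — and is documented as such. Clustering operates on raw,
unscaled features by default, consistent with a no-normalization
preprocessing policy for tree learners; a standardization flag exists for
external data whose scales are pathological.

The baseline comparator is uniform random undersampling of negatives. Its
default target is 1:1 — the convention of standard resampling toolkits —
with any ratio available, including a "match the cluster filter's negative
budget" mode in the pipeline config.

### Augmentation

The synthetic batch size is `N_aug = round(N_major / R) − N_minor`,
clipped at zero; rounding defaults to ceiling and the target ratio R to
24. Backends are fitted on minority rows only:

- **KDE (reference backend).** Product Gaussian kernel over continuous and
  count features; per-feature bandwidth follows the univariate Scott rule
  `σ_j · n^(−1/5)`. Sampling picks a fitting row uniformly and adds
  per-feature Gaussian noise; categorical features are resampled
  independently from their empirical distribution; counts are rounded to
  non-negative integers. The univariate rule is used deliberately: the
  multivariate Scott factor `n^(−1/(d+4))` barely shrinks with n at d ≈ 19
  and produces noise of ~0.8 σ per feature, which smears the minority
  density and measurably degrades downstream precision.
- **Gaussian copula.** Normal-scores transform per smoothed feature
  (Hazen plotting positions), a ridge-stabilized correlation matrix, and
  inverse empirical CDFs on the way out. It preserves marginals and
  pairwise correlation structure tightly, at the cost of assuming a
  unimodal dependence structure.
- **CTGAN / GANBLR adapters.** Deliberately thin: these generators belong
  to external packages, and the adapters raise an explicit
  `BackendUnavailableError` rather than silently substituting anything.

### Fidelity audit

- Squared MMD, biased V-statistic, RBF kernel; bandwidth = median pairwise
  Euclidean distance on the pooled sample, floored at 1.0 (with a warning)
  when the median vanishes. The biased estimator is exactly zero on
  identical samples, which makes the identity tests sharp; absolute MMD
  values are therefore comparable only under a fixed kernel convention.
- PCD = Frobenius norm of the difference of Pearson correlation matrices;
  constant columns contribute correlation 0 by convention (warned).
- Entropy and information gain in bits; default discretization is 64
  equal-width bins over the observed range (native categories for
  categorical features), with a quantile rule available. IG is clipped to
  its theoretical range [0, H(labels)].
- Star summary: per-metric backend ranks mapped linearly onto {1..5},
  ties sharing the higher rating.

### Stacking ensemble

Base learners and their published hyperparameters: XGBoost (learning rate
0.1, max depth 6, 100 rounds), AdaBoost over `max_leaf_nodes=31` trees
with per-learner feature subsampling at rate 0.8 (that parameter set reads
like a LightGBM configuration; it is honoured literally as an AdaBoost
variant), LightGBM (50 iterations). Counts not stated anywhere default to
100 with config override. Folding is stratified 5-fold so both classes
appear in every fold even at 1:24.

The logistic meta-classifier (C = 1.0) is fitted on out-of-fold base
probabilities, to which a logit link is applied (probabilities clipped to
[1e−6, 1−1e−6]). The link is a numerical necessity, not a modelling
flourish: base learners squash their probability ranges very differently
(AdaBoost's SAMME probabilities span roughly [0.12, 0.64]), and a linear
combination on the raw probability scale hands the most squashed learner
a dominating coefficient — in development this cost the stack ~0.06 AUC
relative to its own best base learner. For inference the base learners
are refit on the full table, standard stacking practice.

### Fixed-recall evaluation

The threshold for target recall t is the largest observed score c with
recall(score ≥ c) ≥ t; ties at the threshold are predicted positive. The
achieved ("actual") recall is therefore the minimal feasible recall at or
above the target. By default the threshold is calibrated on the evaluation
set itself, reproducing the per-dataset actual-recall protocol of the
published tables; this leaks the operating point, and the harness equally
supports calibrating on a held-out split and carrying the threshold over.
Display rounding of percentages is decimal half-up to one decimal.

## The synthetic cohort generator

Rows come from a latent Gaussian mixture in standardized z-space, mapped
per feature to natural scales (Gaussian for most chemistry, lognormal for
CRP, Poisson for counts, thresholded Bernoulli or uniform integers for
categoricals). Each latent cluster has a mixture weight, a per-feature
offset, a positive-rate multiplier (label rates renormalize so the global
positive rate is exactly `pos_rate`, default 1/65), and a positive-class
marker shift.

The default 10-cluster specification encodes the structures the pipeline
is designed to exploit, each chosen for a clinical reading:

- **Identity banding.** Each cluster occupies its own platelet band
  (0.8 z spacing), so k-means++ at k = 10 recovers the partition reliably
  across seeds. Earlier development variants with overlapping bands let
  the >1:200 rule fire on interstitial mixtures, making filtering
  erratic.
- **Heterogeneous presentations.** Positives shift along cluster-specific
  marker directions (classic inflammatory, hepatic, urinary, hematologic,
  two mixed, and two *atypical* clusters whose shift magnitude is muted to
  2.9 z against 4.2 z). The minority class is thus a union of small
  disjuncts — the regime where severe imbalance genuinely starves a
  boosted learner and minority amplification genuinely helps; a
  single-direction minority is learned equally well from raw data, which
  would make rebalancing pointless by construction.
- **Low-information clusters.** One pure-negative cluster (weight 0.25)
  and one cluster below a 1:200 positive rate (weight 0.15) sit at
  clinically extreme thrombocytosis with acute-phase markers depressed
  below the febrile baseline. They are redundant easy negatives: their
  region extrapolates safely after the filter removes them, which is what
  makes cluster-based undersampling harmless-to-helpful here, while a
  random undersampler spends its budget on informative rows.
- **Institutional shift.** The external cohort applies an affine latent
  shift (location + scale) after the class effect: its febrile controls
  are systematically sicker (CRP +0.7 z, wider dispersion, similar moves
  on ESR/WBC/AST/UWBC), eroding off-site specificity while preserving
  effect directions — the cross-institution failure mode the pipeline is
  meant to mitigate. The external positive rate is 1/25, matching the
  validation-cohort imbalance of the motivating study design.

Shift magnitudes were calibrated once so that a raw boosted baseline lands
in the operating regime the published tables report (F1 at the 90%-recall
point roughly 0.3–0.45 internally and 0.35–0.55 externally) rather than in
collapse (~0.1) or ceiling (~0.9) regimes where method contrasts are
uninformative.

What the generator does **not** emulate: marginals calibrated to
pediatric reference ranges (feature realism is cosmetic), missing data,
temporal structure, label noise, seasonality of visits, or within-patient
correlation across repeated encounters. Passing tests therefore show that
the pipeline behaves as designed under its intended data geometry — not
that it would achieve any particular performance on real hospital data.

## Problem sizes, seeds, determinism

The bundled fixture suite is desk-scale: 6,500 training rows (~100
positives at 1:64), 4,800 test and 1,600 external rows by default; the
evaluation cohorts are generous relative to training because fixed-recall
operating points are estimated from the positive-score tail and stabilize
only with enough positives. The end-to-end directional check in the test
suite uses 5 seeds with a 3,200-row external cohort and compares seed-mean
F1 at the 90%-recall point: full pipeline vs. a raw-data booster, and
cluster-based vs. conventional random undersampling.

All randomness flows through explicitly seeded NumPy generators; stage
seeds derive from one top-level seed via SHA-256 of `"{seed}:{stage}"`.
Learners run single-threaded with fixed seeds, so a pipeline run is
reproducible byte-for-byte in its metric tables.

## Known limitations

- The metric-swapped Lloyd variant is an approximation of non-Euclidean
  k-means (see above).
- The Gaussian copula backend cannot represent multimodal dependence; on
  strongly clustered minorities the KDE backend is the safer default.
- Cluster-based undersampling is only beneficial when the discarded
  regions are genuinely redundant; if the decisive decision boundary
  borders a discarded cluster, filtering can remove exactly the negatives
  the learner needs. The filter reports per-cluster counts so this can be
  audited, but the package does not attempt to detect it automatically.
- Threshold calibration on the evaluation set reproduces the published
  protocol but is optimistic; use held-out calibration for honest
  prospective estimates.
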