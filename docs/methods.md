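# Methods

This note documents the statistical model, the synthetic cohort the
package validates itself on, and the numerical and design choices a
maintainer would want to know. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Connectomes

A subject-scan connectome is the N×N matrix of Pearson correlations
between node time series, Fisher-transformed (z = arctanh r). Before the
transform, correlations are clipped to ±(1 − 10⁻⁷) so numerically perfect
correlations stay finite; a node with zero temporal variance is an error
(it indicates corrupt input), never a silent NaN. The diagonal is stored
as 0 and never enters any model. Scans are combined by an unweighted
elementwise mean over whatever scans are valid (≥ 1); the count averaged
is recorded for audit. Weighting by scan length was considered and
rejected: the three scan modalities have comparable durations by design,
and an unweighted mean keeps the subject-level connectome invariant to
how a scan is split into runs. Edges are vectorized in canonical
row-major upper-triangle order — pairs (i, j), i < j, i ascending then j —
so E = N(N−1)/2; the vectorize/devectorize pair is an exact bijection on
the off-diagonal.

## CPM

**Screening.** Each edge's partial Pearson correlation with the severity
score given covariates is obtained by residualizing both sides against
[1, X]; the two-tailed p-value uses the t distribution with n − 2 − c
degrees of freedom. With no covariates this is the plain Pearson
correlation. Edges with p < α (default .05) are kept and split by sign.

**Model form.** Severity is regressed on [1, pos_sum, neg_sum], the
per-subject sums of selected positive- and negative-edge strengths. The
two-feature combined model is the default because it yields a single
prediction per subject; positive-only and negative-only variants are
available (`variant=`). When a mask is empty its feature column drops out
(coefficient recorded as 0); with both empty the model is intercept-only
and predicts the training mean.

**Cross-validation.** 10-fold partitions with near-equal fold sizes
(differing by at most 1), repeated (default 100) with the partition of
repeat r drawn from seed + r, so any repeat is independently
reproducible. Screening and regression see only the training folds; this
no-leakage property is asserted in the tests by relabeling held-out
subjects. Per repeat, the Spearman correlation (average ranks for ties)
between out-of-fold predictions and observed scores is recorded; the
model's score is the median over repeats. A training fold with constant
severity aborts that repeat with a logged warning (ρ = NaN, excluded from
the median).

**Fast path.** `run_cv`/`CVEngine` compute per-fold screening statistics
as totals minus held-out-fold sums (one data pass per repeat instead of
one per fold), thresholding |partial r| against the exact t-critical
value, which is algebraically identical to the per-fold refit; the test
suite asserts equality with the straightforward `fit_cpm` loop to 10⁻⁸.
The engine caches everything that does not depend on the behavior vector,
which is what makes 1000-shuffle permutation nulls tractable on one CPU.

**Covariates.** Confounds enter only through the partial correlation at
screening; the outcome is not residualized and covariates are not
prediction-time features. For 6- and 14-month targets the 1-month total
is appended to the covariate list, so follow-up models predict severity
beyond what baseline severity explains. Subjects missing a follow-up are
excluded from that target's model, not imputed.

## Permutation inference

The null shuffles the behavior vector over subjects, leaving connectomes
and covariates aligned, and reruns the full selection + CV pipeline per
shuffle. One-tailed p-values use the add-one rule,
p = (1 + #{null ≥ observed}) / (n_perm + 1), which is never exactly 0 and
finite-sample valid. Two fidelity knobs keep the null affordable:

* `perm_repeats` (default 10; 100 available) — the median-ρ null is
  insensitive to the repeat count, which the calibration suite confirms.
* All shuffles share the fold partitions drawn from the base seed (the
  first `perm_repeats` partitions of the observed run), so the
  permutation distribution is exact conditional on those partitions.

The type-I error of the resulting test is checked directly: on 200 null
(β = 0) cohorts of 100 subjects, the rejection count at α = .05 must fall
in the exact binomial 95% interval.

Cluster models (criteria B/C/D/E) are corrected by Benjamini–Hochberg
step-up across the four models within a timepoint. BH is *not* idempotent
on arbitrary adjusted vectors; the tests assert the properties that do
hold (adjusted ≥ raw, monotone in sorted order, order equivariance,
agreement with an exhaustive step-up oracle).

## Virtual lesions and attribution

"Within and between the network of interest" is read literally: a
network's lesion mask keeps every edge with at least one endpoint in the
network, so between-network edges appear in both endpoint networks' runs.
All lesion runs and the whole-brain run share fold partitions (same
seed), making the outperformance comparison paired; a network drives the
prediction iff its lesioned median ρ exceeds the whole-brain median.
Contribution matrices report both raw selected-edge counts per network
pair and a density normalization (count ÷ possible node pairs:
n_a·n_b off-diagonal, n_a(n_a−1)/2 on the diagonal) because "average
contribution" has no unique formula; reports default to the density.
Degree centrality is the per-node count of incident selected edges,
computed separately per sign (handshake identity: degrees sum to twice
the edge count).

## Synthetic cohorts

The generator produces the statistical structure the pipeline assumes,
with ground truth for parameter-recovery tests. What it emulates:

* **Trajectories.** A five-class mixture (low / remitting / moderate /
  high / delayed) with the published prevalences as default weights.
  Those prevalences sum to 100.1% because each is rounded to one decimal;
  the default weight vector renormalizes them (low = 0.6444…). Each class
  has a latent-severity profile over 1/6/14 months (remitting decreases,
  delayed increases — validated at construction) plus a subject-level
  Gaussian intercept (SD 0.4, a moderate within-class spread).
* **CAPS-5.** 20 ordinal items (0–4) in clusters B = 5, C = 2, D = 7,
  E = 6 (the standard instrument structure; configurable). Each item adds
  unit-variance noise to the latent and counts fixed thresholds
  (−0.5, 0.5, 1.5, 2.5) exceeded, giving totals in 0–80 with cluster
  scores summing to the total, expected totals monotone in the latent,
  and cohort means around 18 at 1 month — a plausible recently-exposed
  sample.
* **Connectomes.** Population edge means ~ N(0.25, 0.15²) in z units
  (typical resting FC scale), per-edge subject deviations (SD 0.10),
  three scans = subject connectome + independent scan noise (SD 0.20).
  Planted edges (default 40 of 1770; 90% touching the target network,
  98% negative) shift by −β × standardized 1-month latent severity.
  β defaults to 0.15 z/SD — there is no published effect-size scale for
  single edges, so this is an explicitly synthetic choice, set once to a
  value at which the pipeline's recovery properties hold robustly.
* **Confounds and dropout.** Age ~ N(33.9, 11.5) clipped to 18–65, sex ~
  Bernoulli(0.494), motion ~ gamma with mean ≈ 0.12 mm. Confounds are
  independent of edges by default, matching the generator's role as a
  calibration instrument. Dropout is missing-completely-at-random at
  84.0% (6 m) and 82.1% (14 m) with 14-month completers nested in
  6-month completers; an informative-dropout tilt exists for robustness
  studies only.

What it does **not** emulate: BOLD dynamics (hemodynamics, temporal
autocorrelation), head-motion artifact structure, task condition effects,
scanner/site effects, or spatially correlated edge noise. Passing tests
therefore demonstrate the statistical machinery — calibration, power at
the configured effect size, localization — not performance on real fMRI.

## Problem sizes

The package's standard study conditions are 60-node connectomes (10
networks of 6 nodes, E = 1770) and 160 subjects, at which a full CPM with
permutations runs in seconds on one CPU; 268 nodes is a configuration
flag for fidelity runs. The calibration study uses 200 datasets × 200
shuffles × 5 repeats; the planted-recovery study uses 20 seeds with 20
repeats per run and a 100-shuffle permutation test on the seed-7 cohort.
The analysis drivers use 50 repeats and 200 shuffles.

## Degenerate inputs and tie-breaks

Zero-variance edges get r = 0 (excluded from selection); Spearman uses
average ranks for ties and refuses constant vectors; a rank-deficient
covariate matrix and a behavior vector collinear with the covariates are
errors naming the problem; fold partition sizes for n not divisible by k
put the extra subjects in the lowest-indexed folds (scikit-learn KFold
convention); selection at exactly p = α is excluded (strict inequality).

## Known limitations

* The combined two-feature model is one of several CPM conventions;
  results for positive-only or negative-only models can differ.
* Consensus predictive-edge counts depend on an arbitrary
  across-fold/repeat threshold; the package reports per-edge selection
  frequencies and a configurable consensus rule rather than one number.
* The permutation null conditions on fold partitions; with very small
  n_perm the discreteness of the add-one p is noticeable.
* Generator realism is deliberately limited (above); effect sizes are
  synthetic and should not be read as expected real-data performance.
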