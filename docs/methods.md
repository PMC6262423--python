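# Methods

This note documents the models and procedures implemented in `neoscore`,
the parameters that matter, the numerical choices, and what the synthetic
testbed can and cannot establish.

## Outcome definition

A labeled subject carries three Bayley-III composite scores (cognitive,
motor, language; each nominally mean 100, SD 15, range 40–160). The severe
label is `min(components) ≤ 70` — any domain more than two standard
deviations below the mean at 18–24 months corrected age. The label is
always derived from the scores at load time and never read from a file; a
stated label that disagrees is overridden with a warning. Records with
incomplete Bayley triples are unlabeled and excluded from every fit and
comparison (infants too impaired to complete testing therefore fall outside
the modeled population — a structural limitation of the outcome
definition, not of the implementation).

## The weighted MRI score

Each injury domain maps to at most one scored level per subject:

* IVH: Papile grade collapsed to none / low (I–II) / high (III–IV);
* WMI: none / isolated punctate (1–2 lesions, no cysts) / multiple
  punctate (>2 lesions) or cystic — any cystic lesion dominates the count;
* CH: none / punctate-or-small (<50% of a cerebellar hemisphere) / large
  (>50%), plus a bilaterality bonus.

"Punctate" and "small" CH are distinct radiological descriptions with the
same point value; the data model stores the merged category and accepts
either synonym on input. The score is the sum of the active levels' points
plus the bilateral bonus. A `WeightTable` must have non-negative integer
entries with the severe level of each domain carrying at least the milder
level's points; under the published weights the attainable range is 0–14,
under the equal-weight baseline (1 point per present feature) 0–4. Score
positivity uses a strict rule throughout: positive iff score > threshold.

## Greedy integer weight learning

`learn_weights` starts from the equal-weight baseline and walks the seven
scored levels in a configurable order (default: descending clinical
severity). For the current feature it repeatedly proposes +1 point,
recomputes all subject scores, picks an operating threshold per the
configured rule, and reads sensitivity and specificity there as exact
rationals (`fractions.Fraction`), so acceptance decisions cannot hinge on
floating-point ties. A proposal is accepted only if sensitivity strictly
increases and specificity does not decrease relative to the last accepted
state; the first rejection moves the search to the next feature. Weights
are capped (default 10), so the iteration count is bounded by
7 × max_weight. A raise that would push a milder level past its domain's
severe sibling is not proposed (logged instead), so every intermediate
table is valid. Results are invariant to subject order and, deliberately,
*not* invariant to feature order.

Two threshold rules are provided:

* `youden` (default): the integer threshold maximizing J = sensitivity +
  specificity − 1, ties broken toward the lowest threshold. This start
  point is already the most sensitive of the J-optimal cutpoints, which
  makes the acceptance rule extremely conservative: a raise is accepted
  only if the new score's Youden point strictly dominates the old one on
  sensitivity without losing specificity, and on cohorts of a few hundred
  subjects or more a single boundary-crossing negative subject vetoes the
  raise. In practice the default search usually returns the baseline
  table unchanged. This behavior is a property of the procedure, not a
  bug; it means published weight tables of this kind are only reachable
  from specificity-heavy starting points or in small samples where the
  boundary is sparsely populated.
* `fixed:K`: the threshold is held at K. Setting K to the baseline's
  maximum attainable score (4) is the natural escalating configuration —
  sensitivity starts at exactly 0 and specificity at 1, so features that
  lift truly-severe subjects past K are accepted until negatives start to
  cross. On cohorts generated from the published weights (n = 2000,
  logistic effect 2.0 per point) this configuration escalates on every
  seed tried and reproduces the published severity ordering
  (high-IVH/multiple-WMI above large CH above the 1-point levels) on most
  seeds, with ties broken by sampling noise on the rest.

## Logistic risk models

Fits are maximum likelihood via Newton–Raphson/IRLS with step halving, so
the log-likelihood is non-decreasing by construction (asserted in tests);
convergence is |Δ log-likelihood| < 1e−8 or 100 iterations. The coefficient
covariance is the inverse observed information at the MLE. Complete
separation is detected when every fitted probability is within 1e−7 of 0 or
1 (or coefficients diverge) and raises an error naming the covariate with
the largest standardized coefficient; rank-deficient designs (infinite VIF)
are refused before fitting. Continuous covariates enter untransformed and
uncentered.

Both McFadden and Nagelkerke pseudo-R² are reported side by side
(Nagelkerke is displayed by default, as is common in the clinical
literature). AIC = 2k − 2ℓ with k counting the intercept. Backwards
stepwise selection repeatedly removes the single covariate whose deletion
most lowers AIC, stopping when no deletion helps; exact ties are broken by
dropping the covariate latest in the candidate ordering, making the
procedure deterministic.

Per-subject risk is expit(xᵀβ) with the delta-method standard error
p(1−p)·√(xᵀΣx). The delta method is a linearization: it tracks a
parametric bootstrap closely at moderate predicted risk (within ~10% at
n ≈ 2000 in the test suite) but deviates near probabilities 0/1, where the
reported SE shrinks toward zero by construction.

VIF for covariate j is 1/(1−R²ⱼ) from an ordinary least-squares regression
of column j on the remaining covariates plus intercept; values above 5 are
flagged, exact dependence reports ∞ and blocks the fit.

## Evaluation statistics

AUC is the Mann–Whitney pair statistic with ties counted ½, identical to
the trapezoidal area under the empirical ROC built over all distinct
cutpoints with the strict positivity rule (asserted as an exact equality in
tests). The AUC variance and the paired comparison of two models on the
same subjects use the DeLong (1988) structural-component estimator with a
normal-approximation two-sided p; a model compared against itself returns
difference 0 and p exactly 1.

Group comparisons follow the field's conventions: Fisher's exact test for
2×2 tables, two-sided by the point-probability criterion (all tables with
point probability no larger than the observed are summed — conventions
differ across packages, so this is stated explicitly); an r×c
generalization (Freeman–Halton) estimated by seeded Monte Carlo with
Patefield sampling of fixed-margin tables (default 10⁵ draws, add-one
correction, MC standard error reported); and the Mann–Whitney U-test for
continuous variables, exact when the pooled sample is ≤ 12 with no ties and
otherwise the normal approximation with midranks, tie correction, and
continuity correction. The cohort report assembles per-group n (%),
mean (SD), or median (range) rows with these p-values and stars at
p < 0.05.

## The synthetic cohort generator

`simulate_cohort` emulates the *published group-conditional summary
statistics* of the development cohort (154 infants, 38 severe): outcome
group first (Bernoulli, prevalence 38/154), then per group —

* injury categories from the group-conditional frequencies (IVH
  none/low/high; merged CH size with a bilaterality Bernoulli conditional
  on CH presence; WMI none/isolated/multiple), with concrete Papile grades
  and lesion counts drawn uniformly within category;
* gestational age from a truncated normal on [22, 30] weeks (25.6 ± 1.6
  severe, 26.2 ± 1.9 non-severe) and birth weight truncated below at
  300 g; truncation shifts the realized means by < 0.04 of the stated
  values;
* binary covariates as Bernoulli at the published count/group-size rates;
* ventilator days log-normal, parameterized to the published per-group
  medians (31.5 vs 4 days) with log-scale SD 1.0/1.1 chosen so the
  published ranges are plausible (only medians and ranges are published);
* the 5-minute Apgar as binomial(9, p) with p matched to the per-group
  central value — a simple group-shifted discrete distribution on 0–9;
* Bayley components from group-conditional normals (rounded, clipped to
  40–160) rejection-sampled to respect the group label, so the re-derived
  label always matches the drawn group; infeasible parameter choices fail
  after a bounded number of rejection rounds.

Covariates are **conditionally independent given the outcome group**: the
source tables publish only per-group marginals, so cross-covariate
correlations (ventilator days with BPD, gestational age with birth weight)
are not modeled. Two consequences matter for interpreting test results.
First, every covariate with a published group difference carries
*independent* signal here, so the all-covariate clinical model is less
redundant than in real data — the published fixed 4-covariate "slim" list
does not reliably beat the 8-covariate full model on AIC in this synthetic
world, whereas the stepwise-selected model (the procedure that produced the
slim list) does, on essentially every seed. The tests assert the
procedural version. Second, passing distributional tests shows the
generator matches the published marginals, not that it reproduces the real
cohort's joint structure.

`simulate_from_score_model` is the parameter-recovery testbed: profiles
from the pooled marginal distribution, the severe label Bernoulli with
logit(p) = c + β·S under a known weight table (default β = 2.0 per point,
strongly discriminative), and c solved numerically so the expected
prevalence matches 38/154. Clinical covariates and Bayley scores are then
filled conditional on the drawn label.

Problem sizes used in the test suite: n = 154 for study-scale fits,
n = 2000 for recovery and DeLong experiments (20 seeds), n = 20000 for
generator calibration checks, 2000-draw bootstraps and 10⁵-draw Monte-Carlo
tests where applicable.

## Known limitations

* The outcome model excludes infants who could not complete developmental
  testing; prediction for that (most severely affected) group is out of
  scope.
* The greedy weight learner is order-dependent and, under the default
  Youden rule, highly conservative (see above); it reproduces a published
  table's *ordering* under the escalating configuration, not its exact
  point values.
* Delta-method standard errors are unreliable near predicted probabilities
  of 0 or 1.
* The generator reproduces marginal and group-conditional summaries only;
  conclusions that depend on cross-covariate correlation structure cannot
  be validated against it.
* In-sample AUC/PPV/NPV of refit models are optimistic; no cross-validation
  machinery is included.
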