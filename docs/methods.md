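# Methods

## Association model

Each non-seed feature *y* is regressed on the seed feature *x* within one
cohort by ordinary least squares with intercept.  With pairwise-complete
samples (only pairs where both values are observed), the reported
statistics are the slope *β*, its standard error, *t* = *β*/se on *n* − 2
degrees of freedom, the two-sided *p* from the *t* distribution, *r*²
equal to the squared Pearson correlation, and the one-predictor adjusted
*r*² = 1 − (1 − *r*²)(*n* − 1)/(*n* − 2).  The direction of an association
is the sign of *β*.

Orientation: the target is regressed on the seed.  For a single predictor,
*p*, |*t*| and *r*² are symmetric in the two variables, so every screening
decision is orientation-invariant; only the coefficient column depends on
the convention, and it is documented as target-on-seed.

Numerical notes.  The genome-wide path and the single-pair path share one
vectorised two-pass kernel (means first, then centered cross-products), so
they are bitwise identical; the two-pass form keeps the acceptance
comparison against a normal-equations oracle at 1e-10 relative.  Exact
collinearity leaves only rounding residue in the residual sum of squares;
residue below 1e-12 of the total sum of squares is snapped to zero so the
degenerate case reports se = 0, *p* = 0, *r*² = 1 exactly.  *p*-values are
never floored; underflow reports 0.  A feature is skipped (with a recorded
reason) when fewer than 4 complete pairs remain or either variable is
constant on them.

No multiple-testing correction is applied by the filters, which consume
raw *p* thresholds; a Benjamini–Hochberg q-value column is available on the
results object for users (`with_fdr()`), and nothing downstream consults
it.

A permutation test of the slope (`permutation_p`, add-one-corrected
two-sided (count + 1)/(n_perm + 1)) serves as an internal oracle for the
parametric *p*; because the permuted seed keeps its marginal values,
ranking by |slope| equals ranking by |correlation|.

## Screening tiers

Three nested filters, each a `FilterTier` value so alternative screens are
configuration, not code:

* **relaxed** — *p* ≤ 0.05 in every cohort, identical slope sign in every
  cohort.  A feature must be measured in every cohort to qualify; a zero
  slope counts as a direction mismatch.
* **strict** — *p* ≤ 2 × 10⁻⁶ *and* adjusted *r*² ≥ 0.1 in at least five
  cohorts, evaluated on relaxed survivors.  Only measured cohorts are
  counted, and the qualifying cohorts are not additionally required to be
  direction-consistent among themselves, because the relaxed tier already
  enforced direction consistency across all cohorts.
* **heatmap** — adjusted *r*² ≥ 0.3 in at least one cohort, evaluated on
  strict survivors.

Tiers are applied sequentially by default (each narrows the previous
tier's survivors, so the sets are nested); `sequential=False` evaluates
each tier independently.  All r² thresholds consult the **adjusted** r²,
the statistic the reference candidate table reports.  The screen is
deterministic and invariant to cohort and feature ordering.

## Replication and specificity

For a candidate set with reference directions taken from the (unanimous)
discovery direction, a validation group's **consistency rate** is the
fraction of candidates significant (*p* ≤ α, default α = 0.05) in the
group with the reference direction; the **opposite rate** is, among
significant candidates, the fraction whose sign flips.  Candidates not
measured in the group stay in the denominator and can never replicate,
making the rates conservative.  Rates render as percentages at two
decimals (e.g. 212/214 → "99.07%").

The subtype screen intersects, over the configured molecular subtypes, the
candidates significant with one shared direction in every subtype.  By
convention subtype groups should have ≥ 30 samples; smaller strata are the
caller's responsibility to exclude, since tiny groups make the per-subtype
regressions unstable.

Tumor/normal **specificity** for one feature in one cancer type is a
five-way partition driven by the two tissue-level regressions: both
significant and same-signed → consistent; both significant, signs differ →
opposite; only tumor significant → tumor_specific; only normal →
normal_specific; else neither.  Exactly one call applies to every
(feature, cancer type) with both tissues measured.

Paired regulation frequency counts tumor − normal log-expression
differences beyond ±`log_fc_threshold` over complete pairs.  The default
threshold of 1.0 log₂ unit (two-fold) is an explicit, configurable
assumption; no published criterion fixes it.

## Survival screening

The expression dichotomy operationalises "the significant low point of the
histogram" as the antimode of a Gaussian kernel density estimate with
Silverman's bandwidth, scanned on a 512-point grid over the observed
range: with at least two local maxima, the threshold is the density
minimum between the two *highest* maxima; otherwise the sample median is
used (`median_fallback`).  The antimode is also rejected in favour of the
median when either resulting group would hold fewer than
`min_group_frac` (default 0.1) of the samples.  This is the central
interpretive decision of the survival stage and is isolated behind one
function with two knobs (bandwidth, minimum group fraction).

The two groups are compared with the standard two-group log-rank test:
at each distinct event time, expected events per group follow the
hypergeometric model, the statistic is (O₁ − E₁)²/V with the summed
hypergeometric variance, referred to χ²(1).  Ties between an event and a
censoring at the same time follow the usual convention (the censored
subject is still at risk at that time).  The per-group observed and
expected event counts are part of the result, which is why the
accumulation lives in-package; the Kaplan–Meier curve itself is delegated
to lifelines, and the test suite cross-checks the log-rank statistic
against lifelines on tied, censored data.  The benefiting group
(`direction_of_benefit`) is the one with the larger restricted mean
survival up to the smaller of the two groups' last observed times.

Cox regression is deliberately absent: the workflow reports only
dichotomized-group comparisons.

## Synthetic data

A linear-Gaussian generative model, chosen for analytic tractability: per
cohort the seed is standard normal, a planted feature with target
correlation ρ is ρ·seed + √(1 − ρ²)·noise (so E[*r*²] = ρ²), and null
features are independent standard normals.  Defaults mirror the study
conditions: eight cohorts with sample sizes 99, 161, 160, 207, 107, 190,
575, 173, and ρ drawn once per feature from (0.15, 0.65) — mapping to
adjusted *r*² ≈ 0.02–0.42, the heterogeneity observed across real
cohorts.  Subtype labels carry per-subtype ρ multipliers; paired
tumor/normal cohorts plant each specificity class by making the seed
correlation present, absent or sign-flipped per tissue (|ρ| = 0.4,
200 pairs by default).

Survival times are exponential with baseline hazard 1/500 days⁻¹ (median
survival ≈ 347 days, a realistic solid-tumor scale) multiplied by the
hazard ratio (default 2) above the planted expression threshold.
Censoring is independent uniform on (0, b), with b solved numerically so
the expected censored fraction equals the configured rate (default 0.2) —
non-informative, matching the log-rank test's assumptions.  Everything is
reproducible from a single integer seed.

What the generator does **not** emulate: platform/batch effects, probe
redundancy, heavy-tailed or count-distributed expression, correlated
censoring, and gene–gene correlation beyond the seed.  Passing tests
therefore demonstrate the correctness and calibration of the statistical
machinery under the model's assumptions, not robustness to real-data
artefacts.

## Problem sizes in tests and the acceptance script

Null calibration uses 20,000 null features per cohort (enough that the
binomial band [0.045, 0.055] around α = 0.05 is ~3 standard errors wide
per cohort); the all-null filter check uses ten seeded runs of 1,000
features over eight cohorts; planted-recovery uses 200 planted + 800 null
features at ρ = 0.6, n = 100 per cohort over five seeds; log-rank null
calibration uses 2,000 replicates of n = 200 and the power check 200
replicates of 200 + 200.  The Monte-Carlo check of the generator's ρ
calibration averages over independent cohorts (independent seed
realizations): within one cohort all planted features share the seed
vector, so their sample correlations are conditionally dependent and their
within-cohort mean is biased by the seed realization itself.

## Known limitations

* Feature matching across cohorts is by exact id; no cross-platform probe
  liftover.
* The antimode detector operates per cohort; a global dichotomy across
  cancer types is out of scope.
* The strict tier requires at least five cohorts by default and will
  refuse smaller designs rather than silently weaken the criterion.
* p-value underflow reports 0, which the relaxed tier treats as
  significant (correct for screening, but 0 is not a probability).
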