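# Methods

## Model and estimand

The package targets conditional average treatment effects (CATEs) in a
point-treatment observational design.  For outcome `Y`, binary treatment
`X`, confounders `C` and candidate modifiers `W`, identification rests on
the usual conditions: conditional exchangeability given `C` (within levels
of `W`), positivity, consistency, no interference, and a correctly specified
outcome model.  Under these, the CATE

    τ(w) = E(Y¹ − Y⁰ | W = w)

is estimable by standardization: fit one outcome model with treatment
interactions, predict each individual's outcome under `X = 1` and `X = 0`
("recycled predictions"), and contrast.  The test-set mean of the
per-individual contrasts is, by construction and exactly, the
standardization estimate of the average treatment effect on that sample —
this identity is asserted in the test-suite rather than assumed.

The pipeline is an S-learner with a deliberately transparent parametric
base model, followed by an unsupervised step that turns the estimated CATE
distribution into named subgroups.

## The outcome model

The training-split design holds the treatment indicator, covariate main
effects, optionally covariate products, and treatment × term interactions.
Continuous columns are centered and scaled by their training-split mean and
sample SD; binary columns (exactly two distinct values) and the treatment
column are left on their natural scale so their coefficients and later
cluster means stay interpretable.  Test-set designs always re-use the
training parameters.

The elastic-net objective, written on the residual-sum-of-squares scale, is

    L(β) = fit(β) + λ Σⱼ pfⱼ [ α|βⱼ| + (1−α)/2 βⱼ² ]

with `fit` = RSS for the gaussian family and the deviance (−2 log-lik) for
the binomial family.  Penalty factors `pfⱼ` are 1 except for the intercept
and the treatment main effect, which are never penalized: a variable whose
coefficient the analysis exists to estimate must not be selected out of its
own model.  The solver is cyclic coordinate descent on the Gram-matrix form
of the problem (IRLS-wrapped for the binomial family), jit-compiled; at
λ = 0 it agrees with OLS / GLM to ~1e−10, and at uniform penalty factors it
agrees with sklearn's `ElasticNet` under the scale identity
λ = 2n·α_sklearn (both asserted in tests).

λ is chosen on a 100-point log grid from λ_max (the smallest λ zeroing all
penalized terms) down to 1e−4·λ_max, by K-fold cross-validation (default
K = 10) with folds that are deterministic given `fold_seed`.  The default
rule is the minimum mean CV loss; a 1-SE rule is exposed
(`PenaltySpec(one_se=True)`).  The minimum rule is known to retain a few
noise terms with very small coefficients; the 1-SE rule is the sparser
choice when selection itself is the goal.

A binary outcome can be modelled either as penalized logistic regression or
as a linear probability model (gaussian family on 0/1 outcomes).  The
pipeline default used for the synthetic study is gaussian: the generator's
risks are additive in covariates and treatment-effect cells, so the linear
probability model is correctly specified there, and its CATEs are exact
risk differences.

## Confounding control

Stabilized IPT weights come from a logistic propensity model on confounder
main effects: `w = P(X=x) / P(X=x | C)`, truncated at the 1st/99th weight
percentiles by default.  Weighted standardized mean differences before and
after weighting are returned as a balance diagnostic; a stabilized-weight
mean outside [0.9, 1.1] triggers a positivity warning.  Perfect separation
and fitted propensities of 0/1 are hard errors.

Post-double selection is available (off by default): the union of terms
selected by the penalized outcome regression, confounders selected by a
penalized propensity regression, and treatment × modifier interactions from
the outcome regression, refit without penalty.

## Modifier discovery

The test-split CATE vector is clustered with Ward's method (scipy linkage;
a brute-force minimal-within-SS-increase oracle verifies the merge sequence
on small instances in the test-suite).  Because Ward needs distinct values,
a tiny seeded jitter — Normal(0, (relative_sd · SD(CATE))²), default
relative_sd = 1e−3, with an absolute floor of 1e−8 when the vector is
constant to machine precision — is added *only* for tree construction and
k-selection; every reported quantity is computed on the un-jittered values.

The number of clusters is chosen with Beale's pseudo-F,

    F(k) = [(W_k − W_{k+1}) / W_{k+1}] /
           [ ((n−k)/(n−k−1)) ((k+1)/k)^{2/p} − 1 ],   p = 1,

comparing against the F(1, n−k−1) critical value at α = 0.10 (the
`NbClust` convention; `beale_alpha` is a config knob).  F is evaluated for
every k up to `k_max` (default 5) and the chosen k is the **largest**
cluster count whose creation is significant.  Scanning all k, rather than
stopping at the first non-significant improvement, is deliberate: for
three equal well-separated spikes the 1-vs-2 improvement ratio is exactly 3
regardless of separation (the best 2-split must leave one heterogeneous
cluster), so a stop-at-first rule can never reach k = 3, while the 2-vs-3
statistic is decisive.  The scan rule returns 2 for a two-mode mixture, 1
for a single Gaussian, and 3 for three spikes.

For each candidate modifier `m`, the z-score in cluster `g` is
`(mean of m in g − overall mean) / overall SD` (one formula for continuous
and binary candidates; proportions are just means of 0/1 columns), and the
importance is the absolute z difference between clusters (max pairwise
difference if k > 2).  Candidates with importance ≥ 0.2 (config default)
are selected.  A selected continuous modifier is dichotomized at the
average of its means in the two extreme clusters.

## Subgroup estimation

Per discovered modifier, the saturated marginal structural model
`{1, X, G, X·G}` is fitted on the full cohort (a config switch restricts it
to the test split, since re-using the training split risks mild optimism).
Under the IPTW estimator the standardized risks are the weighted cell
means, so the risk difference and risk ratio derive from one consistent set
of risks; RD-scale inference uses the weighted linear model with HC0
sandwich covariance, RR-scale inference the same saturated model as a
weighted log-link fit (log-binomial first, Poisson with robust covariance
as fallback).  Under the G-computation estimator, subgroup risks come from
an unweighted outcome model retaining confounder mains, standardized within
each group, with percentile bootstrap CIs (default B = 500, seeded;
resamples with an empty treatment × group cell are skipped, >10% skipped is
an error).  The p-for-interaction is the Wald test of the `X·G` term on
each scale.

## The synthetic generator

The generator emulates an observational blood-pressure-treatment cohort:
age ~ N(65, 8), SBP ~ N(135, 15), sex ~ Bernoulli(0.5) (the confounders,
which raise both treatment probability and outcome risk; pre-weighting
standardized mean differences on age and SBP are ≈ 0.3–0.4 so IPTW
demonstrably matters); eGFR ~ N(73, 10); aspirin ~
Bernoulli(expit(a₀ + a₁·z_eGFR)), so the two true modifiers are positively
correlated (in cohorts both track vascular health).  Treatment is assigned
by a logistic model on the confounders whose intercept is solved by
bisection so the *expected* treated fraction hits the target (default 30%;
at small n the realized fraction can drift by binomial noise, which warns
rather than errors).  Untreated risk is additive,
`b₀ + b_a·aspirin + b_h·1{eGFR≥73} + small confounder terms`, the treatment
effect is an additive cell effect `c₀ + c_a·aspirin + c_h·1{eGFR≥73}`, and
risks are clipped to [0.001, 0.999] (the clip binds for well under 1% of
rows near the tails).  Each row's true potential-outcome risks are emitted,
so true subgroup effects are computable exactly.

The frozen constants were calibrated once, by least squares against a
target set of subgroup margins — risk differences (−0.12 / +0.05 by eGFR
stratum, −0.21 / +0.13 by aspirin), the untreated-risk structure implied by
the companion risk ratios via r₀ = RD/(RR−1), an aspirin prevalence of
0.5117, and a between-cluster eGFR mean gap of 4.57 —
`scripts/calibrate_preset.py` reproduces the derivation.  Presets `a1`,
`a2`, `a3` share this process at n = 10,000 / 100,000 / 1,000; `null` sets
a constant effect at the marginal mean of the cells; `hrs_like` is a
structural variant (majority-treated, low-incidence, harmful exposure) used
for report-format testing only.

What the generator does *not* emulate: covariate measurement error, missing
data (imputation is declared upstream of the tool), non-additive risk
surfaces, unmeasured confounding, informative selection, or time-varying
treatment.  Passing tests therefore certify the pipeline's mechanics and
its behaviour under a favourable, correctly specified world — not
robustness to the misspecifications real cohorts bring.

## Numerical and design choices

- Coordinate-descent tolerance 1e−8 on the maximum coefficient step; Gram
  form shared across a warm-started λ path.
- λ grid anchored at `max |2xᵀr| / max(α, 1e−3)` so the ridge limit keeps a
  finite grid.
- Split is simple random (not stratified), with a resample-and-warn guard
  that both arms appear in both splits.
- Design columns are ordered deterministically (treatment, mains in
  declared order, products lexicographically, then the mirrored treatment
  interactions) so coefficient vectors are comparable across runs.
- Cluster labels are canonicalized by ascending mean CATE; permuting the
  input leaves labels and the importance table unchanged.
- The bimodality diagnostic of the CATE distribution is a kernel-density
  valley-to-peak ratio (flag "bimodal" below 0.5, peaks counted above 5% of
  the modal height).  It is descriptive only and gates nothing; a vector
  constant to machine precision is reported "degenerate".
- Ties in Ward merges are measure-zero for jittered inputs and are left to
  scipy's ordering.

## Limitations

- The k > 2 behaviour of importance scores and cut-offs (max pairwise z
  difference; midpoint of extreme cluster means) is a conservative
  generalization; the procedure is demonstrated and calibrated at k = 2.
- Clustering a one-dimensional CATE vector names modifiers only through
  their association with the discovered clusters; modifiers whose effect is
  orthogonal to the dominant split direction can be missed at threshold
  0.2, and correlated covariates can be co-selected.
- Fitting the subgroup MSM on the full cohort re-uses the training split
  and can be slightly optimistic; the `msm_on_full_data=False` switch
  trades that for wider intervals.
- CV-minimum λ retains occasional tiny noise coefficients; use the 1-SE
  rule when sparsity of the reported model matters.
- No individual-level inference is offered (no per-ITE intervals); only
  aggregate and subgroup estimates carry uncertainty statements.
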