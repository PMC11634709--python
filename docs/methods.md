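# Methods

This note documents the models implemented in `mitolife`, their
assumptions, the defaults and why, and what the synthetic cohorts do and
do not emulate.

## Factorial design and coding

All models share one design: two mitochondrial backgrounds (A/B), two
nuclear backgrounds (A/B) and two diets (control/rapamycin), crossed
fully. Factors are coded sum-to-zero (+1 for the alphabetically first
level, −1 for the second); interaction columns are products of main
effect codes. Under this coding the intercept is the grand mean, each
term tests a balanced contrast, and in a balanced design the terms are
orthogonal, so Type-III tests coincide with sequential ones. Replicate
populations (3 per mitonucleogenotype, 12 in all) are pooled in the
headline models; per-population inference is available separately.

## Synthetic cohorts

`SimTruth` holds the generating truth. Latent death times follow a
location-scale family: y = x'β + σW with y the death time (logistic,
gaussian) or its logarithm (weibull, exponential, lognormal,
loglogistic), W the family's standard variate, and β a map from model
terms to effects (days, or log-days for log-scale families).

Observation mimics the assay: flies enrol at day 3 of adulthood (latent
times below day 3 are redrawn, i.e. the distribution is truncated, so β
keeps its interpretation as the untruncated location); deaths are scored
at three visits per week (days 3, 5, 7, 10, 12, 14, ...), and the
recorded day is the first visit at or after the latent time — death
days are therefore interval-rounded *up* by at most one visit gap.
A single integer seed drives a splittable generator with one substream
per replicate population, so any population can be regenerated in
isolation.

Defaults are the study's layout: 4 mitonucleogenotypes x 3 replicates x
2 diets x 10 vials x 15 females = 3600 flies; logistic lifespans with
location 60 d and scale 6 d (SD ≈ 11 d, realistic for *D. melanogaster*
cohorts), a +6 d rapamycin main effect and a 1.5 d three-way
interaction; egg counts are negative binomial per vial with mean
15 x 4 eggs/female under control, 15 x 2.5 under rapamycin, and
dispersion θ = 5.

What the generator does **not** emulate: per-vial random effects (the
source data give no evidence either way; a vial variance component would
inflate the factorial SEs), censoring (the assay followed all flies to
death; the analysis side still handles right-censored records),
mortality during handling, or day-to-day environmental variation.
Passing tests therefore demonstrate correctness of the estimators under
clean factorial sampling, not robustness to those unmodelled features.

## Parametric survival models

The likelihood for a death at t with linear predictor μ = x'β is
f_W((y−μ)/σ)/σ (times 1/t for log-scale families — the Jacobian keeps
log-likelihoods, and hence AICs, comparable between raw- and log-scale
candidates); a right-censored record contributes S_W((y−μ)/σ). Death
times are treated as exact at the scored day; an interval-censored
likelihood would acknowledge the up-rounding but is left as an
extension, since the visit gap (≤ 3 d) is small against lifespan spread
(SD ~ 11 d).

Fitting is BFGS on (β, ln σ) with the analytic score, started from least
squares on the events, with up to 5 jittered restarts; the covariance is
the inverse observed information (central-difference Hessian in
(β, σ)). Convergence requires the log-likelihood to dominate the start
value and the scaled gradient to vanish (tolerance 1e-8). The
exponential family fixes σ = 1.

Distribution choice fits all six families and keeps the lowest AIC
(AIC = −2ℓ + 2(dim β + 1), the scale counting as a parameter).

**Type-III ANOVA**: Wald statistic (Lβ̂)'(LV̂L')⁻¹(Lβ̂) per term with L
selecting the term's rows; with two-level factors every term has one
degree of freedom and the statistic reduces to β̂²/Var(β̂).

**Fast backward elimination** works entirely from the full model's β̂
and V̂: terms are deleted in ascending order of their Wald chi-square
conditional on the already-deleted set, and deletion stops when the
cumulative chi-square of the deleted set reaches twice its cumulative
degrees of freedom — i.e. while deleting the whole set still lowers the
approximate AIC relative to the full model. One refit of the survivors
finishes the procedure. Hierarchy is deliberately not enforced: a
three-way interaction may outlive its two-way children, which is
exactly the structure of interest in mito-nuclear x drug designs.

**Estimated marginal means** are model predictions on the equally
weighted 2x2x2 reference grid (in a balanced design they equal cell
means); SEs by the delta method. The four within-genotype
rapamycin-vs-control contrasts follow the pairwise convention
(first level minus second, i.e. control − rapamycin) and are reported
multiplied by −1 so that positive values mean life extension. P-values
carry a studentized-range (Tukey) adjustment; the family is taken as
the 8 cell means the contrasts span (for per-population tests, the 24
population-arm means). The source family is not stated in comparable
analyses, so the smallest natural spanning family was chosen; the
adjustment is conservative and always ≥ the raw p-value.

## Cohort demography

At each day x with at least one observed death the life table records
the proportion surviving l_x (deaths over initial cohort size — the
"cohort" estimator; censored flies are not deaths but do leave the risk
set used for weights), the gap Δx to the next such day (the final row
reuses the last gap; a single-day table uses a unit interval),
q_x = (l_x − l_{x+Δx})/(l_x Δx) and μ_x = −ln(1 − q_x). A day-0 anchor
row (l = 1) supports exact reconstruction; it and any terminal q = 1 row
(μ undefined) are flagged and excluded from regression. A KM-based l_x
mode exists for heavily censored data. Age is normalised to percent of
the group's maximum lifespan (the longest-lived individual), putting
groups with different maxima on one axis.

Kaplan–Meier estimation uses lifelines; Greenwood variance and
log-minus-log 95% bands are computed from the event table. The KM
difference curve (treated − control) is evaluated on the union event
grid with variance the sum of the two Greenwood variances; the control
arm is the implicit zero line.

## Segmented mortality regression

The response is μ_x on normalised age, weighted by survivors entering
each day (late-life rates are estimated from few flies and would
otherwise dominate). For K breakpoints the mean is continuous piecewise
linear; estimation augments the weighted linear model with
U_k = max(x − ψ_k, 0) and V_k = −1[x > ψ_k] and iterates
ψ_k ← ψ_k + γ̂_k/δ̂_k until max|γ̂| < 1e-6 (50 iterations cap), with a
damping step that halves the update while the continuous-model RSS would
increase, and projection keeping ψ ordered and inside the data range.
Quantile starts plus 10 random restarts are all explored and the best
converged fit kept, followed by a deterministic neighbourhood polish
(each breakpoint is tried in adjacent data intervals with bounded
refinement, keeping improvements): the iteration is local, and the
package's contract (checked against an exhaustive
interval-by-interval search) is the global weighted-least-squares
optimum. Convergence is declared when the gap coefficients vanish
(max|γ̂| < 1e-6) or, at non-smooth optima where the gap cannot vanish
(ψ pinned at a data point), when the damped iteration is stationary —
breakpoint movement and relative RSS change both numerically zero over
consecutive iterations.

A converged layout is valid only if every segment contains at least 15%
of the observations (configurable). This trim rule is the change-point
field's standard guard: a breakpoint whose flanking segment holds one or
two points has an unidentifiable slope change and a meaningless
delta-method CI, and admitting such layouts lets AIC manufacture
spurious inflections. Invalid layouts are flagged and excluded from
model selection.

The number of inflections (0–3) is chosen by AIC from the weighted
Gaussian log-likelihood ℓ = ½Σln w − (n/2)(ln 2π + ln(RSS_w/n) + 1)
with parameter count (K+2) + K + 1 (mean terms, breakpoints, variance).
This definition is invariant to rescaling all weights; ties within 1e-8
go to the smaller K. Breakpoint CIs are delta-method,
SE(ψ) = SE(γ̂)/|δ̂| at the converged augmented model, t-based with
n − (2K+2) df, truncated to the data range; |δ̂| < 1e-10 flags an
infinite-width interval. Prediction CIs condition on ψ̂ (breakpoint
uncertainty is not propagated — the standard, slightly anticonservative
practice). Two conditions "differ" at a queried lifespan percentile
exactly when their 95% prediction intervals are disjoint; the default
query points 30/50/70% are validated against inflection CIs with a
warning if they collide, and queries outside a group's observed
mortality range are reported as not evaluable.

Outlier diagnostics flag |standardised weighted residual| > 3 or Cook's
distance > 4/n and report the AIC with and without each flagged point
after refitting; exclusion is a user decision (`exclude_outliers` in the
pipeline config), never automatic.

## Fecundity

The response is eggs per vial divided by females per vial (15 by
design), modelled as negative binomial (variance μ + μ²/θ) with log
link over the factorial. Dividing counts by a constant produces
non-integer responses; the NB log-likelihood is evaluated through gamma
functions, which is well defined there — this reproduces the source
convention, while the count-orthodox alternative (raw counts with a
log-females offset) is available as `response="offset"`. Note the
caveat either way: dividing an NB count by 15 shrinks the
variance-to-mean ratio, so the per-female response is typically
*under*-dispersed and θ̂ runs to the Poisson limit; interaction tests
remain valid Wald tests of the log-linear cell structure. Fitting
alternates the IRLS GLM step at fixed θ with a bounded scalar ML update
of θ (method-of-moments start) to joint convergence at 1e-8 relative
log-likelihood; the joint log-likelihood is non-decreasing across
alternations.

## Pipeline

`run_pipeline` sequences simulate/load → survival models → life tables →
KM differences → segmented mortality → comparisons → fecundity, writes
every stage as CSV plus a JSON report, logs every selection decision
(distribution AIC table, K per condition, deleted terms, flagged
outliers), and is byte-deterministic given the seed.
`backcross_purge_fraction(g) = 100(1 − 2⁻ᵍ)` gives the expected percent
of residual donor nuclear differences removed by g backcross
generations (96.875% ≈ 97% at g = 5).

## Numerical choices and limitations

- Monte-Carlo checks in the test suite use 100-500 replicates and the
  cohort sizes given above; rates quoted in the acceptance script are
  estimated at those sizes.
- Wald inference is first-order; with 80 vials the NB Type-III test is
  mildly liberal (nominal 5% ≈ 5-7% empirically).
- AIC selection of breakpoint counts retains an irreducible overfitting
  tail (even with the trim rule, a spurious extra inflection clears the
  2-points-per-parameter penalty in roughly 5-10% of null datasets);
  treat a selected K as a description of the trajectory, not a test.
- No frailty/random effects, no interval-censored likelihood, no
  Gompertz/Makeham parametric hazards (the trajectory analysis is
  deliberately nonparametric-piecewise), no Davies test for breakpoint
  existence, and no zero-inflation in the fecundity model.
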