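# Methods

This note documents the models, the estimation machinery, the synthetic
worlds the test suite runs on, and the design choices made where more than
one defensible option existed.

## Covariance-structure engine

Models are specified in RAM form: a directed-path matrix **A**, a symmetric
(co)variance matrix **S** for exogenous parts and disturbances, and a
selection matrix **F** picking the observed variables, giving the implied
covariance Σ(θ) = F(I−A)⁻¹S(I−A)⁻ᵀFᵀ. Template entries are fixed numbers or
free-parameter labels; a repeated label is an equality constraint, and the
free-parameter count k is the number of distinct labels. Degrees of freedom
are p(p+1)/2 − k against full-rank covariance moments (means are not
modelled by default, which is equivalent to modelling them as saturated:
the mean structure then contributes zero to the discrepancy and to df).

Estimation minimises the normal-theory ML discrepancy
F = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p with an **analytic gradient**
(dF = tr[(Σ⁻¹ − Σ⁻¹SΣ⁻¹)dΣ], with dΣ assembled from the indicator matrices
of each label). Numerical choices:

* **Optimizer.** Per start: bounded L-BFGS-B (variances in
  [−10, 50]·mean-variance, other parameters in [−10, 10]) followed by an
  unbounded BFGS polish, from a heuristic start (variances at half the mean
  observed variance, paths at 0.1, covariances at 0) plus up to four
  jittered restarts, deterministic given the seed. The box on the first
  pass exists because some of these models possess runaway ridges — e.g. a
  trait factor trading off against a reversed residual chain whose
  coefficient approaches 1 — on which unbounded quasi-Newton can escape to
  ±∞ without converging. Restarts stop early when two starts agree on the
  minimum. Convergence requires gradient ∞-norm < 1e-4 on the F scale.
* **Non-PD Σ mid-iteration** returns a large smooth penalty (scaled by the
  most negative eigenvalue), never an exception.
* **Variances are unconstrained** in the final solution (Heywood cases are
  reported, not clamped), matching common SEM practice.
* **χ² scaling** is (n−1)·F (the `chi2_scale="n"` switch gives n·F).
* **Standard errors** come from the inverse observed information, i.e. the
  central-difference Hessian of (n−1)/2·F built from the analytic gradient.
* **Standardization** follows the std.all convention: every path is
  rescaled by sd(source)/sd(target) using model-implied standard deviations
  of *all* variables, latent ones included; covariances become
  correlations. SEs for standardized estimates use the delta method with a
  numerical Jacobian.
* **Fit indices.** CFI = 1 − max(χ²−df,0)/max(χ²_b−df_b, χ²−df, 0);
  TLI = ((χ²_b/df_b)−(χ²/df))/((χ²_b/df_b)−1), unclamped (it may exceed 1
  or go negative); RMSEA = sqrt(max(χ²−df,0)/(df(n−1))), with the 90% CI by
  Brent root-finding on the noncentral-χ² CDF. The independence baseline
  (free variances only) has the closed-form ML solution Σ = diag(S), so its
  χ² is −(n−1)ln|R|; the engine exposes the baseline as an ordinary spec
  and a test verifies the closed form against the fitted value. With df = 0
  the RMSEA is reported as 0 with an explicit flag.
* **RMSEA denominator** is (n−1); a switch selects n.

### Missing data

Sample moments are computed from listwise-complete rows. A full-information
casewise-likelihood estimator is not implemented; the battery's test
surfaces all run on complete synthetic panels, and analyses of incomplete
real panels should be aware of the listwise behaviour.

## The four structural models (T = 3, six observed composites)

Printed reference degrees of freedom — 5, 5, 12, 9 — are enforced by each
builder, which raises if an edited constraint pattern misses its target.

* **RI-CLPM (df = 5).** Trait factors with unit loadings and free
  covariance; occasion residuals carry all occasion variance (observed
  uniquenesses fixed 0); occasion-1 residuals freely covary and are
  orthogonal to the traits; AR and cross-lagged paths among residuals;
  disturbance covariances within occasions 2 and 3. The unstandardized
  paths are **equality-constrained across lags by default**: with free
  lags the model has 20 free parameters (df = 1); the equality constraint
  yields 16 (df = 5), which is the published layout. Standardized
  coefficients still differ per lag (standardization uses occasion-specific
  implied variances), so per-lag standardized cross-lags coexist with
  raw-scale equality. `lag_constrained=False` frees the lags.
* **Time-reversed RI-CLPM (df = 5).** Same trait/residual skeleton; the
  outcome construct's residual chain runs backwards (rY₃ exogenous,
  rY₃→rY₂→rY₁) with concurrent paths rX_t→rY_t (t = 1, 2); the predictor
  construct keeps a forward AR; exogenous rX₁ and rY₃ covary freely; paths
  free per lag; four disturbance variances. 16 free parameters. The exact
  internal variance layout of the published variant is not printed
  anywhere; this one meets the binding constraints (df = 5 and the two
  population sign oracles: concurrent coefficient positive under
  common-state data, negative under true-effect data). A
  `both_directions=True` variant reverses both constructs and adds
  reciprocal concurrent paths in one nonrecursive model (df = 3); the
  default is separate fits per direction.
* **LCSM (df = 12).** Observed composites without measurement error;
  latent change factors defined by fixed-1 paths (score_t = score_{t−1} +
  change_t); coupling (other construct's previous level → change) and
  autoproportion (own previous level → change) equality-constrained across
  lags; change variances equality-constrained across occasions; exogenous
  occasion-1 variances and covariance. 9 free parameters. Within-occasion
  change-change covariances are fixed 0 — the minimal layout reaching the
  reference df; every variance/covariance lives in the spec template and
  can be toggled by editing it.
* **MoSLA (df = 9).** Trait factors (free variances, free covariance);
  occasion state factors loading 1 on X_t and a free loading on Y_t
  equality-constrained across occasions; state AR equality-constrained;
  one shared label for the initial state variance and both innovation
  variances; occasion- and construct-specific unique variances. 12 free
  parameters. The single state-variance label means a stationary-start
  state process (initial variance σ²/(1−φ²)) is approximated, not exactly
  representable; at the reference parameter values the resulting
  population misfit is χ² ≈ 3 at n = 400, far below adequacy thresholds.

## Multilevel models 4–6

Person-mean centering subtracts each person's own across-occasion mean
(single-occasion persons get 0 and are flagged). Records for adjacent
occasions are stacked (two rows per person at T = 3) and fitted with a
person random intercept by ML through statsmodels `MixedLM`. Because the
centered outcome has, by construction, almost no between-person variance,
the variance component often sits at the 0 boundary where statsmodels'
post-fit Hessian inversion fails; the implementation then falls back to
pooled OLS, which is the exact ML solution at that boundary. P-values use
the normal approximation (no Satterthwaite degrees of freedom).
Standardization is grand: each analysis variable (including the centered
scores and the difference) is divided by its own standard deviation over
the stacked frame before fitting, so coefficients are on the β scale. The
same code path serves both directions (X→Y and Y→X) by renaming columns.

## The change-score expectation

For standardized X₁, Y₁, Y₂ the expectation
E(β) = (r_{X1,Y2} − r_{X1,Y1}) / (2(1 − r_{Y1,Y2})) equals
cov(X₁, Y₂−Y₁)/var(Y₂−Y₁), since var(Y₂−Y₁) = 2(1−r_{Y1,Y2}); the
simulation oracle computes exactly that ratio from 10⁶ trivariate-normal
draws. Other scalings of the crude change regression (e.g. dividing by
var(X₁), or standardizing the difference by its own sd) differ only by a
positive factor, so all of them share the sign law: negative iff the
concurrent correlation exceeds the lagged one. Because the denominator
shrinks as the retest correlation grows, a negative expectation becomes
strictly *more* negative with increasing stability — the property test
asserts this direction. Inputs are correlations of standardized variables;
the function does not rescale for unequal variances.

## Synthetic worlds

* **Spurious world (`gen_mosla`).** X_it = trait_x,i + St_it + e; Y_it =
  trait_y,i + λ·St_it + e; traits bivariate normal, states AR(1) with
  stationary initial variance (flag for non-stationary start), unique
  noise independent. All distributions normal — the only supported family,
  matching the normal-theory ML framework.
* **True-effect world (`gen_crosslagged`).** Bivariate AR(1) with
  cross-lagged coefficients, optional additive traits, normal innovations.
* Both worlds have closed-form population covariances
  (`mosla_implied_cov`, `crosslag_implied_cov`) verified against empirical
  moments at n = 3·10⁵ and used for population-level (infinite-n) fitting.
* **Cups (`gen_cups`).** Deterministic: weight_T2 = weight_T1 + water
  exactly; regimes with constant initial weight, varying initial weight,
  or equalized final weight reproduce the didactic slopes +1, −1, +1.

**Reference parameter preset** (`REFERENCE_MOSLA`): trait sd 0.8 per
construct, trait correlation 0.3, state sd 0.8, state AR 0.5, state loading
1 on both constructs, unique sd 0.45. At this point the population
standardized RI-CLPM cross-lag is 0.202 in both directions (squarely in the
0.15–0.25 range typical of published panels of this kind), the population
LCSM coupling is −0.04, the change-score expectation −0.34, and the MoSLA
fits its own world adequately at n = 400. What the generators do *not*
emulate: item-level measurement, floor/ceiling effects, non-normality,
attrition, occasion-specific mean structure. Passing tests therefore show
that the battery behaves correctly under its own assumptions, not that any
particular real dataset satisfies them.

## Battery, evidence table and verdict

Each model contributes its focal standardized coefficient with a 95% CI
(models 1–6) or its fit indices (model 7). Sign categories: '+' if the CI
lies above 0, '−' below, '0' otherwise. A model is *consistent* when its
category equals the predicted sign, *inconsistent* when it is the opposite
sign, neither when null. MoSLA adequacy: CFI ≥ 0.95 **and** RMSEA ≤ 0.06,
closed thresholds, configurable; the χ² p-value is reported but not
gating — no numeric "good fit" convention is universal, so these are this
package's documented defaults. The equal-weight verdict:

* **supported** — ≥ 5/6 of the estimable weight among models 1–6 is
  consistent *and* the MoSLA does not fit adequately;
* **contradicted** — ≥ 1/2 of the estimable weight is inconsistent;
* **inconclusive** — otherwise.

These thresholds operationalize informal evidence aggregation ("how many
models speak for, how many against") and are deliberately conservative
about declaring support: a well-fitting no-causal-paths model vetoes it.
Custom per-model weights replace counts by weight sums with the same 5/6
and 1/2 fractions. No multiple-testing correction is applied: the battery
is confirmatory triangulation across pre-specified sign predictions, not
discovery. Both directions are always reported; direction-symmetric fits
(models 1, 3, 7) are computed once and re-used.

Failures of individual models degrade to "not estimable" rows (the verdict
then uses the estimable subset); only the failure of all seven models
raises. Reports serialize to versioned JSON (sorted keys; byte-identical
given identical input, configuration and seed), CSV, or a plain-text table.

## Problem sizes used by the validation surfaces

Moment-fidelity oracles use 3·10⁵ simulated persons; parameter recovery
10⁵; the change-expectation oracle 10⁶ draws; CI-coverage checks 200
replicates at n = 400; the stochastic battery checks 200 spurious-world
replicates (n = 400) and 100 true-effect replicates (n = 2000, c = 0.3).
In the spurious-world replicate check, pattern membership is judged by
coefficient signs for models 1/2/5 and by "not significantly positive" for
models 3/6: at the reference effect size the standardized cross-lag's
sampling SE at n = 400 is ≈ 0.10 (verified by Monte Carlo against the
reported SEs), so CI-significance of model 1 per replicate has only ≈ 0.5
power and is not a meaningful per-replicate yardstick, whereas the
significance-based machinery is exactly what the verdict rates measure.

## Known limitations

* Normal-theory ML only: no robust/weighted estimators, no categorical
  indicators, no multigroup machinery.
* Listwise-complete moments only (see Missing data above).
* df targets are guaranteed for T = 3; builders produce structurally valid
  specs for larger T but their df values are not reference-checked.
* The time-reversed model's internal variance layout is one defensible
  choice among several with the same df; alternative layouts can be
  expressed directly through `SemModelSpec` templates or model syntax.
* Satterthwaite p-values for the mixed models are out of scope; inference
  there rests on coefficients and normal-approximation CIs.
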