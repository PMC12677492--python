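# paneltri

Triangulation battery for two-construct, three-wave panel data.

A statistically significant cross-lagged effect in a random-intercept
cross-lagged panel model (RI-CLPM) is *consistent with* a causal effect of
one construct on the other — it does not *prove* one. If longitudinal
measures of two constructs X and Y share trait-like confounds and
auto-correlated occasion-specific state factors, the RI-CLPM tends to report
significant but spurious cross-lagged effects. `paneltri` implements a
battery of seven models whose focal coefficients carry *different predicted
signs* under a true increasing effect of X on Y, so that agreement across
models — not one model's p-value — carries the causal conclusion. It is
aimed at researchers in psychology and epidemiology who work with repeated
two-construct panels (the motivating application is work-related curiosity
rated by employees and creativity rated by their supervisors, N = 400, three
occasions).

## The battery

For persons *i* and occasions *t* = 1..3, with composite scores
X<sub>it</sub>, Y<sub>it</sub>:

| model | specification | predicted sign under "X increases Y" |
|---|---|---|
| 1 | RI-CLPM: traits g<sub>X</sub>, g<sub>Y</sub> + within-person residuals with autoregressive and cross-lagged paths (equality-constrained across lags; df = 5) | **+** cross-lag rX<sub>t</sub> → rY<sub>t+1</sub> |
| 2 | time-reversed RI-CLPM: rY<sub>t</sub> ~ rX<sub>t</sub> + rY<sub>t+1</sub> (df = 5) | **−** (high X must have compensated a low earlier Y) |
| 3 | bivariate latent change score model: Y<sub>t</sub> = Y<sub>t−1</sub> + ΔY<sub>t</sub> (fixed 1s), ΔY<sub>t</sub> ~ X<sub>t−1</sub> + Y<sub>t−1</sub> (df = 12) | **+** coupling X → ΔY |
| 4 | multilevel y<sup>c</sup><sub>t+1</sub> ~ x<sup>c</sup><sub>t</sub> + y<sup>c</sup><sub>t</sub> (person-mean-centered, random person intercept) | **+** |
| 5 | multilevel y<sup>c</sup><sub>t</sub> ~ x<sup>c</sup><sub>t</sub> + y<sup>c</sup><sub>t+1</sub> | **−** |
| 6 | multilevel (y<sub>t+1</sub> − y<sub>t</sub>) ~ x<sup>c</sup><sub>t</sub> | **+** |
| 7 | MoSLA — model of spurious longitudinal associations: traits + common auto-correlated state factors, **no** directed X–Y paths (df = 9) | n/a: adequate fit means the data need no causal effects at all |

The SEM models (1, 2, 3, 7) are estimated by a built-in maximum-likelihood
covariance-structure engine (RAM parameterization, analytic-gradient
quasi-Newton, standard errors from the observed information, CFI/TLI/RMSEA
with noncentral-χ² confidence intervals, std.all standardization with
delta-method SEs). Models 4–6 are random-intercept regressions via
statsmodels `MixedLM` (ML).

The expected crude change-score coefficient follows the closed form

    E(β_{X1, Y2−Y1}) = (r_{X1,Y2} − r_{X1,Y1}) / (2 (1 − r_{Y1,Y2}))

negative exactly when the concurrent correlation exceeds the lagged one —
which common state factors and imperfect reliability make the default.

## Worked example

Simulate a panel from the spurious world — correlated traits plus a common
auto-correlated state, **zero** true cross-effects — and run the battery:

```bash
paneltri simulate --generator mosla --n 400 --seed 42 --out panel.csv
paneltri run --input panel.csv --seed 1
```

which prints (direction X → Y):

```
direction X -> Y: verdict = contradicted
model  pred   obs   estimate  mark
    1     +     +     +0.348  ✓
    2     -     +     +0.729  ✗
    3     +     0     -0.014  ·
    4     +     +     +0.113  ✓
    5     -     +     +0.633  ✗
    6     +     -     -0.569  ✗
    7   n/a   fit   CFI=1.00  · adequate fit
```

Read: the RI-CLPM alone (model 1) shows a significant positive cross-lag of
0.348 and would suggest a genuine increasing effect. But the time-reversed
models (2, 5) are significantly *positive* where a true effect predicts
negative, the crude change model (6) is negative where a true effect
predicts positive, and the no-causal-paths MoSLA fits the data well — so the
aggregate verdict is `contradicted`: the cross-lag is what spurious common
states produce, not what a real effect produces. On data generated *with* a
true reciprocal effect (`--generator crosslag`), all six sign checks come
out consistent, the MoSLA misfits, and the verdict is `supported`.

The evidence table, fit statistics and verdicts for both directions can be
written as versioned JSON, CSV or text via `--out report.json --format json`.

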