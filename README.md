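# ordsmooth

Generalized linear/additive models with **penalized ordinal predictors**:
ordered categorical covariates (severity grades, week-of-onset categories,
Likert items) enter through a dummy basis with a quadratic difference
penalty on adjacent level coefficients, smoothing parameters are estimated
by restricted maximum likelihood, and the full GAM inference toolkit —
Wald tests for smooth terms, pointwise Bayesian confidence intervals — is
available for the ordinal terms.  A built-in null-simulation harness
audits whether the resulting p-values can be trusted.

The package is written for biostatisticians and epidemiologists who face
models such as "binary outcome ~ confounders + week of first bacterial
detection", where the week is recorded on an ordinal scale (1..6, then an
open-ended "> 6" top category), some levels hold only a handful of
subjects, and plain dummy coding either wastes the ordering or diverges
outright under quasi-separation.

## Model

For response $y$ from an exponential family with mean $\mu = h(\eta)$,

$$\eta = \alpha + x^\top\gamma + f_1(o_1) + \dots + f_J(o_J),$$

where each ordinal predictor $o_j \in \{1,\dots,k_j\}$ contributes
$f_j(o) = \beta_{jo}$ through the indicator basis $B_{jl}(o) = 1\{o=l\}$.
The coefficients are fitted by minimizing the penalized deviance

$$D(\beta) + \sum_j \lambda_j J_j(\beta_j), \qquad
J_j(\beta_j) = \sum_l (\Delta^m \beta_j)_l^2, \quad m \in \{1, 2\},$$

so the first-order penalty shrinks each effect toward a constant and the
second-order penalty toward a straight line in the level index.  Each
$\lambda_j$ is chosen by Laplace-approximate REML (exact for the Gaussian
case); each dummy block is identified by a sum-to-zero constraint on its
level coefficients.  Parametric covariates get ordinary Wald z-tests;
penalized ordinal terms get the fractional-rank Wald test (second order)
or the random-effects score test (first order, whose penalty null space is
zero-dimensional — a boundary hypothesis in the mixed-model view), the
same dispatch used by reference GAM software.

## Worked example

`examples/fit_cohort.py` simulates a 100-infant cohort (binary lung-disease
outcome, six confounders, three 7-level ordinal bacterial-detection-week
predictors, of which only `pathogenic` truly has an effect) and fits the
full model with second-order penalties:

```
Smooth terms:
               edf  Ref.df   Chi.sq  p-value
gram_neg    3.9799  4.8336  10.0855   0.0648
gram_pos    1.8094  2.2828   1.4091   0.5250
pathogenic  1.0000  1.0000  11.1040   0.0009

Fitted effect of pathogenic-bacteria detection week:
 level    fit  lower  upper
     1  3.472  1.430  5.514
     2  2.314  0.953  3.676
     ...
     7 -3.472 -5.514 -1.430
```

The two null predictors are shrunk toward their penalty null spaces (small
edf, large p); the real decreasing-risk effect is detected (p = 0.0009)
and its fitted level coefficients — here shrunk all the way to a line
(edf = 1) — fall with detection week: the later the bacteria appear, the
lower the fitted risk.  The `lower`/`upper` columns are pointwise 95%
Bayesian intervals on the logit scale.

`examples/calibration_audit.py` reruns the package's p-value audit at 200
replicates: refitting the model on responses simulated from the
confounder-only fit (so the ordinal term is truly null) gives rejection
rates at $\alpha = 0.05$ of 0.065 for the first-order penalty versus 0.035
for the second-order penalty — the first-order test rejects too often,
which is why the second-order penalty is the recommended default for
testing.  `examples/penalty_limits.py` shows the penalty algebra and the
two shrinkage limits (λ→0: raw dummy fit; λ→∞: constant or straight line).

A thin CLI wraps the same calls: `ordsmooth fit --config config.yaml`,
`ordsmooth calibrate`, `ordsmooth simulate` (see `ordsmooth --help`).

## Layout

- `src/ordsmooth/basis.py` — indicator basis, difference/penalty matrices,
  sum-to-zero constraint, null-space bookkeeping
- `src/ordsmooth/fit.py` — penalized IRLS, REML/ML criterion, smoothing
  selection, `fit_gam`
- `src/ordsmooth/inference.py` — Wald tables, smooth-term tests, Bayesian
  intervals, prediction
- `src/ordsmooth/calibration.py` — null-simulation p-value audit
- `src/ordsmooth/synthetic.py` — cohort-style and generic generators with
  stored ground truth
- `src/ordsmooth/io.py`, `src/ordsmooth/cli.py` — tables, config, CLI
- `docs/methods.md` — modelling and numerical details
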