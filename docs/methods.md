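# Methods

## Model and basis

A generalized additive model $\eta = \alpha + x^\top\gamma + \sum_j f_j(o_j)$,
$\mu = h(\eta)$, with canonical links only (binomial/logit, gaussian/identity,
poisson/log).  Ordinal predictors $o_j$ are coded as integer levels
$1..k_j$ ($k_j \ge 3$); an open-ended top category (e.g. a "> 6 weeks"
label) is treated as the ordinary highest level — top-coding is the
caller's responsibility via the I/O level maps.  Each ordinal term uses the
full indicator basis, one dummy per level, so there are no knot or basis
choices to make; smoothness enters only through the penalty

- order 1: $J(\beta)=\sum_{l\ge 2}(\beta_l-\beta_{l-1})^2$, null space =
  constants;
- order 2: $J(\beta)=\sum_l(\beta_{l+1}-2\beta_l+\beta_{l-1})^2$, null
  space = constants and straight lines in the level index.

## Identifiability

The model carries an intercept, so each dummy block is reparameterized
onto the orthogonal complement of the ones vector (an orthonormal
$k\times(k-1)$ map $C$): $Z = BC$, $S = C^\top D^\top D\, C$, and full level
coefficients are recovered as $\beta = C\theta$, which sum to zero by
construction.  Centering over coefficients (rather than over fitted
values) keeps the intercept interpretable and treats levels symmetrically;
the choice shifts plotted level coefficients vertically relative to other
conventions but changes no fitted probability, test statistic or interval
width.  After the constraint the penalty null-space dimension is 0 (order
1) or 1 (order 2) — this single number drives the edf limits under heavy
smoothing and the choice of test (below).  Unobserved levels are allowed
(the penalty interpolates across the gap) and logged as a warning, since
such coefficients are identified only through the penalty.

## Fitting

For fixed $\lambda$, penalized IRLS with canonical-link working weights
$w=V(\mu)$ and step-halving (max 30) whenever a step increases the
penalized deviance; convergence requires relative penalized-deviance
change $<10^{-9}$ *and* max coefficient change $<10^{-8}$, within 200
iterations.  Binomial means start at $(y+0.5)/2$.  Non-convergence is a
flagged state (`converged=False`); inference functions refuse such fits.

Smoothing parameters minimize the Laplace-approximate negative restricted
marginal likelihood

$$V(\lambda) = -\ell(\hat\beta) + \tfrac{1}{2\phi}\hat\beta^\top S_\lambda\hat\beta
 + \tfrac12\log|H/\phi| - \tfrac12\log|S_\lambda/\phi|_+ - \tfrac{M_p}{2}\log 2\pi,$$

with $H = X^\top WX + S_\lambda$, $|\cdot|_+$ the pseudo-determinant over
the penalized subspace and $M_p$ the total null-space dimension.  For the
gaussian family this is exact and equals the closed-form restricted
likelihood of the equivalent linear mixed model (verified in the tests to
$10^{-6}$ over a 41-point grid); the dispersion is profiled analytically
inside the criterion as $(\text{RSS}+\text{pen})/(n-M_p)$, while the
*reported* `GamFit.scale` uses the conventional
$(\text{RSS}+\text{pen})/(n-\text{edf})$.  Binomial and poisson fix
$\phi=1$.  The ML variant integrates only over the penalized subspace
(Schur complement of the unpenalized block) and drops the $M_p$ term.

The search runs on $\log\lambda \in [-12, 12]^J$: a seeding grid followed
by Nelder–Mead (`fatol` $10^{-7}$).  The grid is dense — step 1 for one
term, step 3 for two, the 5-point product for three, coordinate sweeps
beyond — because the REML profile is frequently bimodal under weak or null
effects, with a boundary basin (effect shrunk to its null space) competing
against an interior one; a sparse seed can hand the local search the wrong
basin and measurably distort downstream p-values.  Solutions within 0.5 of
the box edge are reported with a warning: the term is then effectively
unpenalized (lower edge) or projected onto its penalty null space (upper
edge); this is a legitimate, common outcome under null effects, not an
error.

Effective degrees of freedom are the standard trace quantities,
$\mathrm{edf}_j = \mathrm{tr}_j\,(H^{-1}X^\top WX)$ restricted to the
term's columns, with the alternative version
$\mathrm{edf1}_j = \mathrm{tr}_j(2F - FF)$, $F = H^{-1}X^\top WX$, kept for
the smooth tests.  The Bayesian posterior covariance is
$V_b = \phi\,H^{-1}$.

## Smooth-term tests

Terms with a non-trivial penalty null space (order 2) use the
fractional-rank Wald construction (Wood, 2013, *Biometrika* 100:221–228):
the term's coefficients are rotated by the R factor of the IRLS-weighted
term block, the rotated covariance is eigen-decomposed, a pseudo-inverse
of generally non-integer rank $r = \min(k-1,\ \mathrm{edf1}_j)$ is formed
(leading $\lfloor r\rfloor$ directions inverted exactly, the fractional
remainder spread over the next), and the p-value comes from the matching
weighted sum of $\chi^2_1$ variables via the Liu–Tang–Zhang moment
approximation (averaging the two sign variants of the fractional
direction).  `Ref.df` reports $r$.

Terms with a zero-dimensional null space (order 1) pose a boundary
problem — "no effect" is a zero variance component in the mixed-model
formulation — and use the random-effects score-type test (Wood, 2013b):
statistic $\hat\beta_m^\top S_c\,\hat\beta_m/\phi$ with $S_c$ the Schur
complement of $H$ on the term's columns, referenced against
$\sum_i e_i\chi^2_1$ where $e_i$ are the eigenvalues of the statistic's
frequentist null covariance $R_m V_e R_m^\top/\phi$,
$V_e = H^{-1}X^\top WX\,H^{-1}\phi$.  This mirrors the dispatch of the
reference GAM implementation.  A simpler integer-rank chi-square rule was
tried first and rejected: it is visibly mis-calibrated under the null
(conservative for both orders), whereas the implemented pair reproduces
the known pattern — near-nominal second-order behaviour, anti-conservative
first-order behaviour.

Calibration caveat, measured by this package's own audit and confirmed by
running the reference implementation on an identical replicate stream: at
cohort sizes around $n=100$ the second-order test is itself slightly
conservative at the 5% corner (empirical rejection ≈ 0.02–0.04) and
anti-conservative in the 0.1–0.4 mid-range (KS distance to uniform
≈ 0.15); this distortion belongs to the procedure at small $n$, shrinks
with growing $n$, and is not an implementation artifact.

## Confidence intervals

Pointwise level-coefficient intervals map the posterior covariance through
the back-transform: $f = C\hat\theta$, $V_f = CV_{\theta}C^\top$,
$f \pm z_{0.975}\sqrt{\mathrm{diag}\,V_f}$.  By default the target is the
pure centered effect.  When the fitted effect is close to (but not
exactly) linear under the order-2 penalty, these effect-only intervals
under-cover — shrinkage bias concentrates in the few penalized directions
— and the standard fix applies: `include_intercept=True` switches the
target to intercept-plus-effect, adding the intercept row/column of the
posterior into the mapped covariance.  The simulations in the acceptance
suite show effect-only coverage dropping to ≈ 0.83 for a near-linear truth
while the intercept-inclusive target restores ≈ 0.91, without hurting the
clearly-nonlinear case (per-level coverage 0.91–0.97 at $n=1000$).

## Calibration harness

`run_calibration` implements the audit: fit the confounder-only model,
draw replicate responses from its fitted means at the original covariate
values (no covariate resampling), refit with the tested ordinal smooth
added (smoothing parameter re-estimated each time), store the smooth
p-value.  One master seed spawns an independent child stream per
replicate, so single replicates can be reproduced in isolation and whole
runs are bit-identical.  Non-converged refits are excluded and counted;
more than 20% failures aborts.  Summaries: rejection rates on an alpha
grid, the KS distance of the p-values to uniform, and a QQ table truncated
to the small-p corner.

## Synthetic data

`generate_bpd_like` emulates the structure of a neonatal cohort of
extremely-low-birth-weight preterm infants: binary outcome (moderate/severe
chronic lung disease), confounders weight, SGA, sex, multiples, steroid
and antibiotic days, and three mutually correlated 7-level ordinal
predictors (detection week of gram-negative, gram-positive and pathogenic
bacteria) with a sparse first level (default expected share 4%).
Confounder effect sizes default to published cohort-scale logit estimates
(weight −0.012/g, SGA 1.99, male sex 2.11, multiples 1.05, steroids
−0.17/day, antibiotics 0.08/day, intercept 6.43 → prevalence ≈ 0.3);
covariate distributions are not published and were fixed once as
cohort-plausible (weight truncated-normal below 1000 g, Poisson day
counts, Bernoulli binaries), all exposed in `BpdLikeConfig`.  Ordinal
effect shapes per predictor: `null`, `linear`, `decreasing_step` or a
custom vector (centered); the default gives only `pathogenic` a real
(step) effect.  Correlation among the ordinal predictors uses a Gaussian
copula (exchangeable, default 0.3).

What the generator does *not* emulate: the real cohort's exact marginal
distributions and covariate dependencies, informative missingness, any
outcome-dependent sampling, or censoring mechanisms beyond top-coding the
last week category.  Passing tests therefore demonstrate correctness of
the estimator, selector, tests and intervals under a faithful structural
analogue — not agreement with the restricted clinical data themselves,
whose published table values are estimates from data this package cannot
access.

`generate_ordinal_glm` is the minimal single-predictor test-bed (any
family, any effect vector, configurable occupancy) with stored ground
truth for recovery and coverage studies.

## Numerical choices

- Penalty PSD check: eigenvalues ≥ −10⁻¹⁰ accepted, negatives clipped to 0;
  penalty rank via a 10⁻⁸ relative eigenvalue threshold.
- Pseudo-inverse truncation in the smooth test: eigenvalues below
  `eps^0.9` (relative) count as rank-deficient, as in the reference
  implementation.
- Working weights floored at 10⁻¹⁰; binomial means clipped to
  [10⁻¹⁰, 1−10⁻¹⁰] inside link/deviance evaluations.
- An indefinite penalized Hessian raises immediately (it signals rank
  deficiency; the message suggests a stronger smoothing floor).
- Results tables serialize floats with 17 significant digits, so re-reading
  with exact parsing reproduces values bit-for-bit.

## Problem sizes used in the checked experiments

The test suite and `scripts/acceptance.py` run the calibration audit at
500 replicates on an $n=100$ cohort, interval coverage at 500 (suite) or
300 (script) replicates of $n=1000$, recovery at 50 replicates each of
$n \in \{250, 1000, 4000\}$, and the oracle/algebra checks at
$n \le 2000$ — sizes chosen so the full battery completes in minutes on a
single CPU while leaving the Monte-Carlo error well below the widths of
the assertion bands.

## Known limitations

- Canonical links only; no negative binomial, no tensor/interaction
  smooths, no continuous-covariate spline bases (confounders enter
  linearly), no monotonicity (isotonic) constraints, penalty orders 1 and
  2 only.
- GCV smoothing selection is deliberately not offered: inference after GCV
  selection is unreliable in this setting, and REML/ML are the supported
  selectors.
- No multiple-testing adjustment across smooth terms; per-term p-values
  are reported as-is.
- Pointwise (not simultaneous) intervals; no whole-curve bands.
- The first-order-penalty p-values are anti-conservative by the nature of
  the boundary hypothesis; use the second-order penalty when testing.
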