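# Methods

This note documents the statistical machinery implemented in `patternirt`,
the defaults it ships with, and the choices made where more than one
defensible convention exists.

## The measurement model

The scale is nine polytomous items in four ordered severity categories
(coded 0–3; boundaries indexed 1–3). The multidimensional graded response
model (MGRM) puts, for item *j* and latent severity vector θ ∈ ℝ²,

    P*_jt(θ) = F(a_j·θ + d_jt),  t = 1..m_j,

with P*_0 ≡ 1 and P*_{m+1} ≡ 0, and category probabilities by successive
differences. Boundary intercepts are *easiness* parameters and must
strictly descend, which the containers enforce as an invariant.

**Link.** Both the normal-ogive (probit) and logistic links are
implemented behind a single switch; probit is the package default because
the model is usually written as a normal-ogive integral, but the packaged
calibration's metric is not documented at source, so the bank records the
link as configurable rather than a fact. Slopes are not rescaled when the
link is switched; the ~1.7 logistic/probit scaling means cross-link
comparisons of slope values are not meaningful.

**Loading structure.** The scale has simple structure — items 1–5 load on
the liver-stagnation factor, items 6–9 on spleen deficiency — encoded as a
boolean loading pattern with structural zeros held exactly at 0 in every
operation, including every EM iterate. The packaged bank file pins item
9's first slope at 0 (its cell is blank in the source table, which is what
simple structure dictates). Items with an all-zero slope vector are legal
in the containers (simulation studies need null items) but are rejected by
MDISC and the ICC exporter.

**Information.** Item information is directional Fisher information
I(θ; u) = Σ_t (u·∇P_t)² / P_t. The default direction is the item's own
loading direction, and the test surface sums the nine item informations
each along its own direction, over a tensor grid with default range
[−4, 4] per axis and step 0.1 (configurable; information humps for this
calibration sit well inside that window). ICC curves are traced along an
item's own factor with the other coordinate fixed at 0, the prior mean.

**Severity scoring.** EAP scores are posterior means under the N(0, R)
prior and the MGRM likelihood, computed on the same quadrature rule as
estimation; missing items simply contribute no likelihood factor, and a
fully missing row returns the prior mean and SD, flagged.

## Estimation

Marginal maximum likelihood by EM ("full-information item factor
analysis").

* **E-step.** Respondent posteriors over a fixed quadrature rule. The
  default rule is tensor Gauss–Hermite with 21 nodes per dimension, built
  on the independent standard-normal scale and mapped through the Cholesky
  factor of the current latent correlation, so the stored weights are
  exact prior masses and no density reweighting is needed when the
  correlation moves. A scrambled-Sobol quasi-Monte-Carlo rule (default
  2000 points, stored seed) is available as an alternative E-step; the
  deterministic tensor rule is the default because it makes runs exactly
  reproducible.
* **M-step, items.** Each item's expected complete-data log-likelihood is
  maximized by L-BFGS-B with analytic gradients over its free slopes and
  all intercepts. The intercepts are optimized in an order-preserving
  parameterization (d_t = d_{t−1} − exp(g_t)), which keeps category
  probabilities positive at every line-search trial point; category
  probabilities are floored at 1e−12 inside the objective so count/probability
  ratios stay finite when a trial point collapses a cell. Search bounds
  (|slope| ≤ 25, |d₁| ≤ 15, gaps ≤ 12) exist to keep quasi-separated
  samples finite; estimates that touch them are flagged, as are categories
  whose expected count is (near-)zero.
* **M-step, correlation.** With unit variances fixed, the prior M-step
  maximizes −log|R|/2 − tr(R⁻¹M)/2 over correlation matrices, where M is
  the pooled posterior second moment about the origin. For two dimensions
  this is solved exactly by a bounded one-parameter search, which keeps
  the EM log-likelihood monotone; for more dimensions a rescale-to-unit-
  diagonal surrogate is used (close, but not exactly monotone).
* **Starting values and convergence.** Estimation starts from neutral
  values: free slopes 1, intercepts equally spaced and descending. The
  fit stops when the largest absolute change over all free item
  parameters and the latent correlation drops below the tolerance
  (default 1e−4) or after `max_iter` (default 500) iterations. The
  marginal log-likelihood path is recorded and is non-decreasing for the
  deterministic rule.
* **Empty categories.** The graded model is undefined for unobserved
  categories, so observed categories are remapped to a contiguous range
  per item before fitting; the remap is logged and returned with the
  result. With the packaged calibration's very negative top-category
  intercepts, top categories are genuinely rare (population rates of
  0.2–1%), so collapses are expected at a few hundred respondents: they
  reflect the calibration, not a defect of the sample.
* **Standard errors.** Optional, from a central-difference Hessian of the
  marginal log-likelihood at the solution, with the correlation held at
  its estimate. They are not part of the convergence loop.

## Confirmatory factor analysis

ML CFA of Σ = ΛΨΛᵀ + Θ with factor variances fixed at 1 and every
simple-structure loading free (identification by standardized factors; no
marker loading is fixed, so each loading carries a standard error).
Optimization is quasi-Newton with analytic gradients on log residual
variances (positivity) and the arctanh of the factor correlation; residual
variances that collapse below 0.5% of the observed variance are floored
and flagged as Heywood cases.

Conventions, chosen to match how this family of software reports results:

* χ² = (N − 1) · F_min, with S computed on the N − 1 denominator.
* The mean structure is saturated: intercepts contribute nothing to the
  discrepancy but are counted among the free parameters, so for 9 items
  the moment count is 54 and df = 27 (one factor) vs 26 (two factors).
* AIC = χ² + 2q with q = 27 / 28 — the intercept-counting convention
  reproduces published AIC values for this scale exactly from the
  published χ² values, which is how the convention was adjudicated.
* RMSEA = √(max(χ² − df, 0) / (df (N − 1))); CFI against the independence
  baseline (closed form F_base = Σ log s_ii − log|S|, df = p(p−1)/2),
  clipped to [0, 1].
* Input is a covariance matrix plus N; the convenience wrapper computes S
  from a response matrix treating categories as numeric scores on complete
  cases. This replicates the common ML-on-ordinal practice deliberately —
  polychoric CFA and robust corrections are out of scope.

The one-factor model is the two-factor model with the factor correlation
pinned at 1, so its minimized discrepancy can never be lower; the test
suite asserts this nesting along with exact self-fit on implied
covariances.

## Classical statistics

Cronbach's α uses listwise deletion (matching field practice of excluding
incomplete questionnaires) and N − 1 variances, with item-rest
correlations and α-if-deleted per item. Zero-variance items are an error
unless explicitly dropped. Demographic percentages are computed at two
decimals with round-half-up by default and an optional truncation mode;
any cell where the two modes disagree is flagged, since published tables
occasionally truncate and the 0.01 discrepancies are worth surfacing.

## Synthetic respondents

The generator emulates the validation-study conditions: latent severities
from a zero-mean bivariate normal with unit variances and correlation 0.5
(the two factors are assumed correlated; no population value is available,
so 0.5 is a documented stand-in treated as truth-to-recover in tests, not
as an empirical estimate), responses drawn from each item's category
distribution at the respondent's severity using the packaged calibration,
default n = 344. Missingness is completely at random and off by default —
it exists to exercise listwise-deletion code paths, not to model drop-out.

What the generator does *not* emulate: interviewer effects, item-wording
misunderstandings, informative missingness, demographic covariates, or any
misfit of the graded model itself. Passing recovery tests therefore show
that the estimation machinery inverts the generating model correctly at
these sample sizes; they cannot show that the model fits real clinical
responses.

## Problem sizes and numerical checks

The test and acceptance suites run the recovery study at n = 500 / 2000 /
4000 with a fixed seed (slope RMSE < 0.25 and intercept RMSE < 0.30 at
n = 2000; errors shrink from 500 to 4000), the quadrature oracle at 50
respondents against 201² trapezoid integration (1e−3 relative), and the
CFA direction check on 20 study-sized replicates. These sizes were chosen
as the smallest that make the statistical assertions stable.

Numerical details worth knowing: category probabilities are floored at
1e−300 in likelihood evaluations (pure logs) and 1e−12 inside the M-step
objective (ratios); cumulative probabilities saturate at 0/1 in double
precision roughly beyond |z| ≈ 8, so strict-monotonicity checks of ICC
tails must tolerate exactly-flat segments there; EAP integration reuses
the estimation rule, so scores are exactly reproducible.

## Known limitations

* A two-item factor is only weakly identified in the MGRM; slopes can run
  away (quasi-Heywood) at small n. The packaged scale has 5 + 4 items and
  is well behaved at n = 344, but toy configurations with two items per
  factor may converge slowly to boundary-flagged solutions.
* The EM iteration count needed on real clinical data, and QMC point
  counts matching other software, are data-dependent; iteration counts are
  reported but never asserted.
* Test–retest and alternate-form reliability are intentionally absent:
  the validation design this package mirrors could not carry them out.
* No polychoric CFA, no exploratory rotation, no bifactor or Rasch-family
  alternatives, no Bayesian estimation.
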