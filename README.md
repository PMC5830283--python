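# patternirt

Multidimensional item-response and factor-analytic validation of short
polytomous symptom scales, built around a 9-item instrument that grades the
severity of the *liver stagnation / spleen deficiency* pattern in
diarrhoea-predominant irritable bowel syndrome (IBS-D). The pattern is
modelled as two correlated latent severity factors: a **liver-stagnation**
factor driven by the mental symptoms (irritability, depression, discomfort
aggravated by mental disorders, lower-abdominal contracture, sighing) and a
**spleen-deficiency** factor driven by the abdominal-discomfort symptoms
(gastrointestinal rumbling, flatus, anorexia, relief after defecation).
Each item is answered in four ordered categories (0 = none … 3 = serious).

The package is aimed at psychometricians and clinical researchers who need
a complete, reproducible validation pipeline for this kind of scale:
classical reliability, a confirmatory one- versus two-factor comparison,
full-information item calibration, and latent severity scoring — plus a
synthetic-respondent generator so every stage can be exercised and tested
without access to clinical data.

## The models

**Multidimensional graded response model (MGRM).** For item *j* with
discrimination vector **a**ⱼ (one slope per latent dimension), boundary
"easiness" intercepts *d*ⱼ₁ > … > *d*ⱼₘ and latent severity vector **θ**,
the cumulative probabilities are

    P*ⱼₜ(θ) = F(aⱼᵀθ + dⱼₜ),   t = 1..m,   P*ⱼ₀ = 1,  P*ⱼ,ₘ₊₁ = 0,

with *F* the standard normal CDF (probit, the default) or the logistic CDF,
and exact category probabilities Pⱼₜ = P*ⱼₜ − P*ⱼ,ₜ₊₁. The package
evaluates these probabilities, Reckase's multidimensional discrimination
index MDISC = ‖**a**ⱼ‖₂ (items above 1 are high quality, 0.5–1 medium),
directional Fisher information and test-information surfaces, item
character curves, and EAP severity scores. Calibration is marginal maximum
likelihood by EM: a tensor Gauss–Hermite (or scrambled-Sobol QMC) E-step
under a N(0, R) prior with free correlation R, and per-item bounded
quasi-Newton M-steps under confirmatory simple-structure constraints.

**Confirmatory factor analysis.** Structural validity is tested by ML CFA
of the covariance structure Σ = ΛΨΛᵀ + Θ with factor variances fixed at 1,
comparing the unidimensional model against the two-factor model with
χ², CFI, RMSEA and AIC = χ² + 2q (q counts free parameters including the
saturated means: 27 vs 28 for the 9-item models, giving df 27 vs 26).

**Classical statistics.** Cronbach's α with item-rest correlations and
α-if-deleted on complete cases, and demographic percentage tables.

## Worked example

Simulate a study population of 344 respondents from the packaged
calibration (latent correlation 0.5) and run the validation sequence:

```python
import patternirt as pt

ds = pt.simulate_dataset(pt.SimulationConfig(n_respondents=344, seed=3))

rel = pt.cronbach_alpha(ds.responses)
S, means, n = pt.cov_from_responses(ds.responses)
uni = pt.fit_cfa(S, n, pt.one_factor_model(9))
two = pt.fit_cfa(S, n, pt.two_factor_model(ds.bank))
fit = pt.fit_mgrm(ds.responses, bank=ds.bank)
score = pt.eap_score(fit.bank, ds.responses.values[0], latent_cov=fit.latent_corr)
```

This prints (via the obvious format strings):

```
alpha = 0.757
unidimensional: chi2=201.90 df=27 p=0.0000 CFI=0.77 RMSEA=0.14 AIC=255.90
two-factor:     chi2=36.58  df=26 p=0.0815 CFI=0.99 RMSEA=0.03 AIC=92.58
converged=True iters=87 corr=0.469
item_id   a1   a2    d1    d2    d3  MDISC
  item1 1.84 0.00  0.11 -2.47 -5.14   1.84
  item2 3.30 0.00 -1.24 -3.94 -7.58   3.30
  ...
EAP severity: liver stagnation 1.53 (SD 0.32), spleen deficiency -0.30 (SD 0.59)
```

Reading the numbers: internal consistency is acceptable (α ≈ 0.76); the
unidimensional factor model is rejected (RMSEA 0.14, CFI 0.77) while the
two-factor model fits well (RMSEA 0.03, CFI 0.99, lower AIC), confirming
that the mental and abdominal symptom blocks measure distinct but
correlated severities (estimated latent correlation ≈ 0.47); the EM
calibration converges within the 1e-4 tolerance; and the first respondent —
who endorsed the mental symptoms but none of the abdominal ones — scores
1.5 SD above the population mean on liver stagnation but slightly below
the mean on spleen deficiency. Boundary intercepts estimated as NaN-padded
shorter rows arise when a rare top category was unobserved in the sample
and was collapsed away (logged during the fit).

The same pipeline is available from the shell:

```sh
patternirt simulate --n 344 --seed 3 --out study/
patternirt report study/responses.csv --out study/analysis/
```

which writes `results.json` (machine-readable, byte-reproducible under the
deterministic quadrature rule) and `report.txt`, plus the test-information
grid in long format.

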