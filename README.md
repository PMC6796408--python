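# cardiosem

Structural equation modelling of cumulative lifetime abuse and
cardiovascular-disease risk, rebuilt as a tested, reusable Python package.

## The problem

A longitudinal community study of 227 women who had left abusive partners
asked whether the severity of *lifetime* abuse — childhood abuse, partner
abuse, and adult sexual assault — affects early cardiovascular-disease risk
(blood pressure), directly and through depressive symptoms, smoking, and
body weight. The analysis is a covariance-structure SEM with three
distinctive ingredients:

- **A phantom composite.** No single instrument measures lifetime abuse, so
  a latent composite is defined purely by fixed unit paths from the three
  abuse latents; its variance is Var₁+Var₂+Var₃+2(Cov₁₂+Cov₁₃+Cov₂₃) and its
  disturbance is constrained to 20 % of its total variance.
- **A latent growth curve.** Depressive symptoms (CES-D) at five waves load
  on an intercept factor (all loadings 1) and a slope factor (loadings fixed
  0/1/2 at waves 1–3, free at waves 4–5 to allow a non-linear rate of
  change), with correlated intercept/slope disturbances.
- **Fixed reliability-based measurement error.** Each indicator's error
  variance is fixed at a stated fraction of its observed variance
  (e.g. 1 − Cronbach's α = .06 for the childhood-trauma score; 30 % for each
  CES-D wave; 25 % for each blood pressure).

The study's raw data are not public, but its full input moments are printed:
means, SDs and N per indicator, and the 14×14 Pearson correlation matrix.
Those tables ship with the package as CSV fixtures, so the entire published
analysis is reproducible from the printed numbers alone. The model is fitted
by maximum likelihood,

F_ML = ln|Σ(θ)| + tr(S Σ(θ)⁻¹) − ln|S| − p + (x̄−μ(θ))ᵀ Σ(θ)⁻¹ (x̄−μ(θ)),

with Σ(θ) = F(I−A)⁻¹S₀(I−A)⁻ᵀFᵀ in RAM form; χ² = (N−1)·F_ML at the
minimum, with RMSEA/CFI/TLI, a standardized solution, R² per endogenous
latent, standardized residuals, Wald tests, direct/indirect/total effect
decomposition, and parametric-bootstrap percentile intervals.

## Worked example

```python
>>> import cardiosem as cs
>>> study = cs.fit_study()          # packaged moments, final model, ML fit
>>> r = study.result
>>> print(f"chi2 = {r.chi2:.2f} (df = {r.df}), chi2/df = {r.relative_chi2:.2f}")
chi2 = 148.95 (df = 75), chi2/df = 1.99
>>> print(f"RMSEA = {r.rmsea:.3f}  CFI = {r.cfi:.3f}  TLI = {r.tli:.3f}")
RMSEA = 0.066  CFI = 0.937  TLI = 0.923
>>> round(r.standardized_coefficients["DepIntercept~LifetimeAbuse"], 3)
0.441
>>> round(r.r_squared["CVDRisk"], 3)
0.408
>>> row = study.effects.lookup("LifetimeAbuse", "BodyWeight")
>>> print(f"direct {row.direct:.3f}  indirect {row.indirect:.3f}  total {row.total:.3f}")
direct 0.228  indirect -0.056  total 0.172
```

Reading: the model fits acceptably (χ²/df = 1.99, RMSEA .066); more severe
lifetime abuse predicts a higher initial level of depressive symptoms
(β = .44) and, indirectly through smoking, a *lower* body weight
(indirect −.05 partially offsetting the direct +.23); 41 % of the variance
in the CVD-risk latent is explained. The study reports these same
quantities as 1.99, .07, .428, .41, .213/−.048 — the residual differences
come from the 2-decimal rounding of the published correlations.

The `examples/` directory holds one narrative script per capability
(study reproduction, effect decomposition, bootstrap intervals, synthetic
data and recovery, user-defined models); each prints what it computes and
what the numbers mean. A thin CLI wraps the same functions:

```bash
cardiosem fit --bootstrap 500 --seed 7 --out-dir results/
cardiosem simulate --n 227 --coarsen --seed 1
```

## Scope

The package implements the final published model. Out of scope: scoring the
instruments from item-level data, the exploratory respecification search
that produced the final model (modification indices are not computed),
missing-data estimation, and categorical-data (WLSMV-style) estimators.
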