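# Methods

## Model

The package fits covariance-structure models in RAM form. All variables —
14 observed indicators and 10 latents — are stacked into one vector; a
directed-coefficient matrix **A** holds loadings and structural
regressions, a symmetric matrix **S** holds exogenous (co)variances,
disturbances and measurement-error variances, and a vector **m** holds
intercepts and factor means. With **B** = (I−A)⁻¹ and **F** the selector of
observed rows, the implied moments are Σ(θ) = **F B S Bᵀ Fᵀ** and
μ(θ) = **F B m**. The ML discrepancy

F(θ) = ln|Σ| + tr(S_sample Σ⁻¹) − ln|S_sample| − p + (x̄−μ)ᵀΣ⁻¹(x̄−μ)

is minimized over the free parameters; (N−1)·F at the minimum is the model
χ². The mean term is present whenever the model declares mean parameters
and is omitted for covariance-only models.

### The built-in study model

`build_whes_model()` returns the final published model for the 14
indicators (variable order follows the printed correlation matrix):

- **Measurement.** One latent per concept. Single-indicator latents (age,
  the three abuse measures, smoking) have their loading fixed at 1 and
  their error variance fixed at *fraction × observed variance* — the
  fixed-reliability construction, with fractions from 1 − Cronbach's α
  where available and assigned values elsewhere (final values after the
  study's adjustments: AGE 1 %, CTQ 6 %, ISA/ASA 15 %, CES-D 30 % per wave,
  SMOKE 5 %, WC 5 %, BMI 16 %, SBP/DBP 25 %). Two-indicator latents fix the
  first loading (WC for body weight, SBP for CVD risk) and estimate the
  second (BMI, DBP): with error variances fixed as fractions, a second
  fixed-unit loading cannot fit two indicators of very different variance
  (SBP SD 15.5 vs DBP SD 9.5 would leave a standardized diagonal residual
  near 7), and the freed loading is what reproduces the published fit and
  residual profile.
- **Phantom composite.** Lifetime abuse receives fixed unit paths from the
  three abuse latents; its explained variance is the sum of their variances
  plus twice their covariances, and its disturbance is *constrained* to
  (0.20/0.80) × explained variance — i.e. 20 % of total variance —
  re-derived from the current parameter values at every iteration (the
  constraint is part of the gradient via the chain rule).
- **Growth curve.** CES-D waves 1–5 load 1 on the intercept factor; slope
  loadings are fixed 0/1/2 at waves 1–3 and free at waves 4–5. The
  intercept and slope disturbances covary freely.
- **Structure.** Thirteen structural regressions: lifetime abuse →
  {intercept, slope, smoking, body weight, CVD risk}; intercept → body
  weight; slope → {smoking, body weight, CVD risk}; smoking → {body weight,
  CVD risk}; body weight → CVD risk; age → CVD risk. The published effects
  table lists a direct smoking → CVD-risk entry and the stability analysis
  counts thirteen paths, so the model includes it. Six free covariances
  among the four exogenous latents.
- **Means.** Growth-model convention: all five CES-D intercepts fixed at 0,
  intercept and slope factor means free, the nine remaining indicator
  intercepts free. The slope mean is recovered at −2.53 raw CES-D points
  per unit loading (symptoms improve over time).

This gives 44 free parameters against p(p+3)/2 = 119 sample moments:
df = 75, matching the published accounting; the covariance-only variant
(`include_means=False`) has 33 free parameters against 105 moments. The
three abuse indicators are standardized to unit variance before the
covariance is formed, as in the source analysis, because they are measured
on incommensurable scales.

Two indicator moments are not printed and are derived from printed counts:
the binary sexual-assault indicator (mean = prevalence 88/227,
SD = √(p(1−p))) and the 0/1/2-coded smoking history (counts 75/68/84,
population-divisor moments). The divisor choice is immaterial at N = 227
but is documented; the (N−1) scaling enters only through the χ².

## Estimation

- **Gradient.** Analytic, via tr(M dΣ) with
  M = Σ⁻¹ − Σ⁻¹S_sampleΣ⁻¹ − Σ⁻¹ddᵀΣ⁻¹: directed entries contribute
  2(CGB)ⱼᵢ, symmetric entries Hᵢⱼ-terms with H = BᵀGB, mean entries
  −2(Bᵀĝ)ᵢ, and the phantom constraint adds its chain-rule term. The
  gradient is verified against finite differences in the test-suite.
- **Search.** L-BFGS-B from documented starting values (free loadings 1,
  growth-slope loadings 2, structural paths 0.1, exogenous (co)variances at
  the sample moments of their indicators, intercept/slope disturbances at
  35 %/5 % of the first-wave variance, intercepts at sample means),
  followed by a damped-Newton polish using a finite-difference Hessian of
  the analytic gradient, to an infinity-norm gradient tolerance of 1e−8;
  up to 20 jittered restarts (seeded) on failure. The fixture fit converges
  from the default start with gradient norm ~4e−11 in about 1.5 s.
- **Admissibility** is not enforced during search; negative variance
  estimates are reported as Heywood flags, never silently bounded.
  Parameter points where Σ is not positive definite receive a large finite
  penalty and can never be reported as converged solutions.
- **Standard errors** come from the inverse observed information — the
  Hessian of (N−1)/2 · F by central finite differences of the analytic
  gradient — with two-sided normal p-values (α = .05 convention; no
  multiplicity correction, matching the source analysis).
- **Baseline model** for CFI/TLI is the independence model with free
  variances (and saturated means), whose ML minimum has the closed form
  χ²_b = −(N−1)·ln|R|; df_b = p(p−1)/2 = 91.
- **Standardized residuals** use
  (s−σ)/√((σᵢᵢσⱼⱼ+σᵢⱼ²)/N). The largest value for the fixture fit is 1.96;
  this normalization is one of several in use, so the residual magnitude is
  a soft diagnostic rather than a reproduction target.
- **PD repair.** Printed 2-decimal correlations can be marginally
  indefinite; `nearest_pd` clips eigenvalues at a floor and logs the repair
  magnitude. The packaged matrix is positive definite (smallest eigenvalue
  0.103) and is used unchanged.

## Effects and bootstrap

Effects are decomposed on the standardized structural solution:
T = (I−B)⁻¹−I (total), B (direct), T−B (indirect); total = direct +
indirect to machine precision by construction. An explicit DFS
path-enumeration oracle computes the same quantities independently and the
two routes are cross-checked on random acyclic systems in the tests.

The study bootstrapped raw records, which are unavailable; the default here
is a *parametric* bootstrap — replicates of N = 227 records drawn from the
fitted implied Gaussian, re-summarized (including re-standardization of the
abuse indicators), and refitted warm-started from the solution with the
error-variance constants frozen at their original values, exactly as fixed
model constants behave under a raw-data bootstrap. Intervals are percentile
at the stated level; interval agreement with the published raw-data
bootstrap is therefore approximate by construction. Replicates whose final
gradient norm exceeds 1e−4 are dropped and counted; >50 % drops flag the
result unstable. Row-resampling of user-supplied raw data is available
through the same function.

## Synthetic data

`generate` simulates records structurally — exogenous latents and
disturbances from zero-mean Gaussians with the specified (co)variances,
propagated through the directed equations, measurement error added per the
fixed error variances, means added when the model carries them — so the
sample covariance converges to Σ(θ_true). Optional coarsening dichotomizes
the sexual-assault column and trichotomizes the smoking column at empirical
quantiles matching target shares (probit-style discretization; the packaged
defaults are the study margins 38.8 % and 33/30/37 %). Coarsening
attenuates product-moment correlations involving those columns, which the
tests verify; recovery checks on coarsened data are correspondingly
looser. What the generator does *not* emulate: non-Gaussian latent
distributions, longitudinal attrition, floor/ceiling effects of the
instruments — so passing recovery tests demonstrate correctness of the
estimator under the model's own assumptions, not robustness to their
violation.

`recovery_experiment` derives per-replicate seeds deterministically from a
master seed, refits each simulated dataset, and reports bias and RMSE per
parameter. Two details matter for honest recovery checks. First, the fixed
error variances are model *constants*, so each refit reuses the generating
values (`matched_error_fractions` rescales the fractions by generating /
replicate variance); re-materializing them against replicate variances
would inject a misfit that grows with n and masquerades as bias. Second,
each parameter is judged against max(|truth|, natural scale), where the
natural scale comes from the implied SDs at truth — sd(target)/sd(source)
for a directed coefficient, sd_i·sd_j for a covariance, var_i for a
variance, sd_i for a mean — so a 2 % band corresponds to 2 % on the
standardized parameter regardless of the indicator's raw units, and
near-zero paths are assessed on the footing of their standardized
counterparts rather than an impossible relative band.

## Design choices and numerical conventions

- χ² uses (N−1)·F (the convention of the software era the study used);
  N-scaling is available behind `chi2_scale="n"`.
- The mean structure is part of the default published-model fit: the
  printed slope mean, the degrees of freedom (75 = 119 − 44) and the χ²
  are jointly consistent only under a means+covariance fit with the growth
  intercepts fixed at zero. The covariance-only variant remains available
  and fits the same covariance structure with df = 72.
- "A 5 % decrease for waist circumference" is read as a final WC error of
  5 % (10 % → 5 %), since all other adjustments are stated as final
  percentages; the childhood-trauma error stays at 1 − .94 = 6 %.
- The standardized-solution rescaling invariance holds for indicators whose
  metric is absorbed by a free parameter (a free loading or a free latent
  variance). It deliberately does not hold for the CES-D waves: the fixed
  0/1/2 slope loadings make the repeated-measures metric substantive.
- Derived SD cells in the fixtures (sexual assault, smoking) are stored at
  6 decimals and re-derived in tests from the printed counts.
- Tolerances in the reproduction tests (±0.05 on standardized coefficients,
  ±0.15 on χ²/df, ±0.04 on R²) reflect propagation of the ±0.005 rounding
  of each printed correlation through the fit, not estimator noise: the
  fit itself is deterministic.

## Problem sizes used by the test-suite

The suite fits the 44-parameter study model a few dozen times (fixture
moments, rescaled variants, pinned-parameter variants), runs 500
parametric-bootstrap replicates at N = 227 for the interval check, three
recovery replicates at N = 20,000, and Monte-Carlo implied-covariance
checks at N = 3×10⁵ — sizes chosen so every check runs comfortably on one
CPU while keeping Monte-Carlo error well below the tolerances tested.

## Known limitations

- Only recursive (acyclic) structural systems are supported; no FIML for
  missing data; no robust/scaled χ² or categorical-data estimators; no
  modification indices (the exploratory respecification that produced the
  final model is out of scope).
- The bootstrap is parametric unless raw records are supplied; published
  raw-data intervals can differ, particularly for paths with skewed
  indicators.
- Standard errors rely on a finite-difference observed information; for
  models with poorly identified parameters the Hessian inversion is
  reported as unavailable rather than regularized.
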