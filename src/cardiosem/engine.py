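"""Maximum-likelihood covariance-structure estimation.

The model is assembled in RAM form over the stacked vector of observed and
latent variables: a directed-coefficient matrix A, a symmetric
(co)variance matrix S of exogenous variances, disturbances and measurement
errors, and an intercept/mean vector m. The implied moments are

    Sigma(theta) = F (I - A)^-1 S (I - A)^-T F^T,
    mu(theta)    = F (I - A)^-1 m,

with F selecting the observed rows. The ML discrepancy

    F_ML = ln|Sigma| + tr(S_sample Sigma^-1) - ln|S_sample| - p
           [+ (xbar - mu)' Sigma^-1 (xbar - mu)  with a mean structure]

is minimized over the free parameters with an analytic gradient, quasi-Newton
search and a Newton polish; (N-1) * F_ML at the minimum is the model
chi-square. Fit indices, the standardized solution, R-squared, standardized
residuals and Wald tests are derived from the solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import minimize

from .model import ModelSpec
from .moments import MomentSet, nearest_pd, to_covariance

__all__ = [
    "CompiledModel",
    "ParameterAssignment",
    "FitOptions",
    "FitResult",
    "InadmissibleParameterError",
    "compile_model",
    "implied_covariance",
    "ml_discrepancy",
    "fit",
    "baseline_chi2",
    "fit_indices",
    "standardize",
    "r_squared",
    "standardized_residuals",
    "wald_tests",
]


class InadmissibleParameterError(ValueError):
    pass


#: objective value returned outside the admissible (PD) region
_PENALTY = 1e12


@dataclass
class ParameterAssignment:
    """Free-parameter values plus the matrices they assemble to."""

    values: dict[str, float]
    directed: np.ndarray  # A, over all variables (target row, source column)
    symmetric: np.ndarray  # S
    means: np.ndarray  # m
    variable_names: tuple[str, ...]

    def __getitem__(self, label: str) -> float:
        return self.values[label]


@dataclass
class FitOptions:
    standardize: tuple[str, ...] = ()
    chi2_scale: str = "n-1"  # or "n"
    gtol: float = 1e-8
    max_restarts: int = 20
    seed: int = 0
    compute_se: bool = True
    pd_repair_floor: float = 1e-8


@dataclass
class FitResult:
    estimates: ParameterAssignment
    param_names: tuple[str, ...]
    theta: np.ndarray
    discrepancy_min: float
    chi2: float
    df: int
    p_value: float
    rmsea: float
    cfi: float
    tli: float
    baseline_chi2: float
    baseline_df: int
    standardized_coefficients: dict[str, float]
    r_squared: dict[str, float]
    standardized_residuals: np.ndarray
    std_errors: dict[str, float]
    wald_z: dict[str, float]
    wald_p: dict[str, float]
    converged: bool
    n_iterations: int
    n_restarts: int
    gradient_norm: float
    heywood: tuple[str, ...]
    sample_cov: np.ndarray
    implied_cov: np.ndarray
    sample_mean: np.ndarray | None
    implied_mean: np.ndarray | None
    n: int
    model: ModelSpec
    compiled: "CompiledModel"

    @property
    def relative_chi2(self) -> float:
        return self.chi2 / self.df


class CompiledModel:
    """A ModelSpec bound to index arrays for fast assembly and gradients.

    When the spec carries error fractions, fixed measurement-error variances
    are materialized as fraction x observed variance, frozen from the
    MomentSet the model is compiled against.
    """

    def __init__(
        self,
        spec: ModelSpec,
        moments: MomentSet | None = None,
        standardize: tuple[str, ...] = (),
        pd_repair_floor: float = 1e-8,
    ):
        spec.validate()
        self.spec = spec
        self.observed = spec.observed_names
        self.latent = spec.latent_names
        self.names = self.observed + self.latent
        self.p = len(self.observed)
        self.t = len(self.names)
        self.ix = {v: i for i, v in enumerate(self.names)}
        self.standardized = tuple(standardize)

        self.A0 = np.zeros((self.t, self.t))
        self.S0 = np.zeros((self.t, self.t))
        self.m0 = np.zeros(self.t)

        self.sample_cov: np.ndarray | None = None
        self.sample_mean: np.ndarray | None = None
        self.n: int | None = None
        if moments is not None:
            if tuple(moments.variable_names) != tuple(self.observed):
                # allow any ordering of the same variable set
                if set(moments.variable_names) != set(self.observed):
                    raise ValueError(
                        "moment variables do not match model observed variables"
                    )
                idx = [moments.variable_names.index(v) for v in self.observed]
                cov = to_covariance(moments, standardize)[np.ix_(idx, idx)]
                mean = moments.means[idx].copy()
            else:
                cov = to_covariance(moments, standardize)
                mean = moments.means.copy()
            for v in standardize:
                mean[self.observed.index(v)] = 0.0
            self.sample_cov = nearest_pd(cov, pd_repair_floor)
            self.sample_mean = mean
            self.n = moments.n

        if spec.error_fractions:
            if self.sample_cov is None:
                raise ValueError(
                    "model declares error fractions; compile against a MomentSet"
                )
            for v, f in spec.error_fractions.items():
                i = self.ix[v]
                self.S0[i, i] = f * self.sample_cov[self.observed.index(v),
                                                    self.observed.index(v)]

        # free-parameter positions
        self.labels: list[str] = []
        self._apos: dict[str, list[tuple[int, int]]] = {}
        self._spos: dict[str, list[tuple[int, int]]] = {}
        self._mpos: dict[str, list[int]] = {}

        def slot(label: str) -> None:
            if label not in self.labels:
                self.labels.append(label)
                self._apos[label] = []
                self._spos[label] = []
                self._mpos[label] = []

        for pth in spec.paths:
            si, ti = self.ix[pth.source], self.ix[pth.target]
            if pth.kind == "directed":
                if pth.status == "fixed":
                    self.A0[ti, si] = pth.value
                else:
                    slot(pth.label)
                    self._apos[pth.label].append((ti, si))
            else:
                if pth.status == "fixed":
                    self.S0[si, ti] = self.S0[ti, si] = pth.value
                else:
                    slot(pth.label)
                    self._spos[pth.label].append(tuple(sorted((si, ti))))
        for mn in spec.means:
            vi = self.ix[mn.variable]
            if mn.status == "fixed":
                self.m0[vi] = mn.value
            else:
                slot(mn.label)
                self._mpos[mn.label].append(vi)
        self.q = len(self.labels)

        # phantom constraints: S[ph, ph] derived from source (co)variances
        self._phantoms: list[tuple[int, float, list[tuple[int, int, float]]]] = []
        for ph in spec.phantom_constraints:
            pi = self.ix[ph.phantom]
            srcs = [self.ix[s] for s in ph.sources]
            terms = []
            for a in range(len(srcs)):
                terms.append((srcs[a], srcs[a], 1.0))
                for b in range(a + 1, len(srcs)):
                    terms.append((srcs[a], srcs[b], 2.0))
            self._phantoms.append((pi, ph.factor, terms))
        # per-label sensitivity of each phantom disturbance
        self._phantom_coeff = np.zeros((len(self._phantoms), self.q))
        for g, (pi, fac, terms) in enumerate(self._phantoms):
            tset = {(i, j): mult for i, j, mult in terms}
            for k, lab in enumerate(self.labels):
                c = 0.0
                for (i, j) in self._spos[lab]:
                    key = (i, j) if (i, j) in tset else (j, i)
                    if key in tset:
                        c += fac * tset[key]
                self._phantom_coeff[g, k] = c

        if self.sample_cov is not None:
            sgn, self._logdet_sample = np.linalg.slogdet(self.sample_cov)
            if sgn <= 0:
                raise InadmissibleParameterError(
                    "sample covariance not positive definite after repair"
                )

    # -- assembly -----------------------------------------------------------
    def assemble(self, theta: np.ndarray):
        A = self.A0.copy()
        S = self.S0.copy()
        m = self.m0.copy()
        for k, lab in enumerate(self.labels):
            v = theta[k]
            for (i, j) in self._apos[lab]:
                A[i, j] = v
            for (i, j) in self._spos[lab]:
                S[i, j] = v
                S[j, i] = v
            for i in self._mpos[lab]:
                m[i] = v
        for pi, fac, terms in self._phantoms:
            S[pi, pi] = fac * sum(mult * S[i, j] for i, j, mult in terms)
        return A, S, m

    def theta_from_mapping(self, values) -> np.ndarray:
        if isinstance(values, ParameterAssignment):
            values = values.values
        missing = [lab for lab in self.labels if lab not in values]
        if missing:
            raise KeyError(f"missing values for parameters: {missing}")
        return np.array([values[lab] for lab in self.labels], dtype=float)

    def assignment(self, theta: np.ndarray) -> ParameterAssignment:
        A, S, m = self.assemble(theta)
        return ParameterAssignment(
            values={lab: float(theta[k]) for k, lab in enumerate(self.labels)},
            directed=A,
            symmetric=S,
            means=m,
            variable_names=self.names,
        )

    def full_implied(self, theta: np.ndarray):
        A, S, m = self.assemble(theta)
        I = np.eye(self.t)
        try:
            B = np.linalg.inv(I - A)
        except np.linalg.LinAlgError as exc:
            raise InadmissibleParameterError("(I - A) is singular") from exc
        C = B @ S @ B.T
        mu = B @ m
        return A, S, m, B, C, mu

    def implied_covariance(self, theta: np.ndarray) -> np.ndarray:
        C = self.full_implied(theta)[4]
        return C[: self.p, : self.p]

    def implied_mean(self, theta: np.ndarray) -> np.ndarray:
        mu = self.full_implied(theta)[5]
        return mu[: self.p]

    # -- objective and gradient ----------------------------------------------
    def discrepancy(self, theta: np.ndarray, with_grad: bool = False):
        p, t = self.p, self.t
        Ssamp = self.sample_cov
        A, S, m, B, C, mu = self.full_implied(theta)
        Sigma = C[:p, :p]
        sgn, logdet = np.linalg.slogdet(Sigma)
        if sgn <= 0 or not np.isfinite(logdet):
            # outside the admissible region: large finite penalty
            return (_PENALTY, np.zeros(self.q)) if with_grad else _PENALTY
        W = np.linalg.inv(Sigma)
        Fval = logdet + float(np.sum(W * Ssamp)) - self._logdet_sample - p
        use_means = self.spec.has_means and self.sample_mean is not None
        if use_means:
            d = self.sample_mean - mu[:p]
            Wd = W @ d
            Fval += float(d @ Wd)
        if not with_grad:
            return Fval

        M = W - W @ Ssamp @ W
        if use_means:
            M = M - np.outer(Wd, Wd)
        G = np.zeros((t, t))
        G[:p, :p] = M
        H = B.T @ G @ B
        K = C @ G @ B  # for directed entries: dF/dA_ij = 2 K[j, i]
        if use_means:
            ghat = np.zeros(t)
            ghat[:p] = Wd
            w = B.T @ ghat
            v = B @ m
        grad = np.zeros(self.q)
        for k, lab in enumerate(self.labels):
            g = 0.0
            for (i, j) in self._apos[lab]:
                g += 2.0 * K[j, i]
                if use_means:
                    g += -2.0 * w[i] * v[j]
            for (i, j) in self._spos[lab]:
                g += H[i, i] if i == j else 2.0 * H[i, j]
            for i in self._mpos[lab]:
                g += -2.0 * w[i] if use_means else 0.0
            grad[k] = g
        for gi, (pi, fac, terms) in enumerate(self._phantoms):
            grad += self._phantom_coeff[gi] * H[pi, pi]
        return Fval, grad

    # -- starting values ------------------------------------------------------
    def start_values(self) -> np.ndarray:
        """Documented heuristics: free loadings 1; structural paths 0.1;
        exogenous latent (co)variances at the sample moments of their
        indicators (scaled by 1 - error fraction for variances); growth
        intercept/slope disturbances at 35% / 5% of the first indicator
        variance; other disturbances at 50% of the mean indicator variance;
        intercepts at sample means; growth means at the first-wave mean and
        the average per-wave change."""
        roles = {v.name: v.role for v in self.spec.variables}
        kinds = {v.name: v.kind for v in self.spec.variables}
        indicators: dict[str, list[str]] = {}
        for pth in self.spec.paths:
            if pth.kind == "directed" and kinds.get(pth.target) == "observed" \
                    and kinds.get(pth.source) == "latent":
                indicators.setdefault(pth.source, []).append(pth.target)
        cov = self.sample_cov
        mean = self.sample_mean
        frac = self.spec.error_fractions

        def ovar(name: str) -> float:
            i = self.observed.index(name)
            return cov[i, i] if cov is not None else 1.0

        def omean(name: str) -> float:
            return float(mean[self.observed.index(name)]) if mean is not None else 0.0

        theta = np.empty(self.q)
        for k, lab in enumerate(self.labels):
            if self._apos[lab]:
                ti, si = self._apos[lab][0]
                tname, sname = self.names[ti], self.names[si]
                theta[k] = 1.0 if kinds.get(tname) == "observed" else 0.1
                if roles.get(sname) == "growth-slope" and kinds.get(tname) == "observed":
                    theta[k] = 2.0
            elif self._spos[lab]:
                i, j = self._spos[lab][0]
                a, b = self.names[i], self.names[j]
                if i == j:
                    inds = indicators.get(a, [])
                    if roles.get(a) == "growth-intercept" and inds:
                        theta[k] = 0.35 * ovar(inds[0])
                    elif roles.get(a) == "growth-slope" and inds:
                        theta[k] = 0.05 * ovar(inds[0])
                    elif inds:
                        f = frac.get(inds[0], 0.0) if len(inds) == 1 else 0.0
                        base = np.mean([ovar(x) for x in inds])
                        scale = (1.0 - f) if len(inds) == 1 else 0.5
                        theta[k] = scale * base
                    elif kinds.get(a) == "observed":
                        theta[k] = ovar(a)
                    else:
                        theta[k] = 1.0
                else:
                    ia, ib = indicators.get(a, []), indicators.get(b, [])
                    exo_pair = (
                        roles.get(a) == "exogenous" and roles.get(b) == "exogenous"
                        and ia and ib and cov is not None
                    )
                    if exo_pair:
                        theta[k] = cov[self.observed.index(ia[0]),
                                       self.observed.index(ib[0])]
                    else:
                        theta[k] = 0.0
            else:
                vname = self.names[self._mpos[lab][0]]
                if kinds.get(vname) == "observed":
                    theta[k] = omean(vname)
                else:
                    inds = sorted(indicators.get(vname, []))
                    if roles.get(vname) == "growth-slope" and len(inds) >= 2:
                        theta[k] = (omean(inds[-1]) - omean(inds[0])) / max(len(inds) - 1, 1)
                    elif inds:
                        theta[k] = omean(inds[0])
                    else:
                        theta[k] = 0.0
        return theta


def compile_model(
    spec: ModelSpec,
    moments: MomentSet | None = None,
    standardize: tuple[str, ...] = (),
) -> CompiledModel:
    return CompiledModel(spec, moments, standardize)


def implied_covariance(
    m: ModelSpec | CompiledModel, theta, moments: MomentSet | None = None,
    standardize: tuple[str, ...] = (),
) -> np.ndarray:
    """Sigma(theta) over the observed variables."""
    cm = m if isinstance(m, CompiledModel) else CompiledModel(m, moments, standardize)
    if not isinstance(theta, np.ndarray):
        theta = cm.theta_from_mapping(theta)
    return cm.implied_covariance(theta)


def ml_discrepancy(sample_cov: np.ndarray, implied_cov: np.ndarray) -> float:
    """F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p.

    Non-negative, zero iff Sigma == S; both inputs must be symmetric
    positive definite.
    """
    S = np.asarray(sample_cov, float)
    Sig = np.asarray(implied_cov, float)
    if S.shape != Sig.shape or S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("matrices must be square and of equal dimension")
    p = S.shape[0]
    for name, m_ in (("sample", S), ("implied", Sig)):
        w = np.linalg.eigvalsh((m_ + m_.T) / 2)
        if w[0] <= 0:
            raise InadmissibleParameterError(
                f"{name} covariance not positive definite (min eigenvalue {w[0]:.3e})"
            )
    return float(
        np.linalg.slogdet(Sig)[1]
        + np.sum(np.linalg.inv(Sig) * S)
        - np.linalg.slogdet(S)[1]
        - p
    )


def _numeric_hessian(fun_grad, theta: np.ndarray, rel_step: float = 1e-5):
    """Central finite differences of an analytic gradient."""
    q = len(theta)
    Hm = np.empty((q, q))
    for k in range(q):
        h = rel_step * max(1.0, abs(theta[k]))
        tp = theta.copy(); tp[k] += h
        tm = theta.copy(); tm[k] -= h
        gp = fun_grad(tp)[1]
        gm = fun_grad(tm)[1]
        Hm[k] = (gp - gm) / (2 * h)
    return (Hm + Hm.T) / 2


def fit(
    m: ModelSpec,
    moments: MomentSet,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit a model to sample moments by maximum likelihood.

    Quasi-Newton minimization with the analytic gradient from documented
    starting values, followed by a damped Newton polish; up to
    ``max_restarts`` jittered restarts if the gradient norm stays above
    ``gtol``. Convergence is reported honestly; inadmissible (negative
    variance) solutions are flagged as Heywood cases, not silently bounded.
    """
    opts = options or FitOptions()
    cm = CompiledModel(m, moments, opts.standardize, opts.pd_repair_floor)
    rng = np.random.default_rng(opts.seed)

    def fg(th):
        return cm.discrepancy(th, with_grad=True)

    best = None
    n_iter = 0
    restarts = 0
    theta0 = cm.start_values()
    for attempt in range(opts.max_restarts + 1):
        start = theta0 if attempt == 0 else theta0 * (
            1.0 + 0.2 * rng.standard_normal(cm.q)
        ) + 0.05 * rng.standard_normal(cm.q)
        res = minimize(fg, start, jac=True, method="L-BFGS-B",
                       options=dict(maxiter=5000, ftol=1e-16, gtol=1e-10,
                                    maxcor=30))
        n_iter += res.nit
        theta = res.x
        # damped Newton polish toward a tight gradient norm
        for _ in range(30):
            fval, grad = fg(theta)
            gnorm = float(np.linalg.norm(grad, np.inf))
            if gnorm < 0.1 * opts.gtol:
                break
            Hm = _numeric_hessian(fg, theta)
            lam = 0.0
            for _damp in range(12):
                try:
                    step = np.linalg.solve(
                        Hm + lam * np.eye(cm.q), -grad
                    )
                except np.linalg.LinAlgError:
                    lam = max(10 * lam, 1e-8)
                    continue
                cand = theta + step
                fc = cm.discrepancy(cand)
                if fc <= fval + 1e-12:
                    theta = cand
                    break
                lam = max(10 * lam, 1e-8)
            else:
                break
            n_iter += 1
        fval, grad = fg(theta)
        gnorm = float(np.linalg.norm(grad, np.inf))
        if fval < _PENALTY / 10 and (
            best is None or fval < best[0] - 1e-12 or (
                abs(fval - best[0]) <= 1e-12 and gnorm < best[2]
            )
        ):
            best = (fval, theta, gnorm)
        if best is not None and best[2] < opts.gtol:
            break
        restarts = attempt + 1
    if best is None:
        best = (fval, theta, np.inf)
    fmin, theta, gnorm = best
    converged = bool(gnorm < opts.gtol and fmin < _PENALTY / 10)

    n = moments.n
    scale = (n - 1) if opts.chi2_scale == "n-1" else n
    chi2 = scale * fmin
    df = m.n_observed_moments - cm.q

    chib, dfb = baseline_chi2(moments, standardize=opts.standardize,
                              chi2_scale=opts.chi2_scale)
    rmsea, cfi, tli, p_value = fit_indices(chi2, df, chib, dfb, n)

    est = cm.assignment(theta)
    A, S, mvec, B, C, mu = cm.full_implied(theta)
    implied = C[: cm.p, : cm.p]
    std_coeffs = standardize(cm, theta)
    r2 = r_squared(cm, theta)
    resid = standardized_residuals(cm.sample_cov, implied, n)

    heywood = tuple(
        cm.names[i]
        for i in range(cm.t)
        if S[i, i] < -1e-10
    )

    se: dict[str, float] = {}
    wz: dict[str, float] = {}
    wp: dict[str, float] = {}
    if opts.compute_se:
        Hm = _numeric_hessian(fg, theta) * (scale / 2.0)
        try:
            cov_theta = np.linalg.inv(Hm)
            dse = np.sqrt(np.maximum(np.diag(cov_theta), 0.0))
            for k, lab in enumerate(cm.labels):
                s = float(dse[k])
                se[lab] = s
                z = float(theta[k] / s) if s > 0 else np.nan
                wz[lab] = z
                wp[lab] = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else (
                    1.0 if theta[k] == 0 else np.nan
                )
        except np.linalg.LinAlgError:
            se = {lab: np.nan for lab in cm.labels}
            wz = dict(se)
            wp = dict(se)

    return FitResult(
        estimates=est,
        param_names=tuple(cm.labels),
        theta=theta,
        discrepancy_min=fmin,
        chi2=chi2,
        df=df,
        p_value=p_value,
        rmsea=rmsea,
        cfi=cfi,
        tli=tli,
        baseline_chi2=chib,
        baseline_df=dfb,
        standardized_coefficients=std_coeffs,
        r_squared=r2,
        standardized_residuals=resid,
        std_errors=se,
        wald_z=wz,
        wald_p=wp,
        converged=converged,
        n_iterations=int(n_iter),
        n_restarts=restarts,
        gradient_norm=gnorm,
        heywood=heywood,
        sample_cov=cm.sample_cov,
        implied_cov=implied,
        sample_mean=cm.sample_mean if m.has_means else None,
        implied_mean=mu[: cm.p] if m.has_means else None,
        n=n,
        model=m,
        compiled=cm,
    )


def baseline_chi2(
    moments: MomentSet,
    standardize: tuple[str, ...] = (),
    chi2_scale: str = "n-1",
) -> tuple[float, int]:
    """Independence-model chi-square: free variances, zero covariances.

    The ML minimum of the independence model is attained at
    Sigma = diag(S), so chi2 = scale * [sum ln s_ii - ln|S|]; df = p(p-1)/2.
    """
    S = nearest_pd(to_covariance(moments, standardize))
    p = S.shape[0]
    F = float(np.sum(np.log(np.diag(S))) - np.linalg.slogdet(S)[1])
    scale = (moments.n - 1) if chi2_scale == "n-1" else moments.n
    return scale * max(F, 0.0), p * (p - 1) // 2


def fit_indices(
    chi2: float, df: int, chi2_b: float, df_b: int, n: int
) -> tuple[float, float, float, float]:
    """(RMSEA, CFI, TLI, p-value) from the model and baseline chi-squares."""
    if df <= 0 or df_b <= 0 or n <= 1:
        raise ValueError("df, baseline df and n must be positive")
    excess = max(chi2 - df, 0.0)
    rmsea = float(np.sqrt(excess / (df * (n - 1))))
    denom = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 - (excess / denom if denom > 0 else 0.0)
    base_ratio = chi2_b / df_b
    tli = ((base_ratio - chi2 / df) / (base_ratio - 1.0)
           if base_ratio != 1.0 else 1.0)
    p_value = float(stats.chi2.sf(chi2, df))
    return rmsea, cfi, tli, p_value


def _as_compiled(m, theta, moments=None, standardize=()):
    cm = m if isinstance(m, CompiledModel) else CompiledModel(m, moments, standardize)
    if not isinstance(theta, np.ndarray):
        theta = cm.theta_from_mapping(theta)
    return cm, theta


def standardize(
    m: ModelSpec | CompiledModel, theta, moments=None, standardize_vars=()
) -> dict[str, float]:
    """Standardized solution: paths rescaled to unit-variance variables.

    Directed coefficients are multiplied by sd(source)/sd(target) under the
    model-implied SDs; covariances become correlations. Keys are
    ``target~source`` for directed paths and ``a~~b`` for covariances
    (disturbance covariances are reported as disturbance correlations).
    """
    cm, th = _as_compiled(m, theta, moments, standardize_vars)
    A, S, mvec, B, C, mu = cm.full_implied(th)
    var = np.diag(C)
    if np.any(var <= 0):
        bad = cm.names[int(np.argmin(var))]
        raise InadmissibleParameterError(f"zero/negative implied variance for {bad}")
    sd = np.sqrt(var)
    out: dict[str, float] = {}
    for pth in cm.spec.paths:
        si, ti = cm.ix[pth.source], cm.ix[pth.target]
        if pth.kind == "directed":
            key = pth.label or f"{pth.target}~{pth.source}"
            out[key] = float(A[ti, si] * sd[si] / sd[ti])
        else:
            key = pth.label or f"{pth.target}~~{pth.source}"
            if si == ti:
                out[key] = float(S[si, si] / var[si])
            else:
                dsd_s = np.sqrt(S[si, si]) if S[si, si] > 0 else sd[si]
                dsd_t = np.sqrt(S[ti, ti]) if S[ti, ti] > 0 else sd[ti]
                # covariance between two disturbances -> their correlation
                out[key] = float(S[si, ti] / (dsd_s * dsd_t))
    return out


def r_squared(
    m: ModelSpec | CompiledModel, theta, moments=None, standardize_vars=()
) -> dict[str, float]:
    """1 - disturbance variance / implied variance per endogenous latent."""
    cm, th = _as_compiled(m, theta, moments, standardize_vars)
    A, S, mvec, B, C, mu = cm.full_implied(th)
    endo = set()
    latents = set(cm.latent)
    for pth in cm.spec.paths:
        if pth.kind == "directed" and pth.target in latents:
            endo.add(pth.target)
    out = {}
    for v in cm.latent:
        if v in endo:
            i = cm.ix[v]
            out[v] = float(1.0 - S[i, i] / C[i, i])
    return out


def standardized_residuals(
    sample_cov: np.ndarray, implied_cov: np.ndarray, n: int
) -> np.ndarray:
    """(s_ij - sigma_ij) / sqrt((sigma_ii sigma_jj + sigma_ij^2) / n)."""
    S = np.asarray(sample_cov, float)
    Sig = np.asarray(implied_cov, float)
    if S.shape != Sig.shape:
        raise ValueError("dimension mismatch")
    d = np.diag(Sig)
    denom = np.sqrt((np.outer(d, d) + Sig**2) / n)
    return (S - Sig) / denom


def wald_tests(
    m: ModelSpec | CompiledModel, theta, moments: MomentSet | None = None,
    standardize_vars=(), chi2_scale: str = "n-1",
) -> dict[str, tuple[float, float, float]]:
    """Per-parameter (SE, z, two-sided p) from the observed information.

    The information matrix is the Hessian of (scale/2) * F_ML at theta,
    computed by central finite differences of the analytic gradient.
    """
    cm, th = _as_compiled(m, theta, moments, standardize_vars)
    if cm.sample_cov is None:
        raise ValueError("wald_tests requires a model compiled against moments")
    scale = (cm.n - 1) if chi2_scale == "n-1" else cm.n
    Hm = _numeric_hessian(lambda x: cm.discrepancy(x, with_grad=True), th)
    Hm = Hm * (scale / 2.0)
    try:
        cov = np.linalg.inv(Hm)
    except np.linalg.LinAlgError:
        return {lab: (np.nan, np.nan, np.nan) for lab in cm.labels}
    out = {}
    for k, lab in enumerate(cm.labels):
        v = cov[k, k]
        s = float(np.sqrt(v)) if v > 0 else np.nan
        if np.isfinite(s) and s > 0:
            z = float(th[k] / s)
            pval = float(2 * stats.norm.sf(abs(z)))
        elif th[k] == 0:
            z, pval = 0.0, 1.0
        else:
            z, pval = np.nan, np.nan
        out[lab] = (s, z, pval)
    return out
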