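"""Direct / indirect / total effect decomposition and bootstrap intervals.

For a recursive (acyclic) system with standardized structural coefficient
matrix B (B[target, source]), the total-effect matrix is

    T = (I - B)^-1 - I,

the direct effects are B itself and the indirect effects T - B: the sum of
coefficient products over all directed paths of length >= 2. A
path-enumeration oracle (`enumerate_paths`) provides the same quantities by
explicit DFS, which the matrix identity is cross-checked against in the
test-suite. Confidence intervals for standardized coefficients come from a
parametric bootstrap: simulate records from the fitted implied distribution,
refit, and take percentile intervals over the replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import CompiledModel, FitOptions, FitResult, fit
from .model import ModelSpec, topological_order
from .moments import MomentSet

__all__ = [
    "EffectsTable",
    "BootstrapResult",
    "total_effects",
    "indirect_effects",
    "enumerate_paths",
    "structural_coefficient_matrix",
    "effects_table",
    "parametric_bootstrap",
]


@dataclass(frozen=True)
class EffectsTable:
    """Rows of (predictor, outcome, direct, indirect, total)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"predictor", "outcome", "direct", "indirect", "total"}
        if not need <= set(self.table.columns):
            raise ValueError(f"effects table must have columns {sorted(need)}")

    def lookup(self, predictor: str, outcome: str) -> pd.Series:
        t = self.table
        row = t[(t.predictor == predictor) & (t.outcome == outcome)]
        if row.empty:
            raise KeyError(f"no effects row for {predictor} -> {outcome}")
        return row.iloc[0]


def _check_acyclic(B: pd.DataFrame) -> None:
    edges = [
        (src, tgt)
        for src in B.columns
        for tgt in B.index
        if B.loc[tgt, src] != 0.0
    ]
    if topological_order(list(B.index), edges) is None:
        raise ValueError("coefficient matrix contains a cycle")


def _as_frame(coeffs) -> pd.DataFrame:
    if isinstance(coeffs, pd.DataFrame):
        if list(coeffs.index) != list(coeffs.columns):
            raise ValueError("coefficient matrix must be square with matching labels")
        return coeffs.astype(float)
    arr = np.asarray(coeffs, float)
    names = [f"v{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=names, columns=names)


def total_effects(std_coeffs) -> pd.DataFrame:
    """T = (I - B)^-1 - I for an acyclic coefficient matrix B[target, source]."""
    B = _as_frame(std_coeffs)
    _check_acyclic(B)
    I = np.eye(len(B))
    T = np.linalg.inv(I - B.to_numpy()) - I
    return pd.DataFrame(T, index=B.index, columns=B.columns)


def indirect_effects(std_coeffs) -> pd.DataFrame:
    B = _as_frame(std_coeffs)
    return total_effects(B) - B


def enumerate_paths(graph, source: str, target: str):
    """All directed paths source -> target with their coefficient products.

    ``graph`` maps source -> {target: coefficient} (or a coefficient
    DataFrame indexed [target, source]). Returns a list of
    ``(path_tuple, product)``; the sum of products over paths of length >= 2
    equals the indirect effect, the full sum the total effect.
    """
    if isinstance(graph, pd.DataFrame):
        adj: dict[str, dict[str, float]] = {}
        for src in graph.columns:
            for tgt in graph.index:
                c = graph.loc[tgt, src]
                if c != 0.0:
                    adj.setdefault(src, {})[tgt] = float(c)
        nodes = list(graph.index)
    else:
        adj = {s: dict(ts) for s, ts in graph.items()}
        nodes = sorted(set(adj) | {t for ts in adj.values() for t in ts})
    edges = [(s, t) for s, ts in adj.items() for t in ts]
    if topological_order(nodes, edges) is None:
        raise ValueError("graph contains a cycle")
    out: list[tuple[tuple[str, ...], float]] = []

    def dfs(node: str, path: tuple[str, ...], product: float) -> None:
        if node == target and len(path) > 1:
            out.append((path, product))
            return
        for nxt, c in sorted(adj.get(node, {}).items()):
            dfs(nxt, path + (nxt,), product * c)

    dfs(source, (source,), 1.0)
    return out


def structural_coefficient_matrix(result: FitResult) -> pd.DataFrame:
    """Standardized latent-to-latent coefficients of a fitted model."""
    latents = list(result.model.latent_names)
    B = pd.DataFrame(0.0, index=latents, columns=latents)
    std = result.standardized_coefficients
    for pth in result.model.paths:
        if pth.kind != "directed":
            continue
        if pth.source in B.columns and pth.target in B.index:
            key = pth.label or f"{pth.target}~{pth.source}"
            B.loc[pth.target, pth.source] = std[key]
    return B


def effects_table(
    result_or_matrix, pairs=None
) -> EffectsTable:
    """Decompose standardized effects for every predictor -> outcome pair.

    ``pairs`` restricts the rows; by default every ordered pair with a
    nonzero total effect is included. total = direct + indirect exactly.
    """
    if isinstance(result_or_matrix, FitResult):
        B = structural_coefficient_matrix(result_or_matrix)
    else:
        B = _as_frame(result_or_matrix)
    T = total_effects(B)
    Ind = T - B
    rows = []
    if pairs is None:
        pairs = [
            (src, tgt)
            for src in B.columns
            for tgt in B.index
            if T.loc[tgt, src] != 0.0
        ]
    for src, tgt in pairs:
        rows.append(
            dict(
                predictor=src,
                outcome=tgt,
                direct=float(B.loc[tgt, src]),
                indirect=float(Ind.loc[tgt, src]),
                total=float(T.loc[tgt, src]),
            )
        )
    return EffectsTable(pd.DataFrame(rows))


@dataclass
class BootstrapResult:
    replicates: pd.DataFrame  # one row per converged replicate, one col per label
    intervals: pd.DataFrame  # columns: lower, upper; index: label
    level: float
    n_requested: int
    n_converged: int
    seed: int
    unstable: bool

    def interval(self, label: str) -> tuple[float, float]:
        row = self.intervals.loc[label]
        return float(row["lower"]), float(row["upper"])


def parametric_bootstrap(
    m: ModelSpec,
    fitted: FitResult,
    n: int | None = None,
    b: int = 500,
    seed: int = 0,
    level: float = 0.95,
    raw_data: pd.DataFrame | None = None,
) -> BootstrapResult:
    """Percentile bootstrap intervals for the standardized coefficients.

    Each replicate draws ``n`` records from N(mu_hat, Sigma_hat) — the
    fitted implied distribution over the observed variables — (or resamples
    rows of ``raw_data`` when supplied), recomputes the replicate's sample
    moments, refits the same compiled model warm-started at the original
    solution, and records the standardized directed coefficients.
    Non-converged replicates are dropped and counted; more than 50%
    non-convergence flags the result unstable.
    """
    if b < 1:
        raise ValueError("b >= 1 required")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    cm = fitted.compiled
    n = n or fitted.n
    rng = np.random.default_rng(seed)
    mu = fitted.implied_mean if fitted.implied_mean is not None else np.zeros(cm.p)
    Sigma = fitted.implied_cov
    chol = np.linalg.cholesky(Sigma)

    # labels of standardized directed coefficients to track
    track = [
        (pth.label or f"{pth.target}~{pth.source}")
        for pth in m.paths
        if pth.kind == "directed"
    ]
    track += [
        (pth.label or f"{pth.target}~~{pth.source}")
        for pth in m.paths
        if pth.kind == "covariance" and pth.source != pth.target
    ]

    from .engine import standardize as _standardize  # local alias

    rows = []
    n_conv = 0
    for _rep in range(b):
        if raw_data is not None:
            take = rng.integers(0, len(raw_data), size=n)
            X = raw_data.iloc[take][list(cm.observed)].to_numpy(float)
        else:
            X = mu + rng.standard_normal((n, cm.p)) @ chol.T
        xbar = X.mean(axis=0)
        Srep = np.cov(X, rowvar=False)
        # re-standardize the indicators the pipeline standardizes
        sds = np.sqrt(np.diag(Srep))
        z = np.ones(cm.p)
        for v in cm.standardized:
            i = cm.observed.index(v)
            z[i] = 1.0 / sds[i]
            xbar[i] = 0.0
        Srep = Srep * np.outer(z, z)
        rep = _replicate_fit(cm, Srep, xbar, fitted.theta)
        if rep is None:
            continue
        theta_rep, gnorm = rep
        if gnorm > 1e-4:
            continue
        n_conv += 1
        std = _standardize(cm, theta_rep)
        rows.append({lab: std[lab] for lab in track if lab in std})

    reps = pd.DataFrame(rows)
    alpha = 1.0 - level
    if len(reps):
        lower = reps.quantile(alpha / 2)
        upper = reps.quantile(1 - alpha / 2)
    else:
        lower = pd.Series(dtype=float)
        upper = pd.Series(dtype=float)
    intervals = pd.DataFrame({"lower": lower, "upper": upper})
    return BootstrapResult(
        replicates=reps,
        intervals=intervals,
        level=level,
        n_requested=b,
        n_converged=n_conv,
        seed=seed,
        unstable=n_conv < b / 2,
    )


def _replicate_fit(cm: CompiledModel, Srep, xbar, theta_start):
    """Refit the compiled model against replicate moments, warm-started."""
    from scipy.optimize import minimize

    saved = (cm.sample_cov, cm.sample_mean, cm._logdet_sample)
    sgn, logdet = np.linalg.slogdet(Srep)
    if sgn <= 0:
        return None
    cm.sample_cov = Srep
    cm.sample_mean = np.asarray(xbar, float)
    cm._logdet_sample = logdet
    try:
        res = minimize(
            lambda th: cm.discrepancy(th, with_grad=True),
            theta_start, jac=True, method="L-BFGS-B",
            options=dict(maxiter=3000, ftol=1e-16, gtol=1e-8, maxcor=30),
        )
        gnorm = float(np.linalg.norm(res.jac, np.inf))
        return (res.x, gnorm) if np.isfinite(res.fun) else None
    finally:
        cm.sample_cov, cm.sample_mean, cm._logdet_sample = saved
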