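"""Synthetic per-subject data with the statistical structure the model assumes.

Records are generated structurally: exogenous latents and disturbances are
drawn from zero-mean Gaussians with the model's (co)variances, propagated
through the directed equations, and measurement error is added per the
error fractions — so the sample covariance of a large simulated dataset
converges to the model-implied covariance. Optional coarsening discretizes
the adult-sexual-assault indicator to 0/1 and the smoking indicator to
0/1/2 at Gaussian quantiles matching target shares, emulating how the real
indicators were recorded (coarsening attenuates product-moment
correlations; recovery targets on coarsened runs are correspondingly
relaxed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import CompiledModel, FitOptions, fit
from .model import ModelSpec
from .moments import MomentSet

__all__ = ["CoarsenSpec", "SyntheticDataset", "generate",
           "matched_error_fractions", "recovery_experiment"]


@dataclass(frozen=True)
class CoarsenSpec:
    """Probit-style discretization targets.

    ``binary`` maps column -> prevalence (share coded 1); ``ordinal`` maps
    column -> category shares in code order (must sum to 1).
    """

    binary: dict[str, float] = field(default_factory=dict)
    ordinal: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def describe(self) -> str:
        bits = [f"{c}: binary at prevalence {p:g}" for c, p in self.binary.items()]
        bits += [
            f"{c}: ordinal at shares {tuple(round(x, 4) for x in s)}"
            for c, s in self.ordinal.items()
        ]
        return "; ".join(bits) if bits else "none"


@dataclass
class SyntheticDataset:
    records: pd.DataFrame
    truth: dict[str, float]
    seed: int
    coarsening: str

    @property
    def n(self) -> int:
        return len(self.records)

    def to_csv(self, data_path, sidecar_path=None) -> None:
        self.records.to_csv(data_path, index=False)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(
                    {"truth": self.truth, "seed": self.seed,
                     "coarsening": self.coarsening},
                    fh, indent=2,
                )

    def moments(self) -> MomentSet:
        """Sample moments of the records, in model variable order."""
        X = self.records
        return MomentSet(
            variable_names=tuple(X.columns),
            means=X.mean().to_numpy(),
            sds=X.std(ddof=1).to_numpy(),
            correlations=np.corrcoef(X.to_numpy(), rowvar=False),
            n=len(X),
        )


def generate(
    m: ModelSpec,
    theta_true,
    n: int,
    seed: int = 0,
    coarsen: CoarsenSpec | None = None,
    moments: MomentSet | None = None,
    standardize: tuple[str, ...] = (),
    add_means: bool = True,
) -> SyntheticDataset:
    """Simulate ``n`` records from the model at ``theta_true``.

    ``theta_true`` is a label -> value mapping (or a fitted theta vector).
    ``moments`` is required when the model fixes error variances through
    error fractions (they are materialized against it, exactly as in
    fitting). With ``add_means`` the model's mean structure (if any) shifts
    the records; otherwise all variables are zero-mean.
    """
    cm = m if isinstance(m, CompiledModel) else CompiledModel(m, moments, standardize)
    theta = (
        theta_true
        if isinstance(theta_true, np.ndarray)
        else cm.theta_from_mapping(theta_true)
    )
    A, S, mvec, B, C, mu = cm.full_implied(theta)
    w = np.linalg.eigvalsh((S + S.T) / 2)
    if w[0] < -1e-8:
        raise ValueError(
            f"inadmissible theta_true: exogenous matrix has eigenvalue {w[0]:.3e}"
        )
    rng = np.random.default_rng(seed)
    # draw u ~ N(0, S) over all variables, propagate v = B (m + u)
    wclip, V = np.linalg.eigh((S + S.T) / 2)
    root = V @ np.diag(np.sqrt(np.maximum(wclip, 0.0)))
    U = rng.standard_normal((n, cm.t)) @ root.T
    shift = mvec if add_means else np.zeros(cm.t)
    X = (U + shift) @ B.T
    data = pd.DataFrame(X[:, : cm.p], columns=list(cm.observed))

    coarsen = coarsen or CoarsenSpec()
    for col, prev in coarsen.binary.items():
        if not 0.0 < prev < 1.0:
            raise ValueError(f"prevalence for {col} outside (0,1)")
        x = data[col].to_numpy()
        cut = np.quantile(x, 1.0 - prev)
        data[col] = (x > cut).astype(float)
    for col, shares in coarsen.ordinal.items():
        shares = np.asarray(shares, float)
        if abs(shares.sum() - 1.0) > 1e-8 or np.any(shares <= 0):
            raise ValueError(f"shares for {col} must be positive and sum to 1")
        x = data[col].to_numpy()
        cuts = np.quantile(x, np.cumsum(shares)[:-1])
        data[col] = np.searchsorted(cuts, x, side="left").astype(float)

    truth = {lab: float(theta[k]) for k, lab in enumerate(cm.labels)}
    return SyntheticDataset(
        records=data, truth=truth, seed=seed, coarsening=coarsen.describe()
    )


def matched_error_fractions(
    m: ModelSpec, cm: CompiledModel, replicate_moments: MomentSet,
    standardize: tuple[str, ...] = (),
) -> dict[str, float]:
    """Fractions that reproduce the *generating* error variances on new data.

    Fixed measurement-error variances are model constants. A refit against
    replicate moments would re-materialize them as fraction x the
    replicate's sample variances, which differ from the generating values
    by sampling noise and model misfit; that mismatch does not vanish with
    n and would masquerade as estimator bias. Rescaling each fraction by
    (generating variance / replicate variance) keeps the fitted model's
    constants identical to the truth's.
    """
    from .moments import to_covariance

    rep_cov = to_covariance(replicate_moments, standardize)
    out = {}
    for v, f in m.error_fractions.items():
        i = cm.observed.index(v)
        gen_err = cm.S0[cm.ix[v], cm.ix[v]]
        out[v] = min(gen_err / rep_cov[i, i], 0.95)
    return out


def _natural_scales(cm: CompiledModel, theta: np.ndarray) -> np.ndarray:
    """Per-parameter magnitude scales from the implied SDs at truth.

    A directed coefficient's scale is sd(target)/sd(source) (so 2% of scale
    corresponds to 2% on the standardized coefficient), a covariance's is
    sd_i * sd_j, a variance's var_i, a mean's sd_i.
    """
    C = cm.full_implied(theta)[4]
    sd = np.sqrt(np.maximum(np.diag(C), 1e-12))
    scales = np.ones(cm.q)
    for k, lab in enumerate(cm.labels):
        if cm._apos[lab]:
            i, j = cm._apos[lab][0]
            scales[k] = sd[i] / sd[j]
        elif cm._spos[lab]:
            i, j = cm._spos[lab][0]
            scales[k] = sd[i] * sd[j]
        else:
            scales[k] = sd[cm._mpos[lab][0]]
    return scales


def recovery_experiment(
    m: ModelSpec,
    theta_true,
    n_list,
    replicates: int = 20,
    seed: int = 0,
    moments: MomentSet | None = None,
    standardize: tuple[str, ...] = (),
    bias_tolerance: float = 0.02,
) -> pd.DataFrame:
    """Mean bias and RMSE of every free parameter across simulated refits.

    For each n in ``n_list``, ``replicates`` datasets are generated (streams
    derived deterministically from the master seed) and refitted with the
    generating error-variance constants (see
    :func:`matched_error_fractions`). Parameters whose |mean bias| exceeds
    ``bias_tolerance`` x scale at the largest n are flagged; the scale is
    max(|truth|, natural scale), where the natural scale comes from the
    implied SDs at truth, so near-zero paths are judged on the footing of
    their standardized counterparts.
    """
    from dataclasses import replace

    cm = CompiledModel(m, moments, standardize)
    theta = (
        theta_true
        if isinstance(theta_true, np.ndarray)
        else cm.theta_from_mapping(theta_true)
    )
    scales = np.maximum(np.abs(theta), _natural_scales(cm, theta))
    master = np.random.default_rng(seed)
    rows = []
    n_max = max(n_list)
    for n in n_list:
        est = []
        for _rep in range(replicates):
            sub_seed = int(master.integers(0, 2**31 - 1))
            ds = generate(cm, theta, n, seed=sub_seed, add_means=m.has_means)
            mo = ds.moments()
            m_rep = (
                replace(m, error_fractions=matched_error_fractions(
                    m, cm, mo, standardize))
                if m.error_fractions else m
            )
            res = fit(
                m_rep, mo,
                FitOptions(standardize=standardize, compute_se=False,
                           max_restarts=3, seed=sub_seed),
            )
            est.append(res.theta)
        E = np.array(est)
        for k, lab in enumerate(cm.labels):
            truth_k = theta[k]
            bias = float(E[:, k].mean() - truth_k)
            rows.append(
                dict(
                    n=n,
                    parameter=lab,
                    truth=float(truth_k),
                    mean_estimate=float(E[:, k].mean()),
                    bias=bias,
                    rmse=float(np.sqrt(np.mean((E[:, k] - truth_k) ** 2))),
                    scale=float(scales[k]),
                    flagged=bool(
                        n == n_max and abs(bias) > bias_tolerance * scales[k]
                    ),
                )
            )
    return pd.DataFrame(rows)
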