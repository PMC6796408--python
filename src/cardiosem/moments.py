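"""Published moment tables (means, SDs, correlations) and their covariance form.

The study model is fitted to sample moments rather than raw records: a
descriptives table (mean, SD, N per indicator) and a Pearson correlation
matrix. This module reads and validates such tables, converts them to the
covariance matrix the ML engine consumes (optionally forcing selected
indicators to unit variance, i.e. pre-standardization), and repairs
positive-definiteness lost to the 2-decimal rounding of printed
correlations.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MomentSet",
    "MomentValidationError",
    "load_moments",
    "study_moments",
    "binary_sd",
    "categorical_moments",
    "to_covariance",
    "nearest_pd",
]


class MomentValidationError(ValueError):
    """A moment table failed validation; the message names the offending cell."""


@dataclass(frozen=True)
class MomentSet:
    """Named sample means, SDs, correlation matrix and sample size.

    Variable order follows the correlation matrix. Instrument units are
    whatever the source table printed; standardization to unit variance
    happens later, in :func:`to_covariance`.
    """

    variable_names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    correlations: np.ndarray
    n: int

    def __post_init__(self) -> None:
        names = tuple(self.variable_names)
        object.__setattr__(self, "variable_names", names)
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "sds", np.asarray(self.sds, dtype=float))
        object.__setattr__(
            self, "correlations", np.asarray(self.correlations, dtype=float)
        )
        p = len(names)
        if len(set(names)) != p:
            raise MomentValidationError("duplicate variable names")
        for arr, what in ((self.means, "means"), (self.sds, "sds")):
            if arr.shape != (p,):
                raise MomentValidationError(
                    f"{what} has length {arr.shape}, expected {p}"
                )
        if self.correlations.shape != (p, p):
            raise MomentValidationError(
                f"correlation matrix is {self.correlations.shape}, expected ({p}, {p})"
            )
        R = self.correlations
        for i in range(p):
            if not math.isclose(R[i, i], 1.0, abs_tol=1e-9):
                raise MomentValidationError(
                    f"diagonal entry ({names[i]}, {names[i]}) = {R[i, i]}, expected 1"
                )
            for j in range(p):
                if abs(R[i, j]) > 1.0 + 1e-12:
                    raise MomentValidationError(
                        f"correlation ({names[i]}, {names[j]}) = {R[i, j]} outside [-1, 1]"
                    )
                if not math.isclose(R[i, j], R[j, i], abs_tol=1e-9):
                    raise MomentValidationError(
                        f"correlation matrix asymmetric at ({names[i]}, {names[j]})"
                    )
        if np.any(self.sds <= 0) or np.any(~np.isfinite(self.sds)):
            bad = names[int(np.argmin(self.sds))]
            raise MomentValidationError(f"non-positive or missing SD for {bad}")
        if self.n < p + 1:
            raise MomentValidationError(
                f"sample size {self.n} < number of variables + 1 ({p + 1})"
            )

    @property
    def p(self) -> int:
        return len(self.variable_names)

    def index(self, name: str) -> int:
        return self.variable_names.index(name)

    def covariance(self, standardize: tuple[str, ...] = ()) -> np.ndarray:
        return to_covariance(self, standardize)

    def save(self, descriptives_path, correlations_path) -> None:
        """Write the two-CSV representation (round-trips through load_moments)."""
        pd.DataFrame(
            {
                "variable": self.variable_names,
                "mean": self.means,
                "sd": self.sds,
                "n": self.n,
            }
        ).to_csv(descriptives_path, index=False)
        df = pd.DataFrame(
            self.correlations,
            index=pd.Index(self.variable_names, name="variable"),
            columns=self.variable_names,
        )
        df.to_csv(correlations_path)


def _canonical(name: str) -> str:
    return name.strip().upper().replace("-", "").replace("_", "").replace(" ", "")


def load_moments(descriptives_path, correlations_path) -> MomentSet:
    """Read a descriptives CSV and a correlation-matrix CSV into a MomentSet.

    The descriptives file has columns ``variable, mean, sd, n``; the
    correlations file is square with a header row and a first column of
    names. Names are matched after canonicalization (case, dashes and
    underscores ignored); ordering follows the correlations file.
    """
    desc = pd.read_csv(descriptives_path)
    for col in ("variable", "mean", "sd", "n"):
        if col not in desc.columns:
            raise MomentValidationError(f"descriptives file lacks column '{col}'")
    corr = pd.read_csv(correlations_path, index_col=0)
    row_names = [str(v) for v in corr.index]
    col_names = [str(v) for v in corr.columns]
    if [_canonical(v) for v in row_names] != [_canonical(v) for v in col_names]:
        raise MomentValidationError(
            "correlation file row and column names disagree"
        )
    lookup = {_canonical(str(v)): i for i, v in enumerate(desc["variable"])}
    order = []
    for name in row_names:
        key = _canonical(name)
        if key not in lookup:
            raise MomentValidationError(
                f"variable '{name}' missing from descriptives file"
            )
        order.append(lookup[key])
    if len(order) != len(desc):
        raise MomentValidationError(
            "descriptives file lists variables absent from the correlation matrix"
        )
    means = desc["mean"].to_numpy(float)[order]
    sds = desc["sd"].to_numpy(float)[order]
    if desc["sd"].isna().any():
        bad = desc.loc[desc["sd"].isna(), "variable"].iloc[0]
        raise MomentValidationError(f"missing SD for {bad}")
    ns = desc["n"].to_numpy(float)
    if not np.all(ns == ns[0]):
        raise MomentValidationError("descriptives file reports inconsistent n")
    R = corr.to_numpy(float)
    if np.isnan(R).any():
        i, j = map(int, np.argwhere(np.isnan(R))[0])
        raise MomentValidationError(
            f"missing correlation at ({row_names[i]}, {col_names[j]})"
        )
    return MomentSet(
        variable_names=tuple(row_names),
        means=means,
        sds=sds,
        correlations=R,
        n=int(ns[0]),
    )


def study_moments() -> MomentSet:
    """The packaged study fixtures: 14 indicators, N = 227.

    Means and SDs transcribe the published descriptives table; the binary
    sexual-assault indicator's moments are derived from its printed
    prevalence (88/227) via :func:`binary_sd`, and the 0/1/2-coded smoking
    indicator's from its printed category counts (75/68/84) via
    :func:`categorical_moments`.
    """
    pkg = importlib.resources.files("cardiosem.data")
    with importlib.resources.as_file(pkg / "table1_descriptives.csv") as p1, \
            importlib.resources.as_file(pkg / "table2_correlations.csv") as p2:
        return load_moments(p1, p2)


def binary_sd(prevalence: float) -> float:
    """SD of a 0/1 indicator with the given prevalence: sqrt(p(1-p))."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence {prevalence} outside (0, 1)")
    return math.sqrt(prevalence * (1.0 - prevalence))


def categorical_moments(
    counts: dict[str, int], codes: dict[str, float]
) -> tuple[float, float]:
    """Mean and population-form SD of a coded categorical variable.

    The divisor is n (not n-1), matching how the coded variable enters the
    moment matrix; at the study's n = 227 the difference is immaterial.
    """
    if not counts:
        raise ValueError("empty counts")
    missing = set(counts) - set(codes)
    if missing:
        raise ValueError(f"codes missing for categories: {sorted(missing)}")
    if any(c <= 0 for c in counts.values()):
        raise ValueError("counts must be positive")
    n = sum(counts.values())
    mean = sum(counts[k] * codes[k] for k in counts) / n
    var = sum(counts[k] * (codes[k] - mean) ** 2 for k in counts) / n
    return mean, math.sqrt(var)


def to_covariance(
    m: MomentSet, standardize: tuple[str, ...] | list[str] = ()
) -> np.ndarray:
    """Covariance matrix cov[i,j] = r[i,j] * sd_i * sd_j.

    Variables listed in ``standardize`` have their SD forced to 1, i.e. they
    enter the model in z-score metric (the study does this for the three
    abuse indicators, which are measured on incommensurable scales).
    """
    unknown = set(standardize) - set(m.variable_names)
    if unknown:
        raise ValueError(f"unknown identifiers in standardize: {sorted(unknown)}")
    sds = m.sds.copy()
    for name in standardize:
        sds[m.index(name)] = 1.0
    cov = m.correlations * np.outer(sds, sds)
    return (cov + cov.T) / 2.0


def nearest_pd(matrix: np.ndarray, eigen_floor: float = 1e-8) -> np.ndarray:
    """Return the input if positive definite, else the nearest PD repair.

    Eigenvalues below ``eigen_floor`` are clipped to it (the Frobenius-nearest
    symmetric matrix with that spectrum bound); for correlation inputs the
    unit diagonal is restored afterwards and the clip is re-applied until the
    floor holds. Printed correlation tables rounded to 2 decimals can be
    marginally indefinite; the repair magnitude is logged so reproduction
    error can be attributed.
    """
    A = np.asarray(matrix, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("input matrix is not symmetric")
    is_corr = np.allclose(np.diag(A), 1.0, atol=1e-12)
    out = (A + A.T) / 2.0
    for _ in range(100):
        w = np.linalg.eigvalsh(out)
        if w[0] > eigen_floor:
            break
        w_clip, V = np.linalg.eigh(out)
        out = V @ np.diag(np.maximum(w_clip, eigen_floor)) @ V.T
        out = (out + out.T) / 2.0
        if is_corr:
            np.fill_diagonal(out, 1.0)
    delta = float(np.abs(out - A).max())
    if delta > 0:
        logger.info("nearest_pd repaired matrix; max elementwise change %.2e", delta)
    return out
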