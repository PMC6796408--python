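"""JSON and plain-text reports for fitted models.

Values are persisted at full precision in JSON and rounded to 3 decimals
for display. The text report mirrors the layout of the published results
table: outcomes with their R-squared, per-predictor direct/indirect/total
standardized effects (with bootstrap intervals when available), then the
fit-index block.
"""

from __future__ import annotations

import json
from typing import Any

import numpy as np

from .effects import BootstrapResult, EffectsTable
from .engine import FitResult

__all__ = ["fit_report", "render_text", "write_reports"]


def fit_report(
    result: FitResult,
    effects: EffectsTable | None = None,
    bootstrap: BootstrapResult | None = None,
) -> dict[str, Any]:
    """Machine-readable report of a fit (JSON-serializable)."""
    resid = result.standardized_residuals
    out: dict[str, Any] = {
        "n": result.n,
        "converged": result.converged,
        "n_iterations": result.n_iterations,
        "n_restarts": result.n_restarts,
        "gradient_norm": result.gradient_norm,
        "discrepancy": result.discrepancy_min,
        "chi2": result.chi2,
        "df": result.df,
        "p_value": result.p_value,
        "relative_chi2": result.relative_chi2,
        "rmsea": result.rmsea,
        "cfi": result.cfi,
        "tli": result.tli,
        "baseline_chi2": result.baseline_chi2,
        "baseline_df": result.baseline_df,
        "estimates": result.estimates.values,
        "std_errors": result.std_errors,
        "wald_p": result.wald_p,
        "standardized": result.standardized_coefficients,
        "r_squared": result.r_squared,
        "largest_standardized_residual": float(
            resid.flat[np.argmax(np.abs(resid))]
        ),
        "heywood": list(result.heywood),
    }
    if effects is not None:
        out["effects"] = effects.table.to_dict(orient="records")
    if bootstrap is not None:
        out["bootstrap"] = {
            "level": bootstrap.level,
            "n_requested": bootstrap.n_requested,
            "n_converged": bootstrap.n_converged,
            "seed": bootstrap.seed,
            "unstable": bootstrap.unstable,
            "intervals": {
                lab: [float(lo), float(hi)]
                for lab, (lo, hi) in bootstrap.intervals.iterrows()
            },
        }
    return out


def render_text(report: dict[str, Any]) -> str:
    """Human-readable table mirroring the published results layout."""
    lines = []
    lines.append("Standardized causal effects")
    lines.append("=" * 74)
    r2 = report.get("r_squared", {})
    effects = report.get("effects", [])
    intervals = report.get("bootstrap", {}).get("intervals", {})
    by_outcome: dict[str, list[dict]] = {}
    for row in effects:
        by_outcome.setdefault(row["outcome"], []).append(row)
    hdr = f"  {'Predictor':<22}{'Direct':>9}{'Indirect':>10}{'Total':>9}"
    if intervals:
        hdr += f"  {'95% CI':>18}"
    for outcome, rows in by_outcome.items():
        tag = f" (R2 = {r2[outcome]:.3f})" if outcome in r2 else ""
        lines.append(f"{outcome}{tag}")
        lines.append(hdr)
        for row in rows:
            line = (
                f"  {row['predictor']:<22}"
                f"{row['direct']:>9.3f}{row['indirect']:>10.3f}{row['total']:>9.3f}"
            )
            key = f"{row['outcome']}~{row['predictor']}"
            if key in intervals:
                lo, hi = intervals[key]
                line += f"  [{lo: .3f}, {hi: .3f}]"
            lines.append(line)
    lines.append("")
    lines.append("Model fit")
    lines.append("-" * 40)
    lines.append(
        f"chi2 = {report['chi2']:.2f} (df = {report['df']}), "
        f"p = {report['p_value']:.4g}"
    )
    lines.append(f"chi2/df = {report['relative_chi2']:.2f}")
    lines.append(f"RMSEA = {report['rmsea']:.3f}")
    lines.append(f"CFI = {report['cfi']:.3f}")
    lines.append(f"TLI = {report['tli']:.3f}")
    lines.append(
        "largest standardized residual = "
        f"{report['largest_standardized_residual']:.2f}"
    )
    if report.get("heywood"):
        lines.append(f"WARNING Heywood cases: {', '.join(report['heywood'])}")
    if not report["converged"]:
        lines.append("WARNING fit did not reach the convergence tolerance")
    return "\n".join(lines) + "\n"


def write_reports(report: dict[str, Any], json_path, text_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    if text_path is not None:
        with open(text_path, "w") as fh:
            fh.write(render_text(report))
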