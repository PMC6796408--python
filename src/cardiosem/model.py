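"""Declarative covariance-structure models and the built-in study model.

A model is an explicit parameter map: variables (observed or latent),
directed paths and (co)variances that are either fixed to a value or free
under a label, per-indicator measurement-error fractions, optional mean
parameters, and optional phantom-composite constraints.

The built-in model links a phantom "lifetime abuse" composite (child abuse,
partner abuse, adult sexual assault, each feeding it with a fixed unit path)
to cardiovascular-disease risk, directly and through smoking history, body
weight, and a latent growth curve of depressive symptoms measured at five
waves. Measurement error is fixed from reliability (1 - Cronbach's alpha)
or assigned fractions; the phantom's disturbance is constrained to 20% of
its total variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "VariableDef",
    "PathSpec",
    "MeanSpec",
    "PhantomConstraint",
    "ModelSpec",
    "ModelValidationError",
    "build_whes_model",
    "default_error_fractions",
    "count_df",
    "phantom_explained_variance",
    "saturated_model",
    "independence_model",
    "model_to_text",
    "model_from_text",
    "OBSERVED_VARIABLES",
    "ABUSE_INDICATORS",
]

#: Observed indicators, in the order of the published correlation matrix.
OBSERVED_VARIABLES = (
    "AGE", "CTQ", "ASA", "ISA",
    "CESD1", "CESD2", "CESD3", "CESD4", "CESD5",
    "SMOKE", "WC", "BMI", "SBP", "DBP",
)

#: Indicators pre-standardized to unit variance before fitting.
ABUSE_INDICATORS = ("CTQ", "ISA", "ASA")


class ModelValidationError(ValueError):
    pass


@dataclass(frozen=True)
class VariableDef:
    name: str
    kind: str  # "observed" | "latent"
    role: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("observed", "latent"):
            raise ModelValidationError(f"unknown variable kind '{self.kind}'")


@dataclass(frozen=True)
class PathSpec:
    """A directed path (source -> target) or a symmetric (co)variance.

    ``status`` is "free" (estimated, under ``label``) or "fixed" (at
    ``value``). For ``kind == "covariance"``, source == target denotes a
    variance.
    """

    source: str
    target: str
    kind: str  # "directed" | "covariance"
    status: str  # "free" | "fixed"
    value: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("directed", "covariance"):
            raise ModelValidationError(f"unknown path kind '{self.kind}'")
        if self.status not in ("free", "fixed"):
            raise ModelValidationError(f"unknown path status '{self.status}'")
        if self.status == "fixed" and self.value is None:
            raise ModelValidationError(
                f"fixed path {self.source}->{self.target} lacks a value"
            )
        if self.status == "free" and self.label is None:
            sep = "~" if self.kind == "directed" else "~~"
            object.__setattr__(self, "label", f"{self.target}{sep}{self.source}")


@dataclass(frozen=True)
class MeanSpec:
    """Mean (for exogenous/latent variables) or intercept (for indicators)."""

    variable: str
    status: str = "free"
    value: float = 0.0
    label: str | None = None

    def __post_init__(self) -> None:
        if self.status not in ("free", "fixed"):
            raise ModelValidationError(f"unknown mean status '{self.status}'")
        if self.status == "free" and self.label is None:
            object.__setattr__(self, "label", f"{self.variable}~1")


@dataclass(frozen=True)
class PhantomConstraint:
    """Constrain a phantom latent's disturbance to a fraction of its variance.

    The phantom receives fixed unit paths from ``sources``; its explained
    variance is the sum of the sources' variances plus twice their pairwise
    covariances, and its disturbance is held at
    ``error_fraction / (1 - error_fraction)`` times that sum — i.e. the
    disturbance is ``error_fraction`` of the phantom's *total* variance,
    re-derived from the current source parameters at every engine iteration.
    """

    phantom: str
    sources: tuple[str, ...]
    error_fraction: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", tuple(self.sources))
        if not 0.0 <= self.error_fraction < 1.0:
            raise ModelValidationError(
                f"phantom error fraction {self.error_fraction} outside [0, 1)"
            )

    @property
    def factor(self) -> float:
        return self.error_fraction / (1.0 - self.error_fraction)


@dataclass(frozen=True)
class ModelSpec:
    variables: tuple[VariableDef, ...]
    paths: tuple[PathSpec, ...]
    means: tuple[MeanSpec, ...] = ()
    phantom_constraints: tuple[PhantomConstraint, ...] = ()
    error_fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "paths", tuple(self.paths))
        object.__setattr__(self, "means", tuple(self.means))
        object.__setattr__(
            self, "phantom_constraints", tuple(self.phantom_constraints)
        )

    # -- views ------------------------------------------------------------
    @property
    def observed_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables if v.kind == "observed")

    @property
    def latent_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables if v.kind == "latent")

    @property
    def all_names(self) -> tuple[str, ...]:
        return self.observed_names + self.latent_names

    @property
    def has_means(self) -> bool:
        return len(self.means) > 0

    @property
    def free_parameter_labels(self) -> tuple[str, ...]:
        labels: list[str] = []
        for p in self.paths:
            if p.status == "free":
                labels.append(p.label)
        for m in self.means:
            if m.status == "free":
                labels.append(m.label)
        seen = set()
        out = []
        for lab in labels:
            if lab not in seen:
                seen.add(lab)
                out.append(lab)
        return tuple(out)

    @property
    def n_free_parameters(self) -> int:
        return len(self.free_parameter_labels)

    @property
    def n_observed_moments(self) -> int:
        p = len(self.observed_names)
        moments = p * (p + 1) // 2
        if self.has_means:
            moments += p
        return moments

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ModelValidationError("variable names are not unique")
        known = set(names)
        observed = set(self.observed_names)
        latent = set(self.latent_names)
        incoming_loadings: dict[str, int] = {o: 0 for o in observed}
        for p in self.paths:
            for v in (p.source, p.target):
                if v not in known:
                    raise ModelValidationError(f"path references unknown variable '{v}'")
            if p.kind == "directed" and p.target in observed:
                if p.source not in latent:
                    raise ModelValidationError(
                        f"observed variable {p.target} loaded by non-latent {p.source}"
                    )
                incoming_loadings[p.target] += 1
        for o, k in incoming_loadings.items():
            # growth indicators legitimately load on two factors
            if k == 0:
                raise ModelValidationError(
                    f"observed variable {o} has no incoming loading"
                )
        self._check_acyclic()
        if count_df(self) < 0:
            raise ModelValidationError(
                f"negative degrees of freedom ({count_df(self)})"
            )

    def _check_acyclic(self) -> None:
        order = topological_order(
            self.all_names,
            [(p.source, p.target) for p in self.paths if p.kind == "directed"],
        )
        if order is None:
            raise ModelValidationError("directed paths contain a cycle")

    # -- edits ---------------------------------------------------------------
    def with_path(self, path: PathSpec) -> "ModelSpec":
        """Replace (by source/target/kind) or append a path."""
        out = []
        replaced = False
        for p in self.paths:
            same = (
                p.kind == path.kind
                and {p.source, p.target} == {path.source, path.target}
                and (p.kind == "covariance" or (p.source, p.target) == (path.source, path.target))
            )
            if same and not replaced:
                out.append(path)
                replaced = True
            else:
                out.append(p)
        if not replaced:
            out.append(path)
        return replace(self, paths=tuple(out))


def topological_order(
    names, edges
) -> list[str] | None:
    """Kahn's algorithm; None if the directed graph has a cycle."""
    indeg = {n: 0 for n in names}
    adj: dict[str, list[str]] = {n: [] for n in names}
    for s, t in edges:
        adj[s].append(t)
        indeg[t] += 1
    queue = [n for n in names if indeg[n] == 0]
    order = []
    while queue:
        n = queue.pop()
        order.append(n)
        for m in adj[n]:
            indeg[m] -= 1
            if indeg[m] == 0:
                queue.append(m)
    return order if len(order) == len(names) else None


def default_error_fractions() -> dict[str, float]:
    """Measurement-error fractions of the final published model.

    Reliability-based where available (CTQ: 1 - .94), assigned elsewhere,
    after the published adjustments: 15% for ASA and ISA, 30% for each CES-D
    wave, 16% for BMI, 25% for both blood pressures, 5% for waist
    circumference and smoking, 1% for age; 20% for the phantom composite.
    """
    out = {"CTQ": 0.06, "ISA": 0.15, "ASA": 0.15}
    out.update({f"CESD{k}": 0.30 for k in range(1, 6)})
    out.update({"SMOKE": 0.05, "BMI": 0.16, "WC": 0.05,
                "SBP": 0.25, "DBP": 0.25, "AGE": 0.01, "phantom": 0.20})
    return out


# indicator -> (latent, role) for the single- and double-indicator concepts
_MEASUREMENT = {
    "AGE": ("Age", "indicator"),
    "CTQ": ("ChildAbuse", "indicator"),
    "ASA": ("AdultSexualAssault", "indicator"),
    "ISA": ("PartnerAbuse", "indicator"),
    "SMOKE": ("Smoking", "indicator"),
    "WC": ("BodyWeight", "indicator"),
    "BMI": ("BodyWeight", "indicator"),
    "SBP": ("CVDRisk", "indicator"),
    "DBP": ("CVDRisk", "indicator"),
}

_EXOGENOUS = ("Age", "ChildAbuse", "AdultSexualAssault", "PartnerAbuse")
_ABUSE_LATENTS = ("ChildAbuse", "PartnerAbuse", "AdultSexualAssault")

#: The thirteen structural regressions of the final published model.
STRUCTURAL_PATHS = (
    ("LifetimeAbuse", "DepIntercept"),
    ("LifetimeAbuse", "DepSlope"),
    ("LifetimeAbuse", "Smoking"),
    ("LifetimeAbuse", "BodyWeight"),
    ("LifetimeAbuse", "CVDRisk"),
    ("DepIntercept", "BodyWeight"),
    ("DepSlope", "Smoking"),
    ("DepSlope", "BodyWeight"),
    ("DepSlope", "CVDRisk"),
    ("Smoking", "BodyWeight"),
    ("Smoking", "CVDRisk"),
    ("BodyWeight", "CVDRisk"),
    ("Age", "CVDRisk"),
)


def build_whes_model(
    error_fractions: dict[str, float] | None = None,
    free_slope_times: tuple[int, ...] = (4, 5),
    include_means: bool = True,
) -> ModelSpec:
    """The final published lifetime-abuse -> CVD-risk model.

    Structure: a phantom LifetimeAbuse composite fed by the three abuse
    latents with fixed unit paths and a disturbance constrained to 20% of
    its total variance; a depressive-symptom growth curve over five waves
    (intercept loadings fixed at 1; slope loadings fixed at 0/1/2 for waves
    1-3, free for the waves in ``free_slope_times``); single-indicator
    latents for age, the abuse measures and smoking (loading 1, error fixed
    at fraction x observed variance); two-indicator latents for body weight
    (WC fixed 1, BMI free) and CVD risk (SBP fixed 1, DBP free); the
    thirteen structural regressions listed in ``STRUCTURAL_PATHS``; free
    covariances among the four exogenous latents and between the growth
    intercept and slope disturbances.

    With ``include_means`` (the default) the growth-indicator intercepts are
    fixed at 0, the intercept/slope factor means are free, and the nine
    remaining indicator intercepts are free, so the model has 44 free
    parameters against 119 sample moments: df = 75.
    """
    frac = dict(default_error_fractions())
    if error_fractions:
        frac.update(error_fractions)
    missing = [v for v in OBSERVED_VARIABLES if v not in frac]
    if missing:
        raise ModelValidationError(f"missing error fractions for {missing}")
    bad = [v for v, f in frac.items() if not 0.0 <= f < 1.0]
    if bad:
        raise ModelValidationError(f"error fractions outside [0, 1) for {bad}")

    variables = [VariableDef(v, "observed", "indicator") for v in OBSERVED_VARIABLES]
    variables += [
        VariableDef("Age", "latent", "exogenous"),
        VariableDef("ChildAbuse", "latent", "exogenous"),
        VariableDef("AdultSexualAssault", "latent", "exogenous"),
        VariableDef("PartnerAbuse", "latent", "exogenous"),
        VariableDef("LifetimeAbuse", "latent", "phantom"),
        VariableDef("DepIntercept", "latent", "growth-intercept"),
        VariableDef("DepSlope", "latent", "growth-slope"),
        VariableDef("Smoking", "latent", "endogenous"),
        VariableDef("BodyWeight", "latent", "endogenous"),
        VariableDef("CVDRisk", "latent", "endogenous"),
    ]

    paths: list[PathSpec] = []
    # measurement: fixed unit loading per concept; second indicator free
    for ind, (lat, _) in _MEASUREMENT.items():
        if ind in ("BMI", "DBP"):
            paths.append(PathSpec(lat, ind, "directed", "free",
                                  label=f"{lat}=~{ind}"))
        else:
            paths.append(PathSpec(lat, ind, "directed", "fixed", 1.0))
    # growth curve
    for k in range(1, 6):
        paths.append(PathSpec("DepIntercept", f"CESD{k}", "directed", "fixed", 1.0))
    slope_fixed = {1: 0.0, 2: 1.0, 3: 2.0}
    for k in range(1, 6):
        if k in free_slope_times:
            paths.append(PathSpec("DepSlope", f"CESD{k}", "directed", "free",
                                  label=f"DepSlope=~CESD{k}"))
        elif k in slope_fixed:
            paths.append(PathSpec("DepSlope", f"CESD{k}", "directed", "fixed",
                                  slope_fixed[k]))
        # waves 4/5 dropped from the slope entirely when not freed and not
        # in the fixed pattern would misdrop; keep linear pattern instead
        elif k in (4, 5):
            paths.append(PathSpec("DepSlope", f"CESD{k}", "directed", "fixed",
                                  float(k - 1)))
    # phantom composite: fixed unit paths from the abuse latents
    for lat in _ABUSE_LATENTS:
        paths.append(PathSpec(lat, "LifetimeAbuse", "directed", "fixed", 1.0))
    # structural regressions
    for src, tgt in STRUCTURAL_PATHS:
        paths.append(PathSpec(src, tgt, "directed", "free"))
    # free variances: exogenous latents and endogenous disturbances
    for lat in _EXOGENOUS:
        paths.append(PathSpec(lat, lat, "covariance", "free"))
    for lat in ("DepIntercept", "DepSlope", "Smoking", "BodyWeight", "CVDRisk"):
        paths.append(PathSpec(lat, lat, "covariance", "free"))
    # free covariances among exogenous latents; intercept-slope disturbances
    exo = list(_EXOGENOUS)
    for i in range(len(exo)):
        for j in range(i + 1, len(exo)):
            paths.append(PathSpec(exo[i], exo[j], "covariance", "free"))
    paths.append(PathSpec("DepIntercept", "DepSlope", "covariance", "free"))

    means: list[MeanSpec] = []
    if include_means:
        for v in OBSERVED_VARIABLES:
            if v.startswith("CESD"):
                means.append(MeanSpec(v, "fixed", 0.0))
            else:
                means.append(MeanSpec(v, "free"))
        means.append(MeanSpec("DepIntercept", "free"))
        means.append(MeanSpec("DepSlope", "free"))

    spec = ModelSpec(
        variables=tuple(variables),
        paths=tuple(paths),
        means=tuple(means),
        phantom_constraints=(
            PhantomConstraint("LifetimeAbuse", _ABUSE_LATENTS, frac["phantom"]),
        ),
        error_fractions={k: v for k, v in frac.items() if k != "phantom"},
    )
    spec.validate()
    return spec


def count_df(m: ModelSpec) -> int:
    """Degrees of freedom: distinct sample moments minus free parameters.

    Moments are p(p+1)/2 covariances, plus p means when the model carries a
    mean structure.
    """
    return m.n_observed_moments - m.n_free_parameters


def phantom_explained_variance(
    exo_variances, exo_covariances
) -> float:
    """Variance a phantom composite inherits from its (unit-path) sources.

    For three sources: Var1 + Var2 + Var3 + 2(Cov12 + Cov13 + Cov23).
    Generalizes to any number of sources.
    """
    variances = list(exo_variances)
    covariances = list(exo_covariances)
    if any(v <= 0 for v in variances):
        raise ValueError("source variances must be positive")
    total = sum(variances) + 2.0 * sum(covariances)
    if total <= 0:
        raise ValueError(
            f"implied composite variance {total} <= 0 (inadmissible)"
        )
    return total


def saturated_model(variable_names) -> ModelSpec:
    """All observed (co)variances free: df = 0 reference point."""
    names = list(variable_names)
    variables = [VariableDef(n, "observed") for n in names]
    variables += [VariableDef(f"F_{n}", "latent") for n in names]
    paths = [PathSpec(f"F_{n}", n, "directed", "fixed", 1.0) for n in names]
    for i, a in enumerate(names):
        for b in names[i:]:
            paths.append(PathSpec(f"F_{a}", f"F_{b}", "covariance", "free"))
    return ModelSpec(tuple(variables), tuple(paths))


def independence_model(variable_names) -> ModelSpec:
    """Free variances, zero covariances: the baseline for CFI/TLI."""
    names = list(variable_names)
    variables = [VariableDef(n, "observed") for n in names]
    variables += [VariableDef(f"F_{n}", "latent") for n in names]
    paths = [PathSpec(f"F_{n}", n, "directed", "fixed", 1.0) for n in names]
    paths += [PathSpec(f"F_{n}", f"F_{n}", "covariance", "free") for n in names]
    return ModelSpec(tuple(variables), tuple(paths))


# ---------------------------------------------------------------------------
# declarative text round-trip
# ---------------------------------------------------------------------------

def model_to_text(m: ModelSpec) -> str:
    """Serialize a ModelSpec to the package's line-oriented dialect.

    One record per line::

        variable <name> observed|latent [role]
        directed <source> <target> fixed <value> | free <label>
        covariance <a> <b> fixed <value> | free <label>
        mean <variable> fixed <value> | free <label>
        phantom <name> <src1,src2,...> <error_fraction>
        error <indicator> <fraction>
    """
    lines = []
    for v in m.variables:
        lines.append(f"variable {v.name} {v.kind} {v.role}".rstrip())
    for p in m.paths:
        if p.status == "fixed":
            lines.append(f"{p.kind} {p.source} {p.target} fixed {p.value!r}")
        else:
            lines.append(f"{p.kind} {p.source} {p.target} free {p.label}")
    for mn in m.means:
        if mn.status == "fixed":
            lines.append(f"mean {mn.variable} fixed {mn.value!r}")
        else:
            lines.append(f"mean {mn.variable} free {mn.label}")
    for ph in m.phantom_constraints:
        lines.append(
            f"phantom {ph.phantom} {','.join(ph.sources)} {ph.error_fraction!r}"
        )
    for ind, f in m.error_fractions.items():
        lines.append(f"error {ind} {f!r}")
    return "\n".join(lines) + "\n"


def model_from_text(text: str) -> ModelSpec:
    variables: list[VariableDef] = []
    paths: list[PathSpec] = []
    means: list[MeanSpec] = []
    phantoms: list[PhantomConstraint] = []
    fractions: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        kind = tok[0]
        try:
            if kind == "variable":
                variables.append(
                    VariableDef(tok[1], tok[2], tok[3] if len(tok) > 3 else "")
                )
            elif kind in ("directed", "covariance"):
                src, tgt, status = tok[1], tok[2], tok[3]
                if status == "fixed":
                    paths.append(PathSpec(src, tgt, kind, "fixed", float(tok[4])))
                else:
                    paths.append(PathSpec(src, tgt, kind, "free",
                                          label=tok[4] if len(tok) > 4 else None))
            elif kind == "mean":
                var, status = tok[1], tok[2]
                if status == "fixed":
                    means.append(MeanSpec(var, "fixed", float(tok[3])))
                else:
                    means.append(MeanSpec(var, "free",
                                          label=tok[3] if len(tok) > 3 else None))
            elif kind == "phantom":
                phantoms.append(
                    PhantomConstraint(tok[1], tuple(tok[2].split(",")), float(tok[3]))
                )
            elif kind == "error":
                fractions[tok[1]] = float(tok[2])
            else:
                raise ModelValidationError(f"unknown record '{kind}'")
        except (IndexError, ValueError) as exc:
            raise ModelValidationError(f"line {lineno}: {raw!r}: {exc}") from exc
    spec = ModelSpec(tuple(variables), tuple(paths), tuple(means),
                     tuple(phantoms), fractions)
    spec.validate()
    return spec
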