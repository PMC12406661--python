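"""One-compartment population-PK engine.

Models are declarative: typical clearance (CL, L/h) and volume (V, L) are
arithmetic expressions over covariate names, with log-normal
inter-individual variability (IIV) on CL and V and a proportional, additive
or combined residual-error model.  Registries of such models are loaded from
YAML files.

Concentrations under intermittent infusion follow the closed-form
superposition solution: with elimination rate k = CL/V and zero-order
infusion rate R0 = amount / duration, a dose contributes
``(R0/CL)(1 − e^{−k t'})`` during the infusion and decays mono-exponentially
afterwards; dose contributions add by linearity.

Individual parameters are recovered from observed concentrations by MAP
(maximum a posteriori) empirical-Bayes estimation: minimize

    Σ_obs [ (y − f(η))² / σ²(f) + ln σ²(f) ]  +  ηᵀ Ω⁻¹ η

with σ²(f) evaluated at the model-predicted concentration.
"""

from __future__ import annotations

import ast
import math
import operator
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.optimize import minimize

from .cohort import ConcentrationObservation, DoseEvent
from .covariates import CovariateVector


class ModelSpecError(ValueError):
    """A model definition is malformed (bad expression, duplicate name, ...)."""


class PredictionError(ValueError):
    """A model cannot be evaluated on the given covariates."""


class EstimationError(RuntimeError):
    """MAP estimation failed to converge; carries the best iterate."""

    def __init__(self, message: str, best: "IndividualParameters"):
        super().__init__(message)
        self.best = best


# ---------------------------------------------------------------------------
# safe arithmetic expressions

_BINOPS = {
    ast.Add: operator.add,
    ast.Sub: operator.sub,
    ast.Mult: operator.mul,
    ast.Div: operator.truediv,
    ast.Pow: operator.pow,
}
_CMPOPS = {
    ast.Lt: operator.lt,
    ast.LtE: operator.le,
    ast.Gt: operator.gt,
    ast.GtE: operator.ge,
    ast.Eq: operator.eq,
    ast.NotEq: operator.ne,
}
_FUNCS = {"exp": math.exp, "log": math.log, "sqrt": math.sqrt, "min": min, "max": max}


@dataclass(frozen=True)
class Expression:
    """A validated arithmetic expression over covariate names."""

    source: str
    _tree: ast.Expression = field(repr=False, compare=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        try:
            tree = ast.parse(self.source, mode="eval")
        except SyntaxError as exc:
            raise ModelSpecError(f"malformed expression {self.source!r}: {exc}") from None
        _validate_node(tree.body)
        object.__setattr__(self, "_tree", tree)

    @property
    def names(self) -> frozenset[str]:
        """Covariate names the expression references."""
        return frozenset(
            node.id
            for node in ast.walk(self._tree)
            if isinstance(node, ast.Name) and node.id not in _FUNCS
        )

    def __call__(self, covariates: Mapping[str, float]) -> float:
        return _eval_node(self._tree.body, covariates)


def _validate_node(node: ast.AST) -> None:
    if isinstance(node, ast.Constant):
        if not isinstance(node.value, (int, float)):
            raise ModelSpecError(f"non-numeric constant {node.value!r}")
    elif isinstance(node, ast.Name):
        pass
    elif isinstance(node, ast.BinOp) and type(node.op) in _BINOPS:
        _validate_node(node.left)
        _validate_node(node.right)
    elif isinstance(node, ast.UnaryOp) and isinstance(node.op, (ast.USub, ast.UAdd)):
        _validate_node(node.operand)
    elif isinstance(node, ast.Call):
        if not (isinstance(node.func, ast.Name) and node.func.id in _FUNCS):
            raise ModelSpecError("only exp/log/sqrt/min/max calls are allowed")
        for arg in node.args:
            _validate_node(arg)
    elif isinstance(node, ast.IfExp):
        _validate_node(node.test)
        _validate_node(node.body)
        _validate_node(node.orelse)
    elif isinstance(node, ast.Compare):
        if len(node.ops) != 1 or type(node.ops[0]) not in _CMPOPS:
            raise ModelSpecError("only simple comparisons are allowed")
        _validate_node(node.left)
        _validate_node(node.comparators[0])
    else:
        raise ModelSpecError(f"disallowed syntax in expression: {ast.dump(node)}")


def _eval_node(node: ast.AST, env: Mapping[str, float]) -> float:
    if isinstance(node, ast.Constant):
        return float(node.value)
    if isinstance(node, ast.Name):
        try:
            return float(env[node.id])
        except KeyError:
            raise PredictionError(f"missing covariate {node.id!r}") from None
    if isinstance(node, ast.BinOp):
        return _BINOPS[type(node.op)](_eval_node(node.left, env), _eval_node(node.right, env))
    if isinstance(node, ast.UnaryOp):
        v = _eval_node(node.operand, env)
        return -v if isinstance(node.op, ast.USub) else v
    if isinstance(node, ast.Call):
        return float(_FUNCS[node.func.id](*(_eval_node(a, env) for a in node.args)))  # type: ignore[attr-defined]
    if isinstance(node, ast.IfExp):
        return _eval_node(node.body if _eval_node(node.test, env) else node.orelse, env)
    if isinstance(node, ast.Compare):
        return float(
            _CMPOPS[type(node.ops[0])](
                _eval_node(node.left, env), _eval_node(node.comparators[0], env)
            )
        )
    raise ModelSpecError(f"unexpected node {node!r}")


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class ErrorModel:
    kind: str  # proportional | additive | combined
    sigma_prop: float = 0.0  # fraction of the prediction
    sigma_add: float = 0.0  # mg/L

    def __post_init__(self) -> None:
        if self.kind not in ("proportional", "additive", "combined"):
            raise ModelSpecError(f"unknown error model {self.kind!r}")
        if self.kind in ("proportional", "combined") and not self.sigma_prop > 0:
            raise ModelSpecError("proportional sigma must be positive")
        if self.kind in ("additive", "combined") and not self.sigma_add > 0:
            raise ModelSpecError("additive sigma must be positive")

    def variance(self, predicted: np.ndarray) -> np.ndarray:
        """Residual variance at the model-predicted concentration."""
        var = np.zeros_like(predicted, dtype=float)
        if self.kind in ("proportional", "combined"):
            var = var + (self.sigma_prop * predicted) ** 2
        if self.kind in ("additive", "combined"):
            var = var + self.sigma_add**2
        return np.maximum(var, 1e-12)


@dataclass(frozen=True)
class PKModelSpec:
    name: str
    cl_expression: Expression
    v_expression: Expression
    omega_cl: float = 0.0  # variance of log-normal IIV on CL
    omega_v: float = 0.0  # variance of log-normal IIV on V
    error_model: ErrorModel = ErrorModel("proportional", sigma_prop=0.2)

    def __post_init__(self) -> None:
        if self.omega_cl < 0 or self.omega_v < 0:
            raise ModelSpecError("omega variances must be non-negative")

    @property
    def required_covariates(self) -> frozenset[str]:
        return self.cl_expression.names | self.v_expression.names

    def typical_values(self, covariates: CovariateVector) -> tuple[float, float]:
        missing = sorted(self.required_covariates - set(covariates))
        if missing:
            raise PredictionError(f"model {self.name!r}: missing covariate(s) {missing}")
        cl = self.cl_expression(covariates)
        v = self.v_expression(covariates)
        if not (cl > 0 and v > 0):
            raise PredictionError(
                f"model {self.name!r}: non-positive CL={cl:.4g} or V={v:.4g}"
            )
        return cl, v


def make_model(
    name: str,
    cl: str,
    v: str,
    omega_cl: float = 0.0,
    omega_v: float = 0.0,
    error: ErrorModel | None = None,
) -> PKModelSpec:
    """Convenience constructor from expression strings."""
    return PKModelSpec(
        name=name,
        cl_expression=Expression(cl),
        v_expression=Expression(v),
        omega_cl=omega_cl,
        omega_v=omega_v,
        error_model=error or ErrorModel("proportional", sigma_prop=0.2),
    )


#: Covariate names a model expression may reference.
KNOWN_COVARIATES = {
    "age", "sex", "weight", "height", "bmi", "creatinine", "crcl_cg",
    "egfr_ckd_epi", "treatment_day", "rrt_active",
}


def load_model_file(path: str | Path) -> PKModelSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ModelSpecError(f"{path}: not a mapping")
    for key in ("name", "CL", "V"):
        if key not in raw:
            raise ModelSpecError(f"{path}: missing key {key!r}")
    err_raw = raw.get("error", {"type": "proportional", "sigma_prop": 0.2})
    error = ErrorModel(
        kind=err_raw.get("type", "proportional"),
        sigma_prop=float(err_raw.get("sigma_prop", 0.0)),
        sigma_add=float(err_raw.get("sigma_add", 0.0)),
    )
    spec = make_model(
        name=str(raw["name"]),
        cl=str(raw["CL"]),
        v=str(raw["V"]),
        omega_cl=float(raw.get("omega_cl", 0.0)),
        omega_v=float(raw.get("omega_v", 0.0)),
        error=error,
    )
    unknown = sorted(spec.required_covariates - KNOWN_COVARIATES)
    if unknown:
        raise ModelSpecError(f"{path}: unknown covariate token(s) {unknown}")
    return spec


def load_model_registry(spec_paths: Sequence[str | Path] | str | Path) -> list[PKModelSpec]:
    """Load a model registry from YAML files (or a directory of ``*.yaml``)."""
    if isinstance(spec_paths, (str, Path)) and Path(spec_paths).is_dir():
        paths = sorted(Path(spec_paths).glob("*.y*ml"))
    elif isinstance(spec_paths, (str, Path)):
        paths = [Path(spec_paths)]
    else:
        paths = [Path(p) for p in spec_paths]
    registry: list[PKModelSpec] = []
    names: set[str] = set()
    for p in paths:
        spec = load_model_file(p)
        if spec.name in names:
            raise ModelSpecError(f"duplicate model name {spec.name!r} in {p}")
        names.add(spec.name)
        registry.append(spec)
    return registry


# ---------------------------------------------------------------------------
# prediction


@dataclass(frozen=True)
class IndividualParameters:
    eta_cl: float = 0.0
    eta_v: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.eta_cl, self.eta_v], dtype=float)


@dataclass(frozen=True)
class PredictionResult:
    model_name: str
    times: np.ndarray
    predicted: np.ndarray  # mg/L
    etas: IndividualParameters


def _concentration_profile(
    cl: float, v: float, doses: Sequence[DoseEvent], times: np.ndarray
) -> np.ndarray:
    """Closed-form superposition of intermittent-infusion contributions."""
    k = cl / v
    conc = np.zeros_like(times, dtype=float)
    for d in doses:
        r0 = d.amount / d.infusion_duration
        dt = times - d.time
        during = (dt > 0) & (dt <= d.infusion_duration)
        after = dt > d.infusion_duration
        conc[during] += (r0 / cl) * (1.0 - np.exp(-k * dt[during]))
        c_end = (r0 / cl) * (1.0 - np.exp(-k * d.infusion_duration))
        conc[after] += c_end * np.exp(-k * (dt[after] - d.infusion_duration))
    return conc


def predict_concentration(
    spec: PKModelSpec,
    covariates: CovariateVector,
    doses: Sequence[DoseEvent],
    times: Sequence[float],
    etas: IndividualParameters | None = None,
) -> PredictionResult:
    """Individual concentration prediction at the requested times (mg/L)."""
    etas = etas or IndividualParameters()
    tvcl, tvv = spec.typical_values(covariates)
    cl = tvcl * math.exp(etas.eta_cl)
    v = tvv * math.exp(etas.eta_v)
    t = np.asarray(times, dtype=float)
    return PredictionResult(
        model_name=spec.name,
        times=t,
        predicted=_concentration_profile(cl, v, doses, t),
        etas=etas,
    )


def population_predict(
    spec: PKModelSpec,
    covariates: CovariateVector,
    doses: Sequence[DoseEvent],
    times: Sequence[float],
) -> PredictionResult:
    """Prediction for the typical individual (all etas zero)."""
    return predict_concentration(spec, covariates, doses, times, IndividualParameters())


def steady_state_trough(
    cl: float, v: float, amount: float, tinf: float, tau: float
) -> float:
    """Steady-state trough under a fixed interval: the accumulation formula."""
    k = cl / v
    r0 = amount / tinf
    return (
        (r0 / cl)
        * (1.0 - math.exp(-k * tinf))
        * math.exp(-k * (tau - tinf))
        / (1.0 - math.exp(-k * tau))
    )


# ---------------------------------------------------------------------------
# MAP estimation


def map_objective(
    spec: PKModelSpec,
    covariates: CovariateVector,
    doses: Sequence[DoseEvent],
    observations: Sequence[ConcentrationObservation],
    eta: np.ndarray,
) -> float:
    """The MAP objective at ``eta = (eta_cl, eta_v)`` (lower is better)."""
    etas = IndividualParameters(float(eta[0]), float(eta[1]))
    omega = np.array([max(spec.omega_cl, 1e-12), max(spec.omega_v, 1e-12)])
    prior = float(np.sum(eta**2 / omega))
    if not observations:
        return prior
    times = [o.time for o in observations]
    y = np.array([o.value for o in observations], dtype=float)
    f = predict_concentration(spec, covariates, doses, times, etas).predicted
    var = spec.error_model.variance(f)
    return float(np.sum((y - f) ** 2 / var + np.log(var)) + prior)


def map_estimate(
    spec: PKModelSpec,
    covariates: CovariateVector,
    doses: Sequence[DoseEvent],
    observations: Sequence[ConcentrationObservation],
    seed: int = 0,
    tol: float = 1e-8,
    max_restarts: int = 2,
) -> IndividualParameters:
    """MAP empirical-Bayes estimate of the individual etas.

    Starts quasi-Newton (BFGS) from the prior mode eta = 0 with two jittered
    restarts; deterministic given *seed*.  Etas whose omega is zero are held
    at zero.
    """
    free = np.array([spec.omega_cl > 0, spec.omega_v > 0])
    if not observations or not free.any():
        return IndividualParameters()

    def objective(x: np.ndarray) -> float:
        eta = np.zeros(2)
        eta[free] = x
        return map_objective(spec, covariates, doses, observations, eta)

    rng = np.random.default_rng(seed)
    n_free = int(free.sum())
    starts = [np.zeros(n_free)]
    for _ in range(max_restarts):
        starts.append(rng.normal(0.0, 0.3, size=n_free))
    best_x, best_val = starts[0], objective(starts[0])
    converged = False
    for x0 in starts:
        res = minimize(objective, x0, method="BFGS", options={"gtol": 1e-10, "maxiter": 500})
        if res.fun < best_val - 1e-15 or (res.fun <= best_val and not converged):
            best_x, best_val = res.x, float(res.fun)
        if res.success or abs(res.fun - best_val) <= tol:
            converged = True
    eta = np.zeros(2)
    eta[free] = best_x
    params = IndividualParameters(float(eta[0]), float(eta[1]))
    if not converged:
        raise EstimationError("MAP estimation did not converge", params)
    # never worse than the prior mode
    if best_val > objective(np.zeros(n_free)) + 1e-9:
        return IndividualParameters()
    return params
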