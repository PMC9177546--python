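"""Nelder-Mead simplex parameter estimation.

The calibration objective is the weighted sum of squared residuals between
model effluent outputs (BOD, TN, TSS) and the observed targets, which is the
negative log-likelihood (up to constants) under independent normal errors
with the given per-target scales.  The simplex minimizer is implemented from
scratch with the standard coefficients (reflection 1, expansion 2,
contraction 0.5, shrink 0.5) and box bounds enforced by projecting proposed
vertices onto the box (a quadratic-penalty mode is available as an
alternative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .parameters import ParameterRegistry, ParameterVector
from .model import SteadyStateError

__all__ = [
    "ObjectiveSpec",
    "CalibrationResult",
    "objective_wsse",
    "make_objective",
    "nelder_mead",
    "calibrate",
]

#: objective value charged to parameter points where the evaluator fails
NONCONVERGENCE_PENALTY = 1e12


@dataclass(frozen=True)
class ObjectiveSpec:
    """Targets and scales for the calibration objective.

    ``sigmas`` are the per-target normal-error scales (mg/L); where no
    measured spread is available a scale of 5% of the target is the
    conventional fallback.
    """

    targets: Mapping[str, float]            # output name -> observed value
    sigmas: Mapping[str, float]
    codes: Sequence[str]                    # parameter subset to calibrate
    bound_mode: str = "project"             # "project" | "penalty"

    def __post_init__(self) -> None:
        if not self.codes:
            raise ValueError("empty calibration subset")
        for name, s in self.sigmas.items():
            if s <= 0:
                raise ValueError(f"sigma for {name} must be > 0")
        if self.bound_mode not in ("project", "penalty"):
            raise ValueError("bound_mode must be 'project' or 'penalty'")

    @classmethod
    def from_targets(cls, targets: Mapping[str, float], codes: Sequence[str],
                     sigmas: Mapping[str, float] | None = None,
                     rel_fallback: float = 0.05) -> "ObjectiveSpec":
        sig = dict(sigmas or {})
        for name, t in targets.items():
            if name not in sig or sig[name] is None:
                sig[name] = rel_fallback * t if t > 0 else rel_fallback
        return cls(targets=dict(targets), sigmas=sig, codes=tuple(codes))


def objective_wsse(outputs: Mapping[str, float] | np.ndarray,
                   spec: ObjectiveSpec,
                   output_names: Sequence[str] = ("BOD", "TN", "TSS")) -> float:
    """Sum_j ((y_j - t_j)/sigma_j)^2 over the spec's targets."""
    if not isinstance(outputs, Mapping):
        outputs = dict(zip(output_names, np.asarray(outputs, float)))
    total = 0.0
    for name, t in spec.targets.items():
        total += ((outputs[name] - t) / spec.sigmas[name]) ** 2
    return total


def make_objective(evaluator: Callable[[ParameterVector], np.ndarray],
                   spec: ObjectiveSpec,
                   registry: ParameterRegistry,
                   base: ParameterVector | None = None,
                   log: list | None = None) -> Callable[[np.ndarray], float]:
    """Wrap the model contract into f(x) over the calibrated subset.

    Parameters outside the subset stay pinned at ``base``.  Evaluator
    non-convergence is charged a large penalty and logged rather than
    raised, so the simplex can step around pathological corners.
    """
    base = base if base is not None else registry.defaults()
    codes = list(spec.codes)

    def f(x: np.ndarray) -> float:
        params = base.with_values(dict(zip(codes, x)))
        try:
            out = evaluator(params)
        except SteadyStateError as exc:
            if log is not None:
                log.append((tuple(x), str(exc)))
            return NONCONVERGENCE_PENALTY
        return objective_wsse(out, spec)

    return f


@dataclass(frozen=True)
class CalibrationResult:
    """Estimated values with the optimizer trace."""

    x: np.ndarray
    fun: float
    n_iter: int
    n_eval: int
    converged: bool
    termination: str
    trace: np.ndarray                        # best objective per iteration
    move_history: tuple[str, ...]
    simplex: np.ndarray
    codes: tuple[str, ...] = ()
    defaults: np.ndarray | None = None
    residuals: Mapping[str, float] = field(default_factory=dict)
    achieved: Mapping[str, float] = field(default_factory=dict)

    @property
    def estimated(self) -> dict[str, float]:
        return dict(zip(self.codes, self.x))

    @property
    def adjustments(self) -> dict[str, float]:
        """Absolute |estimated - default| per parameter."""
        if self.defaults is None:
            return {}
        return {c: abs(v - d)
                for c, v, d in zip(self.codes, self.x, self.defaults)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "code": list(self.codes),
            "default": self.defaults,
            "estimated": self.x,
            "adjustment": [self.adjustments[c] for c in self.codes],
        })


def _initial_simplex(x0: np.ndarray, bounds: np.ndarray,
                     rel_step: float = 0.05) -> np.ndarray:
    """x0 plus rel_step of each coordinate's range along each axis; the step
    turns inward (or shrinks hard) at a bound edge."""
    n = len(x0)
    simplex = np.tile(x0, (n + 1, 1))
    for i in range(n):
        lo, hi = bounds[i]
        step = rel_step * (hi - lo)
        if x0[i] + step <= hi:
            simplex[i + 1, i] += step
        elif x0[i] - step >= lo:
            simplex[i + 1, i] -= step
        else:
            simplex[i + 1, i] += 0.00025 * (hi - lo)
    return simplex


def nelder_mead(
    f: Callable[[np.ndarray], float],
    x0: np.ndarray,
    bounds: Sequence[tuple[float, float]] | None = None,
    tol_x: float = 1e-8,
    tol_f: float = 0.0,
    max_iter: int = 2000,
    alpha: float = 1.0,
    gamma: float = 2.0,
    beta: float = 0.5,
    delta: float = 0.5,
    bound_mode: str = "project",
    penalty_weight: float = 1e9,
) -> CalibrationResult:
    """Standard Nelder-Mead with reflection/expansion/contraction/shrink.

    Termination: relative inter-vertex spread below ``tol_x`` ("no further
    significant change in parameters"), or best-worst value spread below
    ``tol_f``, or the iteration cap (returned flagged as not converged).
    """
    x0 = np.asarray(x0, float)
    n = len(x0)
    if n < 1:
        raise ValueError("need at least one variable")
    if bounds is None:
        bounds_arr = np.column_stack([np.full(n, -np.inf), np.full(n, np.inf)])
    else:
        bounds_arr = np.asarray(bounds, float)
        if np.any(x0 < bounds_arr[:, 0]) or np.any(x0 > bounds_arr[:, 1]):
            raise ValueError("x0 outside bounds")

    def constrain(x: np.ndarray) -> tuple[np.ndarray, float]:
        if bound_mode == "project" and bounds is not None:
            return np.clip(x, bounds_arr[:, 0], bounds_arr[:, 1]), 0.0
        pen = 0.0
        if bounds is not None:
            viol = np.maximum(bounds_arr[:, 0] - x, 0) \
                + np.maximum(x - bounds_arr[:, 1], 0)
            pen = penalty_weight * float(np.sum(viol ** 2))
        return x, pen

    def feval(x: np.ndarray) -> tuple[np.ndarray, float]:
        xc, pen = constrain(x)
        return xc, f(xc) + pen

    n_eval = 0
    finite_bounds = bounds is not None and np.all(np.isfinite(bounds_arr))
    if finite_bounds:
        simplex = _initial_simplex(x0, bounds_arr)
    else:
        simplex = np.tile(x0, (n + 1, 1))
        for i in range(n):
            simplex[i + 1, i] += 0.05 * max(abs(x0[i]), 1.0)
    fvals = np.empty(n + 1)
    for i in range(n + 1):
        simplex[i], fvals[i] = feval(simplex[i])
        n_eval += 1

    trace: list[float] = []
    moves: list[str] = []
    termination = "max_iter"
    converged = False
    scale = np.maximum(np.max(np.abs(simplex), axis=0), 1.0)

    for it in range(max_iter):
        order = np.argsort(fvals, kind="stable")
        simplex, fvals = simplex[order], fvals[order]
        trace.append(fvals[0])

        spread_x = np.max(np.abs(simplex[1:] - simplex[0]) / scale)
        spread_f = fvals[-1] - fvals[0]
        if spread_x < tol_x:
            termination, converged = "tol_x", True
            break
        if spread_f < tol_f:
            termination, converged = "tol_f", True
            break

        centroid = simplex[:-1].mean(axis=0)
        xr, fr = feval(centroid + alpha * (centroid - simplex[-1]))
        n_eval += 1
        if fr < fvals[0]:
            xe, fe = feval(centroid + gamma * (xr - centroid))
            n_eval += 1
            if fe < fr:
                simplex[-1], fvals[-1] = xe, fe
                moves.append("expand")
            else:
                simplex[-1], fvals[-1] = xr, fr
                moves.append("reflect")
        elif fr < fvals[-2]:
            simplex[-1], fvals[-1] = xr, fr
            moves.append("reflect")
        else:
            if fr < fvals[-1]:       # outside contraction
                xc, fc = feval(centroid + beta * (xr - centroid))
            else:                    # inside contraction
                xc, fc = feval(centroid - beta * (centroid - simplex[-1]))
            n_eval += 1
            if fc < min(fr, fvals[-1]):
                simplex[-1], fvals[-1] = xc, fc
                moves.append("contract")
            else:
                for i in range(1, n + 1):
                    simplex[i], fvals[i] = feval(
                        simplex[0] + delta * (simplex[i] - simplex[0]))
                    n_eval += 1
                moves.append("shrink")

    order = np.argsort(fvals, kind="stable")
    simplex, fvals = simplex[order], fvals[order]
    return CalibrationResult(
        x=simplex[0].copy(), fun=float(fvals[0]), n_iter=len(trace),
        n_eval=n_eval, converged=converged, termination=termination,
        trace=np.array(trace), move_history=tuple(moves), simplex=simplex)


def calibrate(
    evaluator: Callable[[ParameterVector], np.ndarray],
    observed: Mapping[str, float],
    codes: Sequence[str],
    registry: ParameterRegistry,
    sigmas: Mapping[str, float] | None = None,
    base: ParameterVector | None = None,
    tol_x: float = 1e-8,
    max_iter: int = 2000,
) -> CalibrationResult:
    """Joint estimation of the subset ``codes`` against observed effluent
    targets, starting from registry defaults."""
    spec = ObjectiveSpec.from_targets(observed, codes, sigmas)
    base = base if base is not None else registry.defaults()
    f = make_objective(evaluator, spec, registry, base=base)
    x0 = np.array([base[c] for c in codes])
    bounds = [(registry[c].low, registry[c].high) for c in codes]
    res = nelder_mead(f, x0, bounds=bounds, tol_x=tol_x, max_iter=max_iter)

    best = base.with_values(dict(zip(codes, res.x)))
    out = evaluator(best)
    achieved = dict(zip(("BOD", "TN", "TSS"), np.asarray(out, float)))
    residuals = {k: achieved[k] - observed[k] for k in observed}
    defaults = np.array([registry[c].default for c in codes])
    return CalibrationResult(
        x=res.x, fun=res.fun, n_iter=res.n_iter, n_eval=res.n_eval,
        converged=res.converged, termination=res.termination, trace=res.trace,
        move_history=res.move_history, simplex=res.simplex,
        codes=tuple(codes), defaults=defaults, residuals=residuals,
        achieved=achieved)
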