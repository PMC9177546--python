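"""Reduced steady-state IFAS process model.

A continuously stirred reactor with SRT-controlled suspended solids, a fully
retained capacity-capped attached-biomass compartment sharing the bulk
liquid, and an ideal point-settler clarifier.  The evaluator contract the
pipeline stages consume is ``parameter vector -> {BOD, TN, TSS}``.

The biokinetics live in :mod:`ifascal.stoichiometry`; this module owns the
hydraulic balances, the damped-Newton steady-state solver, influent
fractionation and the effluent composition rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .parameters import ParameterRegistry, ParameterVector
from .stoichiometry import (
    COMPONENTS,
    K_NH_NUTRIENT,
    N_COMPONENTS,
    _rates_core,
    rate_constants,
    stoichiometric_matrix,
)

__all__ = [
    "PlantConfig",
    "CompositeMeasurements",
    "FractionationSettings",
    "InfluentState",
    "SteadyState",
    "EffluentSummary",
    "SteadyStateError",
    "fractionate_influent",
    "solve_steady_state",
    "clarifier_split",
    "effluent_summary",
    "EffluentEvaluator",
]

_IDX = {c: i for i, c in enumerate(COMPONENTS)}
_SOLUBLE = ("S_S", "S_I", "S_NH", "S_ND", "S_NO2", "S_NO3", "S_N2")
_PARTICULATE = ("X_S", "X_I", "X_ND", "X_BH", "X_BA1", "X_BA2")
_ATTACHED = ("A_BH", "A_BA1", "A_BA2")
_SOL_IDX = np.array([_IDX[c] for c in _SOLUBLE])
_PART_IDX = np.array([_IDX[c] for c in _PARTICULATE])
_ATT_IDX = np.array([_IDX[c] for c in _ATTACHED])
#: solved state = everything except the fixed dissolved-oxygen column
_STATE_IDX = np.array([i for i, c in enumerate(COMPONENTS) if c != "S_O"])
_STATE_POS = {c: i for i, c in enumerate(c for c in COMPONENTS if c != "S_O")}
#: positions of the biomass pools within the solved state vector
_BIO_STATE_IDX = np.array([_STATE_POS[c] for c in
                           ("X_BH", "X_BA1", "X_BA2", "A_BH", "A_BA1",
                            "A_BA2")])


class SteadyStateError(RuntimeError):
    """Raised when the steady-state solver fails to converge."""

    def __init__(self, message: str, residual_trace: list[float]):
        super().__init__(message)
        self.residual_trace = residual_trace


@dataclass(frozen=True)
class PlantConfig:
    """Operational configuration of the plant.

    Units follow plant convention: volume m3, flow m3/h, SRT d, DO mgO2/L.
    ``ras_flow_m3h`` stores the reported absolute return flow alongside the
    reported ratio; the absolute value is authoritative where they disagree.
    ``attached_capacity_gcod`` is the total attached-biomass ceiling over the
    whole reactor (gCOD retained on media).
    """

    volume_m3: float = 20.0
    flow_m3h: float = 1.8
    srt_d: float = 11.0
    ras_ratio: float = 2.5
    ras_flow_m3h: float | None = 3.7
    was_flow_m3d: float = 2.2
    do_mg_l: float = 2.5
    temperature_c: float = 26.0
    media_fill: float = 0.005
    attached_capacity_gcod: float = 20000.0
    biofilm_do_attenuation: float = 0.05
    clarifier_f_ns: float = 0.005
    f_bod: float = 0.66
    cod_per_vss: float = 1.48
    vss_per_tss: float = 0.63
    mlss_mg_l: float | None = 2000.0

    def __post_init__(self) -> None:
        for name in ("volume_m3", "flow_m3h", "srt_d", "do_mg_l",
                     "attached_capacity_gcod"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("clarifier_f_ns", "f_bod", "vss_per_tss", "media_fill"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")

    @property
    def hrt_h(self) -> float:
        """Hydraulic retention time V/Q in hours."""
        return self.volume_m3 / self.flow_m3h

    @property
    def dilution_rate_d(self) -> float:
        """Hydraulic dilution rate Q/V in 1/d."""
        return self.flow_m3h * 24.0 / self.volume_m3

    @property
    def attached_capacity_gcod_m3(self) -> float:
        return self.attached_capacity_gcod / self.volume_m3

    @property
    def ras_m3h(self) -> float:
        return self.ras_flow_m3h if self.ras_flow_m3h is not None \
            else self.ras_ratio * self.flow_m3h


@dataclass(frozen=True)
class CompositeMeasurements:
    """Composite determinands of one stream (all mg/L), with optional
    reported spreads (the +/- values of the characterization tables)."""

    cod: float
    bod: float
    tss: float
    nh3: float
    tkn: float
    tn: float
    spreads: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("cod", "bod", "tss", "nh3", "tkn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative composite {name}")
        if self.nh3 > self.tkn + 1e-9:
            raise ValueError("NH3-N exceeds TKN")
        if self.tkn > self.tn + 1e-9:
            raise ValueError("TKN exceeds TN")


@dataclass(frozen=True)
class FractionationSettings:
    """Influent fractionation: COD split into readily/slowly biodegradable
    and soluble/particulate inert pools; organic N split soluble/particulate.
    Defaults follow common activated-sludge characterization practice."""

    f_ss: float = 0.20
    f_xs: float = 0.50
    f_si: float = 0.05
    f_xi: float = 0.25
    f_snd: float = 0.40   # soluble share of organic N

    def __post_init__(self) -> None:
        s = self.f_ss + self.f_xs + self.f_si + self.f_xi
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"COD fractions must sum to 1, got {s}")
        if not (0.0 <= self.f_snd <= 1.0):
            raise ValueError("f_snd must lie in [0, 1]")


@dataclass(frozen=True)
class InfluentState:
    """State-variable influent concentrations (gCOD/m3 or gN/m3)."""

    s_s: float
    x_s: float
    s_i: float
    x_i: float
    s_nh: float
    s_nd: float
    x_nd: float
    s_no2: float = 0.0
    s_no3: float = 0.0

    def to_vector(self) -> np.ndarray:
        v = np.zeros(N_COMPONENTS)
        v[_IDX["S_S"]] = self.s_s
        v[_IDX["S_I"]] = self.s_i
        v[_IDX["S_NH"]] = self.s_nh
        v[_IDX["S_ND"]] = self.s_nd
        v[_IDX["S_NO2"]] = self.s_no2
        v[_IDX["S_NO3"]] = self.s_no3
        v[_IDX["X_S"]] = self.x_s
        v[_IDX["X_I"]] = self.x_i
        v[_IDX["X_ND"]] = self.x_nd
        return v

    @property
    def total_cod(self) -> float:
        return self.s_s + self.x_s + self.s_i + self.x_i

    @property
    def tkn(self) -> float:
        return self.s_nh + self.s_nd + self.x_nd


def fractionate_influent(
    composites: CompositeMeasurements,
    fractions: FractionationSettings = FractionationSettings(),
    config: PlantConfig | None = None,
) -> tuple[InfluentState, dict[str, float]]:
    """Split composite determinands into model state variables.

    Total COD and TKN are reconstructed exactly by construction; the second
    return value reports the composites implied by the split (BOD via the
    BOD5/biodegradable-COD factor, TSS via COD:VSS and VSS/TSS) for
    comparison against the measured values.
    """
    state = InfluentState(
        s_s=fractions.f_ss * composites.cod,
        x_s=fractions.f_xs * composites.cod,
        s_i=fractions.f_si * composites.cod,
        x_i=fractions.f_xi * composites.cod,
        s_nh=composites.nh3,
        s_nd=fractions.f_snd * (composites.tkn - composites.nh3),
        x_nd=(1.0 - fractions.f_snd) * (composites.tkn - composites.nh3),
        s_no3=max(composites.tn - composites.tkn, 0.0),
    )
    cfg = config or PlantConfig()
    part_cod = state.x_s + state.x_i
    reconstructed = {
        "cod": state.total_cod,
        "tkn": state.tkn,
        "bod": cfg.f_bod * (state.s_s + state.x_s),
        "tss": part_cod / cfg.cod_per_vss / cfg.vss_per_tss,
        "tn": state.tkn + state.s_no2 + state.s_no3,
    }
    return state, reconstructed


@dataclass(frozen=True)
class EffluentSummary:
    """The three composite model outputs (mg/L)."""

    bod: float
    tn: float
    tss: float
    components: Mapping[str, float] = field(default_factory=dict)

    def as_array(self) -> np.ndarray:
        return np.array([self.bod, self.tn, self.tss])


@dataclass(frozen=True)
class SteadyState:
    """Converged reactor state plus solver diagnostics."""

    state: np.ndarray              # full component vector, COMPONENTS order
    residual_norm: float
    iterations: int
    converged: bool
    residual_trace: tuple[float, ...] = ()

    def __getitem__(self, name: str) -> float:
        return float(self.state[_IDX[name]])


class _ReducedModel:
    """Mass balances dx/dt at fixed (influent, config, params)."""

    def __init__(self, influent: InfluentState, config: PlantConfig,
                 params: ParameterVector):
        self.influent = influent
        self.config = config
        self.params = params
        self.nu_t = stoichiometric_matrix(params).T
        self.inf_vec = influent.to_vector()
        self.dilution = config.dilution_rate_d
        self.srt_loss = 1.0 / config.srt_d
        self.cap = config.attached_capacity_gcod_m3
        self.do = config.do_mg_l
        self._k = rate_constants(params)
        self.do_att = config.biofilm_do_attenuation

    def rhs(self, full: np.ndarray) -> np.ndarray:
        rho = _rates_core(np.maximum(full, 0.0), self._k, self.do, self.cap,
                          self.do_att)
        with np.errstate(invalid="ignore", over="ignore"):
            r = self.nu_t @ rho
        dx = np.zeros(N_COMPONENTS)
        dx[_SOL_IDX] = self.dilution * (self.inf_vec[_SOL_IDX] - full[_SOL_IDX]) \
            + r[_SOL_IDX]
        dx[_PART_IDX] = self.dilution * self.inf_vec[_PART_IDX] \
            - self.srt_loss * full[_PART_IDX] + r[_PART_IDX]
        dx[_ATT_IDX] = r[_ATT_IDX]
        return dx

    def residual(self, x: np.ndarray) -> np.ndarray:
        full = self.full_state(x)
        return self.rhs(full)[_STATE_IDX]

    def residual_batch(self, xs: np.ndarray) -> np.ndarray:
        m = xs.shape[0]
        full = np.zeros((m, N_COMPONENTS))
        full[:, _STATE_IDX] = np.maximum(xs, 0.0)
        full[:, _IDX["S_O"]] = self.do
        rho = _rates_core(full, self._k, self.do, self.cap, self.do_att)
        with np.errstate(invalid="ignore", over="ignore"):
            r = rho @ self.nu_t.T
        dx = np.zeros((m, N_COMPONENTS))
        dx[:, _SOL_IDX] = self.dilution * (self.inf_vec[_SOL_IDX]
                                           - full[:, _SOL_IDX]) + r[:, _SOL_IDX]
        dx[:, _PART_IDX] = self.dilution * self.inf_vec[_PART_IDX] \
            - self.srt_loss * full[:, _PART_IDX] + r[:, _PART_IDX]
        dx[:, _ATT_IDX] = r[:, _ATT_IDX]
        return dx[:, _STATE_IDX]

    def jacobian(self, x: np.ndarray, f0: np.ndarray) -> np.ndarray:
        n = len(x)
        h = 1e-7 * np.maximum(np.abs(x), 1.0)
        xs = np.tile(x, (n, 1))
        xs[np.arange(n), np.arange(n)] += h
        return (self.residual_batch(xs) - f0).T / h

    def full_state(self, x: np.ndarray) -> np.ndarray:
        full = np.zeros(N_COMPONENTS)
        full[_STATE_IDX] = np.maximum(x, 0.0)
        full[_IDX["S_O"]] = self.do
        return full

    def seed(self) -> np.ndarray:
        """Heuristic cold-start guess."""
        full = self.inf_vec.copy()
        # particulates pre-concentrate by roughly D*SRT in an SRT-controlled CSTR
        conc = self.dilution * self.config.srt_d
        full[_PART_IDX] = self.inf_vec[_PART_IDX] * conc * 0.5
        full[_IDX["X_BH"]] = max(200.0, 0.3 * self.influent.total_cod)
        full[_IDX["X_BA1"]] = 30.0
        full[_IDX["X_BA2"]] = 10.0
        full[_IDX["A_BH"]] = 0.05 * self.cap
        full[_IDX["A_BA1"]] = 0.01 * self.cap
        full[_IDX["A_BA2"]] = 0.01 * self.cap
        full[_IDX["S_S"]] = 5.0
        full[_IDX["S_NH"]] = max(1.0, 0.2 * self.influent.s_nh)
        full[_IDX["S_NO2"]] = 0.5
        full[_IDX["S_NO3"]] = 2.0
        return full[_STATE_IDX]


def solve_steady_state(
    influent: InfluentState,
    config: PlantConfig,
    params: ParameterVector,
    tol: float = 1e-10,
    max_iter: int = 500,
    x0: np.ndarray | None = None,
) -> SteadyState:
    """Damped Newton solution of the steady-state balances.

    Positivity is enforced by projection after each step.  If plain Newton
    stalls from a cold start, a short pseudo-transient continuation
    (backward-Euler steps with growing step size, solved with the same
    Newton machinery) re-seeds it.  Washout (a biomass pool at exactly zero)
    is a valid solution, not an error.
    """
    model = _ReducedModel(influent, config, params)
    cold = x0 is None
    x = model.seed() if cold else np.maximum(np.asarray(x0, float), 0.0)
    trace: list[float] = []
    used = 0

    def newton(x: np.ndarray, iters: int) -> tuple[np.ndarray, float, int]:
        f = model.residual(x)
        if not np.all(np.isfinite(f)):
            return x, np.inf, 0
        norm = float(np.max(np.abs(f)))
        n_it = 0
        lu = None
        prev_norm = np.inf
        for _ in range(iters):
            if norm < tol:
                break
            # chord variant: keep the factorized Jacobian while contraction
            # is strong; refresh when progress slows
            if lu is None or norm > 0.2 * prev_norm:
                jac = model.jacobian(x, f)
                if not np.all(np.isfinite(jac)):
                    break
                try:
                    lu = lu_factor(jac)
                except (ValueError, np.linalg.LinAlgError):
                    lu = None
            prev_norm = norm
            step = lu_solve(lu, -f) if lu is not None else None
            if step is None or not np.all(np.isfinite(step)):
                try:
                    step = np.linalg.lstsq(jac, -f, rcond=None)[0]
                except np.linalg.LinAlgError:
                    break
                lu = None
            lam, accepted = 1.0, False
            for _ in range(25):
                x_new = np.maximum(x + lam * step, 0.0)
                f_new = model.residual(x_new)
                norm_new = float(np.max(np.abs(f_new)))
                if np.isfinite(norm_new) and (
                        norm_new < norm * (1.0 - 1e-4 * lam)
                        or norm_new < tol):
                    x, f, norm, accepted = x_new, f_new, norm_new, True
                    break
                lam *= 0.5
            n_it += 1
            trace.append(norm)
            if not accepted:
                break
        return x, norm, n_it

    def continuation(x: np.ndarray, steps: int,
                     dt_max: float = 2.0) -> np.ndarray:
        # approximate backward-Euler with growing but capped step size:
        # follows the stable dynamics towards the attracting steady state
        # instead of jumping to an unstable (washout) root; a large dt_max
        # lets it traverse very slow transients (it then behaves like a
        # heavily damped Newton)
        dt, n = 0.05, len(x)
        for _ in range(steps):
            f = model.residual(x)
            norm = float(np.max(np.abs(f))) if np.all(np.isfinite(f)) else np.inf
            if not np.isfinite(norm):
                break
            if norm < tol:
                break
            jac = model.jacobian(x, f)
            if not np.all(np.isfinite(jac)):
                break
            a = np.eye(n) / dt - jac
            try:
                step = np.linalg.solve(a, f)
            except np.linalg.LinAlgError:
                try:
                    step = np.linalg.lstsq(a, f, rcond=None)[0]
                except np.linalg.LinAlgError:
                    break
            # reject exploding steps; shrink the pseudo-time step instead
            x_new = np.maximum(x + step, 0.0)
            f_new = model.residual(x_new)
            if not np.all(np.isfinite(f_new)) or \
                    float(np.max(np.abs(f_new))) > 1e4 * max(norm, 1.0):
                dt = max(dt * 0.25, 1e-6)
                continue
            # basin guard: backward-Euler with lambda*dt beyond the largest
            # unstable eigenvalue flips a biomass pool negative (clipped to
            # zero), hopping into the washout basin; shrink the step until
            # the flow is resolved
            if dt > 2e-6 and np.any((x[_BIO_STATE_IDX] > 1.0)
                                    & (x_new[_BIO_STATE_IDX] <= 0.0)):
                dt = max(dt * 0.25, 1e-6)
                continue
            x = x_new
            dt = min(dt * 1.5, dt_max)
        return x

    def hopped(x_from: np.ndarray, x_to: np.ndarray) -> bool:
        # Newton killed a species the flow still carried (> 1 g/m3): it
        # jumped into a different (washout) basin rather than converging
        # along the flow
        f_from = model.full_state(x_from)
        f_to = model.full_state(x_to)
        for s_, a_ in zip(_BIOMASS, _ATTACHED):
            alive = f_from[_IDX[s_]] + f_from[_IDX[a_]] > 1.0
            dead = f_to[_IDX[s_]] + f_to[_IDX[a_]] < 1e-6
            if alive and dead:
                return True
        return False

    def flow_solve(x_start: np.ndarray) -> tuple[np.ndarray, float]:
        """Follow the dynamics from ``x_start`` at flow-faithful step sizes,
        polishing with Newton; reject Newton results that hop basins.  The
        system can be bistable (active branch vs locally stable washout);
        the evaluator convention is the branch the dynamics reach from the
        start point."""
        nonlocal used
        x_flow = x_start
        x_n, norm_n = x_start, np.inf
        for steps in (120, 400, 1200, 3000):
            x_flow = continuation(x_flow, steps, dt_max=2.0)
            x_n, norm_n, n_it = newton(x_flow, max_iter)
            used += n_it
            if norm_n < tol and not hopped(x_flow, x_n):
                return x_n, norm_n
        if norm_n < tol:            # converged but possibly hopped: accept
            return x_n, norm_n      # after the flow itself decayed that far
        # last resort: large pseudo-steps (may hop; better than failing)
        for dt_max, steps in ((50.0, 300), (1000.0, 400)):
            x_flow = continuation(x_flow, steps, dt_max=dt_max)
            x_n, norm_n, n_it = newton(x_flow, max(max_iter - used, 30))
            used += n_it
            if norm_n < tol:
                break
        return x_n, norm_n

    if cold:
        x, norm = flow_solve(x)
    else:
        x, norm, n_it = newton(x, max_iter)
        used += n_it
        # a warm start that converged onto a dead pool which could regrow,
        # or onto total washout, is suspect: re-solve along the flow
        if norm >= tol or _washout_unstable(model, x) \
                or _n_washed(model, x) == len(_BIOMASS):
            x2, norm2 = flow_solve(model.seed())
            if norm2 < tol:
                x, norm = x2, norm2

    if norm >= tol:
        raise SteadyStateError(
            f"steady-state solver failed to converge: residual {norm:.3e} "
            f"after {used} Newton iterations", trace)
    return SteadyState(
        state=model.full_state(x), residual_norm=norm, iterations=used,
        converged=True, residual_trace=tuple(trace[-10:]))


_BIOMASS = ("X_BH", "X_BA1", "X_BA2")


def _n_washed(model: _ReducedModel, x: np.ndarray) -> int:
    """Number of biomass species with zero total (suspended + attached)."""
    full = model.full_state(x)
    return sum(full[_IDX[s_]] + full[_IDX[a_]] < 1e-6
               for s_, a_ in zip(_BIOMASS, _ATTACHED))


def _washout_unstable(model: _ReducedModel, x: np.ndarray) -> bool:
    """True if a biomass species is fully washed out (suspended + attached)
    yet could regrow at the ambient substrate concentrations in either
    compartment, i.e. Newton landed on an unstable washout root."""
    full = model.full_state(x)
    p = model.params
    s_s = full[_IDX["S_S"]]
    s_nh = full[_IDX["S_NH"]]
    s_no2 = full[_IDX["S_NO2"]]
    a_tot = sum(full[_IDX[n]] for n in _ATTACHED)
    cap = model.cap
    phi = max(0.0, 1.0 - a_tot / cap) if cap > 0 else 0.0
    k_att, k_det = p["X43"], p["X44"]

    mnut = s_nh / (K_NH_NUTRIENT + s_nh)

    def gross(so: float, name: str) -> float:
        if name == "X_BH":
            return p["X1"] * s_s / (p["X2"] + s_s) * so / (p["X3"] + so) * mnut
        if name == "X_BA1":
            return p["X21"] * s_nh / (p["X22"] + s_nh) * so / (p["X23"] + so)
        return p["X27"] * s_no2 / (p["X28"] + s_no2) * so / (p["X23"] + so) \
            * mnut

    decay = {"X_BH": p["X16"], "X_BA1": p["X17"], "X_BA2": p["X18"]}
    for name, att in zip(_BIOMASS, _ATTACHED):
        total = full[_IDX[name]] + full[_IDX[att]]
        if total >= 1e-6:
            continue
        # linearized coupled suspended/attached subsystem at zero biomass
        a11 = gross(model.do, name) - decay[name] - model.srt_loss - k_att * phi
        a22 = gross(model.do * model.do_att, name) * phi - decay[name] - k_det
        tr, det = a11 + a22, a11 * a22 - k_det * k_att * phi
        lam_max = 0.5 * (tr + np.sqrt(max(tr * tr - 4.0 * det, 0.0)))
        if lam_max > 1e-6:
            return True
    return False



def clarifier_split(mlss_solids: float, config: PlantConfig) -> tuple[float, float]:
    """Ideal point-settler: a non-settleable fraction ``f_ns`` of the mixed
    liquor solids escapes with the effluent; the remainder is routed to the
    underflow (RAS/WAS).  Conservation is exact."""
    if mlss_solids < 0:
        raise ValueError("negative MLSS")
    effluent = config.clarifier_f_ns * mlss_solids
    return effluent, mlss_solids - effluent


def effluent_summary(steady: SteadyState, config: PlantConfig,
                     params: ParameterVector | None = None) -> EffluentSummary:
    """Compose BOD, TN and TSS from the converged state.

    BOD is the BOD5 factor applied to biodegradable effluent COD (soluble
    substrate plus escaping biodegradable particulates); TN sums the
    dissolved nitrogen species and the N bound in escaping particulates;
    TSS converts escaping particulate COD through COD:VSS and VSS/TSS.
    ``params`` supplies the biomass/inert N contents (registry codes X41,
    X42); typical defaults are used when omitted.
    """
    s = steady
    f_ns = config.clarifier_f_ns
    part_biodeg = s["X_S"] + s["X_BH"] + s["X_BA1"] + s["X_BA2"]
    part_cod = part_biodeg + s["X_I"]
    esc = f_ns * part_cod
    bod = config.f_bod * (s["S_S"] + f_ns * part_biodeg)
    i_xb = params["X41"] if params is not None else 0.086
    i_xu = params["X42"] if params is not None else 0.06
    part_n = f_ns * (s["X_ND"] + i_xb * (s["X_BH"] + s["X_BA1"] + s["X_BA2"])
                     + i_xu * s["X_I"])
    tn_dissolved = s["S_NH"] + s["S_ND"] + s["S_NO2"] + s["S_NO3"]
    tn = tn_dissolved + part_n
    tss = esc / config.cod_per_vss / config.vss_per_tss
    return EffluentSummary(
        bod=bod, tn=tn, tss=tss,
        components={
            "S_S": s["S_S"], "S_NH": s["S_NH"], "S_ND": s["S_ND"],
            "S_NO2": s["S_NO2"], "S_NO3": s["S_NO3"],
            "particulate_N": part_n, "escaping_particulate_COD": esc,
        },
    )


class EffluentEvaluator:
    """The pipeline's model contract: parameter vector -> (BOD, TN, TSS).

    Solves are warm-started from the steady state at registry defaults,
    which keeps batch evaluation fast and — because every solve starts from
    the same point — bit-deterministic regardless of evaluation order.
    """

    OUTPUTS = ("BOD", "TN", "TSS")

    def __init__(self, influent: InfluentState, config: PlantConfig,
                 registry: ParameterRegistry, tol: float = 1e-10):
        self.influent = influent
        self.config = config
        self.registry = registry
        self.tol = tol
        self.n_evaluations = 0
        base = solve_steady_state(influent, config, registry.defaults(), tol=tol)
        self._warm = base.state[_STATE_IDX].copy()
        self.base_steady = base

    def steady(self, params: ParameterVector) -> SteadyState:
        self.n_evaluations += 1
        try:
            return solve_steady_state(self.influent, self.config, params,
                                      tol=self.tol, x0=self._warm)
        except SteadyStateError:
            # cold start (pseudo-transient continuation) as a fallback
            return solve_steady_state(self.influent, self.config, params,
                                      tol=self.tol)

    def summary(self, params: ParameterVector) -> EffluentSummary:
        return effluent_summary(self.steady(params), self.config, params)

    def __call__(self, params: ParameterVector) -> np.ndarray:
        """Outputs as an array [BOD, TN, TSS] (mg/L)."""
        return self.summary(params).as_array()

    def evaluate_matrix(self, rows: np.ndarray, codes: list[str],
                        base: ParameterVector | None = None) -> np.ndarray:
        """Evaluate a design matrix.

        ``rows[i]`` holds physical values for ``codes``; all other registry
        parameters are pinned at ``base`` (registry defaults if omitted).
        Returns an (n_rows, 3) array of outputs; rows whose solve fails are
        filled with NaN and counted in ``n_failures``.
        """
        base = base if base is not None else self.registry.defaults()
        out = np.empty((len(rows), 3))
        self.n_failures = 0
        for i, row in enumerate(np.asarray(rows, float)):
            params = base.with_values(dict(zip(codes, row)))
            try:
                out[i] = self(params)
            except SteadyStateError:
                out[i] = np.nan
                self.n_failures += 1
        return out
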