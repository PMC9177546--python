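"""Gujer matrix of the reduced IFAS biokinetic model.

Every stand-in process equation of the reduced model lives in this one file
so it can be audited in a single read.  The model tracks two-step
nitrification (NH4 -> NO2 -> NO3) and two-step denitrification (growth on
NO3 and on NO2, the latter scaled by the nitrite reduction factor), ordinary
heterotrophic growth/decay with death-regeneration, hydrolysis and
ammonification, and a fully retained attached-biomass compartment exchanging
biomass with the bulk through attachment/detachment.

Components are bulk concentrations in g/m3 (= mg/L); COD-bearing components
in gCOD, nitrogen species in gN.  Dissolved oxygen is a fixed environmental
setpoint, not a solved state, but it carries an explicit matrix column so the
per-process COD continuity check closes exactly.

Electron-acceptor COD equivalents (gCOD per gN, relative to NH4 as the
nitrogen reference state): NO2 = 48/14 (3.43), NO3 = 64/14 (4.57),
N2 = 24/14 (1.71).  The familiar denitrification demands follow as
differences: NO3 -> N2 releases 40/14 = 2.86 gCOD/gN of acceptor capacity
and NO2 -> N2 releases 24/14 = 1.71 gCOD/gN.
"""

from __future__ import annotations

import numpy as np

from .parameters import ParameterVector

__all__ = [
    "COMPONENTS",
    "N_COMPONENTS",
    "PROCESSES",
    "stoichiometric_matrix",
    "process_rates",
    "continuity_residuals",
    "COD_EQUIV_NO3",
    "COD_EQUIV_NO2",
]

#: State components. S_* soluble, X_* suspended particulate, A_* attached.
COMPONENTS = (
    "S_S",    # readily biodegradable substrate, gCOD/m3
    "S_I",    # soluble inert, gCOD/m3
    "S_NH",   # ammonia N, gN/m3
    "S_ND",   # soluble organic N, gN/m3
    "S_NO2",  # nitrite N, gN/m3
    "S_NO3",  # nitrate N, gN/m3
    "S_N2",   # dinitrogen from denitrification, gN/m3
    "X_S",    # slowly biodegradable substrate, gCOD/m3
    "X_I",    # particulate inert, gCOD/m3
    "X_ND",   # particulate organic N, gN/m3
    "X_BH",   # suspended heterotrophs, gCOD/m3
    "X_BA1",  # suspended ammonia oxidizers, gCOD/m3
    "X_BA2",  # suspended nitrite oxidizers, gCOD/m3
    "A_BH",   # attached heterotrophs, gCOD/m3 reactor
    "A_BA1",  # attached ammonia oxidizers, gCOD/m3 reactor
    "A_BA2",  # attached nitrite oxidizers, gCOD/m3 reactor
    "S_O",    # dissolved oxygen column (setpoint; continuity bookkeeping only)
)

N_COMPONENTS = len(COMPONENTS)
_IDX = {c: i for i, c in enumerate(COMPONENTS)}

# Exact electron equivalents (gCOD/gN); printed as 2.86 and 1.71 in reports.
_EQ_NO2 = 48.0 / 14.0   # NH4 -> NO2
_EQ_NO3 = 64.0 / 14.0   # NH4 -> NO3
_EQ_N2 = 24.0 / 14.0    # NH4 -> N2
COD_EQUIV_NO3 = _EQ_NO3 - _EQ_N2   # 40/14 = 2.857, NO3 -> N2
COD_EQUIV_NO2 = _EQ_NO2 - _EQ_N2   # 24/14 = 1.714, NO2 -> N2

_POOLS = (("X_BH", "X_BA1", "X_BA2"), ("A_BH", "A_BA1", "A_BA2"))

PROCESSES = tuple(
    [f"{p}_{pool}" for pool in ("susp", "att") for p in (
        "aerobic_growth_het",
        "anoxic_growth_no3",
        "anoxic_growth_no2",
        "decay_het",
        "growth_aob",
        "growth_nob",
        "decay_aob",
        "decay_nob",
    )]
    + ["hydrolysis", "hydrolysis_orgN", "ammonification",
       "attach_het", "attach_aob", "attach_nob",
       "detach_het", "detach_aob", "detach_nob"]
)


def _growth_decay_rows(nu: np.ndarray, row0: int, params: ParameterVector,
                       het: str, aob: str, nob: str,
                       debris_xs: str, debris_xi: str, debris_xnd: str) -> None:
    """Fill the eight growth/decay rows for one biomass pool."""
    Yh_aer = params["X52"]
    Yh_anx = params["X53"]
    f_u = params["X61"]
    Y_a1 = params["X24"]
    Y_a2 = params["X26"]
    i_xb = params["X41"]
    i_xu = params["X42"]

    r = row0
    # aerobic heterotrophic growth
    nu[r, _IDX["S_S"]] = -1.0 / Yh_aer
    nu[r, _IDX[het]] = 1.0
    nu[r, _IDX["S_NH"]] = -i_xb
    nu[r, _IDX["S_O"]] = -(1.0 - Yh_aer) / Yh_aer
    # anoxic growth on nitrate (NO3 -> N2)
    r += 1
    nu[r, _IDX["S_S"]] = -1.0 / Yh_anx
    nu[r, _IDX[het]] = 1.0
    nu[r, _IDX["S_NH"]] = -i_xb
    nu[r, _IDX["S_NO3"]] = -(1.0 - Yh_anx) / (COD_EQUIV_NO3 * Yh_anx)
    nu[r, _IDX["S_N2"]] = (1.0 - Yh_anx) / (COD_EQUIV_NO3 * Yh_anx)
    # anoxic growth on nitrite (NO2 -> N2)
    r += 1
    nu[r, _IDX["S_S"]] = -1.0 / Yh_anx
    nu[r, _IDX[het]] = 1.0
    nu[r, _IDX["S_NH"]] = -i_xb
    nu[r, _IDX["S_NO2"]] = -(1.0 - Yh_anx) / (COD_EQUIV_NO2 * Yh_anx)
    nu[r, _IDX["S_N2"]] = (1.0 - Yh_anx) / (COD_EQUIV_NO2 * Yh_anx)
    # heterotrophic decay (death-regeneration; debris to suspended pools)
    r += 1
    nu[r, _IDX[het]] = -1.0
    nu[r, _IDX[debris_xs]] = 1.0 - f_u
    nu[r, _IDX[debris_xi]] = f_u
    nu[r, _IDX[debris_xnd]] = i_xb - f_u * i_xu
    # AOB growth (NH4 -> NO2)
    r += 1
    nu[r, _IDX[aob]] = 1.0
    nu[r, _IDX["S_NH"]] = -1.0 / Y_a1 - i_xb
    nu[r, _IDX["S_NO2"]] = 1.0 / Y_a1
    nu[r, _IDX["S_O"]] = -(_EQ_NO2 - Y_a1) / Y_a1
    # NOB growth (NO2 -> NO3)
    r += 1
    nu[r, _IDX[nob]] = 1.0
    nu[r, _IDX["S_NH"]] = -i_xb
    nu[r, _IDX["S_NO2"]] = -1.0 / Y_a2
    nu[r, _IDX["S_NO3"]] = 1.0 / Y_a2
    nu[r, _IDX["S_O"]] = -(_EQ_NO3 - _EQ_NO2 - Y_a2) / Y_a2
    # autotroph decay
    for r, bio in ((row0 + 6, aob), (row0 + 7, nob)):
        nu[r, _IDX[bio]] = -1.0
        nu[r, _IDX[debris_xs]] = 1.0 - f_u
        nu[r, _IDX[debris_xi]] = f_u
        nu[r, _IDX[debris_xnd]] = i_xb - f_u * i_xu


def stoichiometric_matrix(params: ParameterVector) -> np.ndarray:
    """(n_processes, n_components) Gujer matrix at the given parameter point."""
    nu = np.zeros((len(PROCESSES), N_COMPONENTS))
    _growth_decay_rows(nu, 0, params, "X_BH", "X_BA1", "X_BA2",
                       "X_S", "X_I", "X_ND")
    # attached pool: growth into A_* columns, decay debris sloughed to the
    # suspended particulate pools
    _growth_decay_rows(nu, 8, params, "A_BH", "A_BA1", "A_BA2",
                       "X_S", "X_I", "X_ND")
    r = 16
    nu[r, _IDX["X_S"]] = -1.0
    nu[r, _IDX["S_S"]] = 1.0                      # hydrolysis
    nu[r + 1, _IDX["X_ND"]] = -1.0
    nu[r + 1, _IDX["S_ND"]] = 1.0                 # organic-N hydrolysis
    nu[r + 2, _IDX["S_ND"]] = -1.0
    nu[r + 2, _IDX["S_NH"]] = 1.0                 # ammonification
    for j, (xs, xa) in enumerate(zip(*_POOLS)):
        nu[r + 3 + j, _IDX[xs]] = -1.0
        nu[r + 3 + j, _IDX[xa]] = 1.0             # attachment
        nu[r + 6 + j, _IDX[xa]] = -1.0
        nu[r + 6 + j, _IDX[xs]] = 1.0             # detachment
    return nu


def _monod(s: float, k: float) -> float:
    return s / (k + s) if s > 0.0 else 0.0


#: ammonia half-saturation of the nutrient-limitation switch on biomass
#: growth (gN/m3).  Growth incorporates nitrogen at i_XB per unit biomass;
#: without this switch the ammonia balance has no nonnegative solution when
#: anabolic N demand exceeds supply (high-yield corners of the screening
#: ranges).  Small enough to be inactive under normal operation.
K_NH_NUTRIENT = 0.05

#: registry codes consumed by the rate equations, in cache order
_RATE_CODES = ("X1", "X2", "X3", "X15", "X11", "X12", "X13", "X14", "X16",
               "X21", "X22", "X23", "X27", "X28", "X17", "X18", "X31", "X32",
               "X33", "X43", "X44")


def rate_constants(params: ParameterVector) -> tuple[float, ...]:
    """Kinetic constants extracted once per parameter point (cacheable)."""
    return tuple(params[c] for c in _RATE_CODES)


# component indices used by the rate equations
_iSS, _iSNH, _iSND, _iSNO2, _iSNO3 = (_IDX[c] for c in
                                      ("S_S", "S_NH", "S_ND", "S_NO2", "S_NO3"))
_iXS, _iXND = _IDX["X_S"], _IDX["X_ND"]
_iXBH, _iXBA1, _iXBA2 = (_IDX[c] for c in ("X_BH", "X_BA1", "X_BA2"))
_iABH, _iABA1, _iABA2 = (_IDX[c] for c in ("A_BH", "A_BA1", "A_BA2"))


def _rates_core(c: np.ndarray, k: tuple[float, ...], so: float,
                cap: float, do_attenuation: float = 1.0) -> np.ndarray:
    """Rates at one state (shape (n_components,)) or a batch of states
    (shape (m, n_components)); the batch path serves the finite-difference
    Jacobian of the steady-state solver."""
    (mu_h, k_s, k_oh, k_o_den, eta_no3, eta_no2, k_no3, k_no2d, b_h,
     mu_a1, k_nh, k_oa, mu_a2, k_no2, b_a1, b_a2, k_h, k_x, k_a,
     k_att, k_det) = k

    single = c.ndim == 1
    cc = c[None, :] if single else c

    # wild trial states during solver line searches may overflow; the
    # solver rejects non-finite residuals, so silence those warnings
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        return _rates_inner(cc, k, so, cap, do_attenuation, single)


def _rates_inner(cc, k, so, cap, do_attenuation, single):
    (mu_h, k_s, k_oh, k_o_den, eta_no3, eta_no2, k_no3, k_no2d, b_h,
     mu_a1, k_nh, k_oa, mu_a2, k_no2, b_a1, b_a2, k_h, k_x, k_a,
     k_att, k_det) = k
    ms = cc[:, _iSS] / (k_s + cc[:, _iSS])
    mno3 = cc[:, _iSNO3] / (k_no3 + cc[:, _iSNO3])
    mno2d = cc[:, _iSNO2] / (k_no2d + cc[:, _iSNO2])
    mnh = cc[:, _iSNH] / (k_nh + cc[:, _iSNH])
    mno2 = cc[:, _iSNO2] / (k_no2 + cc[:, _iSNO2])
    mnut = cc[:, _iSNH] / (K_NH_NUTRIENT + cc[:, _iSNH])

    a_tot = cc[:, _iABH] + cc[:, _iABA1] + cc[:, _iABA2]
    phi = np.maximum(0.0, 1.0 - a_tot / cap) if cap > 0 else np.zeros(len(cc))

    rho = np.zeros((len(cc), len(PROCESSES)))
    # the attached pool sees diffusion-attenuated oxygen (biofilm interior),
    # the bulk pool the full setpoint
    for row0, xbh, xba1, xba2, g, so_pool in (
            (0, cc[:, _iXBH], cc[:, _iXBA1], cc[:, _iXBA2], 1.0, so),
            (8, cc[:, _iABH], cc[:, _iABA1], cc[:, _iABA2], phi,
             so * do_attenuation)):
        mo_h = so_pool / (k_oh + so_pool)
        io = k_o_den / (k_o_den + so_pool)     # oxygen inhibition switch
        mo_a = so_pool / (k_oa + so_pool)
        gh = mu_h * ms * xbh * g * mnut
        rho[:, row0 + 0] = gh * mo_h
        rho[:, row0 + 1] = gh * eta_no3 * io * mno3
        rho[:, row0 + 2] = gh * eta_no2 * io * mno2d
        rho[:, row0 + 3] = b_h * xbh
        rho[:, row0 + 4] = mu_a1 * mnh * mo_a * xba1 * g
        rho[:, row0 + 5] = mu_a2 * mno2 * mo_a * xba2 * g * mnut
        rho[:, row0 + 6] = b_a1 * xba1
        rho[:, row0 + 7] = b_a2 * xba2

    het_tot = cc[:, _iXBH] + cc[:, _iABH]
    xs = cc[:, _iXS]
    active = (het_tot > 0.0) & (xs > 0.0)
    ratio = np.where(active, xs / np.where(het_tot > 0, het_tot, 1.0), 0.0)
    hyd = np.where(active, k_h * ratio / (k_x + ratio) * het_tot, 0.0)
    rho[:, 16] = hyd
    rho[:, 17] = np.where(active, hyd * cc[:, _iXND] / np.where(xs > 0, xs, 1.0),
                          0.0)
    rho[:, 18] = k_a * cc[:, _iSND] * het_tot

    rho[:, 19] = k_att * cc[:, _iXBH] * phi
    rho[:, 20] = k_att * cc[:, _iXBA1] * phi
    rho[:, 21] = k_att * cc[:, _iXBA2] * phi
    rho[:, 22] = k_det * cc[:, _iABH]
    rho[:, 23] = k_det * cc[:, _iABA1]
    rho[:, 24] = k_det * cc[:, _iABA2]
    return rho[0] if single else rho


def process_rates(state: np.ndarray, params: ParameterVector,
                  do_setpoint: float, attached_capacity: float,
                  do_attenuation: float = 1.0) -> np.ndarray:
    """Process rate vector (g/m3/d per process) at a bulk state.

    ``do_setpoint`` is the fixed bulk dissolved oxygen (mgO2/L);
    ``attached_capacity`` the attached-biomass ceiling (gCOD/m3 reactor);
    ``do_attenuation`` scales the oxygen the attached pool experiences
    (diffusion limitation inside the biofilm).
    """
    state = np.asarray(state, float)
    if len(state) != N_COMPONENTS:
        raise ValueError(f"state must have {N_COMPONENTS} entries")
    if np.any(state[: N_COMPONENTS - 1] < -1e-9):
        raise ValueError("negative concentration in state")
    c = np.maximum(state, 0.0)
    return _rates_core(c, rate_constants(params), float(do_setpoint),
                       float(attached_capacity), float(do_attenuation))


# Conservation weights.  COD column: organics carry +1 per gCOD, oxygen -1,
# oxidized N species their electron equivalents relative to NH4; N column:
# gN per unit of component.
def _conservation_weights(params: ParameterVector) -> tuple[np.ndarray, np.ndarray]:
    i_xb = params["X41"]
    i_xu = params["X42"]
    w_cod = np.zeros(N_COMPONENTS)
    w_n = np.zeros(N_COMPONENTS)
    for name in ("S_S", "S_I", "X_S", "X_BH", "X_BA1", "X_BA2", "A_BH",
                 "A_BA1", "A_BA2"):
        w_cod[_IDX[name]] = 1.0
    w_cod[_IDX["X_I"]] = 1.0
    w_cod[_IDX["S_O"]] = -1.0
    w_cod[_IDX["S_NO2"]] = -_EQ_NO2
    w_cod[_IDX["S_NO3"]] = -_EQ_NO3
    w_cod[_IDX["S_N2"]] = -_EQ_N2
    for name in ("S_NH", "S_ND", "S_NO2", "S_NO3", "S_N2", "X_ND"):
        w_n[_IDX[name]] = 1.0
    for name in ("X_BH", "X_BA1", "X_BA2", "A_BH", "A_BA1", "A_BA2"):
        w_n[_IDX[name]] = i_xb
    w_n[_IDX["X_I"]] = i_xu
    return w_cod, w_n


def continuity_residuals(params: ParameterVector) -> dict[str, np.ndarray]:
    """Per-process COD and N continuity residuals (exactly 0 for a mass-
    conserving matrix, up to floating point)."""
    nu = stoichiometric_matrix(params)
    w_cod, w_n = _conservation_weights(params)
    return {"COD": nu @ w_cod, "N": nu @ w_n}
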