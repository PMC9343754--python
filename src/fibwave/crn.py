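"""Courtemanche–Ramirez–Nattel (CRN) human atrial myocyte model: constants,
canonical initial state, and precomputed voltage-dependent rate tables.

The CRN model describes the human atrial action potential with 12 ionic
currents, a two-compartment sarcoplasmic reticulum (uptake + release), and
Ca2+ buffering by troponin, calmodulin and calsequestrin.  State vector
layout (21 variables, used throughout the numerical kernels):

====  ==========  =========================================================
idx   symbol      meaning
====  ==========  =========================================================
0     V           membrane potential (mV)
1-3   m, h, j     I_Na activation / fast + slow inactivation
4-5   oa, oi      I_to activation / inactivation
6-7   ua, ui      I_Kur activation / inactivation
8     xr          I_Kr activation
9     xs          I_Ks activation
10-12 d, f, fCa   I_CaL activation / voltage + Ca inactivation
13-15 u, v, w     SR Ca2+ release (ryanodine receptor) gates
16-18 Nai,Ki,Cai  intracellular Na+, K+, Ca2+ (mM)
19-20 Caup,Carel  SR uptake / release compartment Ca2+ (mM)
====  ==========  =========================================================

Voltage-dependent gate kinetics and current rectification factors are
tabulated on a fine V grid; the integration kernels use linear
interpolation.  Gates are advanced with the Rush–Larsen exponential
update, so the tables store the steady-state value and the per-step decay
factor exp(-dt/tau) with the time step baked in.
"""

from __future__ import annotations

import numpy as np

# physical constants
R = 8.3143          # J / (mol K)
T = 310.0           # K
F = 96.4867         # C / mmol
RTF = R * T / F     # mV

CM = 100.0          # membrane capacitance, pF

# extracellular concentrations (mM)
NA_O = 140.0
K_O = 5.4
CA_O = 1.8

# cell geometry (um^3)
V_I = 13668.0
V_UP = 1109.52
V_REL = 96.48

# maximal conductances (nS/pF) and fluxes
G_NA = 7.8
G_K1 = 0.09
G_TO = 0.1652
G_KR = 0.029411765
G_KS = 0.12941176
G_CAL = 0.12375
G_B_NA = 0.0006744375
G_B_CA = 0.001131
I_NAK_MAX = 0.59933874
KM_NA_I = 10.0
KM_K_O = 1.5
I_NACA_MAX = 1600.0
KM_NA = 87.5
KM_CA = 1.38
K_SAT = 0.1
GAMMA = 0.35
I_PCA_MAX = 0.275
K_REL = 30.0
TAU_TR = 180.0
I_UP_MAX = 0.005
K_UP = 0.00092
CA_UP_MAX = 15.0
TAU_F_CA = 2.0
TAU_U = 8.0

# buffers (mM)
TRPN_MAX = 0.070
KM_TRPN = 0.0005
CMDN_MAX = 0.050
KM_CMDN = 0.00238
CSQN_MAX = 10.0
KM_CSQN = 0.8

KQ10 = 3.0           # temperature scaling of I_to / I_Kur gate kinetics
SIGMA_NAK = (np.exp(NA_O / 67.3) - 1.0) / 7.0

N_STATE = 21
N_CURRENTS = 13  # preset factor vector length, see presets.CURRENTS

#: Published CRN resting state (quiescent model).
INITIAL_STATE = np.array([
    -81.18,        # V
    2.908e-3,      # m
    9.649e-1,      # h
    9.775e-1,      # j
    3.043e-2,      # oa
    9.992e-1,      # oi
    4.966e-3,      # ua
    9.986e-1,      # ui
    3.296e-5,      # xr
    1.869e-2,      # xs
    1.367e-4,      # d
    9.996e-1,      # f
    7.755e-1,      # fCa
    0.0,           # u
    1.0,           # v
    9.992e-1,      # w
    11.17,         # Nai
    139.0,         # Ki
    1.013e-4,      # Cai
    1.488,         # Caup
    1.488,         # Carel
])

# rate-table V grid
TAB_VMIN = -120.0
TAB_VMAX = 80.0
TAB_DV = 0.1
N_TAB_COLS = 30


def _safe_ratio(num: np.ndarray, den: np.ndarray, limit: np.ndarray | float,
                where_singular: np.ndarray) -> np.ndarray:
    out = np.empty_like(num)
    ok = ~where_singular
    out[ok] = num[ok] / den[ok]
    out[where_singular] = limit if np.isscalar(limit) else limit[where_singular]
    return out


def gate_kinetics(v: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Steady-state value and time constant (ms) of each voltage-dependent
    gate at membrane potentials ``v``.  Removable singularities in the
    published rate expressions are replaced by their analytic limits.
    """
    v = np.asarray(v, dtype=float)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    # I_Na m
    x = v + 47.13
    am = _safe_ratio(0.32 * x, 1.0 - np.exp(-0.1 * x), 3.2, np.abs(x) < 1e-9)
    bm = 0.08 * np.exp(-v / 11.0)
    out["m"] = (am / (am + bm), 1.0 / (am + bm))

    # I_Na h, j (piecewise at -40 mV)
    lo = v < -40.0
    ah = np.where(lo, 0.135 * np.exp(-(v + 80.0) / 6.8), 0.0)
    bh = np.where(lo, 3.56 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.35 * v),
                  1.0 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1))))
    out["h"] = (ah / (ah + bh), 1.0 / (ah + bh))

    with np.errstate(over="ignore"):
        aj = np.where(
            lo,
            (-1.2714e5 * np.exp(0.2444 * v) - 3.474e-5 * np.exp(-0.04391 * v))
            * (v + 37.78) / (1.0 + np.exp(0.311 * (v + 79.23))),
            0.0,
        )
    bj = np.where(
        lo,
        0.1212 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14))),
        0.3 * np.exp(-2.535e-7 * v) / (1.0 + np.exp(-0.1 * (v + 32.0))),
    )
    out["j"] = (aj / (aj + bj), 1.0 / (aj + bj))

    # I_to oa, oi
    a = 0.65 / (np.exp(-(v + 10.0) / 8.5) + np.exp(-(v - 30.0) / 59.0))
    b = 0.65 / (2.5 + np.exp((v + 82.0) / 17.0))
    out["oa"] = (1.0 / (1.0 + np.exp(-(v + 20.47) / 17.54)), 1.0 / ((a + b) * KQ10))
    a = 1.0 / (18.53 + np.exp((v + 113.7) / 10.95))
    b = 1.0 / (35.56 + np.exp(-(v + 1.26) / 7.44))
    out["oi"] = (1.0 / (1.0 + np.exp((v + 43.1) / 5.3)), 1.0 / ((a + b) * KQ10))

    # I_Kur ua, ui
    a = 0.65 / (np.exp(-(v + 10.0) / 8.5) + np.exp(-(v - 30.0) / 59.0))
    b = 0.65 / (2.5 + np.exp((v + 82.0) / 17.0))
    out["ua"] = (1.0 / (1.0 + np.exp(-(v + 30.3) / 9.6)), 1.0 / ((a + b) * KQ10))
    a = 1.0 / (21.0 + np.exp(-(v - 185.0) / 28.0))
    b = np.exp((v - 158.0) / 16.0)
    out["ui"] = (1.0 / (1.0 + np.exp((v - 99.45) / 27.48)), 1.0 / ((a + b) * KQ10))

    # I_Kr xr
    x = v + 14.1
    a = _safe_ratio(0.0003 * x, 1.0 - np.exp(-x / 5.0), 0.0015, np.abs(x) < 1e-9)
    x = v - 3.3328
    b = _safe_ratio(7.3898e-5 * x, np.exp(x / 5.1237) - 1.0,
                    7.3898e-5 * 5.1237, np.abs(x) < 1e-9)
    out["xr"] = (1.0 / (1.0 + np.exp(-(v + 14.1) / 6.5)), 1.0 / (a + b))

    # I_Ks xs
    x = v - 19.9
    a = _safe_ratio(4e-5 * x, 1.0 - np.exp(-x / 17.0), 4e-5 * 17.0, np.abs(x) < 1e-9)
    b = _safe_ratio(3.5e-5 * x, np.exp(x / 9.0) - 1.0, 3.5e-5 * 9.0, np.abs(x) < 1e-9)
    out["xs"] = (1.0 / np.sqrt(1.0 + np.exp(-x / 12.7)), 0.5 / (a + b))

    # I_CaL d, f
    x = v + 10.0
    e = np.exp(-x / 6.24)
    tau_d = _safe_ratio(1.0 - e, 0.035 * x * (1.0 + e), 1.0 / (6.24 * 0.035 * 2.0),
                        np.abs(x) < 1e-9)
    out["d"] = (1.0 / (1.0 + np.exp(-x / 8.0)), tau_d)
    out["f"] = (1.0 / (1.0 + np.exp((v + 28.0) / 6.9)),
                9.0 / (0.0197 * np.exp(-(0.0337 ** 2) * x * x) + 0.02))

    # SR release w gate
    x = v - 7.9
    e = np.exp(-x / 5.0)
    tau_w = _safe_ratio(6.0 * (1.0 - e), (1.0 + 0.3 * e) * x, 6.0 / (5.0 * 1.3),
                        np.abs(x) < 1e-9)
    out["w"] = (1.0 - 1.0 / (1.0 + np.exp(-(v - 40.0) / 17.0)), tau_w)
    return out


#: table column order: (inf, rl-factor) pairs for the 12 tabulated gates,
#: then voltage factors for I_K1, g_Kur(V), I_Kr rectification, f_NaK,
#: and the two I_NaCa exponentials.
TAB_GATES = ("m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs", "d", "f", "w")


def build_rate_table(dt: float) -> np.ndarray:
    """Precompute the (n_v, 30) rate table for time step ``dt`` (ms)."""
    v = np.arange(TAB_VMIN, TAB_VMAX + TAB_DV / 2, TAB_DV)
    kin = gate_kinetics(v)
    tab = np.empty((v.size, N_TAB_COLS))
    for i, g in enumerate(TAB_GATES):
        inf, tau = kin[g]
        tab[:, 2 * i] = inf
        tab[:, 2 * i + 1] = np.exp(-dt / tau)
    tab[:, 24] = 1.0 / (1.0 + np.exp(0.07 * (v + 80.0)))
    tab[:, 25] = 0.005 + 0.05 / (1.0 + np.exp(-(v - 15.0) / 13.0))
    tab[:, 26] = 1.0 / (1.0 + np.exp((v + 15.0) / 22.4))
    fvrt = v / RTF
    tab[:, 27] = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * fvrt)
                        + 0.0365 * SIGMA_NAK * np.exp(-fvrt))
    tab[:, 28] = np.exp(GAMMA * fvrt)
    tab[:, 29] = np.exp((GAMMA - 1.0) * fvrt)
    return tab.astype(np.float32)


_table_cache: dict[float, np.ndarray] = {}


def rate_table(dt: float) -> np.ndarray:
    """Cached rate table for time step ``dt``."""
    key = round(float(dt), 9)
    if key not in _table_cache:
        _table_cache[key] = build_rate_table(key)
    return _table_cache[key]
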