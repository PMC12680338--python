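"""Land-type active-contraction model driven by the calcium transient.

Implements the human Land crossbridge/troponin model (troponin binding,
tropomyosin blocking, weak and strong crossbridge states) integrated at
fixed stretch, which is how it feeds the lumped chamber model.  Two
parameters carry the fibrotic remodeling:

* ``t_a_ref`` -- maximum (saturated) active tension, 50 kPa at baseline.
  Output tension is exactly linear in it.
* ``mu`` -- the myofilament binding rate, baseline 9.  It is expressed on a
  scale where mu = 9 corresponds to the published unattached->weakly-bound
  crossbridge rate constant; the effective binding rate is
  ``k_uw_ref * mu / 9``, so halving mu halves crossbridge recruitment and
  slows the contraction (later, lower tension peak).

Distortion (zeta) states are identically zero at fixed stretch and are
omitted; the length dependence of tension and calcium sensitivity is kept
and exercised near stretch 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .transient import Transient

MU_BASELINE = 9.0


@dataclass(frozen=True)
class ContractionParams:
    t_a_ref: float = 50.0  # kPa, saturated tension scale
    mu: float = MU_BASELINE  # myofilament binding rate (published scale = 9)
    s_ta: float = 1.0  # fibrotic multiplier on t_a_ref
    s_mu: float = 1.0  # fibrotic multiplier on mu
    # troponin / tropomyosin constants (published human parameterization)
    ca50_ref: float = 0.805  # uM
    k_trpn: float = 0.1  # 1/ms
    n_trpn: float = 2.0
    k_tm_unblock: float = 1.0  # 1/ms
    trpn50: float = 0.35
    n_tm: float = 5.0
    # crossbridge cycling constants (1/ms)
    k_uw_ref: float = 0.182
    k_ws: float = 0.012
    r_s: float = 0.25
    r_w: float = 0.5
    # length dependence
    beta_0: float = 2.3
    beta_1: float = -2.4

    def __post_init__(self):
        if self.t_a_ref <= 0 or self.mu <= 0:
            raise ValueError("t_a_ref and mu must be positive")

    @classmethod
    def fibrotic(cls, ta=False, mu=False, **kw) -> "ContractionParams":
        """Fibrotic levels scale T_a and mu by 0.5."""
        return cls(s_ta=0.5 if ta else 1.0, s_mu=0.5 if mu else 1.0, **kw)


@njit(cache=True)
def _integrate_land(
    cai_um, dt, stretch, ca50, k_trpn, n_trpn, k_tm_unblock, trpn50, n_tm,
    k_uw, k_ws, r_s, r_w, t_sat, beta_0,
):
    n = len(cai_um)
    ta = np.zeros(n)
    ca_trpn = 1e-8
    tm_b = 1.0
    xs = 0.0
    xw = 0.0
    k_wu = k_uw * (1.0 / r_w - 1.0) - k_ws
    k_su = k_ws * r_w * (1.0 / r_s - 1.0)
    k_b = (
        k_tm_unblock
        * trpn50**n_tm
        / (1.0 - r_s - (1.0 - r_s) * r_w)
    )
    lam = min(stretch, 1.2)
    h_lam = max(0.0, 1.0 + beta_0 * (lam + min(lam, 0.87) - 1.87))
    for i in range(n):
        ca = cai_um[i]
        d_catrpn = k_trpn * ((ca / ca50) ** n_trpn * (1.0 - ca_trpn) - ca_trpn)
        xu = 1.0 - tm_b - xs - xw
        gamma_u = min(100.0, ca_trpn ** (-n_tm / 2.0))
        d_tmb = k_b * gamma_u * xu - k_tm_unblock * ca_trpn ** (n_tm / 2.0) * tm_b
        d_xw = k_uw * xu - k_wu * xw - k_ws * xw
        d_xs = k_ws * xw - k_su * xs
        ca_trpn = min(1.0 - 1e-12, max(1e-12, ca_trpn + dt * d_catrpn))
        tm_b += dt * d_tmb
        xw += dt * d_xw
        xs += dt * d_xs
        ta[i] = h_lam * t_sat / r_s * xs
    return ta


def simulate_tension(
    cai: Transient, params: ContractionParams = ContractionParams(), stretch: float = 1.0
) -> Transient:
    """Integrate the contraction model over ``cai`` (mM) at fixed stretch.

    Returns active tension in kPa on the calcium transient's time base.
    """
    if not (0.8 <= stretch <= 1.2):
        raise ValueError("stretch must lie in [0.8, 1.2]")
    if np.any(cai.y < 0):
        raise ValueError("calcium transient contains negative values")
    cai_um = cai.y * 1e3  # mM -> uM
    ca50 = params.ca50_ref * (1.0 + params.beta_1 * (stretch - 1.0))
    k_uw = params.k_uw_ref * (params.mu * params.s_mu) / MU_BASELINE
    ta = _integrate_land(
        cai_um, cai.dt, stretch, ca50, params.k_trpn, params.n_trpn,
        params.k_tm_unblock, params.trpn50, params.n_tm,
        k_uw, params.k_ws, params.r_s, params.r_w,
        params.t_a_ref * params.s_ta, params.beta_0,
    )
    return Transient(cai.t.copy(), ta, "Ta")


def tension_biomarkers(ta: Transient) -> dict:
    """Peak (kPa), time-to-peak (ms) and 90 % relaxation time of one beat.

    An all-zero trace reports peak 0 with timing fields set to NaN.
    """
    y = ta.y
    peak = float(y.max())
    if peak <= 0.0:
        return {"peak": 0.0, "time_to_peak": float("nan"), "relax90": float("nan")}
    i_peak = int(np.argmax(y))
    t_peak = float(ta.t[i_peak] - ta.t[0])
    thr = 0.1 * peak
    after = y[i_peak:]
    below = np.flatnonzero(after <= thr)
    relax90 = float(ta.t[i_peak + below[0]] - ta.t[i_peak]) if len(below) else float("nan")
    return {"peak": peak, "time_to_peak": t_peak, "relax90": relax90}
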