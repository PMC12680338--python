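"""Cell-scale electrophysiology: pacing protocol, simulation, biomarkers.

The pacing protocol mirrors the study's initialization: 50 pre-pacing beats
at 1 Hz with a 0.025 ms step; the final paced beat is returned for
downstream use (calcium drives the contraction model).  Fibrotic ion-channel
remodeling is a multiplicative scaling of the I_K1, I_CaL and I_Na maximal
conductances (0.5 / 0.5 / 0.6 at the fibrotic level).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..transient import Transient
from . import courtemanche as crn


@dataclass(frozen=True)
class IonicScaling:
    """Multipliers on I_K1, I_CaL and I_Na maximal conductances."""

    s_k1: float = 1.0
    s_cal: float = 1.0
    s_na: float = 1.0

    def __post_init__(self):
        if min(self.s_k1, self.s_cal, self.s_na) <= 0:
            raise ValueError("conductance scalings must be positive")

    @classmethod
    def baseline(cls) -> "IonicScaling":
        return cls(1.0, 1.0, 1.0)

    @classmethod
    def fibrotic(cls, k1=False, cal=False, na=False) -> "IonicScaling":
        """Fibrotic levels: I_K1 x0.5, I_CaL x0.5, I_Na x0.6."""
        return cls(0.5 if k1 else 1.0, 0.5 if cal else 1.0, 0.6 if na else 1.0)


@dataclass(frozen=True)
class PacingProtocol:
    rate: float = 1.0  # Hz
    n_beats: int = 50
    dt: float = 0.025  # ms
    stim_amplitude: float = -20.0  # pA/pF (approx. 2x diastolic threshold)
    stim_duration: float = 2.0  # ms

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.rate <= 0 or self.n_beats < 1:
            raise ValueError("invalid pacing protocol")

    @property
    def period(self) -> float:
        return 1000.0 / self.rate


@dataclass(frozen=True)
class CellBiomarkers:
    v_rest: float  # mV, just before stimulus
    apd90: float  # ms
    cat_amplitude: float  # mM (model concentration units)
    cat_ttp: float  # ms, stimulus to calcium peak


def _first_bad_state(y) -> str:
    for idx, nm in enumerate(crn.STATE_NAMES):
        if not np.isfinite(y[idx]):
            return nm
    return "V"  # blow-up happened mid-step; membrane potential drives it


def simulate_cell(
    scaling: IonicScaling,
    protocol: PacingProtocol = PacingProtocol(),
    record_dt: float | None = None,
    forward_euler: bool = False,
    conductance_overrides: dict | None = None,
) -> dict:
    """Pace a single cell and return the final beat.

    Returns ``{"vm": Transient, "cai": Transient, "t_stim": 0.0}`` with time
    measured from the final beat's stimulus onset.  Integration uses the
    Rush-Larsen scheme unless ``forward_euler`` (the independent cross-check
    path) is requested.  ``conductance_overrides`` maps current names (see
    ``courtemanche.CURRENT_NAMES``) to extra multiplicative factors, the
    hook for conductance-set variants beyond the three fibrotic scalings.
    """
    period = protocol.period
    dt = protocol.dt
    y = crn.Y0.copy()
    gs = crn.scale_vector(conductance_overrides)
    gs[crn.CURRENT_NAMES.index("I_K1")] *= scaling.s_k1
    gs[crn.CURRENT_NAMES.index("I_CaL")] *= scaling.s_cal
    gs[crn.CURRENT_NAMES.index("I_Na")] *= scaling.s_na
    n_pre = int(round((protocol.n_beats - 1) * period / dt))
    stride_pre = max(1, n_pre)  # record nothing useful during pre-pacing
    record_dt = dt if record_dt is None else record_dt
    stride = max(1, int(round(record_dt / dt)))
    n_last = int(round(period / dt))
    try:
        if n_pre > 0:
            crn.integrate(
                y, dt, n_pre, period, protocol.stim_amplitude,
                protocol.stim_duration, gs, stride_pre, forward_euler,
            )
        t, v, ca = crn.integrate(
            y, dt, n_last, period, protocol.stim_amplitude,
            protocol.stim_duration, gs, stride, forward_euler,
        )
    except ZeroDivisionError:
        # a gate time constant collapsed to zero: the state blew up
        raise FloatingPointError(
            f"ionic model diverged: state {_first_bad_state(y)!r} is non-finite"
        ) from None
    for idx, nm in enumerate(crn.STATE_NAMES):
        if not np.isfinite(y[idx]):
            raise FloatingPointError(
                f"ionic model diverged: state {nm!r} is non-finite"
            )
    return {
        "vm": Transient(t, v, "Vm"),
        "cai": Transient(t, ca, "Cai"),
        "t_stim": 0.0,
    }


def biomarkers(vm: Transient, cai: Transient, t_stim: float = 0.0) -> CellBiomarkers:
    """Extract resting potential, APD90 and calcium-transient biomarkers.

    APD90 is the duration spent above ``v_rest + 0.1 * (peak - v_rest)``
    around the upstroke, with linear interpolation at the crossings.
    """
    t, v = vm.t, vm.y
    if t_stim < t[0] or t_stim > t[-1]:
        raise ValueError("t_stim outside the sampled window")
    i_stim = int(np.searchsorted(t, t_stim))
    v_rest = v[max(0, i_stim - 1)] if i_stim > 0 else v[0]
    peak = float(v[i_stim:].max())
    if peak - v_rest < 20.0:
        raise ValueError("no action-potential upstroke detected")
    thr = v_rest + 0.1 * (peak - v_rest)

    above = v[i_stim:] >= thr
    idx_up = np.flatnonzero(above)
    if len(idx_up) == 0:
        raise ValueError("no action-potential upstroke detected")
    i0 = i_stim + idx_up[0]
    # first downward crossing after the peak
    i_peak = i_stim + int(np.argmax(v[i_stim:]))
    below = np.flatnonzero(v[i_peak:] < thr)
    if len(below) == 0:
        raise ValueError("action potential does not repolarize within the beat")
    i1 = i_peak + below[0]

    def _cross(i_hi, i_lo):
        # linear interpolation of the threshold crossing between samples
        v0, v1 = v[i_hi], v[i_lo]
        if v1 == v0:
            return t[i_hi]
        frac = (thr - v0) / (v1 - v0)
        return t[i_hi] + frac * (t[i_lo] - t[i_hi])

    t_up = _cross(i0 - 1, i0) if i0 > 0 else t[i0]
    t_down = _cross(i1 - 1, i1)
    apd90 = float(t_down - t_up)

    ca = cai.y
    cat_amplitude = float(ca.max() - ca.min())
    cat_ttp = float(cai.t[int(np.argmax(ca))] - t_stim)
    return CellBiomarkers(float(v_rest), apd90, cat_amplitude, cat_ttp)
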