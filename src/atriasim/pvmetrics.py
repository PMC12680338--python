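"""PV-loop landmarks, A-loop area, and the five atrial function metrics.

The atrial PV trajectory over one cycle is a figure-eight: the A-loop
(active atrial contraction, traversed from the stimulus) and the V-loop
(passive filling/emptying during ventricular systole).  Landmarks:

* ``lav_preA`` / ``lap_preA`` -- volume and pressure at the stimulus time
  (pre-systolic / end-diastolic state);
* ``lav_min`` / ``lav_max``   -- extreme volumes over the cycle;
* ``lap_maxA``                -- maximum pressure during the A-loop.

Metrics (all dimensionless except the A-loop area, reported in mJ):

* A-loop area: shoelace (Gauss) area of the closed A-loop polygon, the
  stroke work of atrial contraction;
* booster  = (LAVpreA - LAVmin) / LAVpreA   (active emptying fraction);
* reservoir = (LAVmax - LAVmin) / LAVmin;
* conduit  = (LAVmax - LAVpreA) / LAVmax    (passive emptying fraction);
* upstroke = (LAPmaxA - LAPpreA) / LAPpreA.

A-loop segmentation: the loop runs from the stimulus to the first
self-intersection of the PV path after minimum volume, closed at the
intersection point; if the path does not self-intersect within the cycle,
the segment ends where volume first returns to its pre-stimulus level
(mitral-opening fallback).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import mmhg_ml_to_mj


@dataclass
class PVLoop:
    """One cycle of the (volume, pressure) trajectory."""

    time: np.ndarray  # ms
    volume: np.ndarray  # mL
    pressure: np.ndarray  # mmHg
    t_stim: float = 0.0  # ms, atrial stimulus within the cycle

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if not (len(self.time) == len(self.volume) == len(self.pressure)):
            raise ValueError("time, volume, pressure must have equal length")
        if np.any(self.volume <= 0):
            raise ValueError("volume must stay positive")


@dataclass(frozen=True)
class PVLandmarks:
    lav_preA: float
    lap_preA: float
    lav_min: float
    lav_max: float
    lap_maxA: float

    def __post_init__(self):
        if not (self.lav_min <= self.lav_preA <= self.lav_max):
            raise ValueError("landmark ordering violated")


@dataclass(frozen=True)
class MetricSet:
    a_loop_area: float  # mJ
    booster: float
    reservoir: float
    conduit: float
    upstroke: float
    laef_total: float
    laef_active: float
    laef_passive: float

    def as_dict(self) -> dict:
        return {
            "a_loop_area": self.a_loop_area,
            "booster": self.booster,
            "reservoir": self.reservoir,
            "conduit": self.conduit,
            "upstroke": self.upstroke,
            "laef_total": self.laef_total,
            "laef_active": self.laef_active,
            "laef_passive": self.laef_passive,
        }


METRIC_NAMES = ["a_loop_area", "booster", "reservoir", "conduit", "upstroke"]


def _segments_intersect(p1, p2, p3, p4):
    """Proper intersection point of segments p1p2 and p3p4, or None."""
    d1 = p2 - p1
    d2 = p4 - p3
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(denom) < 1e-300:
        return None
    diff = p3 - p1
    t = (diff[0] * d2[1] - diff[1] * d2[0]) / denom
    u = (diff[0] * d1[1] - diff[1] * d1[0]) / denom
    if 0.0 <= t <= 1.0 and 0.0 <= u <= 1.0:
        return p1 + t * d1
    return None


def a_loop_segment(pv: PVLoop) -> np.ndarray:
    """Closed A-loop polygon, shape (k, 2) columns (volume, pressure)."""
    t = pv.time
    if not (t[0] <= pv.t_stim <= t[-1]):
        raise ValueError("t_stim outside the cycle")
    i0 = int(np.searchsorted(t, pv.t_stim))
    pts = np.column_stack([pv.volume, pv.pressure])
    path = pts[i0:]
    i_min = int(np.argmin(path[:, 0]))
    # first segment after the volume minimum that crosses an earlier segment
    for j in range(max(i_min, 1), len(path) - 1):
        a, b = path[j], path[j + 1]
        # only test against segments before the minimum (the down-stroke)
        for k in range(0, max(1, i_min - 1)):
            x = _segments_intersect(path[k], path[k + 1], a, b)
            if x is not None and j > k + 1:
                return np.vstack([x, path[k + 1 : j + 1], x])
    # fallback: close where volume recovers to its pre-stimulus level
    v0 = path[0, 0]
    after_min = np.flatnonzero(path[i_min:, 0] >= v0)
    j_end = i_min + (after_min[0] if len(after_min) else len(path) - 1 - i_min)
    return np.vstack([path[: j_end + 1], path[0]])


def shoelace_area(polygon: np.ndarray) -> float:
    """|Gauss area| of a closed polygon given as (k, 2) vertices."""
    if len(polygon) < 3:
        raise ValueError("polygon needs at least 3 points")
    x, y = polygon[:, 0], polygon[:, 1]
    return 0.5 * abs(float(np.dot(y, np.roll(x, -1)) - np.dot(y, np.roll(x, 1))))


def a_loop_area(pv: PVLoop) -> float:
    """A-loop (atrial stroke work) area in mJ."""
    return mmhg_ml_to_mj(shoelace_area(a_loop_segment(pv)))


def landmarks(pv: PVLoop) -> PVLandmarks:
    t = pv.time
    if not (t[0] <= pv.t_stim <= t[-1]):
        raise ValueError("t_stim outside the cycle")
    lav_preA = float(np.interp(pv.t_stim, t, pv.volume))
    lap_preA = float(np.interp(pv.t_stim, t, pv.pressure))
    seg = a_loop_segment(pv)
    return PVLandmarks(
        lav_preA=lav_preA,
        lap_preA=lap_preA,
        lav_min=float(pv.volume.min()),
        lav_max=float(pv.volume.max()),
        lap_maxA=float(seg[:, 1].max()),
    )


def metric_set(lm: PVLandmarks, a_area_mj: float) -> MetricSet:
    if min(lm.lav_preA, lm.lav_min, lm.lav_max, lm.lap_preA) <= 0:
        raise ValueError("zero or negative landmark denominator")
    booster = (lm.lav_preA - lm.lav_min) / lm.lav_preA
    reservoir = (lm.lav_max - lm.lav_min) / lm.lav_min
    conduit = (lm.lav_max - lm.lav_preA) / lm.lav_max
    upstroke = (lm.lap_maxA - lm.lap_preA) / lm.lap_preA
    return MetricSet(
        a_loop_area=a_area_mj,
        booster=booster,
        reservoir=reservoir,
        conduit=conduit,
        upstroke=upstroke,
        laef_total=(lm.lav_max - lm.lav_min) / lm.lav_max,
        laef_active=booster,
        laef_passive=conduit,
    )


def metrics_from_loop(pv: PVLoop) -> MetricSet:
    """Landmarks + area + metric formulas in one call."""
    return metric_set(landmarks(pv), a_loop_area(pv))
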