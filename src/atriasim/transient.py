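"""Uniformly sampled time series container shared across modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Transient:
    """A uniformly sampled scalar time series (time in ms)."""

    t: np.ndarray
    y: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape:
            raise ValueError("t and y must have identical shape")
        if len(self.t) >= 2:
            dts = np.diff(self.t)
            if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
                raise ValueError("samples must be uniform in time")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)

    def resample(self, dt: float) -> "Transient":
        t_new = np.arange(self.t[0], self.t[-1] + 0.5 * dt, dt)
        return Transient(t_new, np.interp(t_new, self.t, self.y), self.name)

    def shifted(self, delay_ms: float) -> "Transient":
        return Transient(self.t + delay_ms, self.y.copy(), self.name)
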