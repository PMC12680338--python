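"""Reduced Holzapfel-Ogden passive law and virtual stiffness calibration.

Strain energy (per unit reference volume, kPa)::

    Psi = a/(2b) [exp(b (I1 - 3)) - 1]
        + a_f/(2 b_f) [exp(b_f (I4* - 1)^2) - 1] * H(I4* - 1)

with the dispersed (splayed-fiber) pseudo-invariant
``I4* = delta_f * I1 + (1 - 3 delta_f) * I4`` and a tension-only
(conditional) fiber term.  The virtual experiments stretch a unit cube with
the fiber along the longitudinal axis by 5 % in either direction; the
reported load is the nominal (first Piola-Kirchhoff) normal traction on the
stretched face, with traction-free lateral faces.  Incompressibility is
enforced exactly by default (lateral stretches solved so lateral Cauchy
stresses vanish at det F = 1); a bulk-modulus penalty variant is available
as a cross-check.

Fibrotic stiffening is calibrated as in the study: find multipliers
(s_a, s_af) on (a, a_f) such that the 5 %-stretch load changes by a target
factor in each direction (e.g. doubles longitudinally while the transverse
load is unchanged), to within 1 %.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize


@dataclass(frozen=True)
class MaterialParameters:
    a: float = 2.92  # kPa
    b: float = 5.6
    a_f: float = 11.84  # kPa
    b_f: float = 17.95
    delta_f: float = 0.09  # fiber dispersion fraction
    kappa: float = 650.0  # kPa, bulk modulus (penalty variant only)

    def __post_init__(self):
        if min(self.a, self.a_f, self.kappa) <= 0:
            raise ValueError("a, a_f and kappa must be positive")
        if not (0 <= self.delta_f < 1.0 / 3.0):
            raise ValueError("delta_f must lie in [0, 1/3)")

    def scaled(self, s_a: float, s_af: float) -> "MaterialParameters":
        return replace(self, a=s_a * self.a, a_f=s_af * self.a_f)


def _psi_derivs(p: MaterialParameters, i1: float, i4: float):
    """(dPsi/dI1, dPsi/dI4) for the dispersed, tension-only fiber law."""
    i4s = p.delta_f * i1 + (1.0 - 3.0 * p.delta_f) * i4
    psi1 = 0.5 * p.a * np.exp(p.b * (i1 - 3.0))
    if i4s > 1.0:
        # exponent clipped: far outside the physiological range the exact
        # magnitude is irrelevant, only monotonicity matters for the solvers
        expo = min(p.b_f * (i4s - 1.0) ** 2, 200.0)
        dpsi_di4s = p.a_f * (i4s - 1.0) * np.exp(expo)
    else:
        dpsi_di4s = 0.0
    return psi1 + dpsi_di4s * p.delta_f, dpsi_di4s * (1.0 - 3.0 * p.delta_f)


def _cauchy_diag(p: MaterialParameters, lx: float, ly: float, lz: float):
    """Deviatoric diagonal Cauchy stresses (no pressure) for diag(F);
    fiber along x."""
    i1 = lx * lx + ly * ly + lz * lz
    i4 = lx * lx
    psi1, psi4 = _psi_derivs(p, i1, i4)
    sx = 2.0 * psi1 * lx * lx + 2.0 * psi4 * lx * lx
    sy = 2.0 * psi1 * ly * ly
    sz = 2.0 * psi1 * lz * lz
    return sx, sy, sz


def uniaxial_load(
    p: MaterialParameters,
    direction: str,
    stretch: float,
    incompressibility: str = "exact",
) -> float:
    """Nominal load (kPa, force per reference area) on the stretched face.

    ``direction`` is ``"longitudinal"`` (along the fiber) or ``"transverse"``
    (across it).  Lateral faces are traction-free; lateral stretches are
    solved accordingly.
    """
    if stretch < 1.0:
        raise ValueError("stretch must be >= 1")
    if direction not in ("longitudinal", "transverse"):
        raise ValueError("direction must be 'longitudinal' or 'transverse'")
    if stretch == 1.0:
        return 0.0
    lam = stretch

    if incompressibility == "exact":
        if direction == "longitudinal":
            # stretch along the fiber: lateral directions are equivalent
            lt = lam ** -0.5
            sx, sy, _ = _cauchy_diag(p, lam, lt, lt)
            sigma = sx - sy  # pressure eliminated with sigma_lat = 0
            return sigma / lam
        # transverse: stretch along y; unknown fiber-direction stretch lx
        def lateral_residual(lx):
            lz = 1.0 / (lam * lx)
            sx, _, sz = _cauchy_diag(p, lx, lam, lz)
            return sx - sz

        sol = optimize.brentq(lateral_residual, 0.5, 2.0, xtol=1e-12)
        lx = sol
        lz = 1.0 / (lam * lx)
        sx, sy, sz = _cauchy_diag(p, lx, lam, lz)
        sigma = sy - sx  # p chosen so sigma_xx = sigma_zz = 0
        return sigma / lam

    if incompressibility != "penalty":
        raise ValueError("incompressibility must be 'exact' or 'penalty'")

    # penalty variant: solve both lateral stretches for zero lateral stress
    def residuals(lats):
        l1, l2 = lats
        if direction == "longitudinal":
            lx, ly, lz = lam, l1, l2
        else:
            lx, ly, lz = l1, lam, l2
        j = lx * ly * lz
        sx, sy, sz = _cauchy_diag(p, lx, ly, lz)
        pvol = p.kappa * (j - 1.0)  # volumetric Cauchy pressure term
        s = np.array([sx, sy, sz]) / j + pvol
        if direction == "longitudinal":
            return [s[1], s[2]]
        return [s[0], s[2]]

    sol = optimize.fsolve(residuals, [lam**-0.5, lam**-0.5], full_output=True)
    lats, info, ier, msg = sol
    if ier != 1:
        raise RuntimeError(
            f"lateral-stress solve failed to converge: {msg}; "
            f"residual {np.max(np.abs(info['fvec'])):.3e}"
        )
    l1, l2 = lats
    if direction == "longitudinal":
        lx, ly, lz = lam, l1, l2
    else:
        lx, ly, lz = l1, lam, l2
    j = lx * ly * lz
    sx, sy, sz = _cauchy_diag(p, lx, ly, lz)
    pvol = p.kappa * (j - 1.0)
    idx = 0 if direction == "longitudinal" else 1
    sigma = [sx, sy, sz][idx] / j + pvol
    # nominal traction: Cauchy * current area / reference area
    area_ratio = j / lam
    return sigma * area_ratio


@dataclass(frozen=True)
class StiffnessCalibration:
    s_a: float
    s_af: float
    residual_long: float
    residual_trans: float
    iterations: int


def calibrate_stiffness_scaling(
    p: MaterialParameters,
    target_long: float,
    target_trans: float,
    stretch: float = 1.05,
    tol: float = 0.01,
    **load_kwargs,
) -> StiffnessCalibration:
    """Find (s_a, s_af) so the 5 %-stretch loads change by the target factors.

    A damped least-squares iteration on the two load ratios; b, b_f and the
    dispersion are held fixed.  Residuals are relative load errors and must
    fall below ``tol`` (the study's 1 % precision) or an error is raised.
    """
    if target_long <= 0 or target_trans <= 0:
        raise ValueError("targets must be positive")
    base_long = uniaxial_load(p, "longitudinal", stretch, **load_kwargs)
    base_trans = uniaxial_load(p, "transverse", stretch, **load_kwargs)

    n_eval = 0

    def residuals(s):
        nonlocal n_eval
        n_eval += 1
        q = p.scaled(abs(s[0]), abs(s[1]))
        r_l = uniaxial_load(q, "longitudinal", stretch, **load_kwargs) / base_long
        r_t = uniaxial_load(q, "transverse", stretch, **load_kwargs) / base_trans
        return [r_l - target_long, r_t - target_trans]

    sol = optimize.least_squares(
        residuals, x0=[target_trans, target_long], xtol=1e-12, ftol=1e-12, gtol=1e-12
    )
    s_a, s_af = abs(sol.x[0]), abs(sol.x[1])
    r_l, r_t = residuals([s_a, s_af])
    if abs(r_l) / target_long > tol or abs(r_t) / target_trans > tol:
        raise RuntimeError(
            "stiffness calibration did not reach 1% precision: "
            f"residuals ({r_l:.4f}, {r_t:.4f})"
        )
    return StiffnessCalibration(s_a, s_af, r_l / target_long, r_t / target_trans, n_eval)


def equibiaxial_fiber_stress(p: MaterialParameters, stretch: float) -> float:
    """In-plane Cauchy stress for equibiaxial wall stretch (chamber coupling).

    The wall is stretched equally along the fiber and cross-fiber in-plane
    directions (thickness 1/stretch^2 by incompressibility, transmural
    stress eliminated).  Returns the mean in-plane Cauchy stress in kPa; for
    stretch < 1 the isotropic term gives a (physiological) compressive
    stress while the tension-only fiber term switches off.
    """
    lam = max(stretch, 0.3)
    lt = 1.0 / (lam * lam)
    sx, sy, sz = _cauchy_diag(p, lam, lam, lt)
    return 0.5 * ((sx - sz) + (sy - sz))
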