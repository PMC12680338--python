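"""Priority-based, burden-matched fibrosis assignment.

Elements are ranked by descending normalized LGE-like intensity and marked
fibrotic one by one until the element-count burden over the eligible region
(LA body + appendage, pulmonary veins and mitral cap excluded) first reaches
the clinical target.  Raising the target is equivalent to lowering the
intensity cutoff, so fibrotic sets are nested across targets.  The synthetic
burden elevation (x1.5) simply re-runs the assignment at the scaled target.
"""

from __future__ import annotations

import numpy as np

from .cohort import APPENDAGE, BODY, LabeledSurfaceMesh

_EPS = 1e-9


def _eligible(mesh: LabeledSurfaceMesh) -> np.ndarray:
    return (mesh.region_label == BODY) | (mesh.region_label == APPENDAGE)


def burden(mesh: LabeledSurfaceMesh) -> float:
    """Fibrotic element-count fraction over body+appendage elements."""
    elig = _eligible(mesh)
    n = int(elig.sum())
    if n == 0:
        raise ValueError("mesh has no eligible (body/appendage) elements")
    if np.any(mesh.fibrotic & ~elig):
        raise ValueError("fibrotic flags found on vein/mitral elements")
    return float(mesh.fibrotic[elig].sum()) / n


def assign_fibrosis(
    mesh: LabeledSurfaceMesh, target_burden: float
) -> LabeledSurfaceMesh:
    """Return a copy of ``mesh`` with fibrotic flags matching ``target_burden``.

    The achieved burden is the smallest reachable value >= target given the
    element granularity (``ceil(target * n_eligible)`` elements).  Intensity
    ties are broken by element index (stable sort), so the assignment is
    deterministic and monotone in the target.
    """
    if not (0 <= target_burden < 1):
        raise ValueError("target_burden must lie in [0, 1)")
    if mesh.intensity is None:
        raise ValueError("mesh carries no intensity field")
    out = mesh.copy()
    elig_idx = np.flatnonzero(_eligible(out))
    n = len(elig_idx)
    if n == 0:
        raise ValueError("mesh has no eligible (body/appendage) elements")
    k = int(np.ceil(target_burden * n - _EPS))
    out.fibrotic = np.zeros(out.n_triangles, dtype=bool)
    if k > 0:
        order = np.argsort(-out.intensity[elig_idx], kind="stable")
        out.fibrotic[elig_idx[order[:k]]] = True
    return out


def elevate_burden(mesh: LabeledSurfaceMesh, factor: float) -> LabeledSurfaceMesh:
    """Re-assign fibrosis at ``factor`` times the currently achieved burden."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    b = burden(mesh)
    return assign_fibrosis(mesh, min(factor * b, 1.0 - _EPS))
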