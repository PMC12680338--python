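"""Synthetic patient cohort: descriptors, LA-like surfaces, stimulus regions.

The three-patient "paper" preset carries the clinical scalars of the study
cohort (end-diastolic volume, fibrosis burden, total activation time,
longitudinal/transverse conduction velocity, 1 Hz pacing, 2 mm wall).  The
"random" preset samples uniformly within the span of those columns so that
larger cohorts can be generated for testing.

Surfaces are ellipsoid-like closed triangulations with a smooth seeded
radial perturbation, labeled regions (body, appendage, four pulmonary-vein
ostia, mitral cap), a circumferential fiber field tangent to the surface,
and a smooth normalized intensity field standing in for an LGE map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import trimesh
from scipy import sparse
from scipy.special import sph_harm_y

from .units import MM3_PER_ML

# region label codes (per triangle)
BODY, APPENDAGE, VEIN, MITRAL = 0, 1, 2, 3
REGION_NAMES = {BODY: "body", APPENDAGE: "appendage", VEIN: "vein", MITRAL: "mitral"}


@dataclass(frozen=True)
class PatientDescriptor:
    """Anatomical/functional scalars for one (synthetic) patient."""

    id: str
    edv: float  # LA end-diastolic volume, mL
    burden_target: float  # fibrosis burden, fraction of eligible elements
    total_activation_time: float  # ms
    cv_l: float  # longitudinal conduction velocity, m/s
    cv_t: float  # transverse conduction velocity, m/s
    pacing_rate: float = 1.0  # Hz
    wall_thickness: float = 2.0  # mm

    def __post_init__(self):
        if not self.edv > 0:
            raise ValueError("edv must be positive")
        if not (0 <= self.burden_target < 1):
            raise ValueError("burden_target must lie in [0, 1)")
        if not self.cv_t < self.cv_l:
            raise ValueError("cv_t must be smaller than cv_l")
        if not self.total_activation_time > 0:
            raise ValueError("total_activation_time must be positive")


#: Clinical cohort scalars (three patients).  Columns: edv (mL), burden
#: (fraction), total activation time (ms), CV_L (m/s), CV_T (m/s).
_PAPER_ROWS = [
    ("patient1", 110.0, 0.156, 82.0, 1.1500, 0.5142),
    ("patient2", 112.5, 0.239, 56.0, 1.5730, 0.7035),
    ("patient3", 60.0, 0.179, 116.8, 0.835, 0.373),
]


def generate_cohort(
    n: int, seed: int = 0, preset: Literal["paper", "random"] = "paper"
) -> list[PatientDescriptor]:
    """Return ``n`` patient descriptors.

    ``preset="paper"`` returns (up to) the three clinical patients verbatim;
    asking for more than three is an error.  ``preset="random"`` samples each
    scalar uniformly within the span of the clinical columns, rejecting draws
    that violate descriptor invariants (none can occur since cv_t is derived).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if preset == "paper":
        if n > len(_PAPER_ROWS):
            raise ValueError("the clinical preset defines only three patients")
        return [
            PatientDescriptor(pid, edv, b, tat, cvl, cvt)
            for pid, edv, b, tat, cvl, cvt in _PAPER_ROWS[:n]
        ]
    if preset != "random":
        raise ValueError(f"unknown preset {preset!r}")
    rng = np.random.default_rng(seed)
    cols = np.array([[r[1], r[2], r[3], r[4]] for r in _PAPER_ROWS])
    lo, hi = cols.min(axis=0), cols.max(axis=0)
    out = []
    for i in range(n):
        edv, b, tat, cvl = rng.uniform(lo, hi)
        # keep the fixed 1:1/5 conductivity anisotropy (CV ~ sqrt(ratio))
        out.append(
            PatientDescriptor(f"synthetic{i + 1}", edv, b, tat, cvl, cvl / np.sqrt(5.0))
        )
    return out


@dataclass
class LabeledSurfaceMesh:
    """Closed triangulated LA-like surface with per-triangle fields."""

    vertices: np.ndarray  # (nv, 3) mm
    triangles: np.ndarray  # (nt, 3) int
    region_label: np.ndarray  # (nt,) int codes BODY/APPENDAGE/VEIN/MITRAL
    fiber: np.ndarray  # (nt, 3) unit tangent
    intensity: np.ndarray  # (nt,) in [0, 1]
    fibrotic: np.ndarray = field(default=None)  # (nt,) bool

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.fibrotic is None:
            self.fibrotic = np.zeros(len(self.triangles), dtype=bool)

    # -- geometry helpers ---------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    def normals(self) -> np.ndarray:
        v = self.vertices[self.triangles]
        n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def areas(self) -> np.ndarray:
        v = self.vertices[self.triangles]
        return 0.5 * np.linalg.norm(
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
        )

    def enclosed_volume_ml(self) -> float:
        """Cavity volume by the divergence theorem (mL)."""
        v = self.vertices[self.triangles]
        vol = np.einsum("ij,ij->i", v[:, 0], np.cross(v[:, 1], v[:, 2])).sum() / 6.0
        return abs(vol) / MM3_PER_ML

    def total_area_mm2(self) -> float:
        return float(self.areas().sum())

    def is_watertight(self) -> bool:
        return trimesh.Trimesh(
            self.vertices, self.triangles, process=False
        ).is_watertight

    def vertex_adjacency(self) -> sparse.csr_matrix:
        """Symmetric 0/1 vertex adjacency from triangle edges."""
        t = self.triangles
        i = np.concatenate([t[:, 0], t[:, 1], t[:, 2]])
        j = np.concatenate([t[:, 1], t[:, 2], t[:, 0]])
        nv = self.n_vertices
        a = sparse.coo_matrix((np.ones(len(i)), (i, j)), shape=(nv, nv))
        a = ((a + a.T) > 0).astype(np.int8)
        return a.tocsr()

    def copy(self) -> "LabeledSurfaceMesh":
        return LabeledSurfaceMesh(
            self.vertices.copy(),
            self.triangles.copy(),
            self.region_label.copy(),
            self.fiber.copy(),
            self.intensity.copy(),
            self.fibrotic.copy(),
        )


# ---------------------------------------------------------------------------
# surface generation
# ---------------------------------------------------------------------------

#: direction (polar, azimuth in degrees) and angular radius for labeled caps
_VEIN_CAPS = [(40.0, 45.0), (40.0, 135.0), (40.0, 225.0), (40.0, 315.0)]
_VEIN_RADIUS_DEG = 14.0
_MITRAL_RADIUS_DEG = 25.0
_APPENDAGE_DIR = (75.0, 0.0)
_APPENDAGE_RADIUS_DEG = 20.0

#: ellipsoid semi-axis ratios (x, y, z); z holds the mitral (bottom) pole
_AXIS_RATIOS = np.array([1.0, 0.85, 0.70])


def _cap_directions() -> list[tuple[np.ndarray, float]]:
    caps = []
    for pol, az in _VEIN_CAPS:
        caps.append((_unit_dir(pol, az), np.deg2rad(_VEIN_RADIUS_DEG), VEIN))
    caps.append((np.array([0.0, 0.0, -1.0]), np.deg2rad(_MITRAL_RADIUS_DEG), MITRAL))
    caps.append((_unit_dir(*_APPENDAGE_DIR), np.deg2rad(_APPENDAGE_RADIUS_DEG), APPENDAGE))
    return caps


def _unit_dir(polar_deg: float, azimuth_deg: float) -> np.ndarray:
    th, ph = np.deg2rad(polar_deg), np.deg2rad(azimuth_deg)
    return np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])


def _sph_harm_real(m: int, l: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real spherical harmonic; theta = azimuth, phi = polar angle."""
    y = sph_harm_y(l, abs(m), phi, theta)
    if m > 0:
        return np.sqrt(2.0) * y.real
    if m < 0:
        return np.sqrt(2.0) * y.imag
    return y.real


def generate_la_surface(
    d: PatientDescriptor, resolution: float = 2.0, seed: int = 0
) -> LabeledSurfaceMesh:
    """Build an ellipsoid-like closed LA surface matching ``d.edv``.

    ``resolution`` is the target mean edge length in mm; the closest icosphere
    subdivision level is used.  The enclosed volume is rescaled to ``d.edv``
    exactly (well within the 1 % contract), a band-limited spherical-harmonic
    perturbation gives patient-to-patient shape variability, and a smoothed
    vertex-noise field supplies the normalized LGE-like intensity.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    # ellipsoid radius scale from the requested volume
    r_mean = (
        d.edv * MM3_PER_ML / (4.0 / 3.0 * np.pi * np.prod(_AXIS_RATIOS))
    ) ** (1.0 / 3.0)
    # icosphere subdivision: edge ~ 1.05 * r / 2**k
    k = int(np.ceil(np.log2(max(1.0, 1.05 * r_mean / resolution))))
    if k < 3:
        raise ValueError(
            "resolution too coarse to place the five labeled regions; "
            "use a finer (smaller) target edge length"
        )
    k = min(k, 6)
    base = trimesh.creation.icosphere(subdivisions=k, radius=1.0)
    verts = np.asarray(base.vertices).copy()
    tris = np.asarray(base.faces).copy()

    # band-limited radial perturbation (degrees 2..4)
    rng = np.random.default_rng(seed)
    x, y, z = verts.T
    phi_pol = np.arccos(np.clip(z, -1, 1))
    theta_az = np.arctan2(y, x)
    pert = np.zeros(len(verts))
    for l in range(2, 5):
        for m in range(-l, l + 1):
            pert += rng.normal(0.0, 1.0 / l**2) * _sph_harm_real(
                m, l, theta_az, phi_pol
            )
    pert *= 0.05 / max(1e-12, np.abs(pert).max())

    radii = r_mean * (1.0 + pert)
    verts = verts * radii[:, None] * _AXIS_RATIOS[None, :]

    # exact volume match
    mesh0 = trimesh.Trimesh(verts, tris, process=False)
    scale = (d.edv * MM3_PER_ML / abs(mesh0.volume)) ** (1.0 / 3.0)
    verts = verts * scale

    out = LabeledSurfaceMesh(
        vertices=verts,
        triangles=tris,
        region_label=np.full(len(tris), BODY, dtype=np.int64),
        fiber=np.zeros((len(tris), 3)),
        intensity=np.zeros(len(tris)),
    )

    # region labels from angular caps on the unit sphere parameterization
    cen = out.centroids()
    cen_dir = cen / _AXIS_RATIOS[None, :]
    cen_dir = cen_dir / np.linalg.norm(cen_dir, axis=1, keepdims=True)
    for dir_, rad, code in _cap_directions():
        ang = np.arccos(np.clip(cen_dir @ dir_, -1, 1))
        sel = ang < rad
        if code == APPENDAGE:
            sel &= out.region_label == BODY  # priority: mitral/veins first
        out.region_label[sel] = code
    for code in (VEIN, MITRAL, APPENDAGE, BODY):
        if not np.any(out.region_label == code):
            raise ValueError("resolution too coarse to place the five labeled regions")

    # circumferential fiber field: swirl about the mitral (z) axis
    normals = out.normals()
    axis = np.array([0.0, 0.0, 1.0])
    f = np.cross(np.broadcast_to(axis, normals.shape), normals)
    norms = np.linalg.norm(f, axis=1)
    degenerate = norms < 1e-8
    if np.any(degenerate):
        alt = np.array([1.0, 0.0, 0.0])
        proj = alt - normals[degenerate] * (normals[degenerate] @ alt)[:, None]
        f[degenerate] = proj
        norms[degenerate] = np.linalg.norm(f[degenerate], axis=1)
    out.fiber = f / norms[:, None]

    # smooth intensity field: iterated neighbor-averaged vertex noise
    adj = out.vertex_adjacency().astype(float)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    smooth_op = sparse.diags(1.0 / deg) @ adj
    field_v = rng.standard_normal(out.n_vertices)
    for _ in range(25):
        field_v = smooth_op @ field_v
    field_t = field_v[out.triangles].mean(axis=1)
    lo, hi = field_t.min(), field_t.max()
    out.intensity = (field_t - lo) / (hi - lo)
    return out


def generate_stimulus_region(mesh: LabeledSurfaceMesh, seed: int = 0) -> np.ndarray:
    """Contiguous patch of body vertices: the earliest-activation analogue.

    Returns sorted vertex indices; every incident triangle of each returned
    vertex is body-labeled, the patch is connected, non-empty, and covers at
    most 5 % of vertices.
    """
    if not np.any(mesh.region_label == BODY):
        raise ValueError("mesh has no body-labeled triangles")
    nv = mesh.n_vertices
    # vertices whose incident triangles are all body
    non_body = np.unique(mesh.triangles[mesh.region_label != BODY])
    body_only = np.ones(nv, dtype=bool)
    body_only[non_body] = False
    candidates = np.flatnonzero(body_only)
    rng = np.random.default_rng(seed)
    start = int(rng.choice(candidates))

    target = max(1, min(int(0.02 * nv), int(0.05 * nv)))
    adj = mesh.vertex_adjacency()
    patch = {start}
    frontier = [start]
    while frontier and len(patch) < target:
        nxt = []
        for v in frontier:
            for u in adj.indices[adj.indptr[v] : adj.indptr[v + 1]]:
                if body_only[u] and u not in patch:
                    patch.add(int(u))
                    nxt.append(int(u))
                    if len(patch) >= target:
                        break
            if len(patch) >= target:
                break
        frontier = nxt
    return np.array(sorted(patch), dtype=np.int64)
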