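import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from atriasim.cohort import (
    BODY,
    APPENDAGE,
    VEIN,
    LabeledSurfaceMesh,
    generate_cohort,
    generate_la_surface,
)
from atriasim.ep import IonicScaling, PacingProtocol, simulate_cell


@pytest.fixture(scope="session")
def pacing_50():
    return PacingProtocol(rate=1.0, n_beats=50, dt=0.025)


@pytest.fixture(scope="session")
def baseline_cell(pacing_50):
    """Baseline ionic run, 50 pre-pacing beats at 1 Hz."""
    return simulate_cell(IonicScaling.baseline(), pacing_50, record_dt=0.25)


@pytest.fixture(scope="session")
def ik1_cell(pacing_50):
    """I_K1 halved, same protocol."""
    return simulate_cell(IonicScaling.fibrotic(k1=True), pacing_50, record_dt=0.25)


@pytest.fixture(scope="session")
def ical_cell(pacing_50):
    """I_CaL halved, same protocol."""
    return simulate_cell(IonicScaling.fibrotic(cal=True), pacing_50, record_dt=0.25)


@pytest.fixture(scope="session")
def patient1():
    return generate_cohort(3, preset="paper")[0]


@pytest.fixture(scope="session")
def la_surface(patient1):
    """Fine surface (>= 10k eligible elements) for patient 1."""
    return generate_la_surface(patient1, resolution=1.5, seed=7)


@pytest.fixture(scope="session")
def coarse_surface(patient1):
    return generate_la_surface(patient1, resolution=3.0, seed=7)


def toy_mesh(n_eligible=10, n_vein=2, seed=0) -> LabeledSurfaceMesh:
    """Tiny synthetic mesh: triangle geometry is arbitrary, fields matter."""
    rng = np.random.default_rng(seed)
    nt = n_eligible + n_vein
    vertices = rng.normal(size=(nt + 2, 3))
    triangles = np.array([[i, i + 1, i + 2] for i in range(nt)])
    labels = np.array(
        [BODY] * (n_eligible // 2)
        + [APPENDAGE] * (n_eligible - n_eligible // 2)
        + [VEIN] * n_vein
    )
    fiber = np.tile([1.0, 0.0, 0.0], (nt, 1))
    intensity = rng.random(nt)
    return LabeledSurfaceMesh(vertices, triangles, labels, fiber, intensity)


def strip_mesh(nx=61, ny=13, dx=1.0):
    """Flat structured strip in the z=0 plane, fibers along +x, all body."""
    xs, ys = np.meshgrid(np.arange(nx) * dx, np.arange(ny) * dx, indexing="ij")
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(nx * ny)])
    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            v00 = i * ny + j
            v10 = (i + 1) * ny + j
            tris.append([v00, v10, v00 + 1])
            tris.append([v10, v10 + 1, v00 + 1])
    tris = np.array(tris)
    nt = len(tris)
    return LabeledSurfaceMesh(
        verts,
        tris,
        np.full(nt, BODY),
        np.tile([1.0, 0.0, 0.0], (nt, 1)),
        np.zeros(nt),
    )
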