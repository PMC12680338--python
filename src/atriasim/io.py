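"""Persistence: mesh export (ASCII PLY / legacy VTK), tables, configs.

Meshes are written with their per-triangle fields (normalized intensity,
region id, fibrotic flag) and the fiber vector field so they can be
inspected in ParaView or similar.  The cohort table uses the clinical
column names.  YAML round-trips the run configuration; every artifact
directory carries a ``provenance.json`` with the seed and a config hash.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import REGION_NAMES, LabeledSurfaceMesh, PatientDescriptor

COHORT_COLUMNS = {
    "id": "Patient",
    "edv": "LA end-diastolic volume (mL)",
    "burden_target": "LA fibrosis burden (%)",
    "total_activation_time": "Total LA activation time (ms)",
    "cv_l": "CV longitudinal direction (CV_L; m/s)",
    "cv_t": "CV transverse direction (CV_T; m/s)",
}


def cohort_to_csv(descriptors, path) -> None:
    rows = []
    for d in descriptors:
        rows.append(
            {
                COHORT_COLUMNS["id"]: d.id,
                COHORT_COLUMNS["edv"]: d.edv,
                COHORT_COLUMNS["burden_target"]: 100.0 * d.burden_target,
                COHORT_COLUMNS["total_activation_time"]: d.total_activation_time,
                COHORT_COLUMNS["cv_l"]: d.cv_l,
                COHORT_COLUMNS["cv_t"]: d.cv_t,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_mesh_ply(mesh: LabeledSurfaceMesh, path) -> None:
    """ASCII PLY with per-face intensity, region id, fibrotic flag, fiber."""
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {mesh.n_triangles}\n")
        fh.write("property list uchar int vertex_indices\n")
        fh.write("property float intensity\nproperty uchar region\n")
        fh.write("property uchar fibrotic\n")
        fh.write("property float fx\nproperty float fy\nproperty float fz\n")
        fh.write("end_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for i, tri in enumerate(mesh.triangles):
            f = mesh.fiber[i]
            fh.write(
                f"3 {tri[0]} {tri[1]} {tri[2]} {mesh.intensity[i]:.6f} "
                f"{int(mesh.region_label[i])} {int(mesh.fibrotic[i])} "
                f"{f[0]:.6f} {f[1]:.6f} {f[2]:.6f}\n"
            )


def write_mesh_vtk(
    mesh: LabeledSurfaceMesh, path, point_data: dict | None = None
) -> None:
    """Legacy ASCII VTK polydata with cell fields and optional point data."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\natriasim surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} float\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        nt = mesh.n_triangles
        fh.write(f"POLYGONS {nt} {4 * nt}\n")
        for tri in mesh.triangles:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
        fh.write(f"CELL_DATA {nt}\n")
        fh.write("SCALARS intensity float 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(f"{x:.6f}" for x in mesh.intensity) + "\n")
        fh.write("SCALARS region int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(x)) for x in mesh.region_label) + "\n")
        fh.write("SCALARS fibrotic int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(x)) for x in mesh.fibrotic) + "\n")
        fh.write("VECTORS fiber float\n")
        for f in mesh.fiber:
            fh.write(f"{f[0]:.6f} {f[1]:.6f} {f[2]:.6f}\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_vertices}\n")
            for name, values in point_data.items():
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                fh.write(
                    "\n".join(
                        f"{(-1.0 if not np.isfinite(x) else x):.6f}" for x in values
                    )
                    + "\n"
                )


def read_mesh_ply(path) -> LabeledSurfaceMesh:
    """Read back a mesh written by :func:`write_mesh_ply`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = lines.index("end_header")
    nv = int(next(l for l in lines if l.startswith("element vertex")).split()[-1])
    nt = int(next(l for l in lines if l.startswith("element face")).split()[-1])
    verts = np.array(
        [list(map(float, l.split())) for l in lines[i + 1 : i + 1 + nv]]
    )
    tris, inten, region, fibro, fiber = [], [], [], [], []
    for l in lines[i + 1 + nv : i + 1 + nv + nt]:
        parts = l.split()
        tris.append([int(parts[1]), int(parts[2]), int(parts[3])])
        inten.append(float(parts[4]))
        region.append(int(parts[5]))
        fibro.append(bool(int(parts[6])))
        fiber.append([float(parts[7]), float(parts[8]), float(parts[9])])
    return LabeledSurfaceMesh(
        verts,
        np.array(tris),
        np.array(region),
        np.array(fiber),
        np.array(inten),
        np.array(fibro),
    )


def burden_sidecar(mesh: LabeledSurfaceMesh, path) -> None:
    from .fibrosis import burden

    with open(path, "w") as fh:
        json.dump(
            {
                "burden": burden(mesh),
                "n_fibrotic": int(mesh.fibrotic.sum()),
                "n_elements": int(mesh.n_triangles),
            },
            fh,
            indent=2,
        )


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def params_from_yaml(path, cls):
    """Instantiate a parameter dataclass (MaterialParameters,
    ContractionParams, CirculationParams, PacingProtocol, ...) from a YAML
    mapping of field overrides."""
    return cls(**load_config(path))


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a YAML mapping")
    return cfg


def write_provenance(outdir: Path, config: dict, seed: int) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(
            {"config_hash": config_hash(config), "seed": seed, "config": config},
            fh,
            indent=2,
            default=str,
        )
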