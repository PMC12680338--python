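"""End-to-end orchestration: cohort -> fibrosis -> EP -> mechanics -> metrics.

The pipeline stitches the modules into the study's workflow for each
synthetic patient and fibrosis level:

1. generate the LA-like surface, assign (and optionally elevate) fibrosis;
2. calibrate cv_l against the patient's total activation time (eikonal);
3. pre-pace the 8 distinct ionic configurations once (cell cache) and run
   the 1D cable to get emergent CV corrections for the active scalings;
4. calibrate the virtual-stretch stiffness scalings;
5. calibrate the baseline chamber (tension gain, venous return);
6. execute OFAT and/or FFD run specs through the 0D surrogate and score
   each final-cycle PV loop with the five metrics.

Cell-level results are cached by ionic-scaling key: only 8 distinct ionic
configurations exist across all 84 run specs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import conduction, fibrosis
from .cohort import (
    APPENDAGE,
    BODY,
    LabeledSurfaceMesh,
    PatientDescriptor,
    generate_la_surface,
    generate_stimulus_region,
)
from .contraction import ContractionParams, simulate_tension
from .ep import IonicScaling, PacingProtocol, simulate_cell
from .ep.cable import tune_cable
from .hemodynamics import (
    EDV_OVER_VREF,
    BaselineCalibration,
    ChamberModel,
    CirculationParams,
    calibrate_baseline,
    run_cycles,
)
from .passive import MaterialParameters, calibrate_stiffness_scaling
from .pvmetrics import metrics_from_loop
from .sensitivity import FACTORS, RunSpec, apply_runspec, ffd_design, ofat_design
from .transient import Transient

IONIC_LEVELS = [
    ("B", "B", "B"), ("F", "B", "B"), ("B", "F", "B"), ("B", "B", "F"),
    ("F", "F", "B"), ("F", "B", "F"), ("B", "F", "F"), ("F", "F", "F"),
]


def ionic_scaling_for(levels: tuple) -> IonicScaling:
    k1, cal, na = levels
    return IonicScaling.fibrotic(k1 == "F", cal == "F", na == "F")


class CellCache:
    """Final-beat transients per ionic configuration (8 distinct)."""

    def __init__(self, protocol: PacingProtocol = PacingProtocol(), record_dt: float = 1.0):
        self.protocol = protocol
        self.record_dt = record_dt
        self._store: dict = {}

    def get(self, levels: tuple) -> dict:
        if levels not in self._store:
            self._store[levels] = simulate_cell(
                ionic_scaling_for(levels), self.protocol, record_dt=self.record_dt
            )
        return self._store[levels]

    def calcium(self, levels: tuple) -> Transient:
        return self.get(levels)["cai"]


def cable_cv_ratios(
    reference_cv: float = 0.6, levels: Sequence[tuple] = tuple(IONIC_LEVELS)
) -> dict:
    """Emergent CV ratio (vs baseline) for each ionic configuration.

    The monodomain CV response to membrane scalings is, to good
    approximation, independent of the propagation direction, so the same
    ratio corrects both cv_l and cv_t.
    """
    out = {}
    for lv in levels:
        if lv == ("B", "B", "B"):
            out[lv] = (1.0, 1.0)
            continue
        res = tune_cable(reference_cv, ionic_scaling_for(lv))
        r = res.cv_ratio_vs_baseline if res.propagated else 1.0
        out[lv] = (r, r)
    return out


def stiffness_pairs(material: MaterialParameters = MaterialParameters()) -> dict:
    """Calibrated (s_a, s_af) for ST_L, ST_T and their combination."""
    c_l = calibrate_stiffness_scaling(material, 2.0, 1.0)
    c_t = calibrate_stiffness_scaling(material, 1.0, 2.0)
    c_lt = calibrate_stiffness_scaling(material, 2.0, 2.0)
    return {
        "L": (c_l.s_a, c_l.s_af),
        "T": (c_t.s_a, c_t.s_af),
        "LT": (c_lt.s_a, c_lt.s_af),
    }


@dataclass
class PatientSetup:
    """Per-patient, per-burden simulation-ready artifacts."""

    descriptor: PatientDescriptor
    mesh: LabeledSurfaceMesh  # fibrosis assigned
    stimulus: np.ndarray
    cv_l: float  # calibrated baseline longitudinal CV (m/s)
    burden: float
    v_wall: float  # mL
    v_ref: float  # mL
    baseline: BaselineCalibration | None = None
    _delay_cache: dict = field(default_factory=dict, repr=False)


def build_patient(
    d: PatientDescriptor,
    resolution: float = 1.5,
    seed: int = 0,
    burden_factor: float = 1.0,
) -> PatientSetup:
    """Geometry, fibrosis map, stimulus and CV calibration for one patient."""
    mesh = generate_la_surface(d, resolution=resolution, seed=seed)
    mesh = fibrosis.assign_fibrosis(mesh, d.burden_target)
    if burden_factor > 1.0:
        mesh = fibrosis.elevate_burden(mesh, burden_factor)
    stim = generate_stimulus_region(mesh, seed=seed + 1)
    cal = conduction.calibrate_cv(mesh, stim, d.total_activation_time)
    v_wall = mesh.total_area_mm2() * d.wall_thickness / 1000.0
    return PatientSetup(
        descriptor=d,
        mesh=mesh,
        stimulus=stim,
        cv_l=cal.params.cv_l,
        burden=fibrosis.burden(mesh),
        v_wall=v_wall,
        v_ref=d.edv / EDV_OVER_VREF,
    )


def fibrotic_activation_delay(
    setup: PatientSetup, cv_scale_l: float, cv_scale_t: float
) -> float:
    """Mean arrival in fibrotic minus non-fibrotic elements (ms, >= 0)."""
    key = (round(cv_scale_l, 6), round(cv_scale_t, 6))
    if key in setup._delay_cache:
        return setup._delay_cache[key]
    params = conduction.ConductionParams(
        cv_l=setup.cv_l,
        cv_t=conduction.cv_transverse(setup.cv_l),
        fibrotic_scale_l=cv_scale_l,
        fibrotic_scale_t=cv_scale_t,
    )
    act = conduction.eikonal_activation(setup.mesh, params, setup.stimulus)
    tri_t = act[setup.mesh.triangles]
    elem_t = np.where(
        np.all(np.isfinite(tri_t), axis=1), tri_t.mean(axis=1), np.nan
    )
    eligible = (setup.mesh.region_label == BODY) | (
        setup.mesh.region_label == APPENDAGE
    )
    fib = setup.mesh.fibrotic & eligible & np.isfinite(elem_t)
    nor = (~setup.mesh.fibrotic) & eligible & np.isfinite(elem_t)
    if not fib.any() or not nor.any():
        delay = 0.0
    else:
        delay = float(max(0.0, elem_t[fib].mean() - elem_t[nor].mean()))
    setup._delay_cache[key] = delay
    return delay


@dataclass
class StudyContext:
    """Shared (patient-independent) calibration artifacts."""

    cells: CellCache
    cv_ratios: Mapping[tuple, tuple]
    stiffness: Mapping[str, tuple]
    material: MaterialParameters = field(default_factory=MaterialParameters)
    contraction: ContractionParams = field(default_factory=ContractionParams)
    circulation: CirculationParams = field(default_factory=CirculationParams)

    @classmethod
    def create(
        cls,
        protocol: PacingProtocol = PacingProtocol(),
        with_cable: bool = True,
        reference_cv: float = 0.6,
    ) -> "StudyContext":
        cells = CellCache(protocol)
        ratios = (
            cable_cv_ratios(reference_cv)
            if with_cable
            else {lv: (1.0, 1.0) for lv in IONIC_LEVELS}
        )
        return cls(cells=cells, cv_ratios=ratios, stiffness=stiffness_pairs())


def _chamber_for_run(
    setup: PatientSetup, ctx: StudyContext, spec: RunSpec, gain: float
) -> ChamberModel:
    bundle = apply_runspec(spec, ctx.stiffness, ctx.cv_ratios)
    ionic_key = tuple(spec[f] for f in ("I_K1", "I_CaL", "I_Na"))
    cai_fib = ctx.cells.calcium(ionic_key)
    cai_nor = ctx.cells.calcium(("B", "B", "B"))
    con_fib = replace(ctx.contraction, s_ta=bundle["s_ta"], s_mu=bundle["s_mu"])
    ta_fib = simulate_tension(cai_fib, con_fib)
    ta_nor = simulate_tension(cai_nor, ctx.contraction)
    delay = fibrotic_activation_delay(
        setup, bundle["cv_scale_l"], bundle["cv_scale_t"]
    )
    s_a, s_af = bundle["stiffness"]
    return ChamberModel(
        v_wall=setup.v_wall,
        v_ref=setup.v_ref,
        tension_normal=ta_nor,
        tension_fibrotic=ta_fib,
        fibrotic_fraction=setup.burden,
        activation_delay_fib=delay,
        passive_normal=ctx.material,
        passive_fibrotic=ctx.material.scaled(s_a, s_af),
        tension_gain=gain,
    )


def calibrate_patient_baseline(setup: PatientSetup, ctx: StudyContext) -> PatientSetup:
    """Attach the calibrated baseline chamber/circulation to the setup."""
    chamber = _chamber_for_run(setup, ctx, RunSpec.baseline(), gain=1.0)
    cal = calibrate_baseline(setup.descriptor.edv, chamber, ctx.circulation)
    setup.baseline = cal
    return setup


def run_design(
    setup: PatientSetup,
    ctx: StudyContext,
    specs: Sequence[RunSpec],
    loop_dir=None,
) -> pd.DataFrame:
    """Run the surrogate for each spec; one metric row per run.

    With ``loop_dir`` set, each final-cycle PV loop is written as a CSV
    (columns t_ms, volume_mL, pressure_mmHg).
    """
    if setup.baseline is None:
        raise ValueError(
            "patient baseline not calibrated; run calibrate_patient_baseline first"
        )
    gain = setup.baseline.chamber.tension_gain
    circ = setup.baseline.circ
    rows = []
    for spec in specs:
        chamber = _chamber_for_run(setup, ctx, spec, gain)
        res = run_cycles(chamber, circ)
        m = metrics_from_loop(res.pvloop)
        if loop_dir is not None:
            from pathlib import Path

            loop_dir = Path(loop_dir)
            loop_dir.mkdir(parents=True, exist_ok=True)
            pd.DataFrame(
                {
                    "t_ms": res.pvloop.time,
                    "volume_mL": res.pvloop.volume,
                    "pressure_mmHg": res.pvloop.pressure,
                }
            ).to_csv(
                loop_dir / f"{setup.descriptor.id}_{spec.label}.csv", index=False
            )
            if spec == RunSpec.baseline():
                pd.DataFrame(
                    res.convergence, columns=["rel_dP", "rel_dV"]
                ).rename_axis("cycle_pair").to_csv(
                    loop_dir / f"{setup.descriptor.id}_convergence.csv"
                )
        row = {
            "patient": setup.descriptor.id,
            "run": spec.label,
            "burden": setup.burden,
            **m.as_dict(),
            "convergence_p": float(res.convergence[-1, 0]),
            "convergence_v": float(res.convergence[-1, 1]),
        }
        rows.append(row)
    return pd.DataFrame(rows)


def full_study(
    descriptors: Sequence[PatientDescriptor],
    ctx: StudyContext | None = None,
    designs: Sequence[str] = ("ofat", "ffd"),
    burden_factors: Sequence[float] = (1.0, 1.5),
    resolution: float = 1.5,
    seed: int = 0,
    loop_dir=None,
) -> pd.DataFrame:
    """OFAT and/or FFD over a cohort at one or more fibrosis levels."""
    ctx = ctx or StudyContext.create()
    # a run spec can belong to both designs (e.g. the FFD column whose only
    # fibrotic factor is I_Na is also an OFAT run); track membership so the
    # analysis groups on the full 32-run FFD, not an F-count heuristic
    membership: dict[str, set] = {}
    seen: list[RunSpec] = [RunSpec.baseline()]
    membership[RunSpec.baseline().label] = set()
    if "ofat" in designs:
        for s in ofat_design():
            if s not in seen:
                seen.append(s)
            membership.setdefault(s.label, set()).add("ofat")
    if "ffd" in designs:
        for s in ffd_design():
            if s not in seen:
                seen.append(s)
            membership.setdefault(s.label, set()).add("ffd")

    frames = []
    for i, d in enumerate(descriptors):
        for bf in burden_factors:
            setup = build_patient(
                d, resolution=resolution, seed=seed + 101 * i, burden_factor=bf
            )
            setup = calibrate_patient_baseline(setup, ctx)
            sub = None if loop_dir is None else f"{loop_dir}/x{bf:g}"
            df = run_design(setup, ctx, seen, loop_dir=sub)
            df.insert(2, "burden_factor", bf)
            df["in_ofat"] = df["run"].map(lambda l: "ofat" in membership[l])
            df["in_ffd"] = df["run"].map(lambda l: "ffd" in membership[l])
            frames.append(df)
    return pd.concat(frames, ignore_index=True)
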