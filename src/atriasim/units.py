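"""Unit conventions and conversions.

Internal units follow the clinical tables: lengths in mm, volumes in mL
(1 mL = 1000 mm^3), times in ms, conduction velocities in m/s, pressures in
mmHg on the circulation side and kPa on the tissue side, energies in mJ.
"""

KPA_PER_MMHG = 0.1333224
MMHG_PER_KPA = 1.0 / KPA_PER_MMHG

#: 1 mmHg * mL expressed in mJ (= 0.1333 mJ); kPa * mL is exactly 1 mJ.
MJ_PER_MMHG_ML = KPA_PER_MMHG

MM3_PER_ML = 1000.0


def mmhg_to_kpa(p: float) -> float:
    return p * KPA_PER_MMHG


def kpa_to_mmhg(p: float) -> float:
    return p * MMHG_PER_KPA


def mmhg_ml_to_mj(work: float) -> float:
    """Convert PV work from mmHg*mL to millijoule."""
    return work * MJ_PER_MMHG_ML


def cv_mps_to_mm_per_ms(cv: float) -> float:
    """m/s and mm/ms are numerically identical; kept for intent."""
    return cv
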