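"""Designed experiments over the nine fibrosis-associated factors.

Factors (order fixed): CV_L, CV_T, I_K1, I_CaL, I_Na, mu, T_a, ST_L, ST_T.
Each takes level B (baseline) or F (fibrotic).  The one-factor-at-a-time
(OFAT) design is the baseline plus nine single-F runs; the two-level
2^(9-5) fractional factorial design (FFD) is stored as literal data (32
columns) exactly as used in the study, with combination 32 fully fibrotic.

Analysis.  Metrics are normalized per patient by that patient's baseline
before pooling.  The FFD main effect of a factor on a metric is
``mean(F group) / mean(B group) - 1`` with a two-sample t-test and an
Anderson-Darling normality flag per group.  The pairwise interaction
coefficient is the arcsine of the normalized 2D cross-product of the
group-mean vectors ([FiBj, FiFj] x [BiBj, BiFj]): positive values indicate
synergy, negative mitigation, zero parallel interaction-plot lines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

FACTORS = ["CV_L", "CV_T", "I_K1", "I_CaL", "I_Na", "mu", "T_a", "ST_L", "ST_T"]

#: literal 2^(9-5) design, rows in FACTORS order, columns = combinations 1..32
_FFD_ROWS = {
    "CV_L": "BFBFBFBFBFBFBFBFBFBFBFBFBFBFBFBF",
    "CV_T": "BBFFBBFFBBFFBBFFBBFFBBFFBBFFBBFF",
    "I_K1": "BBBBFFFFBBBBFFFFBBBBFFFFBBBBFFFF",
    "I_CaL": "BBBBBBBBFFFFFFFFBBBBBBBBFFFFFFFF",
    "I_Na": "BBBBBBBBBBBBBBBBFFFFFFFFFFFFFFFF",
    "mu": "FFBBBBFFBBFFFFBBBBFFFFBBFFBBBBFF",
    "T_a": "FBFBBFBFBFBFFBFBBFBFFBFBFBFBBFBF",
    "ST_L": "FBBFFBBFBFFBBFFBBFFBBFFBFBBFFBBF",
    "ST_T": "FBBFBFFBFBBFBFFBBFFBFBBFBFFBFBBF",
}
_FFD_CHECKSUM = 144  # total number of F entries (16 per factor)


@dataclass(frozen=True)
class RunSpec:
    """Assignment of each of the nine factors to level B or F."""

    levels: tuple

    def __post_init__(self):
        if len(self.levels) != len(FACTORS):
            raise ValueError("a run spec assigns exactly nine factors")
        if any(l not in ("B", "F") for l in self.levels):
            raise ValueError("levels must be 'B' or 'F'")

    @classmethod
    def baseline(cls) -> "RunSpec":
        return cls(tuple("B") * len(FACTORS))

    @classmethod
    def from_mapping(cls, m: Mapping[str, str]) -> "RunSpec":
        return cls(tuple(m.get(f, "B") for f in FACTORS))

    def __getitem__(self, factor: str) -> str:
        return self.levels[FACTORS.index(factor)]

    def is_fibrotic(self, factor: str) -> bool:
        return self[factor] == "F"

    @property
    def label(self) -> str:
        return "".join(self.levels)

    def as_dict(self) -> dict:
        return dict(zip(FACTORS, self.levels))


def ofat_design() -> list[RunSpec]:
    """Baseline plus nine runs with exactly one factor at the fibrotic level."""
    runs = [RunSpec.baseline()]
    for i in range(len(FACTORS)):
        lv = ["B"] * len(FACTORS)
        lv[i] = "F"
        runs.append(RunSpec(tuple(lv)))
    return runs


def ffd_design() -> list[RunSpec]:
    """The 32 stored fractional-factorial combinations (verbatim)."""
    n_f = sum(row.count("F") for row in _FFD_ROWS.values())
    if n_f != _FFD_CHECKSUM or list(_FFD_ROWS) != FACTORS:
        raise RuntimeError("internal FFD table corrupted")
    runs = []
    for c in range(32):
        runs.append(RunSpec(tuple(_FFD_ROWS[f][c] for f in FACTORS)))
    return runs


# ---------------------------------------------------------------------------
# factor -> parameter bundle
# ---------------------------------------------------------------------------

#: fibrotic scaling factors applied within fibrotic regions
FIBROTIC_SCALES = {
    "CV_L": 0.657,
    "CV_T": 0.520,  # 1:1/8 conductivity anisotropy
    "I_K1": 0.5,
    "I_CaL": 0.5,
    "I_Na": 0.6,
    "mu": 0.5,
    "T_a": 0.5,
}


def apply_runspec(
    spec: RunSpec,
    stiffness_pairs: Mapping[str, tuple] | None = None,
    cv_ionic_ratios: Mapping[tuple, tuple] | None = None,
) -> dict:
    """Concrete fibrotic-region parameter bundle for one run.

    Returns a dict with ``ionic`` (conductance multipliers), ``s_mu`` /
    ``s_ta`` (contraction), ``cv_scale_l`` / ``cv_scale_t`` (conduction,
    including the emergent cable CV correction for the active ionic
    scalings) and ``stiffness`` = (s_a, s_af).

    ``stiffness_pairs`` maps "L" / "T" / "LT" to calibrated (s_a, s_af)
    pairs from the virtual stretch experiments; ``cv_ionic_ratios`` maps an
    (I_K1, I_CaL, I_Na) level triple to (ratio_l, ratio_t) CV corrections
    from the 1D cable.  Both calibration artifacts are required whenever the
    run needs them.
    """
    ionic = (
        0.5 if spec.is_fibrotic("I_K1") else 1.0,
        0.5 if spec.is_fibrotic("I_CaL") else 1.0,
        0.6 if spec.is_fibrotic("I_Na") else 1.0,
    )
    cv_l = FIBROTIC_SCALES["CV_L"] if spec.is_fibrotic("CV_L") else 1.0
    cv_t = FIBROTIC_SCALES["CV_T"] if spec.is_fibrotic("CV_T") else 1.0
    if ionic != (1.0, 1.0, 1.0):
        if cv_ionic_ratios is None:
            raise ValueError(
                "run requires cable CV ratios for ionic scalings; "
                "pass cv_ionic_ratios (missing calibration artifact)"
            )
        key = tuple(spec[f] for f in ("I_K1", "I_CaL", "I_Na"))
        r_l, r_t = cv_ionic_ratios[key]
        cv_l *= r_l
        cv_t *= r_t

    st_l, st_t = spec.is_fibrotic("ST_L"), spec.is_fibrotic("ST_T")
    if st_l or st_t:
        if stiffness_pairs is None:
            raise ValueError(
                "run requires calibrated stiffness scalings; "
                "pass stiffness_pairs (missing calibration artifact)"
            )
        key = "LT" if (st_l and st_t) else ("L" if st_l else "T")
        stiffness = tuple(stiffness_pairs[key])
    else:
        stiffness = (1.0, 1.0)

    return {
        "ionic": ionic,
        "s_mu": FIBROTIC_SCALES["mu"] if spec.is_fibrotic("mu") else 1.0,
        "s_ta": FIBROTIC_SCALES["T_a"] if spec.is_fibrotic("T_a") else 1.0,
        "cv_scale_l": cv_l,
        "cv_scale_t": cv_t,
        "stiffness": stiffness,
    }


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def normalize_by_baseline(results: pd.DataFrame, metrics: Sequence[str]) -> pd.DataFrame:
    """Divide each patient's metric values by that patient's baseline run.

    ``results`` needs columns ``patient``, ``run`` (RunSpec labels; the
    all-B label marks the baseline) plus the metric columns.
    """
    base_label = RunSpec.baseline().label
    out = results.copy()
    for patient, grp in results.groupby("patient"):
        base = grp[grp["run"] == base_label]
        if len(base) != 1:
            raise ValueError(f"patient {patient} needs exactly one baseline run")
        for m in metrics:
            out.loc[grp.index, m] = grp[m] / float(base[m].iloc[0])
    return out


def main_effects(
    normalized: pd.DataFrame, metrics: Sequence[str], designs: Sequence[RunSpec] | None = None
) -> pd.DataFrame:
    """FFD main effects: relative effect, t-test and normality per group.

    ``normalized`` holds baseline-normalized metrics with a ``run`` label
    column; baseline rows (all-B) are excluded from the grouping.  Returns a
    tidy frame with one row per factor x metric.
    """
    base_label = RunSpec.baseline().label
    df = normalized[normalized["run"] != base_label]
    if len(df) == 0:
        raise ValueError("no design runs to analyze")
    rows = []
    for i, factor in enumerate(FACTORS):
        is_f = df["run"].str[i] == "F"
        for m in metrics:
            grp_f = df.loc[is_f, m].to_numpy(dtype=float)
            grp_b = df.loc[~is_f, m].to_numpy(dtype=float)
            if len(grp_f) == 0 or len(grp_b) == 0:
                raise ValueError(f"empty level group for factor {factor}")
            mean_f, mean_b = grp_f.mean(), grp_b.mean()
            effect = mean_f / mean_b - 1.0
            if np.ptp(grp_f) == 0 and np.ptp(grp_b) == 0 and mean_f == mean_b:
                t_stat, p_val = 0.0, 1.0
            else:
                t_stat, p_val = stats.ttest_ind(grp_f, grp_b, equal_var=True)
            normal = True
            for grp in (grp_f, grp_b):
                if len(grp) >= 5 and np.ptp(grp) > 0:
                    # Anderson-Darling at the 5 % level
                    ad = stats.anderson(grp, dist="norm", method="interpolate")
                    normal &= bool(ad.pvalue > 0.05)
            rows.append(
                {
                    "factor": factor,
                    "metric": m,
                    "effect": effect,
                    "mean_F": mean_f,
                    "mean_B": mean_b,
                    "t": float(t_stat),
                    "p": float(p_val),
                    "n_F": len(grp_f),
                    "n_B": len(grp_b),
                    "groups_normal": normal,
                }
            )
    return pd.DataFrame(rows)


def interaction_coefficient(
    m_fb: float,
    m_ff: float,
    m_bb: float,
    m_bf: float,
    convention: str = "group-mean-vectors",
) -> float:
    """Arcsine cross-product interaction of four group means (radians).

    The group means are (F_i B_j, F_i F_j, B_i B_j, B_i F_j); a zero-norm
    vector yields NaN (undefined, flagged).  The default convention takes
    the 2D cross product of the group-mean vectors [FB, FF] x [BB, BF]
    (the literal published form); ``"line-directions"`` instead crosses the
    interaction-plot line directions [1, FF - FB] x [1, BF - BB].  The
    numerator FB*BF - FF*BB (respectively its line-direction analogue) is
    invariant under swapping the two factors, so the sign -- synergistic
    (positive) vs mitigating (negative) -- is swap-symmetric; the
    normalization is only approximately so, and the matrix builder
    evaluates each unordered pair once.
    """
    if convention == "group-mean-vectors":
        v1 = np.array([m_fb, m_ff])
        v2 = np.array([m_bb, m_bf])
    elif convention == "line-directions":
        v1 = np.array([1.0, m_ff - m_fb])
        v2 = np.array([1.0, m_bf - m_bb])
    else:
        raise ValueError(f"unknown convention {convention!r}")
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return float("nan")
    cross = v1[0] * v2[1] - v1[1] * v2[0]
    return float(np.arcsin(np.clip(cross / (n1 * n2), -1.0, 1.0)))


def interaction_coefficients(
    normalized: pd.DataFrame, metrics: Sequence[str]
) -> dict[str, pd.DataFrame]:
    """Pairwise interaction matrices (radians), one per metric.

    Entries are symmetric with NaN diagonal; positive = synergistic,
    negative = mitigating.
    """
    base_label = RunSpec.baseline().label
    df = normalized[normalized["run"] != base_label]
    k = len(FACTORS)
    out = {}
    for m in metrics:
        mat = np.full((k, k), np.nan)
        for i in range(k):
            for j in range(i + 1, k):
                li = df["run"].str[i]
                lj = df["run"].str[j]

                def gmean(a, b):
                    sel = (li == a) & (lj == b)
                    if not sel.any():
                        return float("nan")
                    return float(df.loc[sel, m].mean())

                val = interaction_coefficient(
                    gmean("F", "B"), gmean("F", "F"), gmean("B", "B"), gmean("B", "F")
                )
                mat[i, j] = mat[j, i] = val
        out[m] = pd.DataFrame(mat, index=FACTORS, columns=FACTORS)
    return out
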