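import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atriasim import sensitivity as sens
from atriasim.sensitivity import (
    FACTORS,
    RunSpec,
    apply_runspec,
    ffd_design,
    interaction_coefficient,
    interaction_coefficients,
    main_effects,
    normalize_by_baseline,
    ofat_design,
)

STIFFNESS = {"L": (0.963, 2.293), "T": (2.157, 0.675), "LT": (2.009, 2.000)}
CV_RATIOS = {
    lv: (1.0, 1.0)
    for lv in [
        ("B", "B", "B"), ("F", "B", "B"), ("B", "F", "B"), ("B", "B", "F"),
        ("F", "F", "B"), ("F", "B", "F"), ("B", "F", "F"), ("F", "F", "F"),
    ]
}


class TestDesigns:
    def test_ofat_structure(self):
        runs = ofat_design()
        assert len(runs) == 10
        assert runs[0] == RunSpec.baseline()
        f_positions = []
        for r in runs[1:]:
            fs = [i for i, l in enumerate(r.levels) if l == "F"]
            assert len(fs) == 1
            f_positions.append(fs[0])
        assert sorted(f_positions) == list(range(9))

    def test_ffd_has_32_balanced_combinations(self):
        runs = ffd_design()
        assert len(runs) == 32
        for f in FACTORS:
            assert sum(r.is_fibrotic(f) for r in runs) == 16

    def test_ffd_combination_32_fully_fibrotic(self):
        assert ffd_design()[31].levels == tuple("F" * 9)

    def test_ffd_pairwise_balance(self):
        """Every (level_i, level_j) cell of every factor pair holds 8 runs."""
        runs = ffd_design()
        for i in range(9):
            for j in range(i + 1, 9):
                cells = {}
                for r in runs:
                    cells.setdefault((r.levels[i], r.levels[j]), 0)
                    cells[(r.levels[i], r.levels[j])] += 1
                assert set(cells.values()) == {8}

    def test_corrupted_table_detected(self, monkeypatch):
        monkeypatch.setitem(sens._FFD_ROWS, "mu", "B" * 32)
        with pytest.raises(RuntimeError, match="corrupted"):
            ffd_design()

    def test_runspec_validation(self):
        with pytest.raises(ValueError):
            RunSpec(("B",) * 8)
        with pytest.raises(ValueError):
            RunSpec(("X",) * 9)


class TestApplyRunspec:
    def test_all_baseline_is_identity(self):
        b = apply_runspec(RunSpec.baseline(), STIFFNESS, CV_RATIOS)
        assert b["ionic"] == (1.0, 1.0, 1.0)
        assert b["s_mu"] == b["s_ta"] == 1.0
        assert b["cv_scale_l"] == b["cv_scale_t"] == 1.0
        assert b["stiffness"] == (1.0, 1.0)

    def test_single_longitudinal_stiffening(self):
        spec = RunSpec.from_mapping({"ST_L": "F"})
        b = apply_runspec(spec, STIFFNESS, CV_RATIOS)
        assert b["stiffness"] == (0.963, 2.293)

    def test_combined_stiffening_is_not_the_product(self):
        spec = RunSpec.from_mapping({"ST_L": "F", "ST_T": "F"})
        b = apply_runspec(spec, STIFFNESS, CV_RATIOS)
        assert b["stiffness"] == (2.009, 2.000)
        product = (0.963 * 2.157, 2.293 * 0.675)
        assert b["stiffness"] != product

    def test_ionic_levels_scale_conductances_and_cv(self):
        ratios = dict(CV_RATIOS)
        ratios[("F", "B", "F")] = (0.85, 0.85)
        spec = RunSpec.from_mapping({"I_K1": "F", "I_Na": "F", "CV_L": "F"})
        b = apply_runspec(spec, STIFFNESS, ratios)
        assert b["ionic"] == (0.5, 1.0, 0.6)
        assert b["cv_scale_l"] == pytest.approx(0.657 * 0.85)
        assert b["cv_scale_t"] == pytest.approx(0.85)

    def test_missing_calibration_artifacts_rejected(self):
        with pytest.raises(ValueError, match="stiffness"):
            apply_runspec(RunSpec.from_mapping({"ST_T": "F"}), None, CV_RATIOS)
        with pytest.raises(ValueError, match="cable"):
            apply_runspec(RunSpec.from_mapping({"I_CaL": "F"}), STIFFNESS, None)


def _results_frame(metric_fn, designs=None, patients=("p1", "p2")):
    designs = designs or ([RunSpec.baseline()] + ffd_design())
    rows = []
    for p in patients:
        for spec in designs:
            rows.append({"patient": p, "run": spec.label, "m": metric_fn(p, spec)})
    return pd.DataFrame(rows)


class TestMainEffects:
    def test_normalization_leaves_baseline_at_one(self):
        df = _results_frame(lambda p, s: 3.0 if p == "p1" else 7.0)
        norm = normalize_by_baseline(df, ["m"])
        base = norm[norm["run"] == RunSpec.baseline().label]
        assert np.allclose(base["m"], 1.0)

    def test_identical_groups_give_zero_effect(self):
        df = _results_frame(lambda p, s: 5.0)
        norm = normalize_by_baseline(df, ["m"])
        eff = main_effects(norm, ["m"])
        assert np.allclose(eff["effect"], 0.0)
        assert np.allclose(eff["t"], 0.0)

    def test_hand_built_t_statistic(self):
        """4-vs-4 groups checked against the closed-form pooled t."""
        a = np.array([1.1, 0.9, 1.2, 1.0])
        b = np.array([0.7, 0.8, 0.6, 0.9])
        # CV_L (first factor) splits a vs b; all other factors see both runs
        df = pd.DataFrame(
            {
                "patient": ["p"] * 9,
                "run": [RunSpec.baseline().label]
                + ["F" + "BF" * 4] * 4
                + ["B" + "FB" * 4] * 4,
                "m": [1.0, *a, *b],
            }
        )
        eff = main_effects(df, ["m"])
        row = eff[eff.factor == "CV_L"].iloc[0]
        sp = math.sqrt(((a.var(ddof=1) + b.var(ddof=1)) / 2) * (2 / 4))
        t_expected = (a.mean() - b.mean()) / sp
        assert row["t"] == pytest.approx(t_expected, rel=1e-9)
        assert row["effect"] == pytest.approx(a.mean() / b.mean() - 1)

    def test_planted_effect_recovery(self):
        """A multiplicative +10 % fibrotic effect on one factor is recovered
        exactly by the FFD estimator (balanced design, separable metric)."""

        def metric(p, spec):
            val = 2.0 if p == "p1" else 3.0
            if spec.is_fibrotic("I_CaL"):
                val *= 1.10
            return val

        norm = normalize_by_baseline(_results_frame(metric), ["m"])
        eff = main_effects(norm, ["m"])
        row = eff[eff.factor == "I_CaL"].iloc[0]
        assert row["effect"] == pytest.approx(0.10, abs=1e-12)
        others = eff[eff.factor != "I_CaL"]
        assert np.allclose(others["effect"], 0.0, atol=1e-12)

    def test_additively_separable_effects_recovered_exactly(self):
        """With an additively separable response, pairwise level balance
        makes the group-mean difference recover each factor's increment
        exactly; the ratio estimator then equals increment / mean(B)."""
        deltas = {f: -0.05 * (i + 1) for i, f in enumerate(FACTORS)}

        def metric(p, spec):
            return 4.0 + sum(deltas[f] for f in FACTORS if spec.is_fibrotic(f))

        df = _results_frame(metric)
        eff = main_effects(df, ["m"])
        for f in FACTORS:
            row = eff[eff.factor == f].iloc[0]
            diff = row["mean_F"] - row["mean_B"]
            assert diff == pytest.approx(deltas[f], abs=1e-12)
            assert row["effect"] == pytest.approx(
                deltas[f] / row["mean_B"], rel=1e-12
            )

    def test_empty_frame_rejected(self):
        df = _results_frame(lambda p, s: 1.0, designs=[RunSpec.baseline()])
        with pytest.raises(ValueError):
            main_effects(df, ["m"])


class TestInteractions:
    def test_equal_means_give_zero(self):
        assert interaction_coefficient(2.5, 2.5, 2.5, 2.5) == 0.0

    def test_orthogonal_mean_vectors(self):
        assert interaction_coefficient(1.0, 0.0, 0.0, 1.0) == pytest.approx(
            math.pi / 2
        )

    def test_zero_norm_flagged(self):
        assert math.isnan(interaction_coefficient(0.0, 0.0, 1.0, 1.0))

    @given(
        fb=st.floats(0.1, 3.0),
        ff=st.floats(0.1, 3.0),
        bb=st.floats(0.1, 3.0),
        bf=st.floats(0.1, 3.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_swap_invariance_of_sign(self, fb, ff, bb, bf):
        """Swapping factors permutes the group means (FB,FF,BB,BF) ->
        (BF,FF,BB,FB).  The cross-product numerator FB*BF - FF*BB is
        exactly invariant, so the synergy/mitigation classification is
        swap-symmetric (the normalization is only approximately so)."""
        a = interaction_coefficient(fb, ff, bb, bf)
        b = interaction_coefficient(bf, ff, bb, fb)
        assert np.sign(a) == np.sign(b)
        num = fb * bf - ff * bb
        assert np.sign(a) == np.sign(num) or num == 0

    def test_line_direction_variant(self):
        # parallel interaction-plot lines -> zero, regardless of offset
        assert interaction_coefficient(
            1.0, 1.3, 0.7, 1.0, convention="line-directions"
        ) == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValueError):
            interaction_coefficient(1, 1, 1, 1, convention="nope")

    def test_matrix_symmetric_with_nan_diagonal(self):
        def metric(p, spec):
            val = 1.0
            if spec.is_fibrotic("I_CaL"):
                val *= 0.6
            if spec.is_fibrotic("I_K1"):
                val *= 1.2
            if spec.is_fibrotic("I_CaL") and spec.is_fibrotic("I_K1"):
                val *= 1.15  # planted interaction
            return val

        norm = normalize_by_baseline(_results_frame(metric), ["m"])
        mats = interaction_coefficients(norm, ["m"])
        mat = mats["m"].to_numpy()
        assert np.allclose(mat, mat.T, equal_nan=True)
        assert np.all(np.isnan(np.diag(mat)))
        i, j = FACTORS.index("I_CaL"), FACTORS.index("I_K1")
        assert mat[i, j] != 0.0
        assert abs(mat[i, j]) <= math.pi / 2
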