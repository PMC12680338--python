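import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atriasim.pvmetrics import (
    MetricSet,
    PVLandmarks,
    PVLoop,
    a_loop_area,
    a_loop_segment,
    landmarks,
    metric_set,
    metrics_from_loop,
    shoelace_area,
)
from atriasim.units import MJ_PER_MMHG_ML


def figure_eight_loop(n=2000):
    """Analytic two-lobe PV path: an A-lobe followed by a V-lobe.

    A-lobe (t < 500 ms): ellipse v = 95 - 5 sin(theta), p = 14 - 2 cos(theta)
    traversed once, starting and ending at (95 mL, 12 mmHg).  V-lobe
    (t >= 500 ms): ellipse v = 100 - 5 cos(phi), p = 12 - sin(phi), also
    through (95, 12).  By construction: lav_preA = 95, lav_min = 90,
    lav_max = 105, lap_preA = 12, lap_maxA = 16.
    """
    t = np.linspace(0.0, 1000.0, n, endpoint=False)
    theta = 2 * np.pi * t / 500.0
    v = np.where(t < 500.0, 95.0 - 5.0 * np.sin(theta), 100.0 - 5.0 * np.cos(theta))
    p = np.where(t < 500.0, 14.0 - 2.0 * np.cos(theta), 12.0 - np.sin(theta))
    return PVLoop(t, v, p, t_stim=0.0)


class TestShoelace:
    def test_unit_square(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]], dtype=float)
        assert shoelace_area(sq) == pytest.approx(1.0)

    def test_collinear_degenerate(self):
        line = np.array([[0, 0], [1, 1], [2, 2], [0, 0]], dtype=float)
        assert shoelace_area(line) == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            shoelace_area(np.array([[0.0, 0.0], [1.0, 1.0]]))

    @given(seed=st.integers(0, 100))
    @settings(max_examples=30, deadline=None)
    def test_matches_fan_triangulation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # star-shaped 12-gon around the origin (angles sorted -> simple)
        ang = np.sort(rng.uniform(0, 2 * np.pi, 12))
        rad = rng.uniform(0.5, 2.0, 12)
        poly = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
        # fan triangulation from the origin (signed wedge areas)
        fan = 0.0
        for i in range(12):
            b, c = poly[i], poly[(i + 1) % 12]
            fan += 0.5 * (b[0] * c[1] - b[1] * c[0])
        fan = abs(fan)
        assert shoelace_area(poly) == pytest.approx(fan, rel=1e-12)

    def test_invariant_to_direction_and_start(self):
        rng = np.random.default_rng(5)
        ang = np.sort(rng.uniform(0, 2 * np.pi, 10))
        poly = np.column_stack([np.cos(ang), np.sin(ang)])
        base = shoelace_area(poly)
        assert shoelace_area(poly[::-1]) == pytest.approx(base, rel=1e-12)
        assert shoelace_area(np.roll(poly, 4, axis=0)) == pytest.approx(
            base, rel=1e-12
        )


class TestLandmarks:
    def test_monotone_volume_minimum(self):
        t = np.linspace(0, 1000, 500)
        v = 100.0 - 30.0 * np.minimum(t, 400.0) / 400.0
        p = np.full_like(t, 10.0)
        lm = landmarks(PVLoop(t, v, p, t_stim=0.0))
        assert lm.lav_min == pytest.approx(70.0)
        assert lm.lav_preA == pytest.approx(100.0)

    def test_constant_pressure_trace(self):
        t = np.linspace(0, 1000, 500)
        v = 100.0 - 20.0 * np.sin(np.pi * t / 1000.0)
        p = np.full_like(t, 8.0)
        lm = landmarks(PVLoop(t, v, p, t_stim=0.0))
        assert lm.lap_maxA == lm.lap_preA == 8.0

    def test_figure_eight_hand_values(self):
        pv = figure_eight_loop()
        lm = landmarks(pv)
        assert lm.lav_preA == pytest.approx(95.0, abs=0.1)
        assert lm.lav_min == pytest.approx(90.0, abs=0.1)
        assert lm.lav_max == pytest.approx(105.0, abs=0.1)
        assert lm.lap_maxA == pytest.approx(16.0, abs=0.2)

    def test_stim_outside_cycle_rejected(self):
        pv = figure_eight_loop()
        pv.t_stim = 2000.0
        with pytest.raises(ValueError):
            landmarks(pv)

    def test_landmark_invariants_enforced(self):
        with pytest.raises(ValueError):
            PVLandmarks(50.0, 10.0, 60.0, 100.0, 12.0)


class TestALoop:
    def test_area_of_analytic_loop(self):
        """The A-lobe of the figure-eight is a closed 10 x 4 oval-ish path;
        its shoelace area matches a dense polygon evaluation."""
        pv = figure_eight_loop(4000)
        seg = a_loop_segment(pv)
        assert shoelace_area(seg) > 0
        area = a_loop_area(pv)
        assert area == pytest.approx(
            shoelace_area(seg) * MJ_PER_MMHG_ML, rel=1e-12
        )

    def test_stable_under_resampling(self):
        a1 = a_loop_area(figure_eight_loop(1500))
        a2 = a_loop_area(figure_eight_loop(6000))
        assert a1 == pytest.approx(a2, rel=0.05)


class TestMetricFormulas:
    def test_printed_formula_arithmetic(self):
        lm = PVLandmarks(100.0, 10.0, 70.0, 115.0, 14.0)
        m = metric_set(lm, a_area_mj=1.0)
        assert m.booster == pytest.approx(0.30)
        assert m.reservoir == pytest.approx(45.0 / 70.0)
        assert m.conduit == pytest.approx(15.0 / 115.0)
        assert m.upstroke == pytest.approx(0.40)
        assert m.laef_active == m.booster
        assert m.laef_passive == m.conduit
        assert m.laef_total == pytest.approx(45.0 / 115.0)

    def test_no_contraction_means_zero_booster(self):
        lm = PVLandmarks(70.0, 10.0, 70.0, 115.0, 14.0)
        assert metric_set(lm, 0.0).booster == 0.0

    @given(
        vmin=st.floats(20, 80),
        dpre=st.floats(0.1, 40),
        dmax=st.floats(0.1, 40),
        ppre=st.floats(2, 20),
        dpmax=st.floats(0, 20),
    )
    @settings(max_examples=60, deadline=None)
    def test_duplicate_implementation_oracle(self, vmin, dpre, dmax, ppre, dpmax):
        pre, vmax = vmin + dpre, vmin + dpre + dmax
        lm = PVLandmarks(pre, ppre, vmin, vmax, ppre + dpmax)
        m = metric_set(lm, 1.0)
        # independently coded evaluator
        assert m.booster == pytest.approx((pre - vmin) / pre)
        assert m.reservoir == pytest.approx((vmax - vmin) / vmin)
        assert m.conduit == pytest.approx((vmax - pre) / vmax)
        assert m.upstroke == pytest.approx(dpmax / ppre)
        assert 0 <= m.booster < 1
        assert 0 <= m.conduit < 1
        assert m.reservoir >= m.laef_total

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            metric_set(PVLandmarks(0.0, 10.0, 0.0, 10.0, 12.0), 1.0)
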