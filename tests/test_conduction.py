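import numpy as np
import pytest

from atriasim.conduction import (
    ConductionParams,
    calibrate_cv,
    cv_transverse,
    eikonal_activation,
    fibrotic_cv_t_scale,
    total_activation_time,
)
from atriasim.cohort import generate_stimulus_region
from atriasim.ep import IonicScaling
from atriasim.ep.cable import measure_cv, tune_cable

from conftest import strip_mesh


class TestCvArithmetic:
    @pytest.mark.parametrize(
        "cv_l,expected,decimals",
        [(1.5730, 0.7035, 4), (0.835, 0.373, 3)],
    )
    def test_clinical_cv_t_from_cv_l(self, cv_l, expected, decimals):
        assert round(cv_transverse(cv_l, 1.0 / 5.0), decimals) == expected

    def test_clinical_cv_t_patient1(self):
        # 1.1500/sqrt(5) = 0.51426; the table prints 0.5142
        assert cv_transverse(1.1500, 1.0 / 5.0) == pytest.approx(0.5142, abs=1e-4)

    def test_isotropic_ratio_is_identity(self):
        assert cv_transverse(0.7, 1.0) == 0.7

    def test_fibrotic_cv_t_factor(self):
        """0.657 * sqrt((1/8)/(1/5)) reproduces the printed 0.520."""
        assert fibrotic_cv_t_scale() == pytest.approx(0.520, rel=0.002)


class TestEikonal:
    def test_flat_strip_isotropic_closed_form(self):
        mesh = strip_mesh(nx=61, ny=13, dx=1.0)
        c = 0.8
        params = ConductionParams(cv_l=c, cv_t=c * (1 - 1e-12))
        src = 6 * 13 + 6  # an interior vertex
        act = eikonal_activation(mesh, params, np.array([src]))
        dist = np.linalg.norm(mesh.vertices - mesh.vertices[src], axis=1)
        sel = dist > 10.0  # far field, away from source singularity
        rel = np.abs(act[sel] - dist[sel] / c) / (dist[sel] / c)
        assert np.nanmax(rel) < 0.02

    def test_anisotropic_level_sets_are_ellipses(self):
        mesh = strip_mesh(nx=81, ny=81, dx=1.0)
        params = ConductionParams(cv_l=1.0, cv_t=0.5)
        src = 40 * 81 + 40  # center
        act = eikonal_activation(mesh, params, np.array([src]))
        xy = mesh.vertices[:, :2] - mesh.vertices[src, :2]
        on_x = (np.abs(xy[:, 1]) < 1e-9) & (np.abs(xy[:, 0]) > 20)
        on_y = (np.abs(xy[:, 0]) < 1e-9) & (np.abs(xy[:, 1]) > 20)
        # time to reach distance d: d/cv_l along fiber, d/cv_t across
        t_x = act[on_x] / np.abs(xy[on_x, 0])
        t_y = act[on_y] / np.abs(xy[on_y, 1])
        ratio = t_y.mean() / t_x.mean()
        assert ratio == pytest.approx(params.cv_l / params.cv_t, rel=0.03)

    def test_doubling_speeds_halves_arrival(self):
        mesh = strip_mesh()
        p1 = ConductionParams(cv_l=1.0, cv_t=0.5)
        p2 = ConductionParams(cv_l=2.0, cv_t=1.0)
        a1 = eikonal_activation(mesh, p1, np.array([0]))
        a2 = eikonal_activation(mesh, p2, np.array([0]))
        assert np.allclose(a2, 0.5 * a1, rtol=1e-12, equal_nan=True)

    def test_nonconductive_regions_unassigned(self, coarse_surface):
        stim = generate_stimulus_region(coarse_surface, seed=1)
        params = ConductionParams.from_cv_l(1.0)
        act = eikonal_activation(coarse_surface, params, stim)
        from atriasim.cohort import VEIN, MITRAL

        interior_nc = np.setdiff1d(
            np.unique(coarse_surface.triangles[coarse_surface.region_label == VEIN]),
            np.unique(
                coarse_surface.triangles[
                    (coarse_surface.region_label != VEIN)
                ]
            ),
        )
        if interior_nc.size:
            assert np.all(np.isnan(act[interior_nc]))
        assert np.all(act[stim] == 0.0)

    def test_empty_stimulus_rejected(self, coarse_surface):
        with pytest.raises(ValueError):
            eikonal_activation(
                coarse_surface, ConductionParams.from_cv_l(1.0), np.array([])
            )


class TestCalibrateCv:
    def test_self_recovery_of_planted_cv(self, coarse_surface):
        stim = generate_stimulus_region(coarse_surface, seed=1)
        planted = ConductionParams.from_cv_l(1.0)
        t_own = total_activation_time(
            eikonal_activation(coarse_surface, planted, stim)
        )
        cal = calibrate_cv(coarse_surface, stim, t_own)
        assert cal.params.cv_l == pytest.approx(1.0, rel=0.02)
        assert cal.residual_ms < 1.0

    def test_doubled_target_halves_cv(self, coarse_surface):
        stim = generate_stimulus_region(coarse_surface, seed=1)
        c1 = calibrate_cv(coarse_surface, stim, 60.0)
        c2 = calibrate_cv(coarse_surface, stim, 120.0)
        assert c2.params.cv_l == pytest.approx(0.5 * c1.params.cv_l, rel=0.02)

    def test_invalid_target_rejected(self, coarse_surface):
        with pytest.raises(ValueError):
            calibrate_cv(coarse_surface, np.array([0]), -5.0)


class TestCable:
    def test_cv_scales_with_sqrt_conductivity(self):
        cv1 = measure_cv(0.1)
        cv4 = measure_cv(0.4)
        assert cv4 / cv1 == pytest.approx(2.0, rel=0.02)

    def test_tuning_reaches_target_and_baseline_ratio_is_one(self):
        res = tune_cable(1.0)
        assert res.propagated
        assert res.cv == pytest.approx(1.0, rel=0.01)
        assert res.cv_ratio_vs_baseline == 1.0

    def test_reduced_sodium_slows_conduction(self):
        res = tune_cable(1.0, IonicScaling.fibrotic(na=True))
        assert res.propagated
        assert res.cv_ratio_vs_baseline < 1.0
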