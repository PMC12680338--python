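import numpy as np
import pytest

from atriasim.cohort import (
    BODY,
    MITRAL,
    VEIN,
    PatientDescriptor,
    generate_cohort,
    generate_la_surface,
    generate_stimulus_region,
)


class TestCohort:
    def test_paper_preset_carries_clinical_values(self):
        ds = generate_cohort(3, preset="paper")
        assert [d.edv for d in ds] == [110.0, 112.5, 60.0]
        assert [d.burden_target for d in ds] == [0.156, 0.239, 0.179]
        assert [d.total_activation_time for d in ds] == [82.0, 56.0, 116.8]
        assert [d.cv_l for d in ds] == [1.1500, 1.5730, 0.835]
        assert [d.cv_t for d in ds] == [0.5142, 0.7035, 0.373]
        assert all(d.pacing_rate == 1.0 and d.wall_thickness == 2.0 for d in ds)

    def test_paper_preset_has_only_three_patients(self):
        with pytest.raises(ValueError):
            generate_cohort(5, preset="paper")

    def test_random_preset_empty_and_deterministic(self):
        assert generate_cohort(0, seed=1, preset="random") == []
        a = generate_cohort(5, seed=42, preset="random")
        b = generate_cohort(5, seed=42, preset="random")
        assert a == b
        c = generate_cohort(5, seed=43, preset="random")
        assert a != c

    def test_random_preset_within_clinical_span(self):
        for d in generate_cohort(20, seed=3, preset="random"):
            assert 60.0 <= d.edv <= 112.5
            assert 0.156 <= d.burden_target <= 0.239
            assert 0.835 <= d.cv_l <= 1.5730
            assert d.cv_t < d.cv_l

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(edv=-1.0),
            dict(burden_target=1.0),
            dict(cv_t=2.0),
            dict(total_activation_time=0.0),
        ],
    )
    def test_descriptor_invariants(self, kwargs):
        base = dict(
            id="x", edv=100.0, burden_target=0.1,
            total_activation_time=80.0, cv_l=1.0, cv_t=0.45,
        )
        with pytest.raises(ValueError):
            PatientDescriptor(**{**base, **kwargs})


class TestSurface:
    def test_enclosed_volume_matches_edv(self, patient1, la_surface):
        # independent divergence-theorem oracle
        v = la_surface.vertices[la_surface.triangles]
        vol = abs(
            np.einsum("ij,ij->i", v[:, 0], np.cross(v[:, 1], v[:, 2])).sum() / 6.0
        ) / 1000.0
        assert abs(vol - patient1.edv) / patient1.edv < 0.01

    def test_watertight_every_edge_shared_twice(self, coarse_surface):
        t = coarse_surface.triangles
        edges = np.sort(
            np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]]), axis=1
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        assert np.all(counts == 2)
        # closed surface Euler characteristic
        nv = coarse_surface.n_vertices
        ne = len(np.unique(edges, axis=0))
        nf = coarse_surface.n_triangles
        assert nv - ne + nf == 2

    def test_fibers_unit_and_tangent(self, coarse_surface):
        norms = np.linalg.norm(coarse_surface.fiber, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)
        dots = np.einsum(
            "ij,ij->i", coarse_surface.fiber, coarse_surface.normals()
        )
        assert np.abs(dots).max() < 1e-6

    def test_intensity_normalized(self, coarse_surface):
        assert coarse_surface.intensity.min() >= 0.0
        assert coarse_surface.intensity.max() <= 1.0

    def test_all_regions_present(self, coarse_surface):
        assert set(np.unique(coarse_surface.region_label)) == {0, 1, 2, 3}

    def test_seeded_determinism(self, patient1):
        m1 = generate_la_surface(patient1, resolution=3.0, seed=11)
        m2 = generate_la_surface(patient1, resolution=3.0, seed=11)
        assert np.array_equal(m1.vertices, m2.vertices)
        assert np.array_equal(m1.intensity, m2.intensity)
        m3 = generate_la_surface(patient1, resolution=3.0, seed=12)
        assert not np.array_equal(m1.intensity, m3.intensity)

    def test_too_coarse_resolution_rejected(self, patient1):
        with pytest.raises(ValueError):
            generate_la_surface(patient1, resolution=40.0, seed=0)


class TestStimulusRegion:
    def test_patch_contract(self, coarse_surface):
        patch = generate_stimulus_region(coarse_surface, seed=3)
        assert 1 <= len(patch) <= 0.05 * coarse_surface.n_vertices
        # every incident triangle of a patch vertex is body-labeled
        for code in (VEIN, MITRAL):
            bad = np.unique(
                coarse_surface.triangles[coarse_surface.region_label == code]
            )
            assert not np.intersect1d(patch, bad).size

    def test_patch_connected(self, coarse_surface):
        import networkx as nx

        patch = generate_stimulus_region(coarse_surface, seed=3)
        adj = coarse_surface.vertex_adjacency().tocoo()
        g = nx.Graph(zip(adj.row.tolist(), adj.col.tolist()))
        sub = g.subgraph(patch.tolist())
        assert nx.is_connected(sub)
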