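"""Signed distances, ROI selection and deviation statistics."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st

import guidefit as gf


def _random_watertight_mesh(rng, n_points=27):
    """Random convex hull: watertight, outward-oriented, ~50 triangles."""
    pts = rng.normal(size=(n_points, 3))
    hull = trimesh.convex.convex_hull(pts)
    return hull


class TestSignedDistances:
    def test_query_on_vertex_is_zero(self, sphere4):
        v = sphere4.vertices.view(np.ndarray)[10]
        d = gf.signed_distances(v[None, :], sphere4)
        assert abs(d[0]) < 1e-9

    def test_sphere_analytic_distance(self, sphere4):
        d = gf.signed_distances(np.array([[2.0, 0.0, 0.0]]), sphere4)
        assert abs(d[0] - 1.0) < 0.01  # faceting tolerance

    def test_inside_is_negative(self, sphere4):
        d = gf.signed_distances(np.zeros((1, 3)), sphere4)
        assert d[0] < -0.9

    def test_matches_bruteforce_oracle(self, rng):
        # engine (KD-tree + pseudo-normal) vs exhaustive reference
        # (candidate projections + winding number): independent code paths
        for trial in range(5):
            mesh = _random_watertight_mesh(rng)
            pts = rng.normal(scale=1.5, size=(200, 3))
            fast = gf.signed_distances(pts, mesh)
            brute = gf.signed_distances_bruteforce(pts, mesh)
            assert np.abs(fast - brute).max() < 1e-12

    def test_winding_sign_agrees_with_pseudonormal(self, rng):
        mesh = _random_watertight_mesh(rng)
        pts = rng.normal(scale=1.5, size=(300, 3))
        a = gf.signed_distances(pts, mesh, method="pseudonormal")
        b = gf.signed_distances(pts, mesh, method="winding")
        assert np.allclose(a, b, atol=1e-12)

    def test_magnitude_invariant_under_joint_rigid_motion(self, sphere4, rng):
        from conftest import random_rigid

        pts = rng.normal(scale=2.0, size=(50, 3))
        d0 = gf.signed_distances(pts, sphere4)
        T = random_rigid(rng)
        moved = gf.apply_transform(sphere4, T)
        d1 = gf.signed_distances(T.apply(pts), moved)
        assert np.allclose(np.abs(d0), np.abs(d1), atol=1e-9)


class TestCompareSurfaces:
    def test_identical_meshes_zero(self, sphere4):
        fld = gf.compare_surfaces(sphere4, sphere4, sample_count=2000, seed=0)
        assert np.abs(fld.distances).max() < 1e-9

    def test_outward_offset_positive_mean(self, sphere4):
        offset = sphere4.copy()
        offset.vertices = offset.vertices + 0.1 * offset.vertex_normals
        fld = gf.compare_surfaces(offset, sphere4, sample_count=5000, seed=1)
        assert abs(gf.deviation_stats(fld).mean - 0.1) < 0.005

    def test_radial_shrink_negative_mean(self):
        gold = gf.make_sphere_mesh(8.0, 4)
        shrunk = gf.make_sphere_mesh(7.8, 4)
        fld = gf.compare_surfaces(shrunk, gold, sample_count=5000, seed=1)
        assert abs(gf.deviation_stats(fld).mean - (-0.2)) < 0.005

    def test_enlarging_increases_mean_monotonically(self, sphere4):
        means = []
        for off in (-0.05, 0.0, 0.05):
            test = sphere4.copy()
            test.vertices = test.vertices + off * test.vertex_normals
            fld = gf.compare_surfaces(test, sphere4, sample_count=3000, seed=2)
            means.append(gf.deviation_stats(fld).mean)
        assert means[0] < means[1] < means[2]

    def test_seeded_sampling_reproducible(self, sphere4):
        a = gf.compare_surfaces(sphere4, sphere4, sample_count=500, seed=7)
        b = gf.compare_surfaces(sphere4, sphere4, sample_count=500, seed=7)
        assert np.array_equal(a.sample_points, b.sample_points)


class TestRoi:
    def test_all_vertices_selects_whole_mesh(self, sphere4):
        roi = gf.RoiSpec(vertex_indices=np.arange(len(sphere4.vertices)))
        sub = gf.select_roi(sphere4, roi)
        assert len(sub.faces) == len(sphere4.faces)
        assert np.isclose(sub.area, sphere4.area)

    def test_geodesic_patch_is_strict_subset(self, small_arch):
        seed_pt = small_arch.vertices.view(np.ndarray)[0]
        roi = gf.RoiSpec(seed_points=seed_pt[None, :], radius=3.0)
        sub = gf.select_roi(small_arch, roi)
        assert 0 < sub.area < small_arch.area

    def test_disjoint_seeds_union_of_patches(self, sphere4):
        v = sphere4.vertices.view(np.ndarray)
        top = v[np.argmax(v[:, 2])]
        bottom = v[np.argmin(v[:, 2])]
        radius = 0.4  # patches well separated on the unit sphere
        sub_top = gf.select_roi(sphere4, gf.RoiSpec(seed_points=top[None], radius=radius))
        sub_bot = gf.select_roi(sphere4, gf.RoiSpec(seed_points=bottom[None], radius=radius))
        both = gf.select_roi(
            sphere4, gf.RoiSpec(seed_points=np.vstack([top, bottom]), radius=radius)
        )
        assert len(both.faces) == len(sub_top.faces) + len(sub_bot.faces)

    def test_empty_selection_rejected(self, sphere4):
        # radius smaller than any edge: no face fully inside
        roi = gf.RoiSpec(seed_points=np.array([[0.0, 0.0, 2.0]]), radius=1e-6)
        with pytest.raises(gf.GuidefitError, match="ROI"):
            gf.select_roi(sphere4, roi)

    def test_face_map_traceable(self, sphere4):
        cap = np.flatnonzero(sphere4.vertices.view(np.ndarray)[:, 2] > 0.5)
        roi = gf.RoiSpec(vertex_indices=cap)
        sub = gf.select_roi(sphere4, roi)
        fmap = sub.metadata["roi_face_map"]
        orig_tri = sphere4.triangles[fmap]
        assert np.allclose(np.sort(orig_tri.ravel()), np.sort(sub.triangles.ravel()))

    def test_roi_restricted_comparison(self, small_arch):
        seed_pt = small_arch.vertices.view(np.ndarray)[100]
        roi = gf.RoiSpec(seed_points=seed_pt[None, :], radius=4.0)
        fld = gf.compare_surfaces(small_arch, small_arch, roi=roi, sample_count=500, seed=0)
        assert np.abs(fld.distances).max() < 1e-9
        sub = gf.select_roi(small_arch, roi)
        d, _, _ = gf.SurfaceQuery(sub).closest(fld.sample_points)
        assert d.max() < 1e-9  # samples drawn from the ROI only


class TestStats:
    def test_all_zero(self):
        fld = gf.DeviationField(np.zeros((4, 3)), np.zeros(4))
        s = gf.deviation_stats(fld)
        assert s.mean == 0.0
        assert s.sd == 0.0
        assert s.n == 4

    def test_plus_minus_one_population_convention(self):
        fld = gf.DeviationField(np.zeros((2, 3)), np.array([-1.0, 1.0]))
        s = gf.deviation_stats(fld, bin_width=0.5)
        assert s.mean == 0.0
        assert s.sd == 1.0  # population (1/n), not sample (1/(n-1))

    def test_report_rendering(self):
        s = gf.DeviationStats(mean=-0.008, sd=0.200, n=10, bin_edges=np.array([0, 1]), counts=np.array([10]))
        assert gf.format_stats(s) == "mean value -0.008 mm, SD 0.200 mm"

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=200),
        st.floats(0.01, 1.0),
    )
    def test_histogram_conserves_counts_and_covers_range(self, values, bin_width):
        d = np.asarray(values)
        fld = gf.DeviationField(np.zeros((len(d), 3)), d)
        s = gf.deviation_stats(fld, bin_width=bin_width)
        assert s.counts.sum() == len(d)
        assert s.bin_edges[0] <= d.min()
        assert s.bin_edges[-1] >= d.max()
        # zero-anchored bins
        k = s.bin_edges[0] / bin_width
        assert abs(k - round(k)) < 1e-6

    def test_empty_field_rejected(self):
        fld = gf.DeviationField(np.zeros((0, 3)), np.zeros(0))
        with pytest.raises(gf.GuidefitError, match="empty"):
            gf.deviation_stats(fld)


class TestPlyExport:
    def test_quality_channel_round_trip(self, tmp_path, sphere4):
        fld = gf.compare_surfaces(sphere4, sphere4, sample_count=50, seed=0)
        path = tmp_path / "dev.ply"
        gf.write_deviation_ply(path, fld)
        text = path.read_text().splitlines()
        assert "property float quality" in text
        n = int(next(l for l in text if l.startswith("element vertex")).split()[-1])
        assert n == 50
        body = text[text.index("end_header") + 1 :]
        assert len(body) == 50
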