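"""Morphological sampling, centerline and implicit-solid construction."""

import numpy as np
import pytest

from aneuflow.geometry import (MAX_ARC_ANGLE, REGION_PARENT, REGION_SAC,
                               TABLE_RANGES, AneurysmParams,
                               InvalidParamsError, build_centerline,
                               build_geometry, sample_params)


class TestSampleParams:
    def test_type1_is_straight(self):
        assert sample_params("type1", 7).CP == 0.0

    @pytest.mark.parametrize("model_type", ["type1", "type2"])
    def test_many_draws_within_ranges_and_valid(self, model_type):
        rng = np.random.default_rng(42)
        for _ in range(10_000):
            p = sample_params(model_type, rng)
            for name in ("DA", "CC", "DP"):
                lo, hi = TABLE_RANGES[name]
                assert lo <= getattr(p, name) <= hi
            if model_type == "type2":
                assert TABLE_RANGES["CP"][0] <= p.CP <= TABLE_RANGES["CP"][1]
                assert TABLE_RANGES["LA"][0] <= p.LA <= TABLE_RANGES["LA"][1]
            assert p.CC < (p.DA + p.DP) / 2
            assert p.CC + p.DA / 2 > p.DP / 2
            p.validate()

    def test_seeded_determinism(self):
        assert sample_params("type2", 3) == sample_params("type2", 3)

    def test_impossible_ranges_raise(self):
        with pytest.raises(InvalidParamsError):
            sample_params("type1", 0, ranges={"CC": (30.0, 31.0), "DA": (8.0, 8.1),
                                              "DP": (8.0, 8.1)}, max_attempts=50)

    def test_degenerate_params_rejected_by_validate(self):
        p = AneurysmParams(model_type="type1", DA=8.0, CC=7.9, DP=8.0)
        # CC < (DA+DP)/2 = 8 holds, but force a range violation instead
        bad = AneurysmParams(model_type="type1", DA=15.0, CC=7.0, DP=10.0)
        with pytest.raises(InvalidParamsError):
            bad.validate()
        p.validate()

    def test_wrapping_arcs_rejected(self):
        p = AneurysmParams(model_type="type2", DA=10, CC=7, DP=12.0, CP=0.033, LA=0)
        assert 15 * p.DP * p.CP > MAX_ARC_ANGLE
        assert not p.is_geometrically_valid()


class TestCenterline:
    def test_straight_line(self, type1_params):
        cl = build_centerline(type1_params)
        assert cl.curvature == 0.0
        s = np.linspace(0, cl.length, 7)
        pts = cl.point(s)
        np.testing.assert_allclose(pts[:, 1:], 0.0, atol=1e-15)
        np.testing.assert_allclose(pts[:, 0], s)
        np.testing.assert_allclose(np.linalg.norm(cl.tangent(s), axis=1), 1.0)

    def test_osculating_radius(self):
        p = AneurysmParams(model_type="type2", DA=10, CC=7, DP=10, CP=0.02, LA=45)
        cl = build_centerline(p)
        assert cl.radius == pytest.approx(50e-3, rel=1e-12)  # 1/CP = 50 mm
        # finite-difference curvature at several arc lengths
        for s0 in np.linspace(0.01, cl.length - 0.01, 5):
            h = 1e-5
            p0, p1, p2 = cl.point(np.array([s0 - h, s0, s0 + h]))
            kappa = np.linalg.norm(p0 - 2 * p1 + p2) / h ** 2
            assert kappa == pytest.approx(cl.curvature, rel=1e-4)

    def test_chord_shorter_than_arc(self):
        p = AneurysmParams(model_type="type2", DA=10, CC=7, DP=10, CP=0.03, LA=90)
        cl = build_centerline(p)
        chord = np.linalg.norm(cl.point(cl.length) - cl.point(0.0))
        assert chord < cl.length

    def test_length_covers_developed_flow(self, type2_params):
        cl = build_centerline(type2_params)
        geom = build_geometry(type2_params)
        dp_m = type2_params.DP * 1e-3
        assert geom.s_sac >= 10 * dp_m - 1e-12
        assert cl.length - geom.s_sac >= 5 * dp_m - 1e-12

    def test_projection_roundtrip(self, type2_geometry):
        cl = type2_geometry.centerline
        rng = np.random.default_rng(3)
        s = rng.uniform(0, cl.length, 50)
        d = rng.uniform(0, 4e-3, 50)
        psi = rng.uniform(-np.pi, np.pi, 50)
        pts = cl.place(s, d, psi)
        s2, _, _, d2, psi2 = cl.project(pts)
        np.testing.assert_allclose(s2, s, atol=1e-9)
        np.testing.assert_allclose(d2, d, atol=1e-12)


class TestGeometry:
    def test_sphere_center_in_sac(self, type2_geometry):
        c = type2_geometry.sphere_center[None, :]
        assert type2_geometry.sdf(c)[0] < 0
        assert type2_geometry.region(c)[0] == REGION_SAC

    def test_upstream_point_in_parent(self, type2_geometry):
        p = type2_geometry.centerline.point(np.array([1e-3]))
        assert type2_geometry.sdf(p)[0] < 0
        assert type2_geometry.region(p)[0] == REGION_PARENT

    def test_neck_patch_nonempty_brute_force(self):
        """Surface points satisfying both primitive equations exist (DA=DP=10, CC=7)."""
        geom = build_geometry(AneurysmParams("type1", DA=10, CC=7, DP=10))
        # brute force: sample the sphere surface, look for points on the tube wall
        rng = np.random.default_rng(0)
        u = rng.normal(size=(200_000, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        p = geom.sphere_center + geom.sac_radius * u
        d_wall = np.abs(np.hypot(p[:, 1], p[:, 2]) - geom.tube_radius)
        near = d_wall < 1e-4
        assert near.sum() > 100  # a whole circle of intersection
        assert geom.neck_radius > 0 and geom.neck_area > 0
        # analytic neck circle lies on (or near) both surfaces
        ring = geom.neck_patch_points(64)
        assert np.abs(geom.sdf_sphere(ring)).max() < 0.15 * geom.sac_radius

    def test_detached_sphere_raises(self):
        with pytest.raises(InvalidParamsError):
            build_geometry(AneurysmParams("type1", DA=8.0, CC=15.0, DP=8.0))

    def test_region_partition_matches_brute_force(self, type2_geometry):
        """Labels agree with a polyline nearest-distance classification."""
        geom = type2_geometry
        rng = np.random.default_rng(1)
        pts = geom.sample_interior_points(0.02, rng)
        pts = pts[rng.choice(len(pts), min(1000, len(pts)), replace=False)]
        labels = geom.region(pts)
        # independent path: dense polyline distance instead of arc projection
        s_dense = np.linspace(0.0, geom.centerline.length, 20_000)
        cl_pts = geom.centerline.point(s_dense)
        d_axis = np.array([np.min(np.linalg.norm(cl_pts - q, axis=1)) for q in pts])
        in_sphere = np.linalg.norm(pts - geom.sphere_center, axis=1) < geom.sac_radius
        expected = np.where(in_sphere & (d_axis > geom.tube_radius),
                            REGION_SAC, REGION_PARENT)
        assert np.mean(labels == expected) > 0.999  # polyline discretization slack

    def test_reduces_to_type1_as_curvature_vanishes(self):
        base = dict(DA=10.0, CC=7.0, DP=10.0)
        straight = build_geometry(AneurysmParams("type1", **base))
        probe = np.random.default_rng(2).uniform(
            [-0.01, -0.02, -0.02], [0.16, 0.02, 0.02], size=(500, 3))
        sups = []
        for cp in (3e-3, 1e-3, 3e-4, 1e-4):
            curved = build_geometry(AneurysmParams("type2", CP=cp, LA=0.0, **base))
            sups.append(np.abs(curved.sdf(probe) - straight.sdf(probe)).max())
        assert all(a > b for a, b in zip(sups, sups[1:]))  # monotone convergence
        # sup difference is bounded by the arc's end deviation ~ kappa L^2 / 2
        kappa = 1e-4 * 1e3
        L = straight.centerline.length
        assert sups[-1] < 1.5 * kappa * L ** 2 / 2


class TestSamplers:
    def test_surface_points_on_boundary(self, type2_geometry, rng):
        pts = type2_geometry.sample_surface_points(0.05, rng)
        assert np.abs(type2_geometry.sdf(pts)).max() < 1e-9

    def test_surface_count_scales_with_density(self, type2_geometry):
        n1 = len(type2_geometry.sample_surface_points(0.05, np.random.default_rng(0)))
        n4 = len(type2_geometry.sample_surface_points(0.20, np.random.default_rng(0)))
        assert 0.8 * 4 <= n4 / n1 <= 1.2 * 4

    def test_surface_determinism(self, type2_geometry):
        a = type2_geometry.sample_surface_points(0.05, np.random.default_rng(9))
        b = type2_geometry.sample_surface_points(0.05, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_interior_strictly_inside(self, type2_geometry, rng):
        pts = type2_geometry.sample_interior_points(0.03, rng)
        assert np.all(type2_geometry.sdf(pts) < 0)

    def test_sac_exclusion_flag(self, type2_geometry, rng):
        pts = type2_geometry.sample_interior_points(0.03, rng, include_sac=False)
        assert np.all(type2_geometry.region(pts) == REGION_PARENT)

    def test_interior_determinism(self, type2_geometry):
        a = type2_geometry.sample_interior_points(0.03, np.random.default_rng(4))
        b = type2_geometry.sample_interior_points(0.03, np.random.default_rng(4))
        np.testing.assert_array_equal(a, b)

    def test_near_wall_refinement_doubles_shell_density(self, type1_geometry):
        geom = type1_geometry
        pts = geom.sample_interior_points(0.05, np.random.default_rng(5))
        _, _, _, d_perp, _ = geom.centerline.project(pts)
        tube = geom.region(pts) == REGION_PARENT
        delta = 0.1 * geom.params.DP * 1e-3
        rt = geom.tube_radius
        shell = tube & (d_perp > rt - delta) & (d_perp <= rt)
        core = tube & (d_perp <= rt - delta)
        v_shell = rt ** 2 - (rt - delta) ** 2
        v_core = (rt - delta) ** 2
        ratio = (shell.sum() / v_shell) / (core.sum() / v_core)
        assert 1.6 < ratio < 2.4  # doubled, within sampling noise

    def test_surface_export_roundtrip(self, type1_geometry, tmp_path):
        import trimesh

        out = tmp_path / "model.stl"
        type1_geometry.export_surface(str(out))
        mesh = trimesh.load_mesh(out)
        assert len(mesh.vertices) > 100
        assert np.abs(type1_geometry.sdf(mesh.vertices)).max() < 2e-4
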