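"""Steady-flow surrogate: closed-form profiles, sac vortex, pressure, noise."""

import numpy as np
import pytest

from aneuflow.flow import (BoundaryConditions, NoiseSpec, curved_profile,
                           effective_neck_inflow, generate_flow, mean_speed,
                           neck_inflow_speed, poiseuille_profile, read_flow_vtk,
                           section_mass_flux, skew_amplitude, write_flow_vtk)
from aneuflow.geometry import REGION_SAC, AneurysmParams, build_geometry
from aneuflow.porous import FluidProps, PorousLayerSpec, pressure_drop

BC = BoundaryConditions()
PROPS = FluidProps()
NO_NOISE = NoiseSpec(fraction=0.0)


class TestPoiseuille:
    R = 5e-3  # DP = 10 mm

    def test_no_slip_at_wall(self):
        assert poiseuille_profile(self.R, self.R) == 0.0

    def test_hand_values(self):
        """v_mean = mdot/(rho pi R^2) = 0.05305 m/s, centerline twice that."""
        assert mean_speed(self.R, BC, PROPS) == pytest.approx(0.05305, rel=1e-3)
        assert poiseuille_profile(0.0, self.R) == pytest.approx(0.1061, rel=1e-3)

    def test_quadrature_recovers_mass_flow(self):
        """Integral of rho*v over the disc reproduces the inlet boundary value."""
        x, w = np.polynomial.legendre.leggauss(64)
        r = 0.5 * self.R * (x + 1)
        wr = 0.5 * self.R * w
        v = poiseuille_profile(r, self.R)
        flux = 2 * np.pi * np.sum(PROPS.rho * v * r * wr)
        assert flux == pytest.approx(BC.inlet_mass_flow, rel=1e-3)

    def test_outside_lumen_rejected(self):
        with pytest.raises(ValueError):
            poiseuille_profile(1.01 * self.R, self.R)


class TestCurvedProfile:
    R = 5e-3

    def test_straight_limit_is_poiseuille(self):
        rho = np.linspace(0, 1, 30)
        psi = np.linspace(-np.pi, np.pi, 30)
        v_ax, v_r, v_psi = curved_profile(rho, psi, self.R, 0.0)
        np.testing.assert_allclose(v_ax, poiseuille_profile(rho * self.R, self.R),
                                   rtol=1e-12)
        assert np.all(v_r == 0) and np.all(v_psi == 0)

    def test_outer_half_carries_majority_flux(self):
        """At CP = 0.033 mm^-1 the outer half-section carries > 50 % of the flow."""
        cp = 0.033e3  # 1/m
        n = 400
        x, w = np.polynomial.legendre.leggauss(n)
        r = 0.5 * (x + 1)
        wr = 0.5 * w
        psi = (np.arange(n) + 0.5) * 2 * np.pi / n - np.pi
        RR, PP = np.meshgrid(r, psi, indexing="ij")
        v_ax, _, _ = curved_profile(RR.ravel(), PP.ravel(), self.R, cp)
        flux = (v_ax * RR.ravel()).reshape(n, n) * wr[:, None]
        outer = np.abs(PP) < np.pi / 2  # psi measured from the outer wall
        frac = flux[outer.reshape(n, n)].sum() / flux.sum()
        assert frac > 0.5

    def test_skew_increases_with_curvature(self):
        ks = [skew_amplitude(self.R, cp) for cp in (0.0, 5.0, 10.0, 20.0, 33.0)]
        assert ks[0] == 0.0
        assert all(a < b for a, b in zip(ks, ks[1:]))

    def test_mass_flux_conserved_across_sections(self, type2_geometry):
        inlet = section_mass_flux(type2_geometry, 0.0)
        for s_frac in (0.3, 0.6, 0.95):
            s = s_frac * type2_geometry.centerline.length
            flux = section_mass_flux(type2_geometry, s)
            assert flux == pytest.approx(inlet, rel=5e-3)


class TestSacField:
    def test_zero_inflow_zero_field(self, type2_geometry, rng):
        from aneuflow.flow import sac_field

        pts = type2_geometry.sample_interior_points(0.03, rng)
        pts = pts[type2_geometry.region(pts) == REGION_SAC]
        v = sac_field(type2_geometry, pts, 0.0)
        assert np.all(v == 0.0)

    def test_postop_attenuates_sac_speed(self, type2_geometry, rng):
        pts = type2_geometry.sample_interior_points(0.05, rng)
        sac = type2_geometry.region(pts) == REGION_SAC
        pre = generate_flow(type2_geometry, pts, noise=NO_NOISE, seed=1)
        post = generate_flow(type2_geometry, pts, operative_state="postop",
                             layer=PorousLayerSpec(), noise=NO_NOISE, seed=1)
        assert post.speed[sac].mean() < pre.speed[sac].mean()
        assert np.all(post.speed[sac] <= pre.speed[sac] + 1e-15)

    def test_missing_layer_rejected(self, type2_geometry, rng):
        pts = type2_geometry.sample_interior_points(0.02, rng)
        with pytest.raises(ValueError):
            generate_flow(type2_geometry, pts, operative_state="postop")

    def test_vortex_circulation_sign_consistent(self, type2_geometry):
        """Discrete line integrals around the vortex core share one sign."""
        from aneuflow.flow import _sac_frame, sac_field

        geom = type2_geometry
        n_hat, e_d, omega = _sac_frame(geom)
        v_neck = neck_inflow_speed(geom)
        circulations = []
        for frac in (0.3, 0.5, 0.7):
            radius = frac * geom.sac_radius
            t = np.linspace(0, 2 * np.pi, 200, endpoint=False)
            e1 = e_d
            e2 = np.cross(omega, e1)
            loop = (geom.sphere_center
                    + radius * (np.outer(np.cos(t), e1) + np.outer(np.sin(t), e2)))
            v = sac_field(geom, loop, v_neck)
            dl = np.roll(loop, -1, axis=0) - loop
            circulations.append(float(np.sum(v * dl)))
        signs = np.sign(circulations)
        assert np.all(signs == signs[0]) and signs[0] != 0


class TestPressure:
    def test_outlet_anchored_to_zero(self, type1_geometry):
        cl = type1_geometry.centerline
        pts = cl.place(np.full(8, cl.length * (1 - 1e-12)),
                       np.linspace(0, 0.8, 8) * type1_geometry.tube_radius,
                       np.linspace(-3, 3, 8))
        ff = generate_flow(type1_geometry, pts, noise=NoiseSpec(fraction=0.02), seed=0)
        assert np.abs(ff.pressure).max() < 1e-6

    def test_hagen_poiseuille_drop(self, type1_geometry):
        """End-to-end drop matches 8 mu v_mean L / R^2 (5.94 Pa for 0.1 m at DP=10)."""
        geom = type1_geometry
        vm = mean_speed(geom.tube_radius, BC, PROPS)
        # closed form for a 0.1 m straight tube with DP = 10 mm
        assert 8 * PROPS.mu * vm * 0.1 / geom.tube_radius ** 2 == pytest.approx(5.94, rel=1e-3)
        cl = geom.centerline
        ends = cl.place(np.array([0.0, cl.length]), np.zeros(2), np.zeros(2))
        ff = generate_flow(geom, ends, noise=NO_NOISE, seed=0)
        expected = 8 * PROPS.mu * vm * cl.length / geom.tube_radius ** 2
        assert ff.pressure[0] - ff.pressure[1] == pytest.approx(expected, rel=1e-3)

    def test_postop_sac_offset_equals_layer_drop(self, type2_geometry, rng):
        geom = type2_geometry
        layer = PorousLayerSpec()
        pts = geom.sample_interior_points(0.05, rng)
        sac = geom.region(pts) == REGION_SAC
        pre = generate_flow(geom, pts, noise=NO_NOISE, seed=1)
        post = generate_flow(geom, pts, operative_state="postop", layer=layer,
                             noise=NO_NOISE, seed=1)
        v_th = effective_neck_inflow(geom, neck_inflow_speed(geom), layer)
        expected = pressure_drop(v_th, PROPS, layer)
        np.testing.assert_allclose(pre.pressure[sac] - post.pressure[sac],
                                   expected, rtol=1e-9)


class TestGenerateFlow:
    def test_seeded_determinism(self, type2_geometry, rng):
        pts = type2_geometry.sample_interior_points(0.02, rng)
        a = generate_flow(type2_geometry, pts, seed=7)
        b = generate_flow(type2_geometry, pts, seed=7)
        np.testing.assert_array_equal(a.velocity, b.velocity)
        np.testing.assert_array_equal(a.pressure, b.pressure)

    def test_zero_noise_matches_analytic_composition(self, type2_geometry, rng):
        pts = type2_geometry.sample_interior_points(0.02, rng)
        a = generate_flow(type2_geometry, pts, noise=NO_NOISE, seed=1)
        b = generate_flow(type2_geometry, pts, noise=NO_NOISE, seed=99)
        np.testing.assert_array_equal(a.velocity, b.velocity)

    def test_noise_bounded_by_fraction_of_local_speed(self, type2_geometry, rng):
        pts = type2_geometry.sample_interior_points(0.03, rng)
        clean = generate_flow(type2_geometry, pts, noise=NO_NOISE, seed=1)
        noisy = generate_flow(type2_geometry, pts, noise=NoiseSpec(fraction=0.02), seed=1)
        dv = np.linalg.norm(noisy.velocity - clean.velocity, axis=1)
        # three components, each bounded by fraction*speed
        assert np.all(dv <= np.sqrt(3) * 0.02 * clean.speed + 1e-15)

    def test_wall_adjacent_points_nearly_stagnant(self, type2_geometry, rng):
        geom = type2_geometry
        pts = geom.sample_interior_points(0.08, rng)
        ff = generate_flow(geom, pts, seed=3)
        wall_dist = -geom.sdf(pts)
        # the inlet/outlet caps are flow boundaries, not no-slip walls
        s, _, _, _, _ = geom.centerline.project(pts)
        off_caps = (s > 0.01 * geom.centerline.length) \
            & (s < 0.99 * geom.centerline.length)
        near = (wall_dist < 0.02 * geom.tube_radius) & off_caps
        assert near.sum() > 20
        assert ff.speed[near].max() < 0.10 * ff.meta["v_mean"]

    def test_outside_points_rejected_with_indices(self, type1_geometry):
        pts = np.array([[0.01, 0.0, 0.0], [0.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="indices"):
            generate_flow(type1_geometry, pts)

    def test_curvature_limit_matches_type1(self):
        """A nearly straight type-2 field converges to the type-1 field."""
        base = dict(DA=10.0, CC=7.0, DP=10.0)
        straight = build_geometry(AneurysmParams("type1", **base))
        pts = straight.sample_interior_points(0.02, np.random.default_rng(0))
        f1 = generate_flow(straight, pts, noise=NO_NOISE, seed=0)
        diffs = []
        for cp in (1e-3, 1e-4, 1e-5):
            curved = build_geometry(AneurysmParams("type2", CP=cp, LA=0.0, **base))
            inside = curved.contains(pts)
            # exclude points sitting on the (shifting) sac/parent interface
            same_region = curved.region(pts[inside]) == straight.region(pts[inside])
            f2 = generate_flow(curved, pts[inside], noise=NO_NOISE, seed=0)
            d = np.linalg.norm(f2.velocity - f1.velocity[inside], axis=1)
            diffs.append(d[same_region].max() / f1.meta["v_mean"])
        assert diffs[0] > diffs[1] > diffs[2]
        assert diffs[2] < 0.1

    def test_vtk_import_adapter_roundtrip(self, type1_geometry, rng, tmp_path):
        pts = type1_geometry.sample_interior_points(0.02, rng)
        ff = generate_flow(type1_geometry, pts, seed=2)
        path = tmp_path / "field.vtk"
        write_flow_vtk(path, pts, ff)
        pts2, ff2 = read_flow_vtk(path)
        np.testing.assert_allclose(pts2, pts, rtol=1e-7)
        np.testing.assert_allclose(ff2.velocity, ff.velocity, rtol=1e-6, atol=1e-12)
        np.testing.assert_allclose(ff2.pressure, ff.pressure, rtol=1e-6, atol=1e-12)
        assert ff2.meta["imported"]
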