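"""Parametric side-wall aneurysm geometry.

An idealized side-wall aneurysm is the union of a circular tube (the parent
artery, radius DP/2 about a constant-curvature centerline) and a sphere (the
sac, radius DA/2, center offset CC from the centerline).  Two families are
generated:

* **type 1** — straight parent artery (CP = 0);
* **type 2** — curved parent artery with constant curvature CP, the sac on the
  outer wall by default.

Five morphological parameters (all at the mm interface, converted to SI
meters internally):

====  ==========================================================  =========
DA    sac diameter                                                8–12 mm
CC    sac-center-to-centerline distance                           6–8 mm
DP    parent-artery diameter                                      8–12 mm
CP    parent-artery centerline curvature (type 2)                 0.01–0.033 mm^-1
LA    angular location of the sac along the curved artery         0–180 deg
====  ==========================================================  =========

The centerline always provides >= 10*DP of run-up upstream of the sac and
5*DP downstream so the inflow is fully developed at the sac.  For type 2, LA
slides the sac downstream within a bounded window; draws whose mandatory arc
would wrap the tube onto itself are rejected and resampled.

Coordinate convention: inlet centered at the origin, inlet normal +x, the
curved centerline bending in the x-y plane toward -y (so the outer wall at
the inlet is +y, and the CP -> 0 limit reproduces the type-1 pose).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

__all__ = [
    "TABLE_RANGES",
    "AneurysmParams",
    "Centerline",
    "AneurysmGeometry",
    "InvalidParamsError",
    "sample_params",
    "build_centerline",
    "build_geometry",
    "sample_surface_points",
    "sample_interior_points",
    "REGION_PARENT",
    "REGION_SAC",
]

#: Morphological parameter ranges (mm, mm^-1, degrees).
TABLE_RANGES: Dict[str, Tuple[float, float]] = {
    "DA": (8.0, 12.0),
    "CC": (6.0, 8.0),
    "DP": (8.0, 12.0),
    "CP": (0.01, 0.033),
    "LA": (0.0, 180.0),
}

UPSTREAM_FACTOR = 10.0   # centerline run-up upstream of the sac, in DP
DOWNSTREAM_FACTOR = 5.0  # run-out downstream of the sac, in DP
LA_WINDOW_FACTOR = 5.0   # max extra upstream arc the LA parameter can add, in DP
MAX_ARC_ANGLE = 5.8      # rad; larger arcs bring the tube ends into contact

REGION_PARENT = 0
REGION_SAC = 1

MM = 1e-3


class InvalidParamsError(ValueError):
    """Raised when morphological parameters violate a validity constraint."""


@dataclass(frozen=True)
class AneurysmParams:
    """Morphological parameters of one model (mm / mm^-1 / degrees)."""

    model_type: str  # "type1" | "type2"
    DA: float
    CC: float
    DP: float
    CP: float = 0.0
    LA: float = 0.0

    def __post_init__(self) -> None:
        if self.model_type not in ("type1", "type2"):
            raise InvalidParamsError(f"unknown model_type {self.model_type!r}")
        if self.model_type == "type1" and self.CP != 0.0:
            raise InvalidParamsError("type1 models have a straight artery (CP = 0)")

    def validate(self, ranges: Optional[Dict[str, Tuple[float, float]]] = None) -> None:
        """Check range bounds and the geometric validity inequalities."""
        r = dict(TABLE_RANGES)
        if ranges:
            r.update(ranges)
        for name in ("DA", "CC", "DP"):
            lo, hi = r[name]
            val = getattr(self, name)
            if not lo <= val <= hi:
                raise InvalidParamsError(f"{name}={val} outside [{lo}, {hi}]")
        if self.model_type == "type2":
            lo, hi = r["CP"]
            if not lo <= self.CP <= hi:
                raise InvalidParamsError(f"CP={self.CP} outside [{lo}, {hi}]")
            lo, hi = r["LA"]
            if not lo <= self.LA <= hi:
                raise InvalidParamsError(f"LA={self.LA} outside [{lo}, {hi}]")
        if not self.is_geometrically_valid():
            raise InvalidParamsError("sac sphere does not properly intersect the artery wall")

    def is_geometrically_valid(self) -> bool:
        """Sphere crosses the tube wall without being swallowed or detached.

        CC < (DA+DP)/2 and CC + DA/2 > DP/2; for type 2 additionally the
        mandatory 15*DP arc must not wrap the tube onto itself.
        """
        ok = (self.CC < (self.DA + self.DP) / 2.0
              and self.CC + self.DA / 2.0 > self.DP / 2.0)
        if self.model_type == "type2":
            ok = ok and ((UPSTREAM_FACTOR + DOWNSTREAM_FACTOR) * self.DP * self.CP
                         <= MAX_ARC_ANGLE)
        return ok


def sample_params(
    model_type: str,
    rng_seed,
    ranges: Optional[Dict[str, Tuple[float, float]]] = None,
    max_attempts: int = 1000,
) -> AneurysmParams:
    """Draw morphological parameters uniformly within their ranges.

    Rejection-resamples draws that violate the validity inequalities.
    ``rng_seed`` may be an integer seed or a ``numpy.random.Generator``.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    r = dict(TABLE_RANGES)
    if ranges:
        r.update(ranges)
    for _ in range(max_attempts):
        draw = {k: rng.uniform(*r[k]) for k in ("DA", "CC", "DP")}
        if model_type == "type2":
            draw["CP"] = rng.uniform(*r["CP"])
            draw["LA"] = rng.uniform(*r["LA"])
        else:
            draw["CP"] = 0.0
            draw["LA"] = 0.0  # type-1 canonical placement = the LA = 0 attachment
        params = AneurysmParams(model_type=model_type, **draw)
        if params.is_geometrically_valid():
            return params
    raise InvalidParamsError(
        f"no valid draw in {max_attempts} attempts; check configured ranges")


@dataclass(frozen=True)
class Centerline:
    """Constant-curvature arc (or line) in the x-y plane, arc-length parameterized.

    length    : total arc length, m
    curvature : constant curvature, 1/m (0 = straight)

    The arc starts at the origin with tangent +x and bends toward -y, so the
    outer-wall normal at the inlet is +y.
    """

    length: float
    curvature: float

    @property
    def radius(self) -> float:
        """Osculating-circle radius, m (inf for a straight line)."""
        return np.inf if self.curvature == 0.0 else 1.0 / self.curvature

    def point(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        if self.curvature == 0.0:
            out = np.zeros(s.shape + (3,))
            out[..., 0] = s
            return out
        R = self.radius
        th = s * self.curvature
        return np.stack([R * np.sin(th), -R * (1.0 - np.cos(th)), np.zeros_like(th)], axis=-1)

    def tangent(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        th = s * self.curvature
        return np.stack([np.cos(th), -np.sin(th), np.zeros_like(th)], axis=-1)

    def outer_normal(self, s) -> np.ndarray:
        """In-plane unit normal pointing toward the outer wall (away from the arc center)."""
        s = np.asarray(s, dtype=float)
        th = s * self.curvature
        return np.stack([np.sin(th), np.cos(th), np.zeros_like(th)], axis=-1)

    def binormal(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        out = np.zeros(s.shape + (3,))
        out[..., 2] = 1.0
        return out

    def project(self, points: np.ndarray):
        """Project ``points`` (n, 3) onto the (extended) centerline.

        Returns ``(s, d_out, z, d_perp, psi)``: arc-length coordinate
        (unclamped, may lie outside [0, length]), signed in-plane offset along
        the outer normal, out-of-plane offset, perpendicular distance to the
        centerline and azimuth measured from the outer normal.
        """
        q = np.asarray(points, dtype=float)
        if self.curvature == 0.0:
            s = q[..., 0]
            d_out = q[..., 1]
            z = q[..., 2]
        else:
            R = self.radius
            wx = q[..., 0]
            wy = q[..., 1] + R
            theta = np.arctan2(wx, wy)  # 0 at inlet, increases downstream
            gap = 2.0 * np.pi - self.length * self.curvature
            theta = np.where(theta < -gap / 2.0, theta + 2.0 * np.pi, theta)
            s = theta / self.curvature
            d_out = np.hypot(wx, wy) - R
            z = q[..., 2]
        d_perp = np.hypot(d_out, z)
        psi = np.arctan2(z, d_out)
        return s, d_out, z, d_perp, psi

    def place(self, s, d, psi) -> np.ndarray:
        """Inverse of :meth:`project`: point at arc-length ``s``, radius ``d``, azimuth ``psi``."""
        s = np.asarray(s, dtype=float)
        d = np.asarray(d, dtype=float)
        psi = np.asarray(psi, dtype=float)
        return (self.point(s)
                + (d * np.cos(psi))[..., None] * self.outer_normal(s)
                + (d * np.sin(psi))[..., None] * self.binormal(s))


def build_centerline(params: AneurysmParams) -> Centerline:
    """Centerline of the contracted length: 10*DP upstream of the sac, 5*DP downstream."""
    dp_m = params.DP * MM
    return Centerline(length=(_sac_arclength(params) + DOWNSTREAM_FACTOR * dp_m),
                      curvature=params.CP / MM)


def _sac_arclength(params: AneurysmParams) -> float:
    """Arc-length position of the sac attachment point, m."""
    dp_m = params.DP * MM
    base = UPSTREAM_FACTOR * dp_m
    if params.model_type == "type1" or params.CP == 0.0:
        return base
    # LA slides the sac downstream within a window bounded so the total arc
    # never exceeds MAX_ARC_ANGLE (tube would touch itself).
    cp_per_m = params.CP / MM
    window = min(LA_WINDOW_FACTOR * dp_m,
                 max(0.0, MAX_ARC_ANGLE / cp_per_m
                     - (UPSTREAM_FACTOR + DOWNSTREAM_FACTOR) * dp_m))
    return base + (params.LA / 180.0) * window


@dataclass
class AneurysmGeometry:
    """Implicit solid: tube(DP/2 about the centerline) union sphere(DA/2).

    Exposes a signed-distance-style implicit function (negative inside,
    positive outside, ~0 on the boundary), a region predicate
    (parent artery vs. aneurysm sac), the neck patch where the sphere meets
    the tube wall, and seeded surface/interior point samplers.
    """

    params: AneurysmParams
    offset_side: str = "outer"  # sac offset toward the outer or inner wall
    centerline: Centerline = field(init=False)
    s_sac: float = field(init=False)
    sphere_center: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        # construction requires geometric validity only; range enforcement is
        # the sampler's job (limit studies may use out-of-range curvatures)
        if not self.params.is_geometrically_valid():
            raise InvalidParamsError(
                "sac sphere does not properly intersect the artery wall")
        if self.offset_side not in ("outer", "inner"):
            raise ValueError("offset_side must be 'outer' or 'inner'")
        self.centerline = build_centerline(self.params)
        self.s_sac = _sac_arclength(self.params)
        sign = 1.0 if self.offset_side == "outer" else -1.0
        self.sphere_center = (self.centerline.point(self.s_sac)
                              + sign * self.params.CC * MM
                              * self.centerline.outer_normal(self.s_sac))

    # -- radii (m) --------------------------------------------------------
    @property
    def tube_radius(self) -> float:
        return self.params.DP / 2.0 * MM

    @property
    def sac_radius(self) -> float:
        return self.params.DA / 2.0 * MM

    # -- implicit solid ---------------------------------------------------
    def sdf_tube(self, points: np.ndarray) -> np.ndarray:
        s, _, _, d_perp, _ = self.centerline.project(points)
        return np.maximum(d_perp - self.tube_radius,
                          np.maximum(-s, s - self.centerline.length))

    def sdf_sphere(self, points: np.ndarray) -> np.ndarray:
        q = np.asarray(points, dtype=float)
        return np.linalg.norm(q - self.sphere_center, axis=-1) - self.sac_radius

    def sdf(self, points: np.ndarray) -> np.ndarray:
        """Implicit function of the union solid (negative inside)."""
        return np.minimum(self.sdf_tube(points), self.sdf_sphere(points))

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        return self.sdf(points) <= tol

    def region(self, points: np.ndarray) -> np.ndarray:
        """Region label per point: sac iff inside the sphere and outside the tube.

        Neck-interior points (inside both primitives) belong to the parent
        artery, so sac statistics are independent of lumen flow.
        """
        q = np.asarray(points, dtype=float)
        in_sphere = self.sdf_sphere(q) < 0.0
        _, _, _, d_perp, _ = self.centerline.project(q)
        return np.where(in_sphere & (d_perp > self.tube_radius),
                        REGION_SAC, REGION_PARENT)

    # -- neck patch -------------------------------------------------------
    @property
    def neck_height(self) -> float:
        """Sphere-center height above the (locally planar) tube wall, m."""
        return max(0.0, self.params.CC * MM - self.tube_radius)

    @property
    def neck_radius(self) -> float:
        """Radius of the neck orifice circle, m."""
        h = self.neck_height
        return float(np.sqrt(max(self.sac_radius ** 2 - h ** 2, 0.0)))

    @property
    def neck_area(self) -> float:
        return float(np.pi * self.neck_radius ** 2)

    @property
    def neck_center(self) -> np.ndarray:
        sign = 1.0 if self.offset_side == "outer" else -1.0
        return (self.centerline.point(self.s_sac)
                + sign * self.tube_radius * self.centerline.outer_normal(self.s_sac))

    @property
    def neck_normal(self) -> np.ndarray:
        """Unit normal of the neck patch, pointing from the lumen into the sac."""
        sign = 1.0 if self.offset_side == "outer" else -1.0
        return sign * np.asarray(self.centerline.outer_normal(self.s_sac))

    @property
    def distal_dir(self) -> np.ndarray:
        """Downstream tangent direction at the sac attachment point."""
        return np.asarray(self.centerline.tangent(self.s_sac))

    def neck_patch_points(self, n: int = 200) -> np.ndarray:
        """Points on the neck orifice circle (local-plane approximation)."""
        if self.neck_radius <= 0.0:
            raise InvalidParamsError("degenerate neck: sphere tangent to the wall")
        phi = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        e1 = self.distal_dir
        e2 = np.cross(self.neck_normal, e1)
        return (self.neck_center
                + self.neck_radius * (np.outer(np.cos(phi), e1) + np.outer(np.sin(phi), e2)))

    # -- samplers ---------------------------------------------------------
    def sample_surface_points(self, density: float, rng) -> np.ndarray:
        """Seeded, approximately uniform sample of the solid boundary.

        ``density`` is in points per mm^2.  Covers the tube lateral wall
        (minus the part swallowed by the sac), the sphere wall (minus the part
        inside the tube) and the flat inlet/outlet caps.
        """
        if density <= 0:
            raise ValueError("density must be > 0")
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        d_m2 = density / MM ** 2  # points per m^2
        rt, ra, L = self.tube_radius, self.sac_radius, self.centerline.length
        k = self.centerline.curvature
        pts = []

        # tube lateral wall; curved-tube area element ~ (1 + k*rt*cos(psi))
        n_t = max(1, int(round(2.0 * np.pi * rt * L * d_m2)))
        s = rng.uniform(0.0, L, n_t)
        psi = rng.uniform(-np.pi, np.pi, n_t)
        if k > 0.0:
            w = (1.0 + k * rt * np.cos(psi)) / (1.0 + k * rt)
            keep = rng.uniform(size=n_t) < w
            s, psi = s[keep], psi[keep]
        p = self.centerline.place(s, np.full_like(s, rt), psi)
        pts.append(p[self.sdf_sphere(p) >= 0.0])

        # sphere wall
        n_s = max(1, int(round(4.0 * np.pi * ra ** 2 * d_m2)))
        u = rng.normal(size=(n_s, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        p = self.sphere_center + ra * u
        _, _, _, d_perp, _ = self.centerline.project(p)
        pts.append(p[d_perp >= rt])

        # inlet / outlet caps
        for s_cap in (0.0, L):
            n_c = max(1, int(round(np.pi * rt ** 2 * d_m2)))
            r = rt * np.sqrt(rng.uniform(size=n_c))
            phi = rng.uniform(-np.pi, np.pi, n_c)
            pts.append(self.centerline.place(np.full(n_c, s_cap), r, phi))

        return np.concatenate(pts, axis=0)

    def sample_interior_points(
        self,
        density: float,
        rng,
        include_sac: bool = True,
        include_layer: bool = True,
        layer_thickness: float = 150e-6,
        near_wall_refine: bool = True,
    ) -> np.ndarray:
        """Seeded volumetric sample of the interior (points per mm^3).

        Emulates a boundary-refined CFD node distribution: within 0.1*DP of
        the wall the density is doubled (``near_wall_refine``).  ``include_sac``
        masks out sac-region points; ``include_layer`` controls whether sac
        points within ``layer_thickness`` of the tube wall (the stent-layer
        region after deployment) are kept.
        """
        if density <= 0:
            raise ValueError("density must be > 0")
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        d_m3 = density / MM ** 3
        rt, ra, L = self.tube_radius, self.sac_radius, self.centerline.length
        k = self.centerline.curvature
        delta = 0.1 * self.params.DP * MM  # near-wall refinement band
        pts = []

        def _tube_batch(n: int, r_lo: float, r_hi: float) -> np.ndarray:
            s = rng.uniform(0.0, L, n)
            psi = rng.uniform(-np.pi, np.pi, n)
            r = np.sqrt(rng.uniform(r_lo ** 2, r_hi ** 2, n))
            if k > 0.0:  # curved-tube volume element ~ (1 + k*r*cos(psi))
                w = (1.0 + k * r * np.cos(psi)) / (1.0 + k * r_hi)
                keep = rng.uniform(size=n) < w
                s, psi, r = s[keep], psi[keep], r[keep]
            return self.centerline.place(s, r, psi)

        n_tube = max(1, int(round(np.pi * rt ** 2 * L * d_m3)))
        pts.append(_tube_batch(n_tube, 0.0, rt))
        if near_wall_refine and delta < rt:
            v_shell = np.pi * (rt ** 2 - (rt - delta) ** 2) * L
            pts.append(_tube_batch(max(1, int(round(v_shell * d_m3))), rt - delta, rt))

        def _ball_batch(n: int, r_lo: float, r_hi: float) -> np.ndarray:
            u = rng.normal(size=(n, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            r = (rng.uniform(r_lo ** 3, r_hi ** 3, n)) ** (1.0 / 3.0)
            p = self.sphere_center + r[:, None] * u
            _, _, _, d_perp, _ = self.centerline.project(p)
            return p[d_perp >= rt]  # tube overlap already covered above

        n_ball = max(1, int(round(4.0 / 3.0 * np.pi * ra ** 3 * d_m3)))
        pts.append(_ball_batch(n_ball, 0.0, ra))
        if near_wall_refine and delta < ra:
            v_shell = 4.0 / 3.0 * np.pi * (ra ** 3 - (ra - delta) ** 3)
            pts.append(_ball_batch(max(1, int(round(v_shell * d_m3))), ra - delta, ra))

        out = np.concatenate(pts, axis=0)
        # keep strictly interior points only
        out = out[self.sdf(out) < 0.0]
        if not include_sac:
            out = out[self.region(out) == REGION_PARENT]
        if not include_layer:
            _, _, _, d_perp, _ = self.centerline.project(out)
            in_layer = (self.region(out) == REGION_SAC) & (d_perp <= rt + layer_thickness)
            out = out[~in_layer]
        return out

    # -- export -----------------------------------------------------------
    def surface_mesh(self, n_s: int = 160, n_phi: int = 48):
        """Triangulated boundary surface as a ``trimesh.Trimesh``.

        Built from parametric grids on the tube and sphere with triangles
        interior to the other primitive dropped; intended for export and
        visual inspection, not watertight CFD meshing.
        """
        import trimesh

        rt, ra, L = self.tube_radius, self.sac_radius, self.centerline.length
        meshes = []

        s = np.linspace(0.0, L, n_s)
        phi = np.linspace(-np.pi, np.pi, n_phi, endpoint=False)
        S, PHI = np.meshgrid(s, phi, indexing="ij")
        V = self.centerline.place(S.ravel(), np.full(S.size, rt), PHI.ravel())
        faces = []
        for i in range(n_s - 1):
            for j in range(n_phi):
                a = i * n_phi + j
                b = i * n_phi + (j + 1) % n_phi
                c = (i + 1) * n_phi + j
                d = (i + 1) * n_phi + (j + 1) % n_phi
                faces.append([a, b, d])
                faces.append([a, d, c])
        keep = self.sdf_sphere(V) >= -1e-6
        tube = trimesh.Trimesh(vertices=V, faces=np.asarray(faces), process=False)
        tube.update_faces(keep[tube.faces].all(axis=1))
        meshes.append(tube)

        sphere = trimesh.creation.icosphere(subdivisions=3, radius=ra)
        sphere.apply_translation(self.sphere_center)
        _, _, _, d_perp, _ = self.centerline.project(sphere.vertices)
        sphere.update_faces((d_perp >= rt - 1e-6)[sphere.faces].all(axis=1))
        meshes.append(sphere)
        return trimesh.util.concatenate(meshes)

    def export_surface(self, path: str, **mesh_kwargs) -> None:
        """Write the boundary triangulation to STL or PLY (by file extension)."""
        self.surface_mesh(**mesh_kwargs).export(path)


def build_geometry(params: AneurysmParams, offset_side: str = "outer") -> AneurysmGeometry:
    """Construct the implicit aneurysm solid for validated parameters."""
    return AneurysmGeometry(params=params, offset_side=offset_side)


def sample_surface_points(geometry: AneurysmGeometry, density: float, rng=0) -> np.ndarray:
    return geometry.sample_surface_points(density, rng)


def sample_interior_points(geometry: AneurysmGeometry, density: float, rng=0, **kwargs) -> np.ndarray:
    return geometry.sample_interior_points(density, rng, **kwargs)
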