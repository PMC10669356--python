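"""Parametric layered tooth-PDL-bone geometry.

This module is the synthetic-anatomy generator of the package: it builds
idealized single-rooted (canine/premolar-like) and two-rooted (molar-like)
teeth embedded in an alveolar bone block, with the full tissue layering
used in periodontal load-capacity simulations:

* enamel cap over a dentin body with a pulp cavity,
* a cementum layer on the root, graded in three steps from 50 um at the
  cemento-enamel junction (CEJ) to 150 um at the apex,
* a uniform 0.1 mm periodontal-ligament (PDL) shell,
* a cortical bone shell around a cancellous core, and
* an optional gingival collar.

Geometry is represented parametrically: every tissue interface is a
star-shaped cross-section radius function r(theta, z) around the root
axis.  The axis convention is +z pointing apically with the origin at the
CEJ centroid; attachment loss is measured as +z distance from the CEJ.
The multi-rooted tooth is modelled as a two-lobed root with deep
bucco-lingual furcation grooves below the furcation depth (a partially
fused root form); the interradicular septum of PDL and bone fills the
grooves, giving a well-defined furcation roof.

Attachment reduction removes the PDL and supporting bone coronal to a
plane perpendicular to the root axis, mimicking horizontal periodontal
attachment loss in 1 mm increments.

Units are mm throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "ToothParams",
    "ToothParamError",
    "GeometryError",
    "LayeredToothModel",
    "ImportedToothModel",
    "build_tooth",
    "reduce_attachment",
    "create_pdl_layer",
    "create_cementum_layer",
    "graded_cementum_thickness",
    "offset_closed_curve",
    "import_surfaces",
]

TISSUES = (
    "enamel", "dentin", "pulp", "cementum", "pdl",
    "cortical_bone", "cancellous_bone", "gingiva",
)

#: ordered radial interface names used by the structured mesher; the root
#: axis is ring "0", so interface i bounds radial band i-1 / i.
RING_INTERFACES = (
    "pulp", "dentin_mid", "dentin",
    "cementum", "pdl_mid", "pdl",
    "bone_mid", "cortical_inner", "bone_outer",
)
N_RINGS = len(RING_INTERFACES)


class ToothParamError(ValueError):
    """Infeasible tooth parameter combination; message names the constraint."""


class GeometryError(ValueError):
    """Geometric construction failure (self-intersection, degenerate input...)."""


@dataclass(frozen=True)
class ToothParams:
    """Free parameters of the parametric tooth.

    Dimensions are patient-specific in reality; defaults follow standard
    dental-anatomy ranges (root length ~13 mm for a single-rooted tooth,
    ~12 mm for molar roots, furcation ~3 mm below the CEJ).
    """

    tooth_class: str = "single_rooted"
    root_length: float = 13.0
    crown_height: float = 8.0
    root_apical_radius: float = 1.2
    root_cervical_radius: float = 3.4
    furcation_depth_below_cej: float | None = None
    inter_root_spread: float | None = None
    enamel_thickness: float = 1.0
    pulp_scale: float = 0.35
    cortical_shell_thickness: float = 1.5
    bone_block_dims: tuple[float, float, float] = (14.0, 14.0, 17.0)
    pdl_thickness: float = 0.1
    #: healthy distance from the CEJ to the alveolar crest (biologic
    #: width / supracrestal tissue height); support spans
    #: [crest_offset + attachment_reduction, root_length]
    crest_offset: float = 1.5
    include_gingiva: bool = False

    @staticmethod
    def single(**overrides) -> "ToothParams":
        """Default single-rooted (canine/premolar-like) tooth."""
        return ToothParams(**{"tooth_class": "single_rooted", **overrides})

    @staticmethod
    def multi(**overrides) -> "ToothParams":
        """Default two-rooted (molar-like) tooth with a furcation."""
        defaults = dict(
            tooth_class="multi_rooted",
            root_length=12.0,
            root_cervical_radius=4.5,
            root_apical_radius=1.4,
            furcation_depth_below_cej=3.0,
            inter_root_spread=2.5,
            bone_block_dims=(16.0, 16.0, 16.0),
        )
        defaults.update(overrides)
        return ToothParams(**defaults)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        p = self
        if p.tooth_class not in ("single_rooted", "multi_rooted"):
            raise ToothParamError(
                f"tooth_class must be 'single_rooted' or 'multi_rooted', "
                f"got {p.tooth_class!r}")
        for name in ("root_length", "crown_height", "root_apical_radius",
                     "root_cervical_radius", "enamel_thickness",
                     "cortical_shell_thickness", "pdl_thickness"):
            if not getattr(p, name) > 0:
                raise ToothParamError(f"{name} must be > 0, got {getattr(p, name)}")
        if any(d <= 0 for d in p.bone_block_dims):
            raise ToothParamError("bone_block_dims must be positive")
        if not (0.0 < p.pulp_scale < 0.8):
            raise ToothParamError(
                f"pulp_scale must lie in (0, 0.8) so the pulp stays strictly "
                f"inside the dentin, got {p.pulp_scale}")
        if p.root_apical_radius > p.root_cervical_radius:
            raise ToothParamError(
                "root_apical_radius must not exceed root_cervical_radius "
                "(roots taper apically)")
        if p.tooth_class == "multi_rooted":
            if p.furcation_depth_below_cej is None:
                raise ToothParamError("multi_rooted tooth requires "
                                      "furcation_depth_below_cej")
            if not (0.0 < p.furcation_depth_below_cej < p.root_length):
                raise ToothParamError(
                    "furcation_depth_below_cej must lie strictly between 0 "
                    "and root_length")
            if p.inter_root_spread is None or p.inter_root_spread <= 0:
                raise ToothParamError("multi_rooted tooth requires "
                                      "inter_root_spread > 0")
        if p.enamel_thickness >= p.crown_height / 2:
            raise ToothParamError(
                "enamel_thickness must be smaller than half the crown height")
        if p.crest_offset < 0 or p.crest_offset > p.root_length / 3:
            raise ToothParamError(
                "crest_offset must lie in [0, root_length / 3]")
        bone_radius = min(p.bone_block_dims[0], p.bone_block_dims[1]) / 2.0
        pdl_outer_max = self._max_lobe_radius() + 0.15 + p.pdl_thickness
        if bone_radius - p.cortical_shell_thickness < pdl_outer_max + 0.5:
            raise ToothParamError(
                "cortical shell thicker than the bone available between the "
                "PDL outer surface and the bone block boundary "
                f"(need bone radius > {pdl_outer_max + 0.5 + p.cortical_shell_thickness:.2f} mm)")
        if p.bone_block_dims[2] < p.root_length + 1.0:
            raise ToothParamError(
                "bone block depth must exceed root_length + 1 mm so bone "
                "remains below the apex")

    def _max_lobe_radius(self) -> float:
        # lobes never leave the trunk taper envelope
        return self.root_cervical_radius

    def _lobe_amplitude(self) -> float:
        """Waist depth 'a' of the two-lobed section r = R (1 - a sin^2).

        The furcation grooves carve into the root-trunk taper envelope
        (the lobes stay on it), so the cross-section area decreases
        monotonically with depth like the single root's; the waist
        narrows to R (1 - a) between the lobes.
        """
        if self.tooth_class != "multi_rooted":
            return 0.0
        zf = self.furcation_depth_below_cej
        r = self._base_radius(zf)
        # waist of two fused circular root lobes: lobe centers +-spread/2,
        # lobe radius R - spread/2, waist sqrt(R^2 - spread*R)
        frac = max(0.1, 1.0 - self.inter_root_spread / r)
        return float(np.clip(1.0 - np.sqrt(frac), 0.15, 0.6))

    def _base_radius(self, z: float) -> float:
        t = np.clip(z / self.root_length, 0.0, 1.0)
        return self.root_cervical_radius + (
            self.root_apical_radius - self.root_cervical_radius) * t


# ---------------------------------------------------------------------------
# small mesh queries (self-contained: no spatial-index dependency)

def points_in_mesh(mesh: "trimesh.Trimesh", points: np.ndarray) -> np.ndarray:
    """Boolean containment test by +z ray casting (Moller-Trumbore),
    counting crossings against every triangle."""
    tri = mesh.triangles.view(np.ndarray)
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    d = np.array([0.0, 0.0, 1.0])
    h = np.cross(d, e2)
    a = np.einsum("tj,tj->t", e1, h)
    ok = np.abs(a) > 1e-12
    inv = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
    out = np.empty(len(points), dtype=bool)
    for i, p in enumerate(np.asarray(points, dtype=float)):
        s = p - v0
        u = np.einsum("tj,tj->t", s, h) * inv
        q = np.cross(s, e1)
        v = (q @ d) * inv
        t = np.einsum("tj,tj->t", e2, q) * inv
        hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-9)
        out[i] = (hit.sum() % 2) == 1
    return out


def _ray_first_hit(mesh: "trimesh.Trimesh", origins: np.ndarray,
                   directions: np.ndarray) -> np.ndarray:
    """Distance to the first triangle hit along each ray (nan if none)."""
    tri = mesh.triangles.view(np.ndarray)
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    out = np.full(len(origins), np.nan)
    for i, (p, d) in enumerate(zip(origins, directions)):
        h = np.cross(d, e2)
        a = np.einsum("tj,tj->t", e1, h)
        ok = np.abs(a) > 1e-14
        inv = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
        s = p - v0
        u = np.einsum("tj,tj->t", s, h) * inv
        q = np.cross(s, e1)
        v = np.einsum("tj,j->t", q, d) * inv
        t = np.einsum("tj,tj->t", e2, q) * inv
        hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) \
            & (t > 1e-9)
        if np.any(hit):
            out[i] = t[hit].min()
    return out


def distance_to_surface(mesh: "trimesh.Trimesh", points: np.ndarray
                        ) -> np.ndarray:
    """Unsigned distance from points to a triangulated surface
    (vectorized exact point-triangle distance, brute force)."""
    tri = mesh.triangles.view(np.ndarray)
    b0, e0, e1 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    a = np.einsum("tj,tj->t", e0, e0)
    b = np.einsum("tj,tj->t", e0, e1)
    c = np.einsum("tj,tj->t", e1, e1)
    det = np.maximum(a * c - b * b, 1e-300)
    out = np.empty(len(points))
    for i, p in enumerate(np.asarray(points, dtype=float)):
        diff = b0 - p
        d = np.einsum("tj,tj->t", e0, diff)
        e = np.einsum("tj,tj->t", e1, diff)
        s = np.clip((b * e - c * d) / det, 0.0, 1.0)
        t = np.clip((b * d - a * e) / det, 0.0, 1.0)
        # project back onto the triangle for edge regions
        s2 = np.clip(-(d + b * t) / np.maximum(a, 1e-300), 0.0, 1.0)
        t2 = np.clip(-(e + b * s) / np.maximum(c, 1e-300), 0.0, 1.0)
        cand = np.stack([
            ((diff + e0 * s[:, None] + e1 * t[:, None]) ** 2).sum(1),
            ((diff + e0 * s2[:, None] + e1 * t[:, None]) ** 2).sum(1),
            ((diff + e0 * s[:, None] + e1 * t2[:, None]) ** 2).sum(1),
        ])
        out[i] = np.sqrt(cand.min())
    return out


# ---------------------------------------------------------------------------
# curve offsetting

def offset_closed_curve(radii: np.ndarray, thickness, thetas_out: np.ndarray,
                        ) -> np.ndarray:
    """Normal-offset a star-shaped closed curve given as radii on a uniform
    dense theta grid; return radii of the offset curve at ``thetas_out``.

    The offset is taken along the true outward 2D curve normal, so the
    resulting shell thickness is exact wherever the offset curve does not
    self-intersect; a self-intersecting offset (the angular
    parameterization folding back on itself) raises :class:`GeometryError`
    with the location.
    """
    n = len(radii)
    th = np.arange(n) * (2.0 * np.pi / n)
    x = radii * np.cos(th)
    y = radii * np.sin(th)
    # periodic central differences for the tangent
    dx = np.roll(x, -1) - np.roll(x, 1)
    dy = np.roll(y, -1) - np.roll(y, 1)
    norm = np.hypot(dx, dy)
    # CCW curve: outward normal is the tangent rotated by -90 degrees
    nx, ny = dy / norm, -dx / norm
    qx = x + thickness * nx
    qy = y + thickness * ny
    phi = np.unwrap(np.arctan2(qy, qx))
    if np.any(np.diff(phi) <= 0):
        j = int(np.argmin(np.diff(phi)))
        raise GeometryError(
            f"offset curve self-intersects near theta={th[j]:.3f} rad "
            f"(local curvature radius smaller than offset {np.max(thickness):.3f} mm)")
    rho = np.hypot(qx, qy)
    # re-parameterize by angle (periodic interpolation)
    phi0 = phi - phi[0]
    tq = np.mod(thetas_out - np.arctan2(qy[0], qx[0]), 2.0 * np.pi)
    return np.interp(tq, np.append(phi0, 2.0 * np.pi),
                     np.append(rho, rho[0]))


def graded_cementum_thickness(h_norm) -> np.ndarray:
    """Cementum thickness (mm) at normalized root height h in [0, 1].

    Three abrupt steps by thirds of root height measured from the CEJ:
    50 um cervical, 100 um middle, 150 um apical.
    """
    h = np.asarray(h_norm, dtype=float)
    return np.where(h < 1.0 / 3.0, 0.05, np.where(h < 2.0 / 3.0, 0.10, 0.15))


# ---------------------------------------------------------------------------
# the layered model

_DENSE_N = 1024


@dataclass(frozen=True)
class LayeredToothModel:
    """Parametric layered tooth + alveolus with a given attachment loss.

    The model is fully described by its :class:`ToothParams` and the
    current ``attachment_reduction`` (mm of support removed apically from
    the CEJ); all tissue interfaces are evaluated on demand via
    :meth:`level_radii`.  Models are immutable; :func:`reduce_attachment`
    returns a new model.
    """

    params: ToothParams
    attachment_reduction: float = 0.0
    _solid_cache: dict = field(default_factory=dict, compare=False, repr=False)

    # -- frame and landmarks -------------------------------------------------

    @property
    def root_axis(self) -> np.ndarray:
        """Unit vector, +z pointing apically; origin at the CEJ centroid."""
        return np.array([0.0, 0.0, 1.0])

    @property
    def root_length(self) -> float:
        return self.params.root_length

    @property
    def crown_height(self) -> float:
        return self.params.crown_height

    @property
    def bone_radius(self) -> float:
        return min(self.params.bone_block_dims[0],
                   self.params.bone_block_dims[1]) / 2.0

    @property
    def bone_bottom_z(self) -> float:
        return self.params.bone_block_dims[2]

    @property
    def support_start_z(self) -> float:
        """Coronal limit of the periodontal support (PDL + bone): the
        healthy crest position plus the current attachment reduction."""
        return min(self.params.crest_offset + self.attachment_reduction,
                   self.params.root_length)

    @property
    def pulp_end_z(self) -> float:
        return 0.8 * self.params.root_length

    @property
    def pulp_roof_z(self) -> float:
        return -0.5 * self.params.crown_height

    @property
    def apex_cap_z(self) -> tuple[float, float]:
        """(end of cementum cap, end of PDL cap) below the apex."""
        z0 = self.params.root_length
        return z0 + 0.15, z0 + 0.15 + self.params.pdl_thickness

    @property
    def furcation_start_z(self) -> float | None:
        """Depth below the CEJ at which the furcation (roof) begins."""
        return self.params.furcation_depth_below_cej

    #: mm over which the furcation grooves develop below the furcation
    #: depth; the fornix (roof) of a molar furcation is a dome blending
    #: into the root trunk over a few mm, not a sharp ledge
    _FURCATION_RAMP = 3.0

    @property
    def furcation_roof_point(self) -> np.ndarray | None:
        """Point on the developed furcation roof (inter-root septum side)."""
        zf = self.furcation_start_z
        if zf is None:
            return None
        z = zf + self._FURCATION_RAMP
        r = self._root_surface_radii(z, np.array([np.pi / 2.0]))[0]
        return np.array([0.0, r, z])

    def cej_curve(self, n: int = 128) -> np.ndarray:
        """Points on the cemento-enamel junction (z = 0, dentin surface)."""
        th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        r = self._root_surface_radii(0.0, th)
        return np.column_stack([r * np.cos(th), r * np.sin(th),
                                np.zeros(n)])

    # -- shape functions -----------------------------------------------------

    def _lobe_factor(self, z: float, thetas: np.ndarray) -> np.ndarray:
        a = self.params._lobe_amplitude()
        zf = self.furcation_start_z
        if a == 0.0 or zf is None or z <= zf:
            return np.ones_like(thetas)
        u = np.clip((z - zf) / self._FURCATION_RAMP, 0.0, 1.0)
        smooth = u * u * (3.0 - 2.0 * u)
        # sin^4 grooves approximate the smoothed boundary of two fused
        # circular lobes (narrower than sin^2, wider than the sharp
        # two-circle corner, which a finite offset could not follow)
        return 1.0 - a * smooth * np.sin(thetas) ** 4

    def _root_surface_radii(self, z: float, thetas: np.ndarray) -> np.ndarray:
        """Dentin (root body) outer radius at depth z below the CEJ."""
        return self.params._base_radius(z) * self._lobe_factor(z, thetas)

    def cementum_thickness(self, z: float) -> float:
        return float(graded_cementum_thickness(z / self.params.root_length))

    def crown_outer_radius(self, z: float) -> float:
        """Enamel outer radius in the crown (z < 0); blends to the root
        profile over the last ~1.5 mm above the CEJ."""
        p = self.params
        blend = min(1.5, p.crown_height / 3.0)
        t_eff = max(0.15, p.enamel_thickness * min(1.0, -z / blend))
        return p.root_cervical_radius + t_eff

    # -- ring interface radii for the structured mesher ----------------------

    def level_radii(self, z: float, thetas: np.ndarray) -> np.ndarray:
        """Radii of all :data:`RING_INTERFACES` at height z, shape
        (N_RINGS, len(thetas)).  Rows are strictly increasing."""
        p = self.params
        nt = len(thetas)
        out = np.empty((N_RINGS, nt))
        dense_th = np.arange(_DENSE_N) * (2.0 * np.pi / _DENSE_N)

        zr = min(max(z, 0.0), p.root_length)  # clamp: caps reuse apex profile
        if z < 0.0:  # crown
            rd = np.full(nt, p.root_cervical_radius)
            r_outer = self.crown_outer_radius(z)
            t_eff = r_outer - p.root_cervical_radius
            r6 = rd + t_eff / 2.0
            r7 = rd + t_eff
            r8 = r7 + 0.05
        else:
            rd = self._root_surface_radii(zr, thetas)
            rd_dense = self._root_surface_radii(zr, dense_th)
            # in-plane offsets are enlarged by the axial surface slope so
            # the true (3D normal) layer thickness stays at its nominal
            # value on tapered walls and in the furcation ramp
            dz = 0.05
            slope = (self._root_surface_radii(min(zr + dz, p.root_length),
                                              dense_th)
                     - self._root_surface_radii(max(zr - dz, 0.0), dense_th)
                     ) / (min(zr + dz, p.root_length)
                          - max(zr - dz, 0.0) + 1e-300)
            tilt = np.sqrt(1.0 + slope ** 2)
            t_c = self.cementum_thickness(zr)
            r6 = offset_closed_curve(rd_dense, t_c * tilt, thetas)
            r7 = offset_closed_curve(
                rd_dense, (t_c + p.pdl_thickness / 2.0) * tilt, thetas)
            r8 = offset_closed_curve(
                rd_dense, (t_c + p.pdl_thickness) * tilt, thetas)

        r_pulp = p.pulp_scale * rd
        out[0] = r_pulp                 # pulp boundary
        out[1] = r_pulp + (rd - r_pulp) / 2.0
        out[2] = rd                     # dentin outer
        out[3] = r6                     # cementum outer (root) / enamel mid
        out[4] = r7                     # pdl mid / enamel outer
        out[5] = r8                     # pdl outer = bone interface
        rb = self.bone_radius
        r_ci = rb - p.cortical_shell_thickness
        out[6] = r8 + 0.5 * (r_ci - r8)
        out[7] = r_ci                   # cortical inner
        out[8] = rb                     # outer bone boundary
        return out

    # -- parametric measures (used as quasi-independent oracles) -------------

    def pdl_lateral_area(self, n_z: int = 400, n_th: int = 256) -> float:
        """Area of the lateral PDL-bone interface (outer PDL surface between
        the reduction plane and the apex), by dense quadrature."""
        p = self.params
        z0, z1 = self.support_start_z, p.root_length
        if z1 - z0 <= 0:
            return 0.0
        zs = np.linspace(z0, z1, n_z + 1)
        th = np.arange(n_th) * (2.0 * np.pi / n_th)
        dense_th = np.arange(_DENSE_N) * (2.0 * np.pi / _DENSE_N)
        perims = np.empty(n_z + 1)
        for i, z in enumerate(zs):
            rd = self._root_surface_radii(z, dense_th)
            t = self.cementum_thickness(z) + p.pdl_thickness
            r = offset_closed_curve(rd, t, th)
            x, y = r * np.cos(th), r * np.sin(th)
            perims[i] = np.sum(np.hypot(np.diff(np.append(x, x[0])),
                                        np.diff(np.append(y, y[0]))))
        # slope correction for the tapered wall
        slope = (p.root_cervical_radius - p.root_apical_radius) / p.root_length
        return float(np.trapezoid(perims, zs) * np.sqrt(1.0 + slope ** 2))

    def total_volume(self, n_z: int = 600, n_th: int = 512) -> float:
        """Volume of the full meshed domain (tooth + PDL + bone block),
        by dense quadrature of the outermost cross-section area."""
        z_sup = self.support_start_z
        p = self.params
        th = np.arange(n_th) * (2.0 * np.pi / n_th)
        zs = np.linspace(-p.crown_height, self.bone_bottom_z, n_z + 1)
        areas = np.empty(n_z + 1)
        for i, z in enumerate(zs):
            if z < 0.0:
                r = np.full(n_th, self.crown_outer_radius(z))
            elif z < z_sup and z < p.root_length:
                r = self.level_radii(z, th)[5]  # exposed cementum surface
            else:
                r = np.full(n_th, self.bone_radius)
            areas[i] = 0.5 * np.sum(r * r) * (2.0 * np.pi / n_th)
        return float(np.trapezoid(areas, zs))

    # -- thickness sampling --------------------------------------------------

    def sample_pdl_thickness(self, n: int = 200,
                             rng: np.random.Generator | None = None
                             ) -> np.ndarray:
        """PDL shell thickness at n random points of the PDL outer surface.

        Measured as the distance from each point to the cementum outer
        surface (the PDL inner boundary) along the local inward surface
        normal, which is the wall thickness even inside the narrow
        furcation grooves (a nearest-point query would jump to the
        opposite groove wall there).
        """
        rng = np.random.default_rng(0) if rng is None else rng
        p = self.params
        z0 = self.support_start_z + 0.2
        z1 = p.root_length - 0.2
        zq = rng.uniform(z0, z1, n)
        tq = rng.uniform(0.0, 2.0 * np.pi, n)

        def outer_point(z, t):
            return np.array([*self._ring_point("pdl", z, t), z])

        pts = np.array([outer_point(z, t) for z, t in zip(zq, tq)])
        # inward normal from finite differences of the outer surface
        dth, dz = 1e-3, 1e-3
        p_th = np.array([outer_point(z, t + dth) - outer_point(z, t - dth)
                         for z, t in zip(zq, tq)]) / (2 * dth)
        p_z = np.array([outer_point(z + dz, t) - outer_point(z - dz, t)
                        for z, t in zip(zq, tq)]) / (2 * dz)
        nrm = np.cross(p_th, p_z)
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        # orient inward (toward the axis)
        flip = np.einsum("ij,ij->i", nrm[:, :2], pts[:, :2]) > 0
        nrm[flip] *= -1.0
        inner = self._parametric_surface("cementum", n_z=260, n_th=192)
        return _ray_first_hit(inner, pts, nrm)

    def _ring_point(self, interface: str, z: float, theta: float):
        idx = RING_INTERFACES.index(interface)
        r = self.level_radii(z, np.array([theta]))[idx, 0]
        return r * np.cos(theta), r * np.sin(theta)

    def _parametric_surface(self, interface: str, n_z: int = 200,
                            n_th: int = 128) -> trimesh.Trimesh:
        """Triangulated lateral surface of a named ring interface over the
        root height (open tube; used for distance queries)."""
        idx = RING_INTERFACES.index(interface)
        th = np.arange(n_th) * (2.0 * np.pi / n_th)
        zs = np.linspace(0.0, self.params.root_length, n_z + 1)
        verts = []
        for z in zs:
            r = self.level_radii(z, th)[idx]
            verts.append(np.column_stack(
                [r * np.cos(th), r * np.sin(th), np.full(n_th, z)]))
        verts = np.vstack(verts)
        faces = []
        for k in range(n_z):
            base = k * n_th
            for j in range(n_th):
                a, b = base + j, base + (j + 1) % n_th
                c, d = a + n_th, b + n_th
                faces.append((a, b, d))
                faces.append((a, d, c))
        return trimesh.Trimesh(vertices=verts, faces=np.array(faces),
                               process=False)

    # -- solids and I/O ------------------------------------------------------

    def solids(self, mesh_size: float = 1.2) -> dict[str, trimesh.Trimesh]:
        """Watertight boundary surface per tissue, extracted from a
        conforming volume mesh of the model."""
        key = round(mesh_size, 6)
        if key not in self._solid_cache:
            from .meshing import extract_region_surfaces, generate_mesh
            mesh = generate_mesh(self, size=mesh_size, order=1,
                                 symmetric=False)
            self._solid_cache[key] = extract_region_surfaces(mesh)
        return self._solid_cache[key]

    def export_surfaces(self, directory, file_format: str = "stl",
                        mesh_size: float = 1.2) -> dict[str, Path]:
        """Write one surface file per tissue; returns the paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for tissue, solid in self.solids(mesh_size).items():
            path = directory / f"{tissue}.{file_format}"
            solid.export(path)
            paths[tissue] = path
        return paths


def build_tooth(params: ToothParams) -> LayeredToothModel:
    """Validate parameters and construct a full-support layered model.

    The result has ``attachment_reduction = 0`` and is mirror-symmetric
    about the tooth's mid-sagittal (y = 0) plane.
    """
    params.validate()
    model = LayeredToothModel(params=params, attachment_reduction=0.0)
    # feasibility of the layer offsets (concave furcation grooves must not
    # self-intersect under the cementum+PDL offset)
    th = np.arange(_DENSE_N) * (2.0 * np.pi / _DENSE_N)
    probe = np.linspace(0.0, params.root_length, 25)
    for z in probe:
        rd = model._root_surface_radii(z, th)
        offset_closed_curve(
            rd, model.cementum_thickness(z) + params.pdl_thickness,
            np.array([0.0]))
    return model


def reduce_attachment(model: LayeredToothModel, reduction: float
                      ) -> LayeredToothModel:
    """Remove PDL and supporting bone from the CEJ down to ``reduction`` mm.

    Only the support is altered: the tooth tissues (enamel, dentin,
    cementum, pulp) are untouched, and the root surface coronal to the
    reduction plane becomes exposed.  ``reduction = 0`` returns an
    identical model.
    """
    if not (0.0 <= reduction <= model.params.root_length):
        raise GeometryError(
            f"reduction must lie in [0, root_length={model.params.root_length}], "
            f"got {reduction}")
    return dataclasses.replace(model, attachment_reduction=float(reduction))


# ---------------------------------------------------------------------------
# stand-alone shell construction on triangulated surfaces

def _stitch_shell(surface: trimesh.Trimesh, offsets: np.ndarray
                  ) -> trimesh.Trimesh:
    """Build the watertight solid between a surface and its per-vertex
    normal offset; open boundaries are closed with a rim band."""
    v0 = surface.vertices.view(np.ndarray)
    normals = surface.vertex_normals.view(np.ndarray)
    v1 = v0 + normals * offsets[:, None]
    faces0 = surface.faces.view(np.ndarray)

    # reject locally inverted offsets (self-intersecting shell)
    n_old = surface.face_normals.view(np.ndarray)
    tri = v1[faces0]
    n_new = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    flipped = np.einsum("ij,ij->i", n_new, n_old) <= 0.0
    if np.any(flipped):
        loc = tri[flipped][0].mean(axis=0)
        raise GeometryError(
            f"shell offset self-intersects (flipped facet near {np.round(loc, 3)}); "
            "remesh the surface locally or reduce the thickness")

    n = len(v0)
    faces = [faces0[:, ::-1], faces0 + n]
    edges = trimesh.geometry.faces_to_edges(faces0)
    se = np.sort(edges, axis=1)
    uniq, counts = np.unique(se, axis=0, return_counts=True)
    boundary = {tuple(e) for e in uniq[counts == 1]}
    rim = []
    for a, b in edges:
        if tuple(sorted((a, b))) in boundary:
            # edge (a, b) wound as in its single adjacent face
            rim.append((a, b, b + n))
            rim.append((a, b + n, a + n))
    if rim:
        faces.append(np.array(rim))
    shell = trimesh.Trimesh(vertices=np.vstack([v0, v1]),
                            faces=np.vstack(faces), process=False)
    if shell.volume < 0:
        shell.invert()
    return shell


def create_pdl_layer(root_surface: trimesh.Trimesh, thickness: float = 0.1
                     ) -> trimesh.Trimesh:
    """Create the PDL as a uniform outward offset shell of the root surface.

    The outer root surface is thickened by ``thickness`` (default 0.1 mm)
    along the vertex normals and the enclosed volume is returned as a
    watertight solid.  Open surfaces (e.g. a root wall cut at the CEJ) are
    closed along their rim.
    """
    if not thickness > 0:
        raise GeometryError("PDL thickness must be > 0 (empty shell)")
    return _stitch_shell(root_surface,
                         np.full(len(root_surface.vertices), float(thickness)))


def create_cementum_layer(root_surface: trimesh.Trimesh,
                          cej_point, apex_point,
                          thicknesses: tuple[float, float, float] = (0.05, 0.10, 0.15),
                          ) -> trimesh.Trimesh:
    """Create the graded cementum shell on a root surface.

    Thickness steps through ``thicknesses`` by thirds of the axial height
    from the CEJ (50 um) to the apex (150 um).
    """
    cej = np.asarray(cej_point, dtype=float)
    apex = np.asarray(apex_point, dtype=float)
    height = np.linalg.norm(apex - cej)
    if height <= 1e-9:
        raise GeometryError("apex_point coincides with the CEJ plane; "
                            "root height is zero")
    edge = root_surface.edges_unique_length.mean()
    if height < 3.0 * edge:
        raise GeometryError(
            f"root height {height:.3f} mm shorter than 3 mesh edge lengths "
            f"({3 * edge:.3f} mm): cannot resolve three cementum steps")
    axis = (apex - cej) / height
    h = np.clip((root_surface.vertices - cej) @ axis / height, 0.0, 1.0)
    steps = np.asarray(thicknesses, dtype=float)
    t = steps[np.minimum((h * 3.0).astype(int), 2)]
    return _stitch_shell(root_surface, t)


# ---------------------------------------------------------------------------
# surface import

@dataclass
class ImportedToothModel:
    """Tooth model assembled from user-supplied per-tissue surface meshes.

    Supports validation, PDL synthesis and re-export; volumetric meshing
    is available for parametric models only.
    """

    solids: dict[str, trimesh.Trimesh]
    root_axis: np.ndarray
    cej_z: float | None = None
    attachment_reduction: float = 0.0

    def export_surfaces(self, directory, file_format: str = "stl"
                        ) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for tissue, solid in self.solids.items():
            path = directory / f"{tissue}.{file_format}"
            solid.export(path)
            paths[tissue] = path
        return paths


def _overlap_fraction(a: trimesh.Trimesh, b: trimesh.Trimesh,
                      n: int = 400, seed: int = 0) -> float:
    """Fraction of the interior of a that lies inside b (Monte Carlo)."""
    if not np.any((a.bounds[0] < b.bounds[1]) & (b.bounds[0] < a.bounds[1])):
        return 0.0
    rng = np.random.default_rng(seed)
    lo, hi = a.bounds
    inside_a = np.empty((0, 3))
    for _ in range(20):
        pts = rng.uniform(lo, hi, size=(n, 3))
        inside_a = np.vstack([inside_a, pts[points_in_mesh(a, pts)]])
        if len(inside_a) >= n:
            break
    if len(inside_a) == 0:
        return 0.0
    return float(np.mean(points_in_mesh(b, inside_a[:n])))


def import_surfaces(paths: dict[str, str | Path],
                    config: dict | None = None,
                    generate_pdl: bool = False) -> ImportedToothModel:
    """Assemble a model from per-tissue STL/PLY surface files.

    Each file must be a watertight solid in mm.  Checks: watertightness,
    unit sanity (bounding box below 1 m), and pairwise interior overlap.
    A missing PDL can be synthesized from the root portion of the dentin
    surface with ``generate_pdl=True`` (requires ``config['cej_z']``).
    """
    config = config or {}
    solids: dict[str, trimesh.Trimesh] = {}
    for tissue, path in paths.items():
        # process=True merges the per-face duplicate vertices of STL
        mesh = trimesh.load(str(path), force="mesh", process=True)
        if not mesh.is_watertight:
            raise GeometryError(f"surface for {tissue!r} ({path}) is not watertight")
        extent = float(np.max(mesh.extents))
        if extent > 1000.0:
            raise GeometryError(
                f"surface for {tissue!r} has bounding box {extent:.0f} mm "
                "(> 1 m): units look suspicious, expected mm")
        solids[tissue] = mesh
    names = sorted(solids)
    for i, ta in enumerate(names):
        for tb in names[i + 1:]:
            frac = _overlap_fraction(solids[ta], solids[tb])
            if frac > 0.02:
                raise GeometryError(
                    f"tissue solids {ta!r} and {tb!r} overlap "
                    f"({frac:.0%} of {ta!r} interior inside {tb!r})")
    cej_z = config.get("cej_z")
    if "pdl" not in solids and generate_pdl:
        source = solids.get("cementum", solids.get("dentin"))
        if source is None or cej_z is None:
            raise GeometryError(
                "generate_pdl requires a dentin/cementum surface and "
                "config['cej_z']")
        centroids = source.triangles_center
        root_faces = np.where(centroids[:, 2] > cej_z)[0]
        sub = source.submesh([root_faces], append=True)
        solids["pdl"] = create_pdl_layer(sub, config.get("pdl_thickness", 0.1))
    axis = np.asarray(config.get("root_axis", (0.0, 0.0, 1.0)), dtype=float)
    return ImportedToothModel(solids=solids, root_axis=axis, cej_z=cej_z)
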