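"""Static linear-elasticity solver on region-tagged tet meshes.

Standard displacement-based finite elements: linear (4-node) or
quadratic (10-node) tetrahedra, isotropic Hooke's law per tissue region,
fixed supports on a named boundary facet set, and traction loading on a
named surface patch.  Quadratic elements are the default: the thin,
bending-dominated PDL shell and its near-incompressible response
(nu = 0.45) are handled poorly by linear tets.

The occlusal load protocol ramps a terminal force linearly over
``n_steps``; since the model is linear the intermediate steps are exact
scalings of a single factorized solve, which is verified on every run
rather than assumed.  Units: mm, N, MPa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .materials import MaterialSpec, get_material, isotropic_elastic_tensor
from .meshing import FEMesh

__all__ = [
    "LoadProtocol",
    "SolutionField",
    "LinearSystem",
    "ConstrainedSystem",
    "SolverError",
    "assemble",
    "apply_supports",
    "traction_load",
    "run_load_protocol",
    "solve_terminal",
    "resultant_force",
    "compute_stress",
]


class SolverError(RuntimeError):
    """Ill-posed or failed solve (missing support, singular system...)."""


@dataclass(frozen=True)
class LoadProtocol:
    """Occlusal load ramp.

    ``terminal_force`` is (axial_N, transverse_N): the axial component
    acts along +root-axis (apically, pressing the tooth into its socket,
    as during jaw closure) and the transverse component along the
    ventral unit vector.  The force at step k of ``n_steps`` is
    (k / n_steps) x terminal force (linear ramp).  The default per-tooth
    terminal force (70, 35) N is a tenth of the full-arch masticatory
    muscle force (700, 350) N; see the calibration mode in
    :mod:`periofem.experiments` for anchoring absolute pressures.
    """

    n_steps: int = 70
    terminal_force: tuple[float, float] = (70.0, 35.0)
    application: str = "occlusal_patch"
    axial_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    transverse_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    def force_vector(self) -> np.ndarray:
        axial, transverse = self.terminal_force
        return (axial * np.asarray(self.axial_direction, dtype=float)
                + transverse * np.asarray(self.transverse_direction, dtype=float))

    def scaled(self, factor: float) -> "LoadProtocol":
        a, t = self.terminal_force
        return LoadProtocol(self.n_steps, (a * factor, t * factor),
                            self.application, self.axial_direction,
                            self.transverse_direction)


def resultant_force(protocol: LoadProtocol) -> float:
    """Euclidean norm of the terminal force components, in N."""
    return float(np.hypot(*protocol.terminal_force))


@dataclass
class SolutionField:
    """Nodal displacements and element stresses at one load fraction."""

    displacements: np.ndarray      # (n_nodes, 3) mm
    stress: np.ndarray             # (n_elements, 6) Voigt MPa
    load_fraction: float
    applied_force: np.ndarray      # (3,) N
    equilibrium_rel_error: float = np.nan
    linearity_rel_error: float = np.nan
    materials: dict | None = None  # region -> MaterialSpec, for re-evaluation

    def scaled(self, fraction: float) -> "SolutionField":
        s = fraction / self.load_fraction
        return SolutionField(self.displacements * s, self.stress * s,
                             fraction, self.applied_force * s,
                             self.equilibrium_rel_error,
                             self.linearity_rel_error, self.materials)


# ---------------------------------------------------------------------------
# element matrices

_DN_T4 = np.array([[-1.0, -1.0, -1.0],
                   [1.0, 0.0, 0.0],
                   [0.0, 1.0, 0.0],
                   [0.0, 0.0, 1.0]])

_TET_EDGES = ((0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3))

# 4-point Gauss rule on the tetrahedron (degree 2, exact for the affine
# quadratic-element stiffness)
_GA = 0.5854101966249685
_GB = 0.1381966011250105
_GAUSS_T10 = np.array([
    [_GA, _GB, _GB, _GB],
    [_GB, _GA, _GB, _GB],
    [_GB, _GB, _GA, _GB],
    [_GB, _GB, _GB, _GA],
])  # barycentric (lambda0..lambda3)
_CENTROID = np.full((1, 4), 0.25)


def _dn_dlambda_t10(bary: np.ndarray) -> np.ndarray:
    """d N_a / d lambda_b for the 10-node tet at given barycentric points;
    shape (n_pts, 10, 4)."""
    npts = len(bary)
    out = np.zeros((npts, 10, 4))
    for a in range(4):
        out[:, a, a] = 4.0 * bary[:, a] - 1.0
    for e, (a, b) in enumerate(_TET_EDGES):
        out[:, 4 + e, a] = 4.0 * bary[:, b]
        out[:, 4 + e, b] = 4.0 * bary[:, a]
    return out


def _element_geometry(nodes: np.ndarray, elems: np.ndarray):
    """Return (volumes, dL/dx) with dL/dx of shape (m, 4, 3)."""
    x = nodes[elems[:, :4]]
    e = x[:, 1:] - x[:, :1]                       # (m, 3, 3) edge vectors
    det = np.linalg.det(e)
    vol = det / 6.0
    inv_et = np.linalg.inv(np.swapaxes(e, 1, 2))  # inv(E^T), (m, 3, 3)
    dldx = np.empty((len(elems), 4, 3))
    dldx[:, 1:] = inv_et
    dldx[:, 0] = -inv_et.sum(axis=1)
    return vol, dldx


def _b_matrix(dndx: np.ndarray) -> np.ndarray:
    """Strain-displacement matrix from shape gradients (m, k, 3) ->
    (m, 6, 3k), Voigt [xx, yy, zz, yz, xz, xy] with engineering shear."""
    m, k, _ = dndx.shape
    b = np.zeros((m, 6, 3 * k))
    dx, dy, dz = dndx[:, :, 0], dndx[:, :, 1], dndx[:, :, 2]
    b[:, 0, 0::3] = dx
    b[:, 1, 1::3] = dy
    b[:, 2, 2::3] = dz
    b[:, 3, 1::3] = dz
    b[:, 3, 2::3] = dy
    b[:, 4, 0::3] = dz
    b[:, 4, 2::3] = dx
    b[:, 5, 0::3] = dy
    b[:, 5, 1::3] = dx
    return b


def _resolve_materials(mesh: FEMesh, materials) -> dict[str, MaterialSpec]:
    out = {}
    for name in mesh.region_names:
        if not np.any(mesh.region_id == mesh.region_names.index(name)):
            continue
        if materials is not None and name in materials:
            out[name] = materials[name]
        else:
            out[name] = get_material(name)
    return out


@dataclass
class LinearSystem:
    """Assembled (unconstrained) stiffness with its mesh and materials."""

    stiffness: sp.csr_matrix
    mesh: FEMesh
    materials: dict[str, MaterialSpec]


def assemble(mesh: FEMesh, materials: dict[str, MaterialSpec] | None = None
             ) -> LinearSystem:
    """Assemble the global stiffness matrix.

    ``materials`` maps region names to :class:`MaterialSpec`; regions not
    present fall back to the tissue library.  The unconstrained matrix is
    symmetric positive-semidefinite with the six rigid-body modes in its
    null space.
    """
    mats = _resolve_materials(mesh, materials)
    n_en = mesh.elems.shape[1]
    vol, dldx = _element_geometry(mesh.nodes, mesh.elems)
    if np.any(vol <= 0):
        raise SolverError("mesh contains inverted elements")

    ndof = 3 * mesh.n_nodes
    data_blocks, row_blocks, col_blocks = [], [], []
    for name, spec in mats.items():
        rid = mesh.region_names.index(name)
        sel = np.where(mesh.region_id == rid)[0]
        if len(sel) == 0:
            continue
        c = isotropic_elastic_tensor(spec)
        v = vol[sel]
        if n_en == 4:
            b = _b_matrix(dldx[sel] @ np.eye(3))  # dndx == dldx for tet4
            ke = np.einsum("mia,ij,mjb,m->mab", b, c, b, v, optimize=True)
        else:
            ke = np.zeros((len(sel), 30, 30))
            dn = _dn_dlambda_t10(_GAUSS_T10)      # (4, 10, 4)
            for g in range(4):
                dndx = np.einsum("pa,mac->mpc", dn[g], dldx[sel])
                b = _b_matrix(dndx)
                ke += 0.25 * np.einsum("mia,ij,mjb,m->mab", b, c, b, v,
                                       optimize=True)
        edof = (3 * mesh.elems[sel][:, :, None]
                + np.arange(3)[None, None, :]).reshape(len(sel), 3 * n_en)
        row_blocks.append(np.repeat(edof, 3 * n_en, axis=1).ravel())
        col_blocks.append(np.tile(edof, (1, 3 * n_en)).ravel())
        data_blocks.append(ke.ravel())

    k = sp.coo_matrix(
        (np.concatenate(data_blocks),
         (np.concatenate(row_blocks), np.concatenate(col_blocks))),
        shape=(ndof, ndof)).tocsr()
    return LinearSystem(stiffness=k, mesh=mesh, materials=mats)


# ---------------------------------------------------------------------------
# constraints and loads

@dataclass
class ConstrainedSystem:
    """Linear system with fixed-displacement supports eliminated."""

    system: LinearSystem
    fixed_dofs: np.ndarray
    free_dofs: np.ndarray
    _lu: object = field(default=None, repr=False)

    @property
    def mesh(self) -> FEMesh:
        return self.system.mesh

    def _factor(self):
        if self._lu is None:
            kff = self.system.stiffness[self.free_dofs][:, self.free_dofs]
            try:
                # MMD on A^T+A: far less fill than COLAMD for the
                # symmetric elasticity stiffness
                self._lu = splu(kff.tocsc(), permc_spec="MMD_AT_PLUS_A",
                                options={"SymmetricMode": True})
            except RuntimeError as exc:
                raise SolverError(f"factorization failed: {exc}") from exc
        return self._lu

    def solve(self, f: np.ndarray) -> np.ndarray:
        u = np.zeros_like(f)
        u[self.free_dofs] = self._factor().solve(f[self.free_dofs])
        if not np.all(np.isfinite(u)):
            raise SolverError("singular system: solution is not finite "
                              "(model unsupported?)")
        return u

    def reactions(self, u: np.ndarray, f: np.ndarray) -> np.ndarray:
        r = self.system.stiffness @ u - f
        out = np.zeros_like(f)
        out[self.fixed_dofs] = r[self.fixed_dofs]
        return out


def apply_supports(system: LinearSystem, mesh: FEMesh,
                   support="outer_bone_boundary",
                   kind: str = "fixed",
                   use_symmetry: bool = True) -> ConstrainedSystem:
    """Constrain displacements to zero on boundary facet sets.

    ``support`` is a facet-set name (all three components fixed) or a
    list of ``(name, components)`` pairs for roller-style constraints,
    e.g. ``[("zmin", (2,)), ("xmin", (0,))]``.

    On half meshes (``mesh.symmetry_factor == 2``) the normal displacement
    u_y is additionally constrained to zero on the ``symmetry_plane``
    facet set, which is the exact mirror-symmetry condition.
    """
    if kind != "fixed":
        raise ValueError("only fixed supports are implemented")
    if isinstance(support, str):
        support = [(support, (0, 1, 2))]
    fixed = np.empty(0, dtype=np.int64)
    total_nodes = 0
    for name, comps in support:
        fs = mesh.facet_sets.get(name)
        if fs is None or len(fs) == 0:
            raise SolverError(
                f"support facet set {name!r} is empty: problem is ill-posed")
        nodes = np.unique(fs.nodes)
        total_nodes += len(nodes)
        for c in comps:
            fixed = np.union1d(fixed, 3 * nodes + c)
    if total_nodes == 1:
        warnings.warn("support acts on a single node (point constraint)")
    sym = mesh.facet_sets.get("symmetry_plane")
    if use_symmetry and sym is not None and len(sym):
        fixed = np.union1d(fixed, 3 * np.unique(sym.nodes) + 1)
    free = np.setdiff1d(np.arange(3 * mesh.n_nodes), fixed)
    return ConstrainedSystem(system=system, fixed_dofs=fixed, free_dofs=free)


def traction_load(mesh: FEMesh, facet_set: str, traction: np.ndarray
                  ) -> np.ndarray:
    """Consistent nodal load vector for a uniform traction (MPa) on a
    named facet set."""
    fs = mesh.facet_sets.get(facet_set)
    if fs is None or len(fs) == 0:
        raise SolverError(f"facet set {facet_set!r} is empty")
    areas = fs.areas(mesh.nodes)
    f = np.zeros(3 * mesh.n_nodes)
    t = np.asarray(traction, dtype=float)
    if mesh.order == 1:
        # A/3 per corner node
        for j in range(3):
            w = areas / 3.0
            for comp in range(3):
                np.add.at(f, 3 * fs.nodes[:, j] + comp, w * t[comp])
    else:
        # quadratic triangle, uniform traction: corners get 0, midsides A/3
        for j in range(3, 6):
            w = areas / 3.0
            for comp in range(3):
                np.add.at(f, 3 * fs.nodes[:, j] + comp, w * t[comp])
    return f


# ---------------------------------------------------------------------------
# stress recovery and the load protocol

def compute_stress(mesh: FEMesh, u: np.ndarray,
                   materials: dict[str, MaterialSpec]) -> np.ndarray:
    """Per-element Cauchy stress (Voigt, MPa) at the element centroid."""
    vol, dldx = _element_geometry(mesh.nodes, mesh.elems)
    n_en = mesh.elems.shape[1]
    stress = np.empty((mesh.n_elements, 6))
    uflat = u.reshape(-1)
    for name, spec in materials.items():
        rid = mesh.region_names.index(name)
        sel = np.where(mesh.region_id == rid)[0]
        if len(sel) == 0:
            continue
        c = isotropic_elastic_tensor(spec)
        if n_en == 4:
            dndx = dldx[sel]
        else:
            dn = _dn_dlambda_t10(_CENTROID)[0]    # (10, 4)
            dndx = np.einsum("pa,mac->mpc", dn, dldx[sel])
        b = _b_matrix(dndx)
        edof = (3 * mesh.elems[sel][:, :, None]
                + np.arange(3)[None, None, :]).reshape(len(sel), 3 * n_en)
        strain = np.einsum("mik,mk->mi", b, uflat[edof])
        stress[sel] = strain @ c.T
    return stress


def stress_at_points(mesh: FEMesh, u: np.ndarray,
                     materials: dict[str, MaterialSpec],
                     elem_ids: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Cauchy stress (Voigt) of given elements evaluated at given points.

    For quadratic elements the strain varies linearly within the element,
    so evaluating at e.g. an interface facet centroid (instead of the
    element centroid) removes the sampling offset between the two
    one-sided recoveries of an interface traction.
    """
    elem_ids = np.asarray(elem_ids)
    points = np.asarray(points)
    elems = mesh.elems[elem_ids]
    n_en = elems.shape[1]
    _, dldx_all = _element_geometry(mesh.nodes, mesh.elems[elem_ids])
    # barycentric coordinates of the target points
    x = mesh.nodes[elems[:, :4]]
    a = np.concatenate([np.ones((len(elems), 1, 4)),
                        np.swapaxes(x, 1, 2)], axis=1)
    rhs = np.concatenate([np.ones((len(points), 1)), points], axis=1)
    bary = np.linalg.solve(a, rhs[:, :, None])[:, :, 0]
    uflat = u.reshape(-1)
    out = np.empty((len(elem_ids), 6))
    for name, spec in materials.items():
        if name not in mesh.region_names:
            continue
        rid = mesh.region_names.index(name)
        sel = np.where(mesh.region_id[elem_ids] == rid)[0]
        if len(sel) == 0:
            continue
        c = isotropic_elastic_tensor(spec)
        if n_en == 4:
            dndx = dldx_all[sel]
        else:
            dn = _dn_dlambda_t10(bary[sel])        # (s, 10, 4)
            dndx = np.einsum("spa,sac->spc", dn, dldx_all[sel])
        b = _b_matrix(dndx)
        edof = (3 * elems[sel][:, :, None]
                + np.arange(3)[None, None, :]).reshape(len(sel), 3 * n_en)
        strain = np.einsum("sik,sk->si", b, uflat[edof])
        out[sel] = strain @ c.T
    return out


def solve_terminal(csys: ConstrainedSystem, protocol: LoadProtocol,
                   check: bool = True) -> SolutionField:
    """Solve at the terminal load and verify equilibrium and linearity."""
    mesh = csys.mesh
    fs = mesh.facet_sets.get(protocol.application)
    if fs is None or len(fs) == 0:
        raise SolverError(f"load application set {protocol.application!r} "
                          "is empty")
    area = fs.areas(mesh.nodes).sum()
    force = protocol.force_vector()
    factor = getattr(mesh, "symmetry_factor", 1.0)
    if factor > 1.0 and abs(force[1]) > 1e-12 * np.linalg.norm(force):
        raise SolverError("half (symmetric) mesh requires the load to lie "
                          "in the symmetry plane; re-mesh with "
                          "symmetric=False for general load directions")
    # traction is intensive: full force over full area; the half model
    # carries half the force on half the patch
    force = force / factor
    f = traction_load(mesh, protocol.application, force * factor
                      / (area * factor))
    u = csys.solve(f)
    eq_err = lin_err = np.nan
    if check:
        r = csys.reactions(u, f)
        total_r = r.reshape(-1, 3).sum(axis=0)
        eq_err = float(np.linalg.norm(total_r + force)
                       / max(np.linalg.norm(force), 1e-300))
        u_frac = csys.solve(0.37 * f)
        lin_err = float(np.linalg.norm(u_frac - 0.37 * u)
                        / max(np.linalg.norm(u), 1e-300))
    stress = compute_stress(mesh, u.reshape(-1, 3), csys.system.materials)
    return SolutionField(displacements=u.reshape(-1, 3), stress=stress,
                         load_fraction=1.0, applied_force=force,
                         equilibrium_rel_error=eq_err,
                         linearity_rel_error=lin_err,
                         materials=csys.system.materials)


def run_load_protocol(csys: ConstrainedSystem, protocol: LoadProtocol
                      ) -> list[SolutionField]:
    """Solve the full ramp; step k is the verified linear scaling of the
    terminal solve (identical results to re-solving, one factorization)."""
    terminal = solve_terminal(csys, protocol)
    fractions = np.arange(1, protocol.n_steps + 1) / protocol.n_steps
    return [terminal.scaled(fr) if fr != 1.0 else terminal
            for fr in fractions]
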