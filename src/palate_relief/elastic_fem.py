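"""Small-strain isotropic linear-elastic solver on 4-node tetrahedra.

Constant-strain tetrahedra (tet4), sparse symmetric assembly, exact
Dirichlet elimination and direct factorization.  Stresses are recovered
per element (piecewise constant) together with the von Mises invariant

    sigma_vM = sqrt(3/2 * s : s),   s = sigma - tr(sigma)/3 * I,

which is the quantity thresholded by the relief procedure.  Units are
mm-N-MPa: coordinates mm, forces N, moduli and stresses MPa.

Voigt ordering used throughout: (xx, yy, zz, xy, yz, zx) with engineering
shear strains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla

from .meshgen import TetMesh, PART_NAMES, PART_PLATE, tet_volumes

__all__ = [
    "MaterialParams",
    "BoundaryConditions",
    "DisplacementField",
    "StressField",
    "SingularSystemError",
    "LoadPatchError",
    "element_stiffness",
    "assemble_stiffness",
    "assemble_and_solve",
    "recover_stress",
    "von_mises",
    "make_load",
    "pressure_load",
    "surface_triangles",
    "PLATE_RESIN",
    "MUCOSA_DEFAULT",
]


class SingularSystemError(RuntimeError):
    """The constrained system is singular (e.g. a floating part)."""


class LoadPatchError(ValueError):
    """The requested load patch contains no nodes."""


@dataclass(frozen=True)
class MaterialParams:
    """Isotropic linear-elastic constants: Young's modulus (MPa), Poisson."""

    young_modulus: float
    poisson_ratio: float

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise ValueError(f"young_modulus must be > 0, got {self.young_modulus}")
        if not 0.0 < self.poisson_ratio < 0.5:
            raise ValueError(
                f"poisson_ratio must be in (0, 0.5), got {self.poisson_ratio}"
            )

    @property
    def d_matrix(self) -> np.ndarray:
        """6x6 isotropic constitutive matrix (Voigt, engineering shears)."""
        E, nu = self.young_modulus, self.poisson_ratio
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.arange(3), np.arange(3)] += 2 * mu
        D[np.arange(3, 6), np.arange(3, 6)] = mu
        return D


#: Acrylic resin of the pseudopalatal plate in a humid environment.
PLATE_RESIN = MaterialParams(young_modulus=2650.0, poisson_ratio=0.3)
#: Representative palatal mucosa (the subject-specific modulus is a free
#: parameter of every study; this is a literature-typical default).
MUCOSA_DEFAULT = MaterialParams(young_modulus=3.0, poisson_ratio=0.45)


@dataclass
class BoundaryConditions:
    """Dirichlet constraints and nodal loads for one solve.

    ``fixed_nodes`` are clamped in all three components (the mucosa top
    surface bonded to bone).  ``prescribed_dofs``/``prescribed_values``
    allow per-component constraints (rollers, patch-test fields); dof index
    is ``3 * node + component``.  ``loads`` is a dense (N, 3) nodal force
    array in N.
    """

    fixed_nodes: np.ndarray
    loads: np.ndarray
    prescribed_dofs: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    prescribed_values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def all_prescribed(self, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
        """All constrained dofs and their values, deduplicated."""
        fixed = (3 * np.asarray(self.fixed_nodes, dtype=np.int64)[:, None]
                 + np.arange(3)).ravel()
        dofs = np.concatenate([fixed, np.asarray(self.prescribed_dofs, dtype=np.int64)])
        vals = np.concatenate([np.zeros(len(fixed)), np.asarray(self.prescribed_values, dtype=float)])
        # keep the last assignment for duplicated dofs
        _, idx = np.unique(dofs[::-1], return_index=True)
        idx = len(dofs) - 1 - idx
        return dofs[idx], vals[idx]


@dataclass
class DisplacementField:
    """Nodal displacements (mm) with reactions (N) at constrained dofs."""

    values: np.ndarray  # (N, 3)
    reactions: np.ndarray  # (N, 3), nonzero only at constrained dofs
    residual: float  # relative residual of the reduced solve


@dataclass
class StressField:
    """Per-element stress: Voigt tensor (xx,yy,zz,xy,yz,zx) and von Mises, MPa."""

    tensor: np.ndarray  # (M, 6)
    vm: np.ndarray  # (M,)


def von_mises(tensor: np.ndarray) -> np.ndarray:
    """Von Mises invariant of Voigt stress rows (xx,yy,zz,xy,yz,zx)."""
    t = np.atleast_2d(tensor)
    sx, sy, sz, txy, tyz, tzx = (t[:, i] for i in range(6))
    vm2 = 0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2) + 3.0 * (
        txy**2 + tyz**2 + tzx**2
    )
    return np.sqrt(np.maximum(vm2, 0.0))


def _shape_gradients(nodes: np.ndarray, tets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of the four linear shape functions per element.

    Returns ``(grads, vols)`` with grads of shape (M, 4, 3): row j is
    grad(N_j), constant over the element.
    """
    coords = nodes[tets]  # (M, 4, 3)
    mat = np.concatenate([np.ones((len(tets), 4, 1)), coords], axis=2)  # (M,4,4)
    det = np.linalg.det(mat)
    vols = det / 6.0
    if np.any(vols <= 0):
        raise ValueError("degenerate or inverted tetrahedron (non-positive volume)")
    inv = np.linalg.inv(mat)  # (M, 4, 4)
    grads = inv[:, 1:4, :].transpose(0, 2, 1)  # (M, 4, 3)
    return grads, vols


def _b_matrices(grads: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices, (M, 6, 12)."""
    m = len(grads)
    B = np.zeros((m, 6, 12))
    for j in range(4):
        gx, gy, gz = grads[:, j, 0], grads[:, j, 1], grads[:, j, 2]
        c = 3 * j
        B[:, 0, c + 0] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 0] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c + 0] = gz
        B[:, 5, c + 2] = gx
    return B


def element_stiffness(tet_coords: np.ndarray, material: MaterialParams) -> np.ndarray:
    """12x12 stiffness (N/mm) of one constant-strain tetrahedron."""
    tet_coords = np.asarray(tet_coords, dtype=float).reshape(1, 4, 3)
    grads, vols = _shape_gradients(tet_coords[0], np.arange(4).reshape(1, 4))
    B = _b_matrices(grads)[0]
    return float(vols[0]) * B.T @ material.d_matrix @ B


def _material_for(part_code: int, materials) -> MaterialParams:
    if isinstance(materials, MaterialParams):
        return materials
    if part_code in materials:
        return materials[part_code]
    name = PART_NAMES.get(part_code)
    if name is not None and name in materials:
        return materials[name]
    raise KeyError(f"no material given for part {name or part_code}")


def assemble_stiffness(mesh: TetMesh, materials) -> sp.csr_matrix:
    """Global stiffness matrix (3N x 3N, CSR).

    ``materials`` is a single :class:`MaterialParams` or a mapping from part
    (code or name ``"plate"``/``"mucosa"``) to parameters.
    """
    grads, vols = _shape_gradients(mesh.nodes, mesh.tets)
    B = _b_matrices(grads)
    Ke = np.zeros((mesh.n_tets, 12, 12))
    for code in np.unique(mesh.part):
        D = _material_for(int(code), materials).d_matrix
        m = mesh.part == code
        Ke[m] = np.einsum("eik,ij,ejl->ekl", B[m], D, B[m]) * vols[m, None, None]

    dof = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(mesh.n_tets, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    n = 3 * mesh.n_nodes
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return K


def _check_constrained_components(mesh: TetMesh, prescribed_dofs: np.ndarray) -> None:
    """Every connected node component must contain a constrained node."""
    i = np.repeat(mesh.tets, 4, axis=1).ravel()
    j = np.tile(mesh.tets, (1, 4)).ravel()
    adj = sp.coo_matrix(
        (np.ones(len(i), dtype=np.int8), (i, j)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsr()
    n_comp, labels = csgraph.connected_components(adj, directed=False)
    constrained_nodes = np.unique(prescribed_dofs // 3)
    ok = np.zeros(n_comp, dtype=bool)
    ok[np.unique(labels[constrained_nodes])] = True
    if ok.all():
        return
    # name the floating components by the parts they contain
    bad = []
    node_part = np.zeros(mesh.n_nodes, dtype=np.int64)
    for code in np.unique(mesh.part):
        node_part[np.unique(mesh.tets[mesh.part == code])] = code
    for comp in np.flatnonzero(~ok):
        parts = sorted(
            PART_NAMES.get(int(c), str(c))
            for c in np.unique(node_part[labels == comp])
        )
        bad.append(f"component of {int(np.sum(labels == comp))} nodes"
                   f" (parts: {', '.join(parts)})")
    raise SingularSystemError(
        "unconstrained rigid-body modes: no Dirichlet constraint reaches "
        + "; ".join(bad)
    )


def assemble_and_solve(
    mesh: TetMesh, materials, bcs: BoundaryConditions
) -> DisplacementField:
    """Solve K u = f with exact elimination of prescribed dofs.

    Uses a sparse direct factorization; the relative residual of the
    reduced system is checked against 1e-8.  Reactions are recovered as
    ``K u - f`` at the constrained dofs; global equilibrium (reactions
    balancing the applied load) holds to solver precision.
    """
    n_dof = 3 * mesh.n_nodes
    p_dofs, p_vals = bcs.all_prescribed(mesh.n_nodes)
    if len(p_dofs) == 0:
        raise SingularSystemError("no Dirichlet constraints: the model floats")
    _check_constrained_components(mesh, p_dofs)

    K = assemble_stiffness(mesh, materials)
    f = np.asarray(bcs.loads, dtype=float).ravel()
    if f.shape != (n_dof,):
        raise ValueError(f"loads must have shape ({mesh.n_nodes}, 3)")

    free = np.setdiff1d(np.arange(n_dof), p_dofs, assume_unique=False)
    u = np.zeros(n_dof)
    u[p_dofs] = p_vals

    K_ff = K[free][:, free].tocsc()
    rhs = f[free] - K[free][:, p_dofs] @ p_vals
    try:
        lu = spla.splu(K_ff)
        u_f = lu.solve(rhs)
    except RuntimeError as exc:  # exactly singular factor
        raise SingularSystemError(f"singular stiffness matrix: {exc}") from exc
    if not np.all(np.isfinite(u_f)):
        raise SingularSystemError("singular stiffness matrix: non-finite solution")
    u[free] = u_f

    rhs_norm = np.linalg.norm(rhs)
    res = np.linalg.norm(K_ff @ u_f - rhs)
    residual = res / rhs_norm if rhs_norm > 0 else res
    if residual > 1e-8:
        raise SingularSystemError(
            f"direct solve did not converge: relative residual {residual:.3e}"
        )

    r = np.zeros(n_dof)
    r[p_dofs] = (K[p_dofs] @ u) - f[p_dofs]
    return DisplacementField(
        values=u.reshape(-1, 3), reactions=r.reshape(-1, 3), residual=float(residual)
    )


def recover_stress(mesh: TetMesh, materials, u: DisplacementField | np.ndarray) -> StressField:
    """Piecewise-constant stress tensor and von Mises per element."""
    uv = u.values if isinstance(u, DisplacementField) else np.asarray(u, dtype=float)
    grads, _ = _shape_gradients(mesh.nodes, mesh.tets)
    B = _b_matrices(grads)
    ue = uv[mesh.tets].reshape(mesh.n_tets, 12)
    strain = np.einsum("eij,ej->ei", B, ue)
    stress = np.empty_like(strain)
    for code in np.unique(mesh.part):
        D = _material_for(int(code), materials).d_matrix
        m = mesh.part == code
        stress[m] = strain[m] @ D.T
    return StressField(tensor=stress, vm=von_mises(stress))


def surface_triangles(mesh: TetMesh, node_set: str) -> np.ndarray:
    """Boundary triangles all of whose nodes lie in ``node_set``."""
    faces = mesh.boundary_faces()
    members = np.zeros(mesh.n_nodes, dtype=bool)
    members[mesh.node_sets[node_set]] = True
    return faces[members[faces].all(axis=1)]


def _nodal_areas(mesh: TetMesh, tris: np.ndarray) -> np.ndarray:
    """Tributary area per node from a triangle set (A/3 to each vertex)."""
    p = mesh.nodes[tris]
    areas = 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
    )
    out = np.zeros(mesh.n_nodes)
    np.add.at(out, tris.ravel(), np.repeat(areas / 3.0, 3))
    return out


def pressure_load(mesh: TetMesh, node_set: str, traction: np.ndarray) -> np.ndarray:
    """Consistent nodal loads (N, 3) for a uniform traction (MPa) on a surface."""
    tris = surface_triangles(mesh, node_set)
    w = _nodal_areas(mesh, tris)
    return w[:, None] * np.asarray(traction, dtype=float)[None, :]


def make_load(
    mesh: TetMesh,
    total_force: float = 111.0,
    patch_radius: float = 3.0,
    fixed_set: str = "bone_surface",
    surface_set: str = "oral_surface",
) -> BoundaryConditions:
    """Bite load on the plate's oral surface plus the bone-surface clamp.

    The force (default 111 N, the subject's pain-onset bite force) acts in
    the ``-z`` sense — pressing the plate onto the mucosa — distributed
    over oral-surface nodes within ``patch_radius`` (footprint distance) of
    the plate centre, weighted by nodal tributary area.  The distributed
    components sum to the total force exactly; a patch that degenerates to
    a single node is allowed but warned about, an empty patch is an error.
    """
    if total_force <= 0:
        raise ValueError(f"total_force must be > 0, got {total_force}")
    tris = surface_triangles(mesh, surface_set)
    w = _nodal_areas(mesh, tris)
    surf = mesh.node_sets[surface_set]
    xy = mesh.nodes[surf, :2]
    center = 0.5 * (xy.min(axis=0) + xy.max(axis=0))
    dist = np.linalg.norm(xy - center, axis=1)
    patch = surf[dist <= patch_radius]
    if len(patch) == 0:
        raise LoadPatchError(
            f"no {surface_set} nodes within {patch_radius} mm of the plate centre"
        )
    if len(patch) == 1:
        warnings.warn(
            "load patch contains a single node; expect a local stress "
            "singularity under refinement",
            stacklevel=2,
        )
    weights = w[patch]
    if weights.sum() == 0:  # isolated patch nodes: fall back to equal split
        weights = np.ones(len(patch))
    weights = weights / weights.sum()
    loads = np.zeros((mesh.n_nodes, 3))
    loads[patch, 2] = -total_force * weights
    # force the float sum to the exact total
    k = patch[np.argmax(weights)]
    loads[k, 2] -= total_force + loads[patch, 2].sum()
    return BoundaryConditions(fixed_nodes=mesh.node_sets[fixed_set], loads=loads)
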