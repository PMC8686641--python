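"""Conforming labelled tetrahedral meshes of the plate-mucosa bilayer.

The mesher lays a structured grid over the footprint, extrudes node columns
through the mucosa and the plate, and splits every hexahedral cell into six
tetrahedra with the Kuhn (Freudenthal) rule.  Because the rule is applied
identically in every cell, face diagonals of neighbouring cells match and
the mesh is conforming; in particular the plate-mucosa interface is a shared
triangulated surface, which realises the bonded ("adhesion") condition by
shared nodes without an external mesh generator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .palate_synth import LayeredGeometry

__all__ = [
    "TetMesh",
    "InterfaceFacets",
    "MeshingError",
    "mesh_layered",
    "box_mesh",
    "tet_volumes",
    "PART_MUCOSA",
    "PART_PLATE",
    "PART_NAMES",
]

PART_MUCOSA = 1
PART_PLATE = 2
PART_NAMES = {PART_MUCOSA: "mucosa", PART_PLATE: "plate"}

# Kuhn split of a hexahedron: vertices indexed by corner bits (dx, dy, dz),
# the six tets are the paths 000 -> 111 through each axis permutation.
_KUHN_PATHS = (
    (0, 1, 2),
    (0, 2, 1),
    (1, 0, 2),
    (1, 2, 0),
    (2, 0, 1),
    (2, 1, 0),
)


class MeshingError(RuntimeError):
    """Raised for degenerate geometry or invalid meshing parameters."""


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volume (mm^3) of every tetrahedron."""
    p = nodes[tets]
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    c = p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


@dataclass
class InterfaceFacets:
    """Triangles shared between a mucosa tet and a plate tet.

    ``tris`` holds node triples; ``mucosa_tet``/``plate_tet`` the single
    adjacent element on each side; ``centroid_xy`` the footprint coordinate
    of each triangle centroid; ``area`` the 3D triangle area and
    ``footprint_area`` its projection onto the footprint plane (these agree
    on a flat slab).
    """

    tris: np.ndarray  # (F, 3) int
    mucosa_tet: np.ndarray  # (F,) int
    plate_tet: np.ndarray  # (F,) int
    centroid_xy: np.ndarray  # (F, 2) float
    area: np.ndarray  # (F,) float
    footprint_area: np.ndarray  # (F,) float

    def __len__(self) -> int:
        return len(self.tris)


@dataclass
class TetMesh:
    """Labelled 4-node tetrahedral mesh of the bilayer.

    ``part`` holds ``PART_MUCOSA``/``PART_PLATE`` per tet and ``segment_id``
    the mucosal segment (1..14) per mucosa tet (0 for plate tets).  Named
    node sets index into ``nodes``; the ones produced by the mesher are
    ``bone_surface`` (mucosa top, to be fixed), ``oral_surface`` (plate
    bottom, where the bite load acts) and ``interface``.

    After relief, ``relief_pairs`` records (original, duplicate) node pairs
    across the decoupled interface and ``relieved_facets`` the facet ids (in
    the pre-relief facet table) that were decoupled.
    """

    nodes: np.ndarray  # (N, 3) float, mm
    tets: np.ndarray  # (M, 4) int, positively oriented
    part: np.ndarray  # (M,) int
    segment_id: np.ndarray  # (M,) int
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    relief_pairs: np.ndarray | None = None  # (R, 2) int
    relieved_facets: np.ndarray | None = None  # (R_f,) int

    _facets: InterfaceFacets | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.part = np.ascontiguousarray(self.part, dtype=np.int64)
        self.segment_id = np.ascontiguousarray(self.segment_id, dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def volumes(self) -> np.ndarray:
        return tet_volumes(self.nodes, self.tets)

    def part_volume(self, part: int) -> float:
        return float(self.volumes()[self.part == part].sum())

    def validate(self) -> None:
        vols = self.volumes()
        if np.any(vols <= 0):
            bad = int(np.sum(vols <= 0))
            raise MeshingError(f"{bad} tetrahedra with non-positive volume")
        if self.tets.min() < 0 or self.tets.max() >= self.n_nodes:
            raise MeshingError("tet connectivity references invalid node indices")
        for name, idx in self.node_sets.items():
            if len(idx) and (idx.min() < 0 or idx.max() >= self.n_nodes):
                raise MeshingError(f"node set {name!r} references invalid indices")

    def copy(self) -> "TetMesh":
        return TetMesh(
            nodes=self.nodes.copy(),
            tets=self.tets.copy(),
            part=self.part.copy(),
            segment_id=self.segment_id.copy(),
            node_sets={k: v.copy() for k, v in self.node_sets.items()},
            relief_pairs=None if self.relief_pairs is None else self.relief_pairs.copy(),
            relieved_facets=None
            if self.relieved_facets is None
            else self.relieved_facets.copy(),
        )

    # -- interface facets ---------------------------------------------

    def interface_facets(self) -> InterfaceFacets:
        """Find (and cache) all triangles shared between the two parts."""
        if self._facets is None:
            self._facets = _find_interface_facets(self)
        return self._facets

    def boundary_faces(self) -> np.ndarray:
        """(B, 3) node triples of faces belonging to exactly one tet."""
        faces = _all_faces(self.tets)
        key = np.sort(faces, axis=1)
        _, inv, counts = np.unique(
            key, axis=0, return_inverse=True, return_counts=True
        )
        return faces[counts[inv] == 1]


_FACE_LOCAL = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


def _all_faces(tets: np.ndarray) -> np.ndarray:
    return tets[:, _FACE_LOCAL].reshape(-1, 3)


def _find_interface_facets(mesh: TetMesh) -> InterfaceFacets:
    faces = _all_faces(mesh.tets)
    owner = np.repeat(np.arange(mesh.n_tets), 4)
    key = np.sort(faces, axis=1)
    uniq, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)

    shared = np.flatnonzero(counts == 2)
    order = np.argsort(inv, kind="stable")
    # for faces appearing twice, owners are consecutive in `order`
    pos = np.searchsorted(inv[order], shared)
    o1 = owner[order[pos]]
    o2 = owner[order[pos + 1]]
    p1, p2 = mesh.part[o1], mesh.part[o2]
    mask = p1 != p2
    o1, o2 = o1[mask], o2[mask]
    tris = uniq[shared[mask]]
    mucosa_tet = np.where(mesh.part[o1] == PART_MUCOSA, o1, o2)
    plate_tet = np.where(mesh.part[o1] == PART_PLATE, o1, o2)

    # deterministic ordering by sorted node triple
    order2 = np.lexsort((tris[:, 2], tris[:, 1], tris[:, 0]))
    tris, mucosa_tet, plate_tet = tris[order2], mucosa_tet[order2], plate_tet[order2]

    p = mesh.nodes[tris]
    centroid_xy = p.mean(axis=1)[:, :2]
    cr = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    area = 0.5 * np.linalg.norm(cr, axis=1)
    footprint_area = 0.5 * np.abs(cr[:, 2])
    return InterfaceFacets(
        tris=tris,
        mucosa_tet=mucosa_tet,
        plate_tet=plate_tet,
        centroid_xy=centroid_xy,
        area=area,
        footprint_area=footprint_area,
    )


def _split_hexes(corner_ids: np.ndarray) -> np.ndarray:
    """Split hex cells into 6 tets each.

    ``corner_ids`` is (H, 2, 2, 2): node id at corner (dx, dy, dz).
    """
    tets = []
    for path in _KUHN_PATHS:
        idx = [(0, 0, 0)]
        cur = [0, 0, 0]
        for axis in path:
            cur[axis] = 1
            idx.append(tuple(cur))
        tets.append(
            np.stack([corner_ids[:, i, j, k] for (i, j, k) in idx], axis=1)
        )
    return np.concatenate(tets, axis=0)


def _orient_positive(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    vols = tet_volumes(nodes, tets)
    flip = vols < 0
    tets = tets.copy()
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    return tets


def mesh_layered(geometry: LayeredGeometry, mesh_edge: float | None = None) -> TetMesh:
    """Mesh the bilayer geometry with a structured tetrahedral grid.

    In-plane spacing is approximately ``mesh_edge`` (default: the config's
    value); through-thickness layer counts are ``ceil(thickness/mesh_edge)``
    with a minimum of 2 for the mucosa and 1 for the plate, so the mucosal
    stress gradient driving the relief decision is always resolved.
    """
    cfg = geometry.config
    h = cfg.mesh_edge if mesh_edge is None else float(mesh_edge)
    if h <= 0:
        raise MeshingError(f"mesh_edge must be > 0, got {h}")

    w, length = cfg.arch_half_width, cfg.arch_length
    nx = max(2, 2 * int(np.ceil(w / h)))  # even so the midline is a grid line
    ny = max(1, int(np.ceil(length / h)))
    t_max = geometry.thickness_map.max_thickness
    nz_m = max(2, int(np.ceil(t_max / h)))
    nz_p = max(1, int(np.ceil(cfg.plate_thickness / h)))
    nz = nz_m + nz_p

    xs = np.linspace(-w, w, nx + 1)
    ys = np.linspace(0.0, length, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")  # (nx+1, ny+1)

    zb = geometry.bone_z(X, Y)
    t = geometry.thickness(X, Y)
    if np.any(t <= 0):
        raise MeshingError("mucosa thickness must be strictly positive everywhere")
    zi = zb + t
    zo = zi + cfg.plate_thickness

    # node columns: mucosa layers 0..nz_m, plate layers nz_m..nz
    frac_m = np.arange(nz_m + 1) / nz_m
    frac_p = np.arange(1, nz_p + 1) / nz_p
    z_cols = np.concatenate(
        [
            zb[..., None] + t[..., None] * frac_m,  # (nx+1, ny+1, nz_m+1)
            zi[..., None] + cfg.plate_thickness * frac_p,  # (nx+1, ny+1, nz_p)
        ],
        axis=-1,
    )
    n_per_col = nz + 1
    nid = np.arange((nx + 1) * (ny + 1) * n_per_col).reshape(nx + 1, ny + 1, n_per_col)
    nodes = np.empty((nid.size, 3))
    nodes[:, 0] = np.broadcast_to(X[..., None], z_cols.shape).ravel()
    nodes[:, 1] = np.broadcast_to(Y[..., None], z_cols.shape).ravel()
    nodes[:, 2] = z_cols.ravel()

    # hex cells, layer by layer
    def _hex_ids(k: int) -> np.ndarray:
        c = np.empty((nx * ny, 2, 2, 2), dtype=np.int64)
        base = nid[:, :, k]
        for dx in (0, 1):
            for dy in (0, 1):
                c[:, dx, dy, 0] = base[dx : nx + dx, dy : ny + dy].ravel()
                c[:, dx, dy, 1] = nid[dx : nx + dx, dy : ny + dy, k + 1].ravel()
        return c

    all_tets, all_parts = [], []
    for k in range(nz):
        tets_k = _split_hexes(_hex_ids(k))
        all_tets.append(tets_k)
        part = PART_MUCOSA if k < nz_m else PART_PLATE
        all_parts.append(np.full(len(tets_k), part, dtype=np.int64))
    tets = np.concatenate(all_tets)
    part = np.concatenate(all_parts)
    tets = _orient_positive(nodes, tets)

    centroids = nodes[tets].mean(axis=1)
    segment_id = np.where(
        part == PART_MUCOSA,
        geometry.segment_at(centroids[:, 0], centroids[:, 1]),
        0,
    )

    node_sets = {
        "bone_surface": np.sort(nid[:, :, 0].ravel()),
        "interface": np.sort(nid[:, :, nz_m].ravel()),
        "oral_surface": np.sort(nid[:, :, nz].ravel()),
    }
    mesh = TetMesh(
        nodes=nodes, tets=tets, part=part, segment_id=segment_id, node_sets=node_sets
    )
    mesh.validate()
    return mesh


def box_mesh(
    lx: float,
    ly: float,
    lz: float,
    n: int | tuple[int, int, int] = 1,
    part: int = PART_PLATE,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> TetMesh:
    """Structured tet mesh of a box — a verification fixture factory.

    With ``n = 1`` a unit box is one hexahedron split into six tetrahedra.
    All tets carry the same part label; node sets ``bottom`` (z = origin_z),
    ``top`` (z = origin_z + lz) and the axis-plane sets ``x0``/``y0`` are
    provided for roller-support fixtures.
    """
    if isinstance(n, int):
        nx = ny = nz = n
    else:
        nx, ny, nz = n
    xs = origin[0] + np.linspace(0, lx, nx + 1)
    ys = origin[1] + np.linspace(0, ly, ny + 1)
    zs = origin[2] + np.linspace(0, lz, nz + 1)
    nid = np.arange((nx + 1) * (ny + 1) * (nz + 1)).reshape(nx + 1, ny + 1, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    c = np.empty((nx * ny * nz, 2, 2, 2), dtype=np.int64)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                c[:, dx, dy, dz] = nid[
                    dx : nx + dx, dy : ny + dy, dz : nz + dz
                ].ravel()
    tets = _orient_positive(nodes, _split_hexes(c))
    node_sets = {
        "bottom": np.sort(nid[:, :, 0].ravel()),
        "top": np.sort(nid[:, :, nz].ravel()),
        "x0": np.sort(nid[0, :, :].ravel()),
        "y0": np.sort(nid[:, 0, :].ravel()),
    }
    mesh = TetMesh(
        nodes=nodes,
        tets=tets,
        part=np.full(len(tets), part, dtype=np.int64),
        segment_id=np.zeros(len(tets), dtype=np.int64),
        node_sets=node_sets,
    )
    mesh.validate()
    return mesh
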