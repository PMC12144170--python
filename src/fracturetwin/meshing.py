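"""Voxel label map to conforming tetrahedral mesh conversion.

Every non-background voxel is subdivided into 6 tetrahedra (Kuhn
subdivision along the main diagonal). Because each voxel uses the same
local diagonal orientation, face diagonals agree between neighbouring
voxels and the mesh is conforming by construction. Nodes are deduplicated
by exact grid-index arithmetic, so conformity is bit-exact rather than
tolerance-based.

Element order 1 gives 4-node constant-strain tetrahedra; order 2 inserts
one unique mid-edge node per edge, giving 10-node quadratic tetrahedra
(the C3D10 element family).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import BACKGROUND, LabelMap

# Kuhn subdivision: 6 tetrahedra per voxel, one per permutation of the axes.
# Local corners are bit triples (bx, by, bz); every tet walks from (0,0,0)
# to (1,1,1) adding one axis at a time. Odd permutations are reordered to
# keep the signed volume positive.
_PERMUTATIONS = [
    (0, 1, 2),
    (1, 2, 0),
    (2, 0, 1),  # even
    (0, 2, 1),
    (2, 1, 0),
    (1, 0, 2),  # odd
]


def _perm_sign(p) -> int:
    a, b, c = p
    return 1 if (a, b, c) in {(0, 1, 2), (1, 2, 0), (2, 0, 1)} else -1


def _local_tets() -> np.ndarray:
    """(6, 4) local corner bit-codes (bx + 2*by + 4*bz) per tetrahedron."""
    tets = []
    for p in _PERMUTATIONS:
        v0 = np.zeros(3, dtype=int)
        v1 = v0.copy()
        v1[p[0]] = 1
        v2 = v1.copy()
        v2[p[1]] = 1
        v3 = np.ones(3, dtype=int)
        verts = [v0, v1, v2, v3]
        if _perm_sign(p) < 0:
            verts = [v0, v1, v3, v2]
        tets.append([int(v[0] + 2 * v[1] + 4 * v[2]) for v in verts])
    return np.asarray(tets, dtype=np.int64)


_LOCAL_TETS = _local_tets()
_CORNER_BITS = np.array(
    [[(c >> 0) & 1, (c >> 1) & 1, (c >> 2) & 1] for c in range(8)], dtype=np.int64
)

#: C3D10 mid-edge node ordering: corner pairs for nodes 5..10.
TET10_EDGES = np.array([(0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3)])


@dataclass
class TetMesh:
    """Tetrahedral mesh with per-element region labels and named node sets."""

    nodes: np.ndarray  # (nn, 3) mm
    elements: np.ndarray  # (ne, 4) or (ne, 10) node indices
    element_label: np.ndarray  # (ne,) region id
    legend: dict[int, str]
    element_order: int = 1
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    element_voxel: np.ndarray | None = None  # flat source-voxel index per element
    spacing: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def corner_elements(self) -> np.ndarray:
        """Corner connectivity (ne, 4) regardless of element order."""
        return self.elements[:, :4]

    def element_region_names(self) -> np.ndarray:
        lut = np.empty(max(self.legend) + 1, dtype=object)
        for k, v in self.legend.items():
            lut[k] = v
        return lut[self.element_label]

    def region_id(self, name: str) -> int:
        for k, v in self.legend.items():
            if v == name:
                return k
        raise KeyError(f"region {name!r} not in mesh legend")

    def elements_in_region(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.element_label == self.region_id(name))

    def element_volumes(self) -> np.ndarray:
        """Signed volumes from the corner nodes (positive for valid meshes)."""
        x = self.nodes[self.corner_elements]
        t = x[:, 1:] - x[:, :1]
        return np.linalg.det(t) / 6.0

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.corner_elements].mean(axis=1)

    def boundary_faces(self) -> np.ndarray:
        """(nf, 3) corner-node faces that belong to exactly one tetrahedron."""
        faces = _all_faces(self.corner_elements)
        key = np.sort(faces, axis=1)
        _, inv, counts = np.unique(
            key, axis=0, return_inverse=True, return_counts=True
        )
        return faces[counts[inv] == 1]

    def boundary_nodes(self) -> np.ndarray:
        """All node indices lying on the mesh boundary (incl. mid-edge nodes)."""
        bf = self.boundary_faces()
        ids = set(np.unique(bf).tolist())
        if self.element_order == 2:
            # mid-edge nodes whose both corner endpoints share a boundary face
            corner_faces = {tuple(sorted(f)) for f in bf}
            elems = self.elements
            for e in range(self.n_elements):
                conn = elems[e]
                for li, (a, b) in enumerate(TET10_EDGES):
                    mid = conn[4 + li]
                    # edge belongs to a boundary face of this element?
                    for fi in _TET_FACES:
                        fa = tuple(sorted(conn[list(fi)]))
                        if fa in corner_faces and conn[a] in fa and conn[b] in fa:
                            ids.add(int(mid))
                            break
        return np.array(sorted(ids), dtype=np.int64)


_TET_FACES = np.array([(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)])


def _all_faces(corner_elements: np.ndarray) -> np.ndarray:
    return corner_elements[:, _TET_FACES].reshape(-1, 3)


def voxels_to_tetmesh(labels: LabelMap, element_order: int = 1) -> TetMesh:
    """Subdivide every non-background voxel into 6 conforming tetrahedra.

    Shared corner (and, for order 2, mid-edge) nodes are deduplicated by
    grid-index arithmetic; each tetrahedron inherits its source voxel's
    region label. Total mesh volume equals foreground voxel count times the
    voxel volume exactly.
    """
    if element_order not in (1, 2):
        raise ValueError("element_order must be 1 or 2")
    fg = labels.labels != BACKGROUND
    vox = np.flatnonzero(fg.ravel())
    if vox.size == 0:
        raise ValueError("label map has no foreground voxels")
    nx, ny, nz = labels.dims
    ix, rem = np.divmod(vox, ny * nz)
    iy, iz = np.divmod(rem, nz)

    # Global grid-corner ids on the (nx+1, ny+1, nz+1) corner lattice.
    def corner_gid(bx, by, bz):
        return (ix + bx) + (nx + 1) * ((iy + by) + (ny + 1) * (iz + bz))

    corners = np.stack(
        [corner_gid(*_CORNER_BITS[c]) for c in range(8)], axis=1
    )  # (nvox, 8)

    conn = corners[:, _LOCAL_TETS]  # (nvox, 6, 4)
    conn = conn.reshape(-1, 4)

    used, inv = np.unique(conn, return_inverse=True)
    elements = inv.reshape(-1, 4).astype(np.int64)

    # gid = cx + (nx+1)*(cy + (ny+1)*cz)
    cz, crem = np.divmod(used, (nx + 1) * (ny + 1))
    cy, cx = np.divmod(crem, nx + 1)
    nodes = np.stack(
        [
            labels.origin[0] + cx * labels.spacing[0],
            labels.origin[1] + cy * labels.spacing[1],
            labels.origin[2] + cz * labels.spacing[2],
        ],
        axis=1,
    ).astype(float)

    element_label = np.repeat(labels.labels.ravel()[vox], 6).astype(np.int32)
    element_voxel = np.repeat(vox, 6)

    mesh = TetMesh(
        nodes=nodes,
        elements=elements,
        element_label=element_label,
        legend=dict(labels.legend),
        element_order=1,
        element_voxel=element_voxel,
        spacing=labels.spacing.copy(),
    )
    if element_order == 2:
        mesh = _promote_to_order2(mesh)
    return mesh


def _promote_to_order2(mesh: TetMesh) -> TetMesh:
    """Insert unique mid-edge nodes, turning TET4 into TET10 connectivity."""
    conn = mesh.elements
    nn = mesh.n_nodes
    e0 = conn[:, TET10_EDGES[:, 0]]
    e1 = conn[:, TET10_EDGES[:, 1]]
    lo = np.minimum(e0, e1)
    hi = np.maximum(e0, e1)
    key = lo.astype(np.int64) * nn + hi.astype(np.int64)
    uniq, inv = np.unique(key, return_inverse=True)
    mid_ids = nn + inv.reshape(conn.shape[0], 6)
    ulo, uhi = np.divmod(uniq, nn)
    mid_nodes = 0.5 * (mesh.nodes[ulo] + mesh.nodes[uhi])
    return TetMesh(
        nodes=np.vstack([mesh.nodes, mid_nodes]),
        elements=np.hstack([conn, mid_ids]),
        element_label=mesh.element_label,
        legend=mesh.legend,
        element_order=2,
        node_sets=dict(mesh.node_sets),
        element_voxel=mesh.element_voxel,
        spacing=mesh.spacing,
    )


def define_cuboid_nodeset(
    mesh: TetMesh, name: str, box: tuple[tuple[float, float], ...]
) -> TetMesh:
    """Add the node set of all nodes inside the closed axis-aligned box.

    ``box`` is ((xmin, xmax), (ymin, ymax), (zmin, zmax)) in mm. Cuboid
    regions at the bone ends serve as reference areas for applying loads
    or constraints. An empty resulting set is an error: a boundary set
    must contain at least one node.
    """
    box = tuple((float(lo), float(hi)) for lo, hi in box)
    for lo, hi in box:
        if not lo < hi:
            raise ValueError("box must satisfy min < max per axis")
    mask = np.ones(mesh.n_nodes, dtype=bool)
    for axis, (lo, hi) in enumerate(box):
        mask &= (mesh.nodes[:, axis] >= lo) & (mesh.nodes[:, axis] <= hi)
    ids = np.flatnonzero(mask)
    if ids.size == 0:
        raise ValueError(f"node set {name!r} is empty: box does not meet the mesh")
    mesh.node_sets[name] = ids
    return mesh
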