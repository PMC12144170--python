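"""Static linear-elastic finite elements on labeled tetrahedral meshes.

Small-strain isotropic elasticity, solved as a single static load step:
Dirichlet constraints on a distal node set, total forces split equally
over proximal node sets, sparse assembly and either a direct factorization
(default at desk scale, deterministic) or ILU-preconditioned conjugate
gradients for larger systems. Strain and stress tensors are recovered per
element at the centroid (order 1: the element's constant state; order 2:
the average over the 4-point Gauss rule, which equals the centroid value
for the affine strain field of a TET10).

Units are mm-N-MPa throughout, so displacements come out in mm and
stresses in MPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import MaterialTable
from .meshing import TET10_EDGES, TetMesh

#: Above this many free degrees of freedom the solver switches from a
#: general sparse factorization to the layer-structured block solver
#: (falling back to ILU-preconditioned CG for unstructured meshes).
DIRECT_SOLVE_MAX_DOF = 80_000

#: Relative residual tolerance for the iterative path.
CG_RTOL = 1e-10


@dataclass
class DirichletBC:
    """Prescribed displacement on a node set; None leaves an axis free.

    Each axis value may be a scalar (applied to every node in the set) or
    an array with one value per set node, e.g. to prescribe a linear
    displacement field on the boundary.
    """

    node_set: str
    ux: "float | np.ndarray | None" = 0.0
    uy: "float | np.ndarray | None" = 0.0
    uz: "float | np.ndarray | None" = 0.0

    @property
    def per_axis(self):
        return (self.ux, self.uy, self.uz)


@dataclass
class NeumannBC:
    """A total force vector (N) distributed over a node set.

    ``distribution="equal"`` (default) splits the total equally across the
    set's nodes — the convention for cuboid load-reference regions, which
    is insensitive away from the ends by Saint-Venant's principle.
    ``distribution="area"`` weights nodes consistently with a uniform
    traction on the boundary faces spanned by the set (corner nodes get
    their tributary face area; for quadratic elements the standard
    zero-corner / third-per-midside rule), which reproduces closed-form
    uniform-stress states exactly.
    """

    node_set: str
    force: tuple[float, float, float]
    distribution: str = "equal"


@dataclass
class LoadCase:
    name: str
    dirichlet: list[DirichletBC] = field(default_factory=list)
    neumann: list[NeumannBC] = field(default_factory=list)

    def validate(self, mesh: TetMesh) -> None:
        if not self.dirichlet:
            raise ValueError("load case needs at least one Dirichlet constraint")
        for bc in self.dirichlet + self.neumann:
            if bc.node_set not in mesh.node_sets:
                raise ValueError(f"node set {bc.node_set!r} not defined on the mesh")
        for bc in self.neumann:
            if not np.all(np.isfinite(bc.force)):
                raise ValueError("force vectors must be finite")


@dataclass
class FESolution:
    """Displacements, per-element tensors and reactions for one load case."""

    mesh: TetMesh
    displacements: np.ndarray  # (nn, 3) mm
    strain: np.ndarray  # (ne, 3, 3)
    stress: np.ndarray  # (ne, 3, 3) MPa
    reactions: np.ndarray  # (nn, 3) N, nonzero only on constrained nodes
    load_case: LoadCase | None = None
    solver_info: dict = field(default_factory=dict)

    def applied_forces(self) -> np.ndarray:
        return external_force_field(self.mesh, self.load_case)

    def equilibrium_residual(self) -> float:
        """|sum(reactions) + sum(applied)| relative to the applied magnitude."""
        f = self.applied_forces()
        total_applied = f.sum(axis=0)
        total_reaction = self.reactions.sum(axis=0)
        scale = max(np.linalg.norm(f, axis=1).sum(), 1.0)
        return float(np.linalg.norm(total_reaction + total_applied) / scale)


def _nodeset_weights(mesh: TetMesh, ids: np.ndarray, distribution: str) -> np.ndarray:
    """Per-node weights (summing to 1) for distributing a total force."""
    if distribution == "equal":
        return np.full(len(ids), 1.0 / len(ids))
    if distribution != "area":
        raise ValueError(f"unknown force distribution {distribution!r}")
    in_set = np.zeros(mesh.n_nodes, dtype=bool)
    in_set[ids] = True
    faces = mesh.boundary_faces()
    on = faces[np.all(in_set[faces], axis=1)]
    if on.shape[0] == 0:
        raise ValueError("node set spans no boundary face; cannot area-weight")
    v0 = mesh.nodes[on[:, 0]]
    areas = 0.5 * np.linalg.norm(
        np.cross(mesh.nodes[on[:, 1]] - v0, mesh.nodes[on[:, 2]] - v0), axis=1
    )
    w = np.zeros(mesh.n_nodes)
    if mesh.element_order == 1:
        for k in range(3):
            np.add.at(w, on[:, k], areas / 3.0)
    else:
        mid_lookup = _edge_midnode_map(mesh)
        for k in range(3):
            a, b = on[:, k], on[:, (k + 1) % 3]
            mids = np.array(
                [mid_lookup[(min(i, j), max(i, j))] for i, j in zip(a, b)]
            )
            np.add.at(w, mids, areas / 3.0)
    wset = w[ids]
    total = wset.sum()
    if total <= 0:
        raise ValueError("node set has zero tributary area")
    return wset / total


def _edge_midnode_map(mesh: TetMesh) -> dict[tuple[int, int], int]:
    lookup: dict[tuple[int, int], int] = {}
    conn = mesh.elements
    for li, (a, b) in enumerate(TET10_EDGES):
        na, nb = conn[:, a], conn[:, b]
        lo = np.minimum(na, nb)
        hi = np.maximum(na, nb)
        for l_, h_, m_ in zip(lo, hi, conn[:, 4 + li]):
            lookup[(int(l_), int(h_))] = int(m_)
    return lookup


def external_force_field(mesh: TetMesh, load: "LoadCase | None") -> np.ndarray:
    """Assemble the applied nodal force field (nn, 3) of a load case."""
    f = np.zeros((mesh.n_nodes, 3))
    if load is None:
        return f
    for bc in load.neumann:
        ids = mesh.node_sets[bc.node_set]
        w = _nodeset_weights(mesh, ids, bc.distribution)
        f[ids] += w[:, None] * np.asarray(bc.force, dtype=float)
    return f


# ---------------------------------------------------------------------------
# Element matrices
# ---------------------------------------------------------------------------

# 4-point Gauss rule on the reference tetrahedron (barycentric coordinates).
_GA = (5.0 + 3.0 * np.sqrt(5.0)) / 20.0
_GB = (5.0 - np.sqrt(5.0)) / 20.0
GAUSS4 = np.array(
    [
        [_GA, _GB, _GB, _GB],
        [_GB, _GA, _GB, _GB],
        [_GB, _GB, _GA, _GB],
        [_GB, _GB, _GB, _GA],
    ]
)


def _elastic_moduli(E: np.ndarray, nu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    return lam, mu


def _d_matrix(E: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """(ne, 6, 6) isotropic stiffness in Voigt order (xx, yy, zz, xy, yz, zx)."""
    lam, mu = _elastic_moduli(E, nu)
    ne = E.shape[0]
    D = np.zeros((ne, 6, 6))
    for i in range(3):
        for j in range(3):
            D[:, i, j] = lam
        D[:, i, i] = lam + 2.0 * mu
        D[:, 3 + i, 3 + i] = mu
    return D


def _lambda_gradients(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray]:
    """Barycentric gradients (ne, 4, 3) and element volumes (ne,)."""
    x = mesh.nodes[mesh.corner_elements]
    J = x[:, 1:] - x[:, :1]  # rows are edge vectors
    det = np.linalg.det(J)
    bad = np.flatnonzero(det <= 0)
    if bad.size:
        raise ValueError(
            f"element {int(bad[0])} has non-positive volume; mesh is invalid"
        )
    Jinv = np.linalg.inv(J)
    grad = np.empty((x.shape[0], 4, 3))
    grad[:, 1:] = np.transpose(Jinv, (0, 2, 1))
    grad[:, 0] = -grad[:, 1:].sum(axis=1)
    return grad, det / 6.0


def _tet10_dN_dlambda() -> np.ndarray:
    """(ngp, 10, 4) shape-function gradients w.r.t. barycentric coords."""
    out = np.zeros((GAUSS4.shape[0], 10, 4))
    for g, lam in enumerate(GAUSS4):
        for i in range(4):
            out[g, i, i] = 4.0 * lam[i] - 1.0
        for k, (a, b) in enumerate(TET10_EDGES):
            out[g, 4 + k, a] = 4.0 * lam[b]
            out[g, 4 + k, b] = 4.0 * lam[a]
    return out


_DN_DLAM_10 = _tet10_dN_dlambda()


def _b_matrix(dN: np.ndarray) -> np.ndarray:
    """Strain-displacement matrix (ne, 6, 3*npe) from shape grads (ne, npe, 3)."""
    ne, npe, _ = dN.shape
    B = np.zeros((ne, 6, 3 * npe))
    gx, gy, gz = dN[:, :, 0], dN[:, :, 1], dN[:, :, 2]
    B[:, 0, 0::3] = gx
    B[:, 1, 1::3] = gy
    B[:, 2, 2::3] = gz
    B[:, 3, 0::3] = gy
    B[:, 3, 1::3] = gx
    B[:, 4, 1::3] = gz
    B[:, 4, 2::3] = gy
    B[:, 5, 0::3] = gz
    B[:, 5, 2::3] = gx
    return B


def assemble_stiffness(mesh: TetMesh, materials: MaterialTable,
                       chunk: int = 60_000) -> sp.csr_matrix:
    """Assemble the global stiffness matrix (3 dof per node)."""
    if materials.E.shape[0] != mesh.n_elements:
        raise ValueError("material table does not cover all elements")
    ndof = 3 * mesh.n_nodes
    npe = mesh.elements.shape[1]
    grad_all, vol_all = _lambda_gradients(mesh)
    K = sp.csr_matrix((ndof, ndof))
    for start in range(0, mesh.n_elements, chunk):
        sl = slice(start, min(start + chunk, mesh.n_elements))
        Ke = _element_stiffness(mesh, materials, sl, grad_all[sl], vol_all[sl])
        conn = mesh.elements[sl]
        edof = (3 * conn[:, :, None] + np.arange(3)).reshape(-1, 3 * npe)
        rows = np.repeat(edof, 3 * npe, axis=1).ravel()
        cols = np.tile(edof, (1, 3 * npe)).ravel()
        K = K + sp.coo_matrix(
            (Ke.ravel(), (rows, cols)), shape=(ndof, ndof)
        ).tocsr()
    return K


def _element_stiffness(mesh: TetMesh, materials: MaterialTable, sl: slice,
                       grad: np.ndarray, vol: np.ndarray) -> np.ndarray:
    D = _d_matrix(materials.E[sl], materials.nu[sl])
    if mesh.element_order == 1:
        B = _b_matrix(grad)
        return np.einsum("eik,eij,ejl,e->ekl", B, D, B, vol, optimize=True)
    Ke = np.zeros((grad.shape[0], 30, 30))
    for g in range(GAUSS4.shape[0]):
        dN = np.einsum("na,eac->enc", _DN_DLAM_10[g], grad)
        B = _b_matrix(dN)
        Ke += np.einsum("eik,eij,ejl,e->ekl", B, D, B, vol / 4.0, optimize=True)
    return Ke


# ---------------------------------------------------------------------------
# Solve
# ---------------------------------------------------------------------------


def _rigid_mode_deficiency(mesh: TetMesh, fixed_dof: np.ndarray) -> int:
    """How many of the 6 rigid-body modes the constraints fail to suppress."""
    nodes = mesh.nodes
    nn = nodes.shape[0]
    modes = np.zeros((3 * nn, 6))
    for a in range(3):
        modes[a::3, a] = 1.0
    c = nodes - nodes.mean(axis=0)
    # rotations about x, y, z
    modes[1::3, 3], modes[2::3, 3] = -c[:, 2], c[:, 1]
    modes[0::3, 4], modes[2::3, 4] = c[:, 2], -c[:, 0]
    modes[0::3, 5], modes[1::3, 5] = -c[:, 1], c[:, 0]
    restricted = modes[fixed_dof]
    if restricted.shape[0] == 0:
        return 6
    rank = np.linalg.matrix_rank(restricted, tol=1e-9 * max(1.0, np.abs(c).max()))
    return 6 - int(rank)


def assemble_and_solve(
    mesh: TetMesh,
    materials: MaterialTable,
    load: LoadCase,
    direct_max_dof: int = DIRECT_SOLVE_MAX_DOF,
) -> FESolution:
    """Solve K u = f with the load case's constraints and recover tensors.

    The displacement field minimizes the elastic energy subject to the
    prescribed displacements; each Neumann total force is split equally
    across its node set. Reactions are recovered from the residual on
    constrained degrees of freedom, so global equilibrium
    (sum reactions = -sum applied) holds to solver tolerance.
    """
    load.validate(mesh)
    ndof = 3 * mesh.n_nodes

    fixed = np.zeros(ndof, dtype=bool)
    u_fix = np.zeros(ndof)
    for bc in load.dirichlet:
        ids = mesh.node_sets[bc.node_set]
        for axis, val in enumerate(bc.per_axis):
            if val is None:
                continue
            dofs = 3 * ids + axis
            fixed[dofs] = True
            u_fix[dofs] = val
    if not fixed.any():
        raise ValueError("no degree of freedom is constrained")
    deficiency = _rigid_mode_deficiency(mesh, fixed)
    if deficiency > 0:
        raise ValueError(
            f"singular system: {deficiency} unconstrained rigid-body mode(s)"
        )

    f = external_force_field(mesh, load).ravel()

    K = assemble_stiffness(mesh, materials)
    free = ~fixed
    Kff = K[free][:, free].tocsc()
    rhs = f[free] - K[free][:, fixed] @ u_fix[fixed]

    nfree = int(free.sum())
    u = u_fix.copy()
    if nfree:
        if nfree <= direct_max_dof:
            lu = spla.splu(Kff)
            u[free] = lu.solve(rhs)
            info = {"method": "splu", "n_free_dof": nfree}
        else:
            layers = _free_dof_layers(mesh, free)
            if layers is not None:
                u[free], info = _solve_block_tridiagonal(Kff, rhs, layers)
            else:
                u[free], info = _solve_cg(Kff, rhs)
            info["n_free_dof"] = nfree
    else:
        info = {"method": "none", "n_free_dof": 0}

    residual = K @ u - f
    reactions = np.zeros(ndof)
    reactions[fixed] = residual[fixed]

    strain, stress = recover_fields(mesh, materials, u.reshape(-1, 3))
    return FESolution(
        mesh=mesh,
        displacements=u.reshape(-1, 3),
        strain=strain,
        stress=stress,
        reactions=reactions.reshape(-1, 3),
        load_case=load,
        solver_info=info,
    )


def _free_dof_layers(mesh: TetMesh, free: np.ndarray) -> np.ndarray | None:
    """Layer index per free dof for the block-tridiagonal path, or None.

    Voxel meshes are extruded along the bone axis: nodes fall on discrete
    z-planes and elements couple only adjacent planes, so grouping free
    dofs by z-plane (in the native node ordering, which is z-major) yields
    a block-tridiagonal stiffness matrix. Returns None when the structure
    is unusable (few layers, order-2 mesh, non-monotone ordering).
    """
    if mesh.element_order != 1:
        return None
    z = mesh.nodes[:, 2]
    zu, layer_of_node = np.unique(z, return_inverse=True)
    if zu.size < 8:
        return None
    layers = np.repeat(layer_of_node, 3)[free]
    if np.any(np.diff(layers) < 0):
        return None
    return layers


def _solve_block_tridiagonal(Kff: sp.csc_matrix, rhs: np.ndarray,
                             layers: np.ndarray) -> tuple[np.ndarray, dict]:
    """Exact block-Cholesky elimination layer by layer along the bone axis.

    With dofs grouped by z-plane the reduced stiffness is block
    tridiagonal: K = [D_i on the diagonal, E_i coupling layer i to i+1].
    Forward elimination forms Schur complements S_1 = D_1,
    S_{i+1} = D_{i+1} - E_i^T S_i^{-1} E_i, each factored densely
    (Cholesky) and stored packed; the off-diagonal blocks stay sparse.
    This is a direct solve whose memory scales with (layer size)^2 times
    the number of layers rather than with global fill-in.
    """
    import scipy.linalg as sla

    Kcoo = Kff.tocoo()
    span = np.abs(layers[Kcoo.row] - layers[Kcoo.col])
    if span.max() > 1:
        return _solve_cg(Kff, rhs)

    uniq = np.unique(layers)
    slices = []
    start = 0
    counts = np.bincount(np.searchsorted(uniq, layers))
    for c in counts:
        slices.append(slice(start, start + int(c)))
        start += int(c)
    nlay = len(slices)

    from scipy.linalg.blas import dsyrk

    Kcsr = Kff.tocsr()
    factors: list[tuple[np.ndarray, int]] = []  # packed lower Cholesky per layer
    offdiag: list[sp.csr_matrix] = []
    S = Kcsr[slices[0], slices[0]].toarray()
    for i in range(nlay):
        c, _low = sla.cho_factor(S, lower=True, overwrite_a=True, check_finite=False)
        b = c.shape[0]
        factors.append((c[np.tril_indices(b)].astype(np.float64), b))
        if i < nlay - 1:
            E = Kcsr[slices[i], slices[i + 1]]
            # S_{i+1} = D_{i+1} - E^T S_i^{-1} E = D_{i+1} - (L^{-1}E)^T (L^{-1}E)
            M = sla.solve_triangular(c, E.toarray(), lower=True,
                                     check_finite=False)
            D = np.asfortranarray(Kcsr[slices[i + 1], slices[i + 1]].toarray())
            # rank-k update touches the lower triangle only, which is all
            # the next cho_factor(lower=True) reads
            S = dsyrk(-1.0, M, beta=1.0, c=D, trans=1, lower=1,
                      overwrite_c=1)
            offdiag.append(E)
        del c

    def unpack(i):
        packed, b = factors[i]
        L = np.zeros((b, b))
        L[np.tril_indices(b)] = packed
        return L

    # forward sweep: c_i = b_i - E_{i-1}^T S_{i-1}^{-1} c_{i-1}
    cvecs = [rhs[slices[0]].copy()]
    for i in range(1, nlay):
        L = unpack(i - 1)
        y = sla.cho_solve((L, True), cvecs[i - 1], check_finite=False)
        cvecs.append(rhs[slices[i]] - offdiag[i - 1].T @ y)
    # backward sweep: x_i = S_i^{-1} (c_i - E_i x_{i+1})
    x = np.empty_like(rhs)
    L = unpack(nlay - 1)
    x[slices[nlay - 1]] = sla.cho_solve((L, True), cvecs[nlay - 1],
                                        check_finite=False)
    for i in range(nlay - 2, -1, -1):
        L = unpack(i)
        x[slices[i]] = sla.cho_solve(
            (L, True), cvecs[i] - offdiag[i] @ x[slices[i + 1]],
            check_finite=False,
        )
    return x, {"method": "block_tridiagonal", "n_layers": nlay}


def _solve_cg(Kff: sp.csc_matrix, rhs: np.ndarray) -> tuple[np.ndarray, dict]:
    ilu = spla.spilu(Kff, drop_tol=1e-5, fill_factor=12.0)
    M = spla.LinearOperator(Kff.shape, ilu.solve)
    x, code = spla.cg(Kff, rhs, rtol=CG_RTOL, atol=0.0, maxiter=20_000, M=M)
    if code != 0:
        raise RuntimeError(f"conjugate gradients failed to converge (info={code})")
    return x, {"method": "cg+ilu", "cg_info": int(code)}


def recover_fields(
    mesh: TetMesh, materials: MaterialTable, u: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-element centroid strain and stress tensors from displacements."""
    grad, _ = _lambda_gradients(mesh)
    if mesh.element_order == 1:
        ue = u[mesh.elements]  # (ne, 4, 3)
        gu = np.einsum("eia,eib->eab", ue, grad)
    else:
        ue = u[mesh.elements]  # (ne, 10, 3)
        gu = np.zeros((mesh.n_elements, 3, 3))
        for g in range(GAUSS4.shape[0]):
            dN = np.einsum("na,eac->enc", _DN_DLAM_10[g], grad)
            gu += np.einsum("eia,eib->eab", ue, dN) / GAUSS4.shape[0]
    strain = 0.5 * (gu + np.transpose(gu, (0, 2, 1)))
    lam, mu = _elastic_moduli(materials.E, materials.nu)
    tr = np.trace(strain, axis1=1, axis2=2)
    stress = 2.0 * mu[:, None, None] * strain
    stress[:, np.arange(3), np.arange(3)] += (lam * tr)[:, None]
    return strain, stress
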