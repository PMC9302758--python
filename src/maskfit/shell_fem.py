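"""Flat triangular shell finite elements for the soft-tissue face model.

The face is modelled as a single-layer linear-elastic shell: each triangle
carries a constant-strain membrane (CST), a Mindlin/Reissner plate-bending
block and a transverse-shear block, superposed in a local frame and rotated
to global axes.  Each node has 6 global DOFs (u_x, u_y, u_z, th_x, th_y,
th_z); the in-plane drilling rotation th_z has no physical stiffness in this
formulation and is stabilized with a small artificial stiffness so the
assembled system is nonsingular on near-coplanar patches.

Default material: E = 0.03 MPa, nu = 0.49, h = 2 mm — soft facial tissue as
a thin shell.  Units: mm / MPa / N (consistent: MPa*mm^2 = N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import GeometryError, ParameterError, RankError
from .mesh_core import TriSurfaceMesh

__all__ = [
    "ShellMaterial",
    "ElementStiffness",
    "FaceFEModel",
    "elasticity_matrices",
    "element_stiffness",
    "assemble_stiffness",
    "solve_static",
]

DOFS_PER_NODE = 6
#: local element DOFs before drilling augmentation: 3 nodes x (u, v, w, th_x, th_y)
LOCAL_ELEMENT_DOFS = 15


@dataclass(frozen=True)
class ShellMaterial:
    """Linear-elastic shell material.

    E : elastic modulus (MPa); nu : Poisson's ratio; h : thickness (mm);
    kappa : transverse-shear correction factor; drilling_factor :
    dimensionless scale of the artificial drilling stiffness.
    """

    E: float = 0.03
    nu: float = 0.49
    h: float = 2.0
    kappa: float = 5.0 / 6.0
    drilling_factor: float = 1e-6

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ParameterError("E must be positive")
        if not 0.0 <= self.nu < 0.5:
            raise ParameterError("nu must satisfy 0 <= nu < 0.5 (0.5 is singular)")
        if self.h <= 0:
            raise ParameterError("h must be positive")
        if not 0.0 < self.kappa <= 1.0:
            raise ParameterError("kappa must lie in (0, 1]")
        if self.drilling_factor < 0:
            raise ParameterError("drilling_factor must be nonnegative")

    @property
    def G(self) -> float:
        """Shear modulus E / (2(1 + nu)) in MPa."""
        return self.E / (2.0 * (1.0 + self.nu))


def elasticity_matrices(material: ShellMaterial):
    """Constitutive blocks (D_b, D_p, D_s) of the flat shell.

    D_b = E h^3 / (12 (1 - nu^2)) * [[1, nu, 0], [nu, 1, 0], [0, 0, (1-nu)/2]]
    (bending, N*mm); D_p is the same pattern times E / (1 - nu^2) (membrane,
    per unit thickness, MPa — multiplied by h during integration); and
    D_s = kappa * G * h is the transverse shear rigidity per unit length
    (N/mm).
    """
    if material.nu >= 0.5:  # unreachable through ShellMaterial; guard anyway
        raise ParameterError("nu = 0.5 makes the material matrix singular")
    nu = material.nu
    pattern = np.array(
        [[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, (1.0 - nu) / 2.0]]
    )
    D_b = material.E * material.h**3 / (12.0 * (1.0 - nu**2)) * pattern
    D_p = material.E / (1.0 - nu**2) * pattern
    D_s = material.kappa * material.G * material.h
    return D_b, D_p, D_s


@dataclass
class ElementStiffness:
    """18x18 element stiffness in global axes (node-major u,v,w,thx,thy,thz)."""

    element_index: int
    K_local: np.ndarray


def _local_frame(coords: np.ndarray):
    e1 = coords[1] - coords[0]
    n = np.cross(e1, coords[2] - coords[0])
    nn = np.linalg.norm(n)
    if nn <= 2e-9:  # 2*area
        raise GeometryError("degenerate triangle (area below tolerance)")
    e3 = n / nn
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(e3, e1)
    return np.vstack([e1, e2, e3])  # rows: local axes in global components


def _plate_bending_dkt(local: np.ndarray, D_b: np.ndarray, A: float) -> np.ndarray:
    """Discrete-Kirchhoff triangle bending stiffness (9x9).

    Nodal DOFs (w, th_x, th_y) with right-hand rotations about the local
    axes (Kirchhoff: th_x = w,y and th_y = -w,x).  Transverse shear strain
    is constrained to zero along the edges, so the shear block is absorbed
    and the element is free of shear locking.  Curvatures are linear; the
    3-point mid-edge rule integrates the stiffness exactly.
    """
    x, y = local[:, 0], local[:, 1]
    # sides k = 4, 5, 6 <-> node pairs (2,3), (3,1), (1,2), zero-based below
    pairs = [(1, 2), (2, 0), (0, 1)]
    P = np.zeros(3)
    q = np.zeros(3)
    t = np.zeros(3)
    r = np.zeros(3)
    for k, (i, j) in enumerate(pairs):
        xij, yij = x[i] - x[j], y[i] - y[j]
        l2 = xij**2 + yij**2
        P[k] = -6.0 * xij / l2
        q[k] = 3.0 * xij * yij / l2
        t[k] = -6.0 * yij / l2
        r[k] = 3.0 * yij**2 / l2
    P4, P5, P6 = P
    q4, q5, q6 = q
    t4, t5, t6 = t
    r4, r5, r6 = r

    def h_derivs(xi, eta):
        Hx_xi = np.array([
            P6 * (1 - 2 * xi) + (P5 - P6) * eta,
            q6 * (1 - 2 * xi) - (q5 + q6) * eta,
            -4 + 6 * (xi + eta) + r6 * (1 - 2 * xi) - eta * (r5 + r6),
            -P6 * (1 - 2 * xi) + eta * (P4 + P6),
            q6 * (1 - 2 * xi) - eta * (q6 - q4),
            -2 + 6 * xi + r6 * (1 - 2 * xi) + eta * (r4 - r6),
            -eta * (P5 + P4),
            eta * (q4 - q5),
            -eta * (r5 - r4),
        ])
        Hy_xi = np.array([
            t6 * (1 - 2 * xi) + eta * (t5 - t6),
            1 + r6 * (1 - 2 * xi) - eta * (r5 + r6),
            -q6 * (1 - 2 * xi) + eta * (q5 + q6),
            -t6 * (1 - 2 * xi) + eta * (t4 + t6),
            -1 + r6 * (1 - 2 * xi) + eta * (r4 - r6),
            -q6 * (1 - 2 * xi) - eta * (q4 - q6),
            -eta * (t4 + t5),
            eta * (r4 - r5),
            -eta * (q4 - q5),
        ])
        Hx_eta = np.array([
            -P5 * (1 - 2 * eta) - xi * (P6 - P5),
            q5 * (1 - 2 * eta) - xi * (q5 + q6),
            -4 + 6 * (xi + eta) + r5 * (1 - 2 * eta) - xi * (r5 + r6),
            xi * (P4 + P6),
            xi * (q4 - q6),
            -xi * (r6 - r4),
            P5 * (1 - 2 * eta) - xi * (P4 + P5),
            q5 * (1 - 2 * eta) + xi * (q4 - q5),
            -2 + 6 * eta + r5 * (1 - 2 * eta) + xi * (r4 - r5),
        ])
        Hy_eta = np.array([
            -t5 * (1 - 2 * eta) - xi * (t6 - t5),
            1 + r5 * (1 - 2 * eta) - xi * (r5 + r6),
            -q5 * (1 - 2 * eta) + xi * (q5 + q6),
            xi * (t4 + t6),
            xi * (r4 - r6),
            -xi * (q4 - q6),
            t5 * (1 - 2 * eta) - xi * (t4 + t5),
            -1 + r5 * (1 - 2 * eta) + xi * (r4 - r5),
            -q5 * (1 - 2 * eta) - xi * (q4 - q5),
        ])
        return Hx_xi, Hy_xi, Hx_eta, Hy_eta

    x31, y31 = x[2] - x[0], y[2] - y[0]
    x12, y12 = x[0] - x[1], y[0] - y[1]
    Kb = np.zeros((9, 9))
    for xi, eta in ((0.5, 0.0), (0.5, 0.5), (0.0, 0.5)):
        Hx_xi, Hy_xi, Hx_eta, Hy_eta = h_derivs(xi, eta)
        B = (1.0 / (2.0 * A)) * np.vstack([
            y31 * Hx_xi + y12 * Hx_eta,
            -x31 * Hy_xi - x12 * Hy_eta,
            -x31 * Hx_xi - x12 * Hx_eta + y31 * Hy_xi + y12 * Hy_eta,
        ])
        Kb += (A / 3.0) * B.T @ D_b @ B
    return Kb


def _plate_mindlin(
    local: np.ndarray, D_b: np.ndarray, D_s: float, h: float, A: float,
    b: np.ndarray, c: np.ndarray,
) -> np.ndarray:
    """Linear Mindlin plate triangle (9x9) with mid-edge shear integration
    and shear relaxation h^2/(h^2 + L^2/12); retained for comparison (it is
    markedly stiffer than DKT on thin elements)."""
    # normal-rotation variables phi_x = -th_y, phi_y = th_x (Kirchhoff
    # limit: phi = grad w with right-hand nodal rotations)
    Bb = np.zeros((3, 9))
    for i in range(3):
        Bb[0, 3 * i + 2] = -b[i]
        Bb[1, 3 * i + 1] = c[i]
        Bb[2, 3 * i + 1] = b[i]
        Bb[2, 3 * i + 2] = -c[i]
    Kp = A * Bb.T @ D_b @ Bb

    L_max2 = max(
        np.sum((local[1] - local[0]) ** 2),
        np.sum((local[2] - local[1]) ** 2),
        np.sum((local[0] - local[2]) ** 2),
    )
    Ds_eff = D_s * h**2 / (h**2 + L_max2 / 12.0)
    Ks = np.zeros((9, 9))
    for N in ((0.5, 0.5, 0.0), (0.0, 0.5, 0.5), (0.5, 0.0, 0.5)):
        Bs = np.zeros((2, 9))
        for i in range(3):
            Bs[0, 3 * i] = b[i]
            Bs[0, 3 * i + 2] = N[i]
            Bs[1, 3 * i] = c[i]
            Bs[1, 3 * i + 1] = -N[i]
        Ks += (A / 3.0) * Bs.T @ Bs
    return Kp + Ds_eff * Ks


def element_stiffness(
    coords,
    material: ShellMaterial,
    element_index: int = -1,
    formulation: str = "dkt",
) -> ElementStiffness:
    """Flat-shell stiffness of one triangle (18x18, global axes).

    Local formulation: CST membrane plus a plate block — by default the
    discrete-Kirchhoff triangle (DKT), which is locking-free for the thin
    shells used here; ``formulation="mindlin"`` selects a linear
    Mindlin/Reissner triangle with relaxed mid-edge shear integration.  The
    drilling rotation is stabilized by an artificial zero-row-sum block
    scaled to ``drilling_factor`` times the largest plate diagonal.
    """
    coords = np.asarray(coords, dtype=float)
    R = _local_frame(coords)
    local = (coords - coords[0]) @ R.T
    x, y = local[:, 0], local[:, 1]
    area2 = (x[1] - x[0]) * (y[2] - y[0]) - (x[2] - x[0]) * (y[1] - y[0])
    A = 0.5 * area2
    if A <= 1e-9:
        raise GeometryError(
            f"degenerate triangle (area {A:.3g} mm^2)"
            + (f" in element {element_index}" if element_index >= 0 else "")
        )
    b = np.array([y[1] - y[2], y[2] - y[0], y[0] - y[1]]) / area2
    c = np.array([x[2] - x[1], x[0] - x[2], x[1] - x[0]]) / area2

    D_b, D_p, D_s = elasticity_matrices(material)

    # membrane (CST): local DOFs [u1 v1 u2 v2 u3 v3]
    Bm = np.zeros((3, 6))
    for i in range(3):
        Bm[0, 2 * i] = b[i]
        Bm[1, 2 * i + 1] = c[i]
        Bm[2, 2 * i] = c[i]
        Bm[2, 2 * i + 1] = b[i]
    Km = material.h * A * Bm.T @ D_p @ Bm

    # plate block: local DOFs [w1 thx1 thy1 w2 thx2 thy2 w3 thx3 thy3]
    if formulation == "dkt":
        Kplate = _plate_bending_dkt(local, D_b, A)
    elif formulation == "mindlin":
        Kplate = _plate_mindlin(local, D_b, D_s, material.h, A, b, c)
    else:
        raise ParameterError(f"unknown formulation {formulation!r}")

    # scatter into the 18x18 local matrix (node-major u,v,w,thx,thy,thz)
    K18 = np.zeros((18, 18))
    mem_idx = [0, 1, 6, 7, 12, 13]
    plate_idx = [2, 3, 4, 8, 9, 10, 14, 15, 16]
    K18[np.ix_(mem_idx, mem_idx)] += Km
    K18[np.ix_(plate_idx, plate_idx)] += Kplate

    # artificial drilling stiffness (zero row sum: no energy for uniform th_z)
    k_dr = material.drilling_factor * float(np.max(np.diag(Kplate)))
    drill = k_dr * np.array(
        [[1.0, -0.5, -0.5], [-0.5, 1.0, -0.5], [-0.5, -0.5, 1.0]]
    )
    drill_idx = [5, 11, 17]
    K18[np.ix_(drill_idx, drill_idx)] += drill

    # rotate local -> global: local dof vector = T @ global dof vector
    T = np.zeros((18, 18))
    for blk in range(6):
        T[3 * blk : 3 * blk + 3, 3 * blk : 3 * blk + 3] = R
    K_global = T.T @ K18 @ T
    K_global = 0.5 * (K_global + K_global.T)
    return ElementStiffness(element_index, K_global)


@dataclass
class FaceFEModel:
    """Assembled sparse face stiffness with DOF bookkeeping.

    Node i owns global DOFs 6i..6i+5 (u_x, u_y, u_z, th_x, th_y, th_z).
    All 6 DOFs of open-boundary vertices are fixed (clamped).
    """

    mesh: TriSurfaceMesh
    material: ShellMaterial
    K_f: sp.csr_matrix
    fixed_dofs: np.ndarray
    n_dofs: int
    dofs_per_node: int = DOFS_PER_NODE
    _free_lu: object = field(default=None, repr=False, compare=False)

    @property
    def free_dofs(self) -> np.ndarray:
        mask = np.ones(self.n_dofs, dtype=bool)
        mask[self.fixed_dofs] = False
        return np.flatnonzero(mask)

    def free_factorization(self):
        """Cached sparse LU of the free-free stiffness block."""
        if self._free_lu is None:
            if len(self.fixed_dofs) == 0:
                raise RankError(
                    "stiffness is singular: no fixed boundary; apply boundary "
                    "conditions (the mesh has no open edge to clamp)"
                )
            free = self.free_dofs
            K_ff = self.K_f[free][:, free].tocsc()
            self._free_lu = spla.splu(K_ff)
        return self._free_lu


def node_dofs(nodes) -> np.ndarray:
    """Global DOF indices (node-major, 6 per node) of the given vertices."""
    nodes = np.asarray(nodes, dtype=np.int64).ravel()
    return (nodes[:, None] * DOFS_PER_NODE + np.arange(DOFS_PER_NODE)).ravel()


def assemble_stiffness(
    mesh: TriSurfaceMesh,
    material: ShellMaterial | None = None,
    formulation: str = "dkt",
) -> FaceFEModel:
    """Assemble the global sparse shell stiffness K_f of the face."""
    if mesh.n_triangles == 0:
        raise ParameterError("cannot assemble an empty mesh")
    material = material or ShellMaterial()
    n_dofs = DOFS_PER_NODE * mesh.n_vertices

    n_e = mesh.n_triangles
    rows = np.empty((n_e, 18, 18), dtype=np.int64)
    cols = np.empty((n_e, 18, 18), dtype=np.int64)
    data = np.empty((n_e, 18, 18), dtype=float)
    for e in range(n_e):
        tri = mesh.triangles[e]
        ke = element_stiffness(mesh.vertices[tri], material, e, formulation).K_local
        dofs = node_dofs(tri)
        rows[e] = dofs[:, None]
        cols[e] = dofs[None, :]
        data[e] = ke
    K = sp.coo_matrix(
        (data.ravel(), (rows.ravel(), cols.ravel())), shape=(n_dofs, n_dofs)
    ).tocsr()
    K = 0.5 * (K + K.T)

    fixed = node_dofs(mesh.boundary_vertices)
    return FaceFEModel(mesh, material, K.tocsr(), fixed, n_dofs)


def solve_static(model: FaceFEModel, loads) -> np.ndarray:
    """Solve K_f u = f with clamped boundary DOFs (loads must vanish there).

    Returns the full displacement vector (mm and rad); relative residual on
    the free block is checked to 1e-8.
    """
    f = np.asarray(
        loads.toarray().ravel() if sp.issparse(loads) else loads, dtype=float
    )
    if f.shape != (model.n_dofs,):
        raise ParameterError(f"load vector must have length {model.n_dofs}")
    if np.any(f[model.fixed_dofs] != 0.0):
        raise ParameterError("loads must be zero on fixed DOFs")
    free = model.free_dofs
    lu = model.free_factorization()
    u = np.zeros(model.n_dofs)
    u[free] = lu.solve(f[free])
    if not np.all(np.isfinite(u)):
        raise RankError("singular free stiffness block; check boundary conditions")
    fnorm = np.linalg.norm(f[free])
    if fnorm > 0:
        resid = np.linalg.norm(model.K_f[free][:, free] @ u[free] - f[free])
        if resid > 1e-8 * fnorm:
            raise RankError(f"static solve residual too large: {resid / fnorm:.3e}")
    return u
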