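"""Master-node selection and static condensation of the face stiffness.

The face vertices that can touch the mask across *all* design variants are
the master nodes; every other free DOF is a slave and is eliminated exactly
(Guyan reduction, which is exact for statics with zero slave loads):

    K_r = K_m - K_c^T K_slave^{-1} K_c

computed with one sparse factorization of the slave block and multi-RHS
solves; K_slave^{-1} is never formed.  The factorization is kept for slave
displacement recovery, so the full field can be reconstructed from any
master solution without re-solving the full model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .errors import GeometryError, ParameterError, RankError
from .mask_geometry import MaskNodeSet
from .mesh_core import TriSurfaceMesh
from .shell_fem import FaceFEModel, node_dofs

__all__ = [
    "ReducedModel",
    "select_master_nodes",
    "condense",
    "recover_full_displacement",
    "closest_point_on_triangles",
    "nearest_triangles",
]


# ---------------------------------------------------------------------------
# point-to-triangle proximity
# ---------------------------------------------------------------------------


def closest_point_on_triangles(points: np.ndarray, tri_coords: np.ndarray):
    """Closest point on each triangle to each query point (vectorized).

    points: (n, 3); tri_coords: (n, 3, 3) one triangle per point.  Returns
    (closest (n, 3), distance (n,)).  Standard barycentric region algorithm.
    """
    p = np.asarray(points, float)
    a, b, c = tri_coords[:, 0], tri_coords[:, 1], tri_coords[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4
    denom = va + vb + vc
    safe = np.where(denom == 0, 1.0, denom)
    v = vb / safe
    w = vc / safe
    out = a + v[:, None] * ab + w[:, None] * ac  # interior projection

    def _edge(p0, e, num, den):
        t = np.clip(num / np.where(den == 0, 1.0, den), 0.0, 1.0)
        return p0 + t[:, None] * e

    # exclusive Voronoi regions (Ericson), applied over the interior default
    on_bc = _edge(b, c - b, d4 - d3, (d4 - d3) + (d5 - d6))
    on_ac = _edge(a, ac, d2, d2 - d6)
    on_ab = _edge(a, ab, d1, d1 - d3)
    out = np.where(((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0))[:, None], on_bc, out)
    out = np.where(((vb <= 0) & (d2 >= 0) & (d6 <= 0))[:, None], on_ac, out)
    out = np.where(((vc <= 0) & (d1 >= 0) & (d3 <= 0))[:, None], on_ab, out)
    out = np.where(((d6 >= 0) & (d5 <= d6))[:, None], c, out)
    out = np.where(((d3 >= 0) & (d4 <= d3))[:, None], b, out)
    out = np.where(((d1 <= 0) & (d2 <= 0))[:, None], a, out)
    return out, np.linalg.norm(out - p, axis=1)


def nearest_triangles(
    mesh: TriSurfaceMesh, points: np.ndarray, k_candidates: int = 48
):
    """Nearest mesh triangle (exact point-to-triangle distance) per point.

    A cKDTree over triangle centroids proposes candidates; exact distances
    decide among them.  The candidate set is provably sufficient when the
    k-th centroid distance exceeds the best exact distance plus the largest
    triangle circumradius; otherwise it is widened.
    Returns (triangle_index (n,), distance (n,)).
    """
    pts = np.atleast_2d(np.asarray(points, float))
    tri_pts = mesh.vertices[mesh.triangles]
    centroids = tri_pts.mean(axis=1)
    radii = np.linalg.norm(tri_pts - centroids[:, None, :], axis=2).max(axis=1)
    max_radius = float(radii.max())
    tree = cKDTree(centroids)
    m = len(centroids)
    k = min(k_candidates, m)
    best_tri = np.empty(len(pts), dtype=np.int64)
    best_d = np.empty(len(pts))
    todo = np.arange(len(pts))
    while len(todo):
        cd, ci = tree.query(pts[todo], k=k)
        cd = np.atleast_2d(cd)
        ci = np.atleast_2d(ci)
        flat_pts = np.repeat(pts[todo], k, axis=0)
        flat_tris = ci.ravel()
        _, dist = closest_point_on_triangles(flat_pts, tri_pts[flat_tris])
        dist = dist.reshape(len(todo), k)
        j = np.argmin(dist, axis=1)
        rows = np.arange(len(todo))
        best_tri[todo] = ci[rows, j]
        best_d[todo] = dist[rows, j]
        if k >= m:
            break
        # sufficiency: anything outside the k-th centroid ball is farther
        safe = best_d[todo] <= cd[:, -1] - max_radius
        todo = todo[~safe]
        k = min(4 * k, m)
    return best_tri, best_d


def select_master_nodes(
    mesh: TriSurfaceMesh, mask_variants: list[MaskNodeSet] | MaskNodeSet
) -> np.ndarray:
    """Union of contact-candidate face vertices over all mask variants.

    For every mask node of every variant the nearest face triangle is found
    (exact point-to-triangle distance) and its three vertices are added;
    boundary (clamped) vertices are excluded from the result.
    """
    if isinstance(mask_variants, MaskNodeSet):
        mask_variants = [mask_variants]
    if not mask_variants:
        raise ParameterError("need at least one mask variant")
    selected: set[int] = set()
    max_dist = 0.0
    for variant in mask_variants:
        tri_idx, dist = nearest_triangles(mesh, variant.nodes)
        max_dist = max(max_dist, float(dist.max()))
        selected.update(np.unique(mesh.triangles[tri_idx]).tolist())
    masters = np.array(sorted(selected - set(mesh.boundary_vertices.tolist())))
    if len(masters) == 0:
        raise GeometryError(
            "master-node selection is empty (mask may be far from the face; "
            f"max mask-to-face distance {max_dist:.3g} mm)"
        )
    return masters


# ---------------------------------------------------------------------------
# static condensation
# ---------------------------------------------------------------------------


@dataclass
class ReducedModel:
    """Statically condensed face model on the master DOFs.

    ``slave_factorization`` maps a slave-block RHS to the slave solution;
    recovery of the full field is u_s = -K_slave^{-1} K_c u_m with zero
    slave loads, exactly reproducing the unreduced solution.
    """

    master_nodes: np.ndarray
    master_dofs: np.ndarray
    slave_dofs: np.ndarray
    fixed_dofs: np.ndarray
    n_dofs: int
    K_r: np.ndarray
    slave_factorization: object = field(repr=False)
    K_c: sp.csr_matrix = field(repr=False)  # slave x master coupling block
    _chol: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def n_master_dofs(self) -> int:
        return len(self.master_dofs)

    @property
    def n_slave_dofs(self) -> int:
        return len(self.slave_dofs)

    def master_dof_local(self, vertex: int, component: int) -> int:
        """Local index in the reduced system of (vertex, dof component)."""
        g = vertex * 6 + component
        pos = np.searchsorted(self.master_dofs, g)
        if pos >= len(self.master_dofs) or self.master_dofs[pos] != g:
            raise ParameterError(f"vertex {vertex} component {component} is not a master DOF")
        return int(pos)

    def cholesky(self):
        from scipy.linalg import cho_factor

        if self._chol is None:
            self._chol = cho_factor(self.K_r, lower=True)
        return self._chol

    def save(self, path) -> None:
        """Compressed archive (master indices + dense K_r) for sweep reuse."""
        np.savez_compressed(
            path,
            master_nodes=self.master_nodes,
            master_dofs=self.master_dofs,
            slave_dofs=self.slave_dofs,
            fixed_dofs=self.fixed_dofs,
            n_dofs=np.int64(self.n_dofs),
            K_r=self.K_r,
        )


def condense(model: FaceFEModel, master_nodes) -> ReducedModel:
    """Statically condense K_f onto all 6 DOFs of the master nodes."""
    master_nodes = np.unique(np.asarray(master_nodes, dtype=np.int64))
    if len(master_nodes) == 0:
        raise ParameterError("need at least one master node")
    if np.intersect1d(master_nodes, model.mesh.boundary_vertices).size:
        raise ParameterError("master nodes must not lie on the fixed boundary")

    master_dofs = np.sort(node_dofs(master_nodes))
    free_mask = np.ones(model.n_dofs, dtype=bool)
    free_mask[model.fixed_dofs] = False
    slave_mask = free_mask.copy()
    slave_mask[master_dofs] = False
    slave_dofs = np.flatnonzero(slave_mask)

    K = model.K_f
    K_mm = K[master_dofs][:, master_dofs].toarray()
    if len(slave_dofs):
        K_ss = K[slave_dofs][:, slave_dofs].tocsc()
        K_c = K[slave_dofs][:, master_dofs].tocsr()
        try:
            lu = spla.splu(K_ss)
        except RuntimeError as exc:  # pragma: no cover - singular slave block
            raise RankError(
                "singular slave block; insufficient boundary conditions"
            ) from exc
        X = lu.solve(K_c.toarray())
        K_r = K_mm - K_c.T @ X
    else:
        lu = None
        K_c = sp.csr_matrix((0, len(master_dofs)))
        K_r = K_mm
    K_r = 0.5 * (K_r + K_r.T)
    return ReducedModel(
        master_nodes=master_nodes,
        master_dofs=master_dofs,
        slave_dofs=slave_dofs,
        fixed_dofs=np.asarray(model.fixed_dofs),
        n_dofs=model.n_dofs,
        K_r=K_r,
        slave_factorization=lu,
        K_c=K_c,
    )


def recover_full_displacement(reduced: ReducedModel, u_m: np.ndarray) -> np.ndarray:
    """Expand a master displacement to the full DOF vector.

    Slave part: u_s = -K_slave^{-1} K_c u_m (zero slave forces); fixed DOFs
    are zero.
    """
    u_m = np.asarray(u_m, float)
    if u_m.shape != (reduced.n_master_dofs,):
        raise ParameterError(
            f"u_m must have length {reduced.n_master_dofs}, got {u_m.shape}"
        )
    u = np.zeros(reduced.n_dofs)
    u[reduced.master_dofs] = u_m
    if reduced.n_slave_dofs:
        u[reduced.slave_dofs] = -reduced.slave_factorization.solve(
            reduced.K_c @ u_m
        )
    return u


def load_reduced(path) -> ReducedModel:
    """Load a reduced model saved with :meth:`ReducedModel.save`.

    The slave factorization is not stored; recovery needs re-condensation,
    but contact solves on K_r work directly.
    """
    data = np.load(path)
    return ReducedModel(
        master_nodes=data["master_nodes"],
        master_dofs=data["master_dofs"],
        slave_dofs=data["slave_dofs"],
        fixed_dofs=data["fixed_dofs"],
        n_dofs=int(data["n_dofs"]),
        K_r=data["K_r"],
        slave_factorization=None,
        K_c=sp.csr_matrix((len(data["slave_dofs"]), len(data["master_dofs"]))),
    )
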