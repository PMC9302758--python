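"""Node-to-node Lagrange-multiplier contact between face and rigid mask.

The mask is rigid and is pushed a prescribed depth toward the face along a
fixed direction (default -Z for a face looking along +Z).  Each mask node
pairs with its nearest master face vertex; the prescribed penetration to
resolve is

    d_f = push_depth - clearance

where clearance is the initial signed distance from the face vertex to its
mask node along the push direction.  Pairs with d_f <= 0 never touch at
this depth and are dropped (zero-pressure regions).  The remaining pairs
enforce u . direction = d_f on the vertex translation through Lagrange
multipliers in the saddle system

    [ K_r  C_r ] [u_m]   [f_r]
    [ C_r^T  0 ] [ L ] = [d_f]

solved by block elimination (Schur complement on the multipliers); a
tensile-multiplier active-set loop removes pairs with negative contact
force and re-solves until all retained multipliers are compressive.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve, solve
from scipy.spatial import cKDTree

from .condensation import ReducedModel
from .errors import ContactError, ParameterError, RankError
from .mask_geometry import MaskNodeSet
from .mesh_core import TriSurfaceMesh
from .shell_fem import FaceFEModel

__all__ = [
    "ContactProblem",
    "ContactSolution",
    "build_contact_problem",
    "solve_contact",
    "solve_contact_full",
]

DEFAULT_DIRECTION = (0.0, 0.0, -1.0)  # mask pushes toward the +Z-facing face


@dataclass(frozen=True)
class ContactProblem:
    """Node-to-node contact pairs with prescribed penetrations.

    ``face_vertices``/``mask_nodes`` are the retained (d_f > 0) pairs,
    unique in face vertex.  ``all_face_vertices`` also records pairs dropped
    in gap pre-screening, so that zero-pressure nodes can be reported.
    """

    face_vertices: np.ndarray      # (n_pairs,) vertex indices, unique
    mask_node_indices: np.ndarray  # (n_pairs,) indices into the mask node set
    gaps: np.ndarray               # (n_pairs,) d_f > 0, mm
    push_depth: float
    direction: np.ndarray
    all_face_vertices: np.ndarray  # pairs before gap screening, unique
    f_r: np.ndarray | None = None  # optional external master load

    @property
    def n_pairs(self) -> int:
        return len(self.face_vertices)

    def constraint_matrix(self, reduced: ReducedModel) -> np.ndarray:
        """Dense C_r (n_master_dofs x n_pairs): direction cosines on the
        translation DOFs of each paired master vertex."""
        C = np.zeros((reduced.n_master_dofs, self.n_pairs))
        for j, v in enumerate(self.face_vertices):
            for comp in range(3):
                if self.direction[comp] != 0.0:
                    C[reduced.master_dof_local(int(v), comp), j] = self.direction[comp]
        return C


@dataclass
class ContactSolution:
    """Result of a contact solve on the reduced model."""

    u_m: np.ndarray                # master displacement (mm, rad)
    lambdas: np.ndarray            # contact force per active pair (N, >= 0)
    active_pairs: np.ndarray      # indices into the problem's retained pairs
    iterations: int
    solve_time: float = 0.0

    @property
    def total_force(self) -> float:
        """Total contact force along the push direction (N)."""
        return float(self.lambdas.sum())


def build_contact_problem(
    mesh: TriSurfaceMesh,
    reduced: ReducedModel,
    mask_nodes: MaskNodeSet,
    push_depth: float,
    direction=DEFAULT_DIRECTION,
) -> ContactProblem:
    """Pair each mask node with its nearest master face vertex.

    When several mask nodes map to the same face vertex the closest wins.
    Clearance is measured along the push direction; pairs whose clearance
    exceeds the push depth are dropped.
    """
    if push_depth <= 0:
        raise ParameterError("push_depth must be positive")
    direction = np.asarray(direction, float)
    nrm = np.linalg.norm(direction)
    if nrm == 0:
        raise ParameterError("direction must be a nonzero vector")
    direction = direction / nrm

    master_xyz = mesh.vertices[reduced.master_nodes]
    tree = cKDTree(master_xyz)
    _, nearest = tree.query(mask_nodes.nodes)
    face_vertex = reduced.master_nodes[nearest]

    # clearance: distance the mask travels along `direction` before touching
    clearance = np.einsum(
        "ij,j->i", mask_nodes.nodes - mesh.vertices[face_vertex], -direction
    )

    # unique in face vertex: keep the closest mask node
    order = np.lexsort((clearance, face_vertex))
    fv_sorted = face_vertex[order]
    keep = np.ones(len(order), dtype=bool)
    keep[1:] = fv_sorted[1:] != fv_sorted[:-1]
    sel = order[keep]

    gaps = push_depth - clearance[sel]
    positive = gaps > 0
    if not np.any(positive):
        raise ContactError(
            f"no contact at push depth {push_depth} mm "
            f"(min clearance {clearance[sel].min():.3g} mm)"
        )
    return ContactProblem(
        face_vertices=face_vertex[sel][positive],
        mask_node_indices=np.asarray(sel)[positive],
        gaps=gaps[positive],
        push_depth=float(push_depth),
        direction=direction,
        all_face_vertices=face_vertex[sel],
    )


def _active_set_solve(solve_K, C, d, f, max_iters: int, tol: float):
    """Shared active-set loop: solve_K maps RHS columns -> K^{-1} RHS."""
    n_pairs = C.shape[1]
    active = np.arange(n_pairs)
    u = None
    lam = np.empty(0)
    for it in range(1, max_iters + 1):
        Ca = C[:, active]
        Y = solve_K(Ca)
        S = Ca.T @ Y
        rhs = d[active] - (Ca.T @ solve_K(f) if f is not None else 0.0)
        try:
            lam = solve(S, rhs, assume_a="pos")
        except np.linalg.LinAlgError as exc:
            raise RankError(
                f"singular contact Schur complement (duplicate constraints among "
                f"pairs {active.tolist()})"
            ) from exc
        negative = lam < -tol
        if not np.any(negative):
            u = Y @ lam + (solve_K(f) if f is not None else 0.0)
            return u, np.maximum(lam, 0.0), active, it
        active = active[~negative]
        if len(active) == 0:
            raise ContactError("all contact pairs released (tensile); no contact")
    raise ContactError(f"active-set loop did not converge in {max_iters} iterations")


def solve_contact(
    reduced: ReducedModel,
    problem: ContactProblem,
    max_active_set_iters: int = 50,
    tol: float = 1e-10,
) -> ContactSolution:
    """Solve the reduced saddle-point contact system with an active-set loop.

    Signs are fixed so that retained multipliers are compressive (lambda >=
    0 is the contact force on the face along the push direction).
    """
    t0 = time.perf_counter()
    C = problem.constraint_matrix(reduced)
    chol = reduced.cholesky()

    def solve_K(rhs):
        return cho_solve(chol, rhs)

    f = problem.f_r if problem.f_r is not None else None
    u_m, lam, active, it = _active_set_solve(
        solve_K, C, problem.gaps, f, max_active_set_iters, tol
    )
    sol = ContactSolution(
        u_m=u_m,
        lambdas=lam,
        active_pairs=active,
        iterations=it,
        solve_time=time.perf_counter() - t0,
    )
    # constraint satisfaction on active pairs
    resid = np.abs(C[:, active].T @ u_m - problem.gaps[active])
    if len(resid) and resid.max() > 1e-8:
        raise RankError(f"contact constraint residual {resid.max():.3e} mm")
    return sol


def solve_contact_full(
    model: FaceFEModel,
    problem: ContactProblem,
    max_active_set_iters: int = 50,
    tol: float = 1e-10,
):
    """Contact solve on the unreduced sparse model (validation/benchmark path).

    Assembles the full augmented saddle system on the free DOFs and runs the
    same active-set loop.  Returns (full displacement vector, lambdas,
    active pair indices).
    """
    free = model.free_dofs
    pos = -np.ones(model.n_dofs, dtype=np.int64)
    pos[free] = np.arange(len(free))
    C = np.zeros((len(free), problem.n_pairs))
    for j, v in enumerate(problem.face_vertices):
        for comp in range(3):
            if problem.direction[comp] != 0.0:
                g = int(v) * 6 + comp
                if pos[g] < 0:
                    raise ParameterError(f"paired vertex {v} is fixed")
                C[pos[g], j] = problem.direction[comp]
    lu = model.free_factorization()

    def solve_K(rhs):
        return lu.solve(np.asarray(rhs))

    f = None
    if problem.f_r is not None:  # pragma: no cover - f_r defaults to zero
        f = problem.f_r
    u_free, lam, active, _ = _active_set_solve(
        solve_K, C, problem.gaps, f, max_active_set_iters, tol
    )
    u = np.zeros(model.n_dofs)
    u[free] = u_free
    return u, lam, active
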