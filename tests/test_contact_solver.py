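"""Lagrange-multiplier contact: pairing, saddle solve, active set, statics."""

import numpy as np
import pytest
import scipy.sparse as sp

from maskfit import (
    MaskDesign,
    build_contact_problem,
    condense,
    recover_full_displacement,
    reference_loop_on_face,
    sample_mask_nodes,
    select_master_nodes,
    solve_contact,
    solve_contact_full,
)
from maskfit.condensation import ReducedModel
from maskfit.contact_solver import ContactProblem
from maskfit.errors import ContactError, ParameterError
from maskfit.mask_geometry import MaskNodeSet
from maskfit.mesh_core import SyntheticFaceSpec, generate_synthetic_face
from maskfit.shell_fem import ShellMaterial, assemble_stiffness


def _single_dof_reduced(k: float) -> ReducedModel:
    """A reduced model with one master node (6 DOFs) and scalar stiffness on
    each DOF, for closed-form checks."""
    return ReducedModel(
        master_nodes=np.array([0]),
        master_dofs=np.arange(6),
        slave_dofs=np.empty(0, dtype=np.int64),
        fixed_dofs=np.empty(0, dtype=np.int64),
        n_dofs=6,
        K_r=k * np.eye(6),
        slave_factorization=None,
        K_c=sp.csr_matrix((0, 6)),
    )


class TestBuildContactProblem:
    def test_zero_clearance_gap_equals_push(self, face_mesh, reduced8):
        v = int(reduced8.master_nodes[0])
        nodes = MaskNodeSet(face_mesh.vertices[v][None], np.array([0]))
        problem = build_contact_problem(face_mesh, reduced8, nodes, 3.0)
        assert problem.n_pairs == 1
        assert problem.gaps[0] == pytest.approx(3.0)

    def test_far_node_dropped(self, face_mesh, reduced8):
        v = int(reduced8.master_nodes[0])
        near = face_mesh.vertices[v] + [0, 0, 0.5]
        far = face_mesh.vertices[int(reduced8.master_nodes[-1])] + [0, 0, 5.0]
        nodes = MaskNodeSet(np.vstack([near, far]), np.array([0, 1]))
        problem = build_contact_problem(face_mesh, reduced8, nodes, 3.0)
        assert problem.n_pairs == 1
        assert len(problem.all_face_vertices) == 2

    def test_no_contact_raises(self, face_mesh, reduced8):
        v = int(reduced8.master_nodes[0])
        nodes = MaskNodeSet(face_mesh.vertices[v][None] + [0, 0, 9.0], np.array([0]))
        with pytest.raises(ContactError):
            build_contact_problem(face_mesh, reduced8, nodes, 3.0)

    def test_duplicate_face_vertex_keeps_closest(self, face_mesh, reduced8):
        v = int(reduced8.master_nodes[0])
        base = face_mesh.vertices[v]
        nodes = MaskNodeSet(
            np.vstack([base + [0, 0, 1.0], base + [0, 0, 0.2]]), np.array([0, 1])
        )
        problem = build_contact_problem(face_mesh, reduced8, nodes, 3.0)
        assert problem.n_pairs == 1
        assert problem.gaps[0] == pytest.approx(3.0 - 0.2)

    def test_pairing_matches_bruteforce_nearest_vertex(
        self, small_mesh, small_model
    ):
        spec = SyntheticFaceSpec(target_vertex_count=300, seed=3)
        loop = reference_loop_on_face(spec)
        nodes = sample_mask_nodes(MaskDesign(loop))
        masters = select_master_nodes(small_mesh, [nodes])
        reduced = condense(small_model, masters)
        problem = build_contact_problem(small_mesh, reduced, nodes, 3.0)
        # O(N*M) oracle over master vertices
        mv = small_mesh.vertices[masters]
        for pair_idx, mask_idx in enumerate(problem.mask_node_indices):
            p = nodes.nodes[mask_idx]
            d = np.linalg.norm(mv - p, axis=1)
            assert problem.face_vertices[pair_idx] == masters[np.argmin(d)]

    def test_invalid_push_depth(self, face_mesh, reduced8, mask_nodes8):
        with pytest.raises(ParameterError):
            build_contact_problem(face_mesh, reduced8, mask_nodes8, -1.0)


class TestSolveContact:
    def test_single_pair_closed_form(self):
        # one pair on one free node with scalar stiffness k and gap d:
        # u = d along the push direction, lambda = k*d
        k, d = 4.0, 0.7
        reduced = _single_dof_reduced(k)
        problem = ContactProblem(
            face_vertices=np.array([0]),
            mask_node_indices=np.array([0]),
            gaps=np.array([d]),
            push_depth=3.0,
            direction=np.array([0.0, 0.0, -1.0]),
            all_face_vertices=np.array([0]),
        )
        sol = solve_contact(reduced, problem)
        assert sol.lambdas[0] == pytest.approx(k * d)
        assert sol.u_m[2] == pytest.approx(-d)  # pushed along -Z

    def test_gap_scaling_scales_lambdas(self, reduced8, face_mesh, mask_nodes8):
        problem = build_contact_problem(face_mesh, reduced8, mask_nodes8, 3.0)
        sol = solve_contact(reduced8, problem)
        scaled = ContactProblem(
            face_vertices=problem.face_vertices,
            mask_node_indices=problem.mask_node_indices,
            gaps=2.0 * problem.gaps,
            push_depth=problem.push_depth,
            direction=problem.direction,
            all_face_vertices=problem.all_face_vertices,
        )
        sol2 = solve_contact(reduced8, scaled)
        np.testing.assert_array_equal(sol.active_pairs, sol2.active_pairs)
        np.testing.assert_allclose(sol2.lambdas, 2.0 * sol.lambdas, rtol=1e-10)

    def test_constraint_residual_and_nonnegative_lambdas(
        self, face_mesh, reduced8, mask_nodes8
    ):
        problem = build_contact_problem(face_mesh, reduced8, mask_nodes8, 3.0)
        sol = solve_contact(reduced8, problem)
        C = problem.constraint_matrix(reduced8)
        resid = C[:, sol.active_pairs].T @ sol.u_m - problem.gaps[sol.active_pairs]
        assert np.abs(resid).max() < 1e-8
        assert np.all(sol.lambdas >= 0)

    def test_complementarity_of_released_pairs(self, face_mesh, reduced8, mask_nodes8):
        # re-adding one released pair must produce a tensile multiplier
        problem = build_contact_problem(face_mesh, reduced8, mask_nodes8, 3.0)
        sol = solve_contact(reduced8, problem)
        released = np.setdiff1d(np.arange(problem.n_pairs), sol.active_pairs)
        if len(released) == 0:
            pytest.skip("no released pairs at this push depth")
        from scipy.linalg import cho_solve, solve

        test_set = np.sort(np.append(sol.active_pairs, released[0]))
        C = problem.constraint_matrix(reduced8)[:, test_set]
        Y = cho_solve(reduced8.cholesky(), C)
        lam = solve(C.T @ Y, problem.gaps[test_set], assume_a="pos")
        j = int(np.flatnonzero(test_set == released[0])[0])
        assert lam[j] < 0

    def test_total_force_monotone_in_push_depth(self, face_mesh, reduced8, mask_nodes8):
        totals = []
        for depth in (2.0, 3.0, 4.0):
            problem = build_contact_problem(face_mesh, reduced8, mask_nodes8, depth)
            totals.append(solve_contact(reduced8, problem).total_force)
        assert totals[0] <= totals[1] <= totals[2]

    def test_static_equilibrium_with_boundary_reaction(
        self, face_mesh, face_model, reduced8, mask_nodes8
    ):
        # total contact force balances the reaction transmitted to the
        # clamped boundary along the push direction
        problem = build_contact_problem(face_mesh, reduced8, mask_nodes8, 3.0)
        sol = solve_contact(reduced8, problem)
        u = recover_full_displacement(reduced8, sol.u_m)
        r = face_model.K_f @ u
        reaction = sum(
            float(np.dot(r[6 * v : 6 * v + 3], problem.direction))
            for v in face_mesh.boundary_vertices
        )
        assert reaction + sol.total_force == pytest.approx(
            0.0, abs=1e-6 * sol.total_force
        )


class TestReductionExactness:
    """Reduced contact solve == full-model contact solve (the central
    correctness property of the condensation + contact pipeline)."""

    @pytest.mark.parametrize("seed,target", [(11, 200), (12, 500), (13, 900)])
    def test_reduced_equals_full_solve(self, seed, target):
        spec = SyntheticFaceSpec(target_vertex_count=target, seed=seed)
        mesh = generate_synthetic_face(spec)
        model = assemble_stiffness(mesh, ShellMaterial())
        loop = reference_loop_on_face(spec, phase=0.1 * seed)
        nodes = sample_mask_nodes(MaskDesign(loop))
        masters = select_master_nodes(mesh, [nodes])
        reduced = condense(model, masters)
        problem = build_contact_problem(mesh, reduced, nodes, 3.0)

        sol = solve_contact(reduced, problem)
        u_reduced = recover_full_displacement(reduced, sol.u_m)
        u_full, lam_full, active_full = solve_contact_full(model, problem)

        np.testing.assert_array_equal(sol.active_pairs, active_full)
        scale_u = np.abs(u_full).max()
        assert np.abs(u_reduced - u_full).max() < 1e-8 * scale_u
        scale_l = np.abs(lam_full).max()
        assert np.abs(sol.lambdas - lam_full).max() < 1e-8 * scale_l
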