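"""Shell element and assembly: constitutive blocks, patch tests, benchmark."""

import numpy as np
import pytest

from maskfit import (
    ShellMaterial,
    TriSurfaceMesh,
    assemble_stiffness,
    elasticity_matrices,
    element_stiffness,
    solve_static,
    structured_rectangle_mesh,
)
from maskfit.errors import GeometryError, ParameterError, RankError
from maskfit.shell_fem import LOCAL_ELEMENT_DOFS


@pytest.fixture(scope="module")
def soft_tissue():
    return ShellMaterial()  # E=0.03 MPa, nu=0.49, h=2 mm


class TestMaterial:
    def test_defaults_are_soft_tissue(self, soft_tissue):
        assert soft_tissue.E == 0.03
        assert soft_tissue.nu == 0.49
        assert soft_tissue.h == 2.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"E": 0.0},
            {"nu": 0.5},
            {"nu": -0.1},
            {"h": 0.0},
            {"kappa": 0.0},
            {"drilling_factor": -1.0},
        ],
    )
    def test_invalid_material_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            ShellMaterial(**kwargs)

    def test_elasticity_matrix_values(self, soft_tissue):
        D_b, D_p, D_s = elasticity_matrices(soft_tissue)
        # bending rigidity E h^3 / (12 (1 - nu^2)) on the default soft-tissue constants
        assert D_b[0, 0] == pytest.approx(0.03 * 8.0 / (12.0 * (1 - 0.2401)), rel=1e-12)
        assert D_b[0, 0] == pytest.approx(0.0263189, rel=1e-4)
        # shear modulus G = E / (2 (1 + nu))
        assert soft_tissue.G == pytest.approx(0.0100671, rel=1e-4)
        assert D_s == pytest.approx(soft_tissue.kappa * soft_tissue.G * soft_tissue.h)
        np.testing.assert_allclose(D_b, D_b.T)
        np.testing.assert_allclose(D_p * soft_tissue.h**3 / 12.0, D_b, rtol=1e-12)

    def test_zero_poisson_structure(self):
        D_b, _, _ = elasticity_matrices(ShellMaterial(E=1.0, nu=0.0, h=2.0))
        assert D_b[0, 1] == 0.0
        assert D_b[2, 2] == pytest.approx(1.0 * 8.0 / 24.0)


class TestElementStiffness:
    coords = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [1.0, 2.0, 0.0]])

    def test_local_dof_count_before_drilling(self):
        # 3 translations + 2 rotations per node on 3 nodes
        assert LOCAL_ELEMENT_DOFS == 15

    def test_symmetric_psd(self, soft_tissue):
        K = element_stiffness(self.coords, soft_tissue).K_local
        assert np.abs(K - K.T).max() < 1e-10 * np.abs(K).max()
        eig = np.linalg.eigvalsh(K)
        assert eig.min() > -1e-10 * eig.max()

    def test_rigid_translations_have_zero_energy(self, soft_tissue):
        K = element_stiffness(self.coords, soft_tissue).K_local
        for d in range(3):
            v = np.zeros(18)
            v[d::6] = 1.0
            assert abs(v @ K @ v) < 1e-10 * K.diagonal().max()

    def test_rigid_rotations_have_zero_energy(self, soft_tissue):
        coords = np.array([[0.0, 0.0, 1.0], [3.0, 0.5, 0.8], [1.0, 2.0, 1.5]])
        K = element_stiffness(coords, soft_tissue).K_local
        for ax in range(3):
            th = np.zeros(3)
            th[ax] = 1.0
            v = np.zeros(18)
            for i in range(3):
                v[6 * i : 6 * i + 3] = np.cross(th, coords[i])
                v[6 * i + 3 : 6 * i + 6] = th
            assert abs(v @ K @ v) < 1e-9 * K.diagonal().max()

    def test_membrane_block_matches_cst_oracle(self, soft_tissue):
        # independent B-matrix integration of the constant-strain triangle
        # on a right triangle with legs 1, 1
        coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        K = element_stiffness(coords, soft_tissue).K_local
        mem_idx = [0, 1, 6, 7, 12, 13]
        K_mem = K[np.ix_(mem_idx, mem_idx)]

        x = coords[:, 0]
        y = coords[:, 1]
        A = 0.5
        b = np.array([y[1] - y[2], y[2] - y[0], y[0] - y[1]]) / (2 * A)
        c = np.array([x[2] - x[1], x[0] - x[2], x[1] - x[0]]) / (2 * A)
        B = np.zeros((3, 6))
        for i in range(3):
            B[0, 2 * i] = b[i]
            B[1, 2 * i + 1] = c[i]
            B[2, 2 * i] = c[i]
            B[2, 2 * i + 1] = b[i]
        _, D_p, _ = elasticity_matrices(soft_tissue)
        K_oracle = soft_tissue.h * A * B.T @ D_p @ B
        np.testing.assert_allclose(K_mem, K_oracle, atol=1e-10)

    def test_constant_curvature_patch(self, soft_tissue):
        # w = x^2/2 (unit kappa_xx): energy must equal 0.5 * D_b[0,0] * A
        K = element_stiffness(self.coords, soft_tissue).K_local
        D_b, _, _ = elasticity_matrices(soft_tissue)
        v = np.zeros(18)
        for i in range(3):
            v[6 * i + 2] = 0.5 * self.coords[i, 0] ** 2
            v[6 * i + 4] = -self.coords[i, 0]  # th_y = -w,x
        A = 3.0  # 0.5 * |cross|
        assert v @ K @ v / 2 == pytest.approx(0.5 * D_b[0, 0] * A, rel=1e-10)

    def test_degenerate_triangle_raises(self, soft_tissue):
        bad = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        with pytest.raises(GeometryError):
            element_stiffness(bad, soft_tissue)

    def test_frame_invariance_under_rotation(self, soft_tissue):
        # energy of a deformation pattern is invariant under rigid rotation
        # of element + pattern
        rng = np.random.default_rng(0)
        v = rng.normal(size=18)
        K0 = element_stiffness(self.coords, soft_tissue).K_local
        e0 = v @ K0 @ v
        from scipy.spatial.transform import Rotation

        R = Rotation.from_rotvec([0.4, -0.3, 0.7]).as_matrix()
        coords_r = self.coords @ R.T
        v_r = v.copy()
        for i in range(6):
            v_r[3 * i : 3 * i + 3] = R @ v[3 * i : 3 * i + 3]
        K1 = element_stiffness(coords_r, soft_tissue).K_local
        assert v_r @ K1 @ v_r == pytest.approx(e0, rel=1e-9)


class TestAssembly:
    def test_dof_bookkeeping(self, face_mesh, face_model):
        assert face_model.n_dofs == 6 * face_mesh.n_vertices

    def test_assembled_symmetry(self, face_model):
        K = face_model.K_f
        diff = abs(K - K.T).max()
        assert diff < 1e-12 * abs(K).max()

    def test_single_triangle_assembly_equals_element(self, soft_tissue):
        mesh = TriSurfaceMesh(
            np.array([[0.0, 0, 0], [3, 0, 0], [1, 2, 0]]), np.array([[0, 1, 2]])
        )
        model = assemble_stiffness(mesh, soft_tissue)
        K_e = element_stiffness(mesh.vertices, soft_tissue).K_local
        np.testing.assert_allclose(model.K_f.toarray(), K_e, atol=1e-14)

    def test_free_block_positive_definite(self, small_model):
        free = small_model.free_dofs
        K_ff = small_model.K_f[free][:, free].toarray()
        eig_min = np.linalg.eigvalsh(K_ff)[0]
        assert eig_min > 0

    def test_fixed_dofs_are_boundary_dofs(self, face_mesh, face_model):
        expected = sorted(
            6 * v + c for v in face_mesh.boundary_vertices for c in range(6)
        )
        assert sorted(face_model.fixed_dofs.tolist()) == expected


class TestSolveStatic:
    def test_zero_load_zero_displacement(self, small_model):
        u = solve_static(small_model, np.zeros(small_model.n_dofs))
        assert np.all(u == 0)

    def test_linearity_in_load(self, small_model, rng):
        f = np.zeros(small_model.n_dofs)
        free = small_model.free_dofs
        f[free] = rng.normal(size=len(free))
        u1 = solve_static(small_model, f)
        u3 = solve_static(small_model, 3.0 * f)
        np.testing.assert_allclose(u3, 3.0 * u1, rtol=1e-10, atol=1e-14)

    def test_doubling_E_halves_displacement(self, small_mesh):
        f = None
        us = []
        for E in (0.03, 0.06):
            model = assemble_stiffness(small_mesh, ShellMaterial(E=E))
            if f is None:
                f = np.zeros(model.n_dofs)
                interior = np.setdiff1d(
                    np.arange(small_mesh.n_vertices), small_mesh.boundary_vertices
                )
                f[6 * interior[5] + 2] = -1e-3
            us.append(solve_static(model, f))
        np.testing.assert_allclose(us[1], 0.5 * us[0], rtol=1e-9, atol=1e-16)

    def test_load_on_fixed_dof_rejected(self, small_model):
        f = np.zeros(small_model.n_dofs)
        f[small_model.fixed_dofs[0]] = 1.0
        with pytest.raises(ParameterError):
            solve_static(small_model, f)

    def test_unconstrained_model_raises_rank_error(self):
        # closed surface: no open edge, nothing clamped
        t = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])
        v = np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]])
        model = assemble_stiffness(TriSurfaceMesh(v, t), ShellMaterial())
        f = np.zeros(model.n_dofs)
        f[2] = 1.0
        with pytest.raises(RankError):
            solve_static(model, f)


class TestPlateBenchmark:
    """Clamped square plate, central point load, vs the classical series
    solution w_c = 0.00560 P a^2 / D."""

    E, nu, h, a = 0.03, 0.3, 2.0, 100.0
    P = 1e-3

    def _center_deflection(self, n):
        mat = ShellMaterial(E=self.E, nu=self.nu, h=self.h)
        mesh = structured_rectangle_mesh(n, n, self.a, self.a)
        model = assemble_stiffness(mesh, mat)
        i = int(np.argmin(np.linalg.norm(mesh.vertices[:, :2], axis=1)))
        f = np.zeros(model.n_dofs)
        f[6 * i + 2] = -self.P
        u = solve_static(model, f)
        return abs(u[6 * i + 2])

    def test_convergence_to_series_solution(self):
        D = self.E * self.h**3 / (12 * (1 - self.nu**2))
        w_ref = 0.00560 * self.P * self.a**2 / D
        errors = [
            abs(self._center_deflection(n) - w_ref) / w_ref for n in (8, 16, 32)
        ]
        assert errors[-1] < 0.05
        # monotone error decrease over the three refinement levels
        assert errors[0] > errors[1] > errors[2]
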