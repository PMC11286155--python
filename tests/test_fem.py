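"""Finite-element core: materials, assembly, solve, strain/stress."""

import numpy as np
import pytest

from cranioload import (
    AgeMaterialModel,
    ConstraintSet,
    FactorizedSystem,
    Solution,
    assemble,
    element_materials,
    material_at_age,
    strain_stress,
)
from cranioload.errors import DomainError, MeshQualityError, SingularSystemError
from cranioload.fem import hooke_matrix

from conftest import FORCES_48, block_mesh


class TestMaterials:
    @pytest.mark.parametrize(
        "age,expected",
        [
            (3, (421.0, 0.22, 30.0, 0.30)),
            (12, (1546.0, 0.22, 930.0, 0.30)),
            (48, (6046.0, 0.22, 930.0, 0.30)),  # joint modulus frozen at 12 mo
        ],
    )
    def test_age_growth_law(self, age, expected):
        assert material_at_age(age) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("age", [2.9, 48.1, -1.0])
    def test_age_domain(self, age):
        with pytest.raises(DomainError):
            material_at_age(age)

    def test_suture_elements_get_joint_modulus(self):
        from cranioload import SkullParams, build_skull_mesh
        from conftest import COARSE

        mesh = build_skull_mesh(SkullParams(age_months=6, **COARSE))
        E, nu = element_materials(mesh, 6.0)
        sut = mesh.is_suture()
        assert sut.any()
        assert np.allclose(E[sut], 330.0) and np.allclose(nu[sut], 0.30)
        assert np.allclose(E[~sut], 421.0 + 125.0 * 3.0) and np.allclose(nu[~sut], 0.22)


class TestAssembly:
    def test_rigid_modes_in_null_space(self):
        mesh = block_mesh(1, 1, 1)
        K = assemble(mesh, 100.0, 0.3)
        K = K.toarray()
        assert np.allclose(K, K.T, atol=1e-10)
        for axis in range(3):
            t = np.zeros((mesh.n_nodes, 3))
            t[:, axis] = 1.0
            assert np.allclose(K @ t.ravel(), 0.0, atol=1e-9)

    def test_against_dense_brute_force(self):
        # independent oracle: per-element shape coefficients from a 4x4
        # polynomial solve, dense python-loop assembly
        mesh = block_mesh(1, 1, 2, pitch=0.8)
        E, nu = 321.0, 0.27
        C = hooke_matrix(E, nu)
        n = mesh.n_nodes
        K_ref = np.zeros((3 * n, 3 * n))
        for tet in mesh.tets:
            X = mesh.nodes[tet]
            M = np.hstack([np.ones((4, 1)), X])
            coef = np.linalg.inv(M)  # rows: 1, x, y, z coefficients
            vol = abs(np.linalg.det(M)) / 6.0
            B = np.zeros((6, 12))
            for i in range(4):
                gx, gy, gz = coef[1, i], coef[2, i], coef[3, i]
                B[:, 3 * i : 3 * i + 3] = [
                    [gx, 0, 0], [0, gy, 0], [0, 0, gz],
                    [gy, gx, 0], [0, gz, gy], [gz, 0, gx],
                ]
            Ke = vol * B.T @ C @ B
            dof = np.array([3 * nd + ax for nd in tet for ax in range(3)])
            K_ref[np.ix_(dof, dof)] += Ke
        K = assemble(mesh, E, nu).toarray()
        assert np.allclose(K, K_ref, atol=1e-12 * np.abs(K_ref).max())

    def test_inverted_element_rejected(self):
        mesh = block_mesh(1, 1, 1)
        mesh.tets[0] = mesh.tets[0][[1, 0, 2, 3]]
        with pytest.raises(MeshQualityError):
            assemble(mesh, 100.0, 0.3)


class TestSolve:
    def _clamped_block(self):
        mesh = block_mesh(4, 2, 2)
        fixed = np.flatnonzero(mesh.nodes[:, 0] == 0.0)
        cons = ConstraintSet(nodes=fixed)
        K = assemble(mesh, 500.0, 0.3)
        return mesh, FactorizedSystem(K, cons, mesh.nodes)

    def test_zero_load(self):
        mesh, sys_ = self._clamped_block()
        sol = sys_.solve(np.zeros((mesh.n_nodes, 3)))
        assert np.allclose(sol.u, 0.0) and np.allclose(sol.reactions, 0.0)

    def test_global_equilibrium(self, rng):
        mesh, sys_ = self._clamped_block()
        f = rng.normal(size=(mesh.n_nodes, 3))
        f[sys_.constraints.nodes] = 0.0
        sol = sys_.solve(f)
        total = f.sum(axis=0) + sol.reactions.sum(axis=0)
        assert np.linalg.norm(total) < 1e-8 * np.linalg.norm(f)

    def test_superposition_and_linearity(self, rng):
        mesh, sys_ = self._clamped_block()
        f1 = rng.normal(size=(mesh.n_nodes, 3))
        f2 = rng.normal(size=(mesh.n_nodes, 3))
        u1, u2 = sys_.solve(f1).u, sys_.solve(f2).u
        u12 = sys_.solve(f1 + f2).u
        assert np.allclose(u12, u1 + u2, atol=1e-8 * np.abs(u1).max())
        assert np.allclose(sys_.solve(2.5 * f1).u, 2.5 * u1, atol=1e-10)

    def test_insufficient_constraints(self):
        mesh = block_mesh(2, 1, 1)
        K = assemble(mesh, 100.0, 0.3)
        collinear = np.flatnonzero(
            (mesh.nodes[:, 1] == 0.0) & (mesh.nodes[:, 2] == 0.0)
        )
        with pytest.raises(SingularSystemError):
            FactorizedSystem(K, ConstraintSet(nodes=collinear), mesh.nodes)
        with pytest.raises(SingularSystemError):
            FactorizedSystem(K, ConstraintSet(nodes=collinear[:2]), mesh.nodes)

    def test_cantilever_matches_slender_beam_theory(self):
        # 40 x 4 x 4 mm bar, tip load; Euler-Bernoulli delta = PL^3/(3EI).
        # Refinement level frozen at 0.5 mm (8 elements through the depth).
        E, nu, P, L, h = 2000.0, 0.0, 1.0, 40.0, 4.0
        mesh = block_mesh(80, 8, 8, pitch=0.5)
        K = assemble(mesh, E, nu)
        cons = ConstraintSet(nodes=np.flatnonzero(mesh.nodes[:, 0] == 0.0))
        sys_ = FactorizedSystem(K, cons, mesh.nodes)
        tip = np.flatnonzero(mesh.nodes[:, 0] == L)
        f = np.zeros((mesh.n_nodes, 3))
        f[tip, 2] = -P / tip.size
        sol = sys_.solve(f)
        tip_def = sol.u[tip, 2].mean()
        I = h**4 / 12.0
        expected = -P * L**3 / (3 * E * I)
        assert tip_def == pytest.approx(expected, rel=0.15)

    def test_stiffer_materials_displace_less(self):
        mesh = block_mesh(4, 2, 2)
        cons = ConstraintSet(nodes=np.flatnonzero(mesh.nodes[:, 0] == 0.0))
        f = np.zeros((mesh.n_nodes, 3))
        f[np.flatnonzero(mesh.nodes[:, 0] == 4.0), 2] = -1.0
        norms = {}
        for age in (3.0, 48.0):
            E, _, _, _ = material_at_age(age)
            sys_ = FactorizedSystem(assemble(mesh, E, 0.22), cons, mesh.nodes)
            norms[age] = np.abs(sys_.solve(f).u).max()
        assert norms[48.0] < norms[3.0]


class TestStrainStress:
    def _fields_from_displacement(self, mesh, A, E=1000.0, nu=0.25, **kw):
        u = mesh.nodes @ A.T
        sol = Solution(u=u, reactions=np.zeros_like(u), residual=0.0)
        return strain_stress(mesh, E, nu, sol, **kw)

    def test_patch_test_constant_strain(self):
        mesh = block_mesh(3, 2, 2, pitch=0.7)
        A = np.array([[1e-3, 2e-4, -1e-4], [5e-5, -2e-3, 3e-4], [1e-4, 2e-4, 5e-4]])
        res = self._fields_from_displacement(mesh, A)
        sym = 0.5 * (A + A.T)
        expected = np.array(
            [sym[0, 0], sym[1, 1], sym[2, 2], 2 * sym[0, 1], 2 * sym[1, 2], 2 * sym[0, 2]]
        )
        assert np.allclose(res.strain, expected[None, :], atol=1e-10)

    def test_uniaxial_stress_von_mises(self):
        E, nu, e = 1000.0, 0.25, 1e-3
        mesh = block_mesh(2, 2, 2)
        A = np.diag([e, -nu * e, -nu * e])
        res = self._fields_from_displacement(mesh, A, E=E, nu=nu)
        assert np.allclose(res.stress[:, 0], E * e, rtol=1e-10)
        assert np.allclose(res.stress[:, 1:], 0.0, atol=1e-12)
        assert np.allclose(res.vm_stress, E * e, rtol=1e-10)

    def test_hydrostatic_state_has_zero_von_mises(self):
        mesh = block_mesh(2, 2, 2)
        res = self._fields_from_displacement(mesh, np.eye(3) * 1e-3)
        assert np.allclose(res.vm_stress, 0.0, atol=1e-9)
        assert np.allclose(res.vm_strain, 0.0, atol=1e-6)

    def test_pure_shear_von_mises(self):
        E, nu, g = 1000.0, 0.25, 2e-3
        mu = E / (2 * (1 + nu))
        mesh = block_mesh(2, 2, 2)
        A = np.zeros((3, 3))
        A[0, 1] = g
        res = self._fields_from_displacement(mesh, A, E=E, nu=nu)
        assert np.allclose(res.vm_stress, np.sqrt(3) * mu * g, rtol=1e-10)
        expected_eps = np.sqrt(3) * g / (2 * (1 + nu)) * 1e6
        assert np.allclose(res.vm_strain, expected_eps, rtol=1e-10)

    def test_effective_poisson_override(self):
        mesh = block_mesh(1, 1, 1)
        A = np.zeros((3, 3))
        A[0, 1] = 1e-3
        r_mat = self._fields_from_displacement(mesh, A, nu=0.25)
        r_half = self._fields_from_displacement(mesh, A, nu=0.25, strain_nu_effective=0.5)
        assert np.allclose(r_half.vm_strain * 1.5, r_mat.vm_strain * 1.25, rtol=1e-10)


class TestMirrorSymmetry:
    def test_symmetric_muscle_load_gives_mirrored_displacements(self, coarse_model):
        model = coarse_model
        sol = model.system(1).solve(model.muscle_loads(dict(FORCES_48)))
        m = model.mesh.mirror_node_map()
        u_m = sol.u[m].copy()
        u_m[:, 0] = -u_m[:, 0]
        scale = np.abs(sol.u).max()
        assert np.allclose(sol.u, u_m, atol=1e-6 * scale)
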