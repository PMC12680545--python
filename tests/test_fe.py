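"""Finite-element solver checks against closed-form mechanics oracles."""

import numpy as np
import pytest

from femrisk.bvf import BVFMap
from femrisk.fe import (
    MaterialLaw,
    SidewaysFallSetup,
    ForceDisplacementCurve,
    apply_sideways_fall_bcs,
    bone_strength,
    build_mesh,
    equivalent_strain,
    fall_load_axis,
    hex8_stiffness,
    solve_linear,
    solve_nonlinear,
)
from femrisk.fe.hex8 import centroid_b_matrix, elasticity_matrix
from femrisk.fe.solve import FESystem

E0, NU = 15e9, 0.3


def make_bar(n_axis=8, n_side=2, h=1.0, bvf=1.0):
    """Bar along x: mesh plus the boundary-condition setup that realises a
    uniaxial-stress state (axial drive, free lateral faces, rigid-body
    pins consistent with the uniform solution)."""
    shape = (n_axis, n_side, n_side)
    mesh = build_mesh(BVFMap(np.full(shape, bvf), (h, h, h)), 0.001)
    coords = mesh.node_coords_m()
    L = n_axis * h * 1e-3
    head = np.nonzero(np.isclose(coords[:, 0], 0.0))[0]
    troch = np.nonzero(np.isclose(coords[:, 0], L))[0]
    # pins on interior cross-section nodes, consistent with uniform strain
    mid = np.isclose(coords[:, 0], h * 1e-3)
    a = np.nonzero(mid & np.isclose(coords[:, 1], 0)
                   & np.isclose(coords[:, 2], 0))[0][0]
    b = np.nonzero(mid & np.isclose(coords[:, 1], 0)
                   & np.isclose(coords[:, 2], n_side * h * 1e-3))[0][0]
    setup = SidewaysFallSetup(
        head_nodes=head, trochanter_nodes=troch, distal_nodes=[],
        load_axis=[1.0, 0.0, 0.0],
        pins=((int(a), 1), (int(a), 2), (int(b), 1)))
    area = (n_side * h * 1e-3) ** 2
    return mesh, setup, area


class TestElementStiffness:
    def test_symmetric_psd_with_six_rigid_modes(self):
        K = hex8_stiffness(E0, NU, (1e-3, 1e-3, 1.5e-3))
        assert np.allclose(K, K.T)
        w = np.linalg.eigvalsh(K)
        scale = w.max()
        assert w.min() > -1e-12 * scale
        assert (np.abs(w) < 1e-9 * scale).sum() == 6

    def test_rigid_translation_gives_zero_force(self):
        K = hex8_stiffness(E0, NU, (1e-3, 1e-3, 1e-3))
        for comp in range(3):
            u = np.zeros(24)
            u[comp::3] = 1.0
            assert np.abs(K @ u).max() < 1e-6 * np.abs(K).max()

    def test_linearity_in_modulus(self):
        K1 = hex8_stiffness(E0, NU, (1e-3, 2e-3, 1e-3))
        K2 = hex8_stiffness(2 * E0, NU, (1e-3, 2e-3, 1e-3))
        np.testing.assert_allclose(K2, 2 * K1, rtol=1e-13)

    def test_uniaxial_state_matches_hooke_oracle(self):
        # unit cube, uniaxial stress along x with lateral contraction nu:
        # the element's centroid stress must be (E*eps, 0, 0, 0, 0, 0)
        h = 1e-3
        eps = 1e-3
        offsets = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0],
                            [0, 0, 1], [1, 0, 1], [0, 1, 1], [1, 1, 1]],
                           float) * h
        u = np.zeros(24)
        u[0::3] = eps * offsets[:, 0]
        u[1::3] = -NU * eps * offsets[:, 1]
        u[2::3] = -NU * eps * offsets[:, 2]
        strain = centroid_b_matrix((h, h, h)) @ u
        stress = elasticity_matrix(E0, NU) @ strain
        expected = np.array([E0 * eps, 0, 0, 0, 0, 0])
        np.testing.assert_allclose(stress, expected, atol=1e-6 * E0 * eps)

    def test_degenerate_dimension_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            hex8_stiffness(E0, NU, (1e-3, 0.0, 1e-3))

    def test_equivalent_strain_is_axial_strain_for_uniaxial_stress(self):
        eps_ax = 2e-3
        voigt = np.array([eps_ax, -NU * eps_ax, -NU * eps_ax, 0, 0, 0])
        assert equivalent_strain(voigt, NU) == pytest.approx(eps_ax, rel=1e-12)


class TestMeshBuild:
    def test_full_block_counts(self):
        mesh = build_mesh(BVFMap(np.ones((2, 2, 2)), (1, 1, 1)), 0.01)
        assert mesh.n_elements == 8
        assert mesh.n_nodes == 27

    def test_interior_void_excluded(self):
        bvf = np.ones((3, 3, 3))
        bvf[1, 1, 1] = 0.0
        mesh = build_mesh(BVFMap(bvf, (1, 1, 1)), 0.01)
        assert mesh.n_elements == 26

    def test_largest_component_kept(self):
        bvf = np.zeros((7, 2, 2))
        bvf[0:2] = 1.0       # 8 voxels
        bvf[4:7] = 1.0       # 12 voxels, disconnected
        mesh = build_mesh(BVFMap(bvf, (1, 1, 1)), 0.01)
        assert mesh.n_elements == 12
        assert mesh.elem_ijk[:, 0].min() == 4

    def test_empty_mesh_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            build_mesh(BVFMap(np.zeros((3, 3, 3)), (1, 1, 1)), 0.5)

    def test_deterministic_numbering(self):
        rng = np.random.default_rng(0)
        bvf = BVFMap(rng.uniform(0, 1, (5, 5, 5)), (1, 1, 1))
        m1, m2 = build_mesh(bvf, 0.3), build_mesh(bvf, 0.3)
        np.testing.assert_array_equal(m1.elem_nodes, m2.elem_nodes)
        np.testing.assert_array_equal(m1.node_grid_ids, m2.node_grid_ids)


class TestLoadAxis:
    def test_identity_rotation_is_ground_normal(self):
        np.testing.assert_allclose(fall_load_axis(0, 0), [1, 0, 0],
                                   atol=1e-15)

    def test_sideways_fall_axis_matches_rotation_oracle(self):
        from scipy.spatial.transform import Rotation
        axis = fall_load_axis(10, 15)
        oracle = Rotation.from_euler("yz", [10, 15], degrees=True).apply(
            [1.0, 0.0, 0.0])
        np.testing.assert_allclose(axis, oracle, atol=1e-12)
        assert np.linalg.norm(axis) == pytest.approx(1.0)


class TestPatchTest:
    def test_uniform_strain_reproduced_to_machine_precision(self):
        """Affine boundary displacements on a cuboid reproduce the uniform
        strain state exactly (trilinear elements contain affine fields)."""
        shape = (4, 3, 3)
        mesh = build_mesh(BVFMap(np.ones(shape), (1.0, 1.2, 0.8)), 0.01)
        coords = mesh.node_coords_m()
        A = np.array([[1e-3, 2e-4, -1e-4],
                      [2e-4, -5e-4, 3e-4],
                      [-1e-4, 3e-4, 7e-4]])   # symmetric strain tensor
        u_affine = coords @ A.T
        grid = mesh.node_grid_coords()
        boundary = np.zeros(mesh.n_nodes, bool)
        for ax, n in enumerate(shape):
            boundary |= (grid[:, ax] == 0) | (grid[:, ax] == n)
        b_idx = np.nonzero(boundary)[0]
        pres = (3 * b_idx[:, None] + np.arange(3)[None, :]).ravel()
        vals = u_affine[b_idx].ravel()
        u = solve_linear(mesh, np.full(mesh.n_elements, E0), NU, pres, vals)
        np.testing.assert_allclose(u.reshape(-1, 3), u_affine,
                                   atol=1e-12 * np.abs(u_affine).max())
        sys_ = FESystem(mesh, NU)
        strains = sys_.element_strains(u)
        expected = np.array([A[0, 0], A[1, 1], A[2, 2],
                             2 * A[0, 1], 2 * A[1, 2], 2 * A[0, 2]])
        np.testing.assert_allclose(
            strains, np.tile(expected, (mesh.n_elements, 1)),
            atol=1e-9 * np.abs(expected).max())


class TestBarOracles:
    def test_linear_regime_reaction_matches_hooke(self):
        mesh, setup, area = make_bar()
        law = MaterialLaw(k=1e-9)
        res = solve_nonlinear(mesh, setup, law, target_strain=0.01, n_steps=5)
        expected = E0 * area * 0.01 / 1e3
        assert res.strength_kN == pytest.approx(expected, rel=5e-3)
        # exact to solver precision, in fact
        assert res.strength_kN == pytest.approx(expected, rel=1e-8)

    def test_equilibrium_residual_below_tolerance(self):
        mesh, setup, area = make_bar()
        res = solve_nonlinear(mesh, setup, MaterialLaw(),
                              target_strain=0.03, n_steps=10)
        assert max(res.diagnostics["equilibrium_residual"]) < 1e-6

    def test_sech_bar_peak_matches_closed_form(self):
        """Apparent stress E0*eps*sech(k*eps) peaks at eps*=x*/k where
        x*tanh(x*)=1; the simulated curve must match within 2%."""
        def bisect(f, lo, hi, n=200):
            for _ in range(n):
                mid = 0.5 * (lo + hi)
                if f(lo) * f(mid) <= 0:
                    hi = mid
                else:
                    lo = mid
            return 0.5 * (lo + hi)

        x_star = bisect(lambda x: x * np.tanh(x) - 1.0, 0.5, 2.0)
        assert x_star == pytest.approx(1.19968, abs=1e-4)
        k = 120.0
        law = MaterialLaw(k=k)
        eps_star = x_star / k
        stress_star = E0 * eps_star / np.cosh(x_star)
        assert stress_star == pytest.approx(0.6627 * E0 / k, rel=1e-3)

        mesh, setup, area = make_bar()
        res = solve_nonlinear(mesh, setup, law, target_strain=0.03,
                              n_steps=60)
        force_star = stress_star * area / 1e3
        assert res.strength_kN == pytest.approx(force_star, rel=0.02)
        assert res.strain_at_peak == pytest.approx(eps_star, rel=0.02)

    def test_strength_scales_linearly_with_tissue_modulus(self):
        mesh, setup, _ = make_bar(n_axis=6)
        r1 = solve_nonlinear(mesh, setup, MaterialLaw(E0=E0),
                             target_strain=0.02, n_steps=8)
        r2 = solve_nonlinear(mesh, setup, MaterialLaw(E0=2 * E0),
                             target_strain=0.02, n_steps=8)
        assert r2.strength_kN == pytest.approx(2 * r1.strength_kN, rel=1e-6)

    def test_doubling_bvf_doubles_linear_reaction(self):
        law = MaterialLaw(k=1e-9)
        m1, s1, _ = make_bar(n_axis=6, bvf=0.4)
        m2, s2, _ = make_bar(n_axis=6, bvf=0.8)
        r1 = solve_nonlinear(m1, s1, law, target_strain=0.005, n_steps=5)
        r2 = solve_nonlinear(m2, s2, law, target_strain=0.005, n_steps=5)
        assert r2.strength_kN == pytest.approx(2 * r1.strength_kN, rel=1e-8)

    def test_refinement_leaves_uniform_stiffness_unchanged(self):
        law = MaterialLaw(k=1e-9)
        m1, s1, _ = make_bar(n_axis=6, n_side=2, h=1.0)
        m2, s2, _ = make_bar(n_axis=12, n_side=4, h=0.5)
        r1 = solve_nonlinear(m1, s1, law, target_strain=0.005, n_steps=5)
        r2 = solve_nonlinear(m2, s2, law, target_strain=0.005, n_steps=5)
        assert r2.strength_kN == pytest.approx(r1.strength_kN, rel=0.01)


class TestCurveAndErrors:
    def test_bone_strength_of_toy_curves(self):
        c = ForceDisplacementCurve([0, 1, 2], [0, 2, 1.5], [0, 0.01, 0.02])
        peak = bone_strength(c)
        assert peak.strength_kN == 2
        assert peak.strain_at_peak == 0.01
        mono = ForceDisplacementCurve([0, 1, 2], [0, 1, 3], [0, 0.01, 0.02])
        assert bone_strength(mono).strength_kN == 3

    def test_non_monotone_displacements_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            ForceDisplacementCurve([0, 2, 1], [0, 1, 2], [0, 0.1, 0.2])

    def test_too_few_steps_rejected(self):
        mesh, setup, _ = make_bar(n_axis=4)
        with pytest.raises(ValueError, match="n_steps"):
            solve_nonlinear(mesh, setup, MaterialLaw(), n_steps=3)

    def test_empty_patch_rejected(self):
        mesh, _, _ = make_bar(n_axis=4)
        with pytest.raises(ValueError, match="non-empty"):
            SidewaysFallSetup(head_nodes=[], trochanter_nodes=[1])

    def test_overlapping_patches_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SidewaysFallSetup(head_nodes=[1, 2], trochanter_nodes=[2, 3])

    def test_interior_patch_node_rejected(self):
        mesh = build_mesh(BVFMap(np.ones((3, 3, 3)), (1, 1, 1)), 0.01)
        grid = mesh.node_grid_coords()
        interior = np.nonzero((grid == 1).all(axis=1))[0]
        surface = np.nonzero((grid[:, 0] == 0))[0]
        setup = SidewaysFallSetup(head_nodes=interior,
                                  trochanter_nodes=surface[:4],
                                  load_axis=[1, 0, 0])
        with pytest.raises(ValueError, match="surface"):
            apply_sideways_fall_bcs(mesh, setup)

    def test_material_law_validation(self):
        with pytest.raises(ValueError):
            MaterialLaw(E0=-1)
        with pytest.raises(ValueError):
            MaterialLaw(nu=0.6)
        with pytest.raises(ValueError):
            MaterialLaw(k=0)
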