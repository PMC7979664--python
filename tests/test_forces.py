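"""Deformation gradients and elastic force assembly versus the independent
finite-difference energy gradient."""

import numpy as np
import pytest
from scipy.stats import special_ortho_group

from hypercell import (
    deformation_gradients,
    elastic_forces,
    fd_force_oracle,
    material_from_E_nu,
    precompute_reference,
    total_energy,
)
from hypercell.fixtures import (
    affine_displacement,
    random_affine_gradients,
    smooth_displacement_field,
    unit_tet_mesh,
)


class TestDeformationGradients:
    def test_zero_displacement_gives_identity(self, ball_coarse, ball_coarse_ref):
        F = deformation_gradients(ball_coarse, ball_coarse_ref,
                                  np.zeros((ball_coarse.n_vertices, 3)))
        assert np.abs(F - np.eye(3)).max() < 1e-14

    def test_affine_field_exact(self, ball_coarse, ball_coarse_ref):
        for G in random_affine_gradients(5, scale=0.08, seed=3):
            u = affine_displacement(ball_coarse, G)
            F = deformation_gradients(ball_coarse, ball_coarse_ref, u)
            assert np.abs(F - (G + np.eye(3))).max() < 1e-12

    def test_rigid_translation_gives_identity(self, ball_coarse, ball_coarse_ref):
        u = np.tile([0.3, -0.1, 0.7], (ball_coarse.n_vertices, 1))
        F = deformation_gradients(ball_coarse, ball_coarse_ref, u)
        assert np.abs(F - np.eye(3)).max() < 1e-13


class TestElasticForces:
    def test_zero_displacement_zero_force(self, ball_coarse, ball_coarse_ref, mat_nh):
        f = elastic_forces(ball_coarse, ball_coarse_ref,
                           np.zeros((ball_coarse.n_vertices, 3)), mat_nh)
        assert np.abs(f).max() == 0.0

    def test_rigid_rotation_zero_force(self, ball_coarse, ball_coarse_ref, mat_mr):
        R = special_ortho_group.rvs(3, random_state=np.random.RandomState(5))
        c = ball_coarse.vertices.mean(axis=0)
        u = (ball_coarse.vertices - c) @ R.T + c - ball_coarse.vertices
        f = elastic_forces(ball_coarse, ball_coarse_ref, u, mat_mr)
        assert np.abs(f).max() <= 1e-9 * mat_mr.mu * ball_coarse.radius**2

    def test_translation_invariance(self, ball_coarse, ball_coarse_ref, mat_mr):
        u = smooth_displacement_field(ball_coarse, seed=11)
        f0 = elastic_forces(ball_coarse, ball_coarse_ref, u, mat_mr)
        f1 = elastic_forces(ball_coarse, ball_coarse_ref,
                            u + np.array([5.0, -2.0, 1.0]), mat_mr)
        assert np.abs(f1 - f0).max() <= 1e-12 * np.abs(f0).max() + 1e-13

    def test_rotation_equivariance(self, ball_coarse, ball_coarse_ref, mat_mr):
        R = special_ortho_group.rvs(3, random_state=np.random.RandomState(8))
        u = smooth_displacement_field(ball_coarse, seed=12)
        f0 = elastic_forces(ball_coarse, ball_coarse_ref, u, mat_mr)
        x = ball_coarse.vertices
        u_rot = (x + u) @ R.T - x  # rotate the deformed configuration
        f1 = elastic_forces(ball_coarse, ball_coarse_ref, u_rot, mat_mr)
        assert np.abs(f1 - f0 @ R.T).max() <= 1e-9 * np.abs(f0).max()

    def test_global_force_balance(self, ball_coarse, ball_coarse_ref, mat_mr):
        u = smooth_displacement_field(ball_coarse, seed=13)
        f = elastic_forces(ball_coarse, ball_coarse_ref, u, mat_mr)
        assert np.abs(f.sum(axis=0)).max() <= 1e-10 * np.abs(f).max()

    def test_single_element_force_balance(self, mat_mr, rng):
        m = unit_tet_mesh()
        ref = precompute_reference(m)
        u = 0.1 * rng.standard_normal((4, 3))
        f = elastic_forces(m, ref, u, mat_mr)
        assert np.abs(f.sum(axis=0)).max() <= 1e-10 * np.abs(f).max()

    def test_inversion_raises_with_element(self, mat_nh):
        m = unit_tet_mesh()
        ref = precompute_reference(m)
        u = np.zeros((4, 3))
        u[0, 0] = -1.5  # reflects the element through the x = 0 plane
        with pytest.raises(ValueError, match="element 0"):
            elastic_forces(m, ref, u, mat_nh)


class TestFiniteDifferenceOracle:
    def test_zero_state(self, mat_nh):
        m = unit_tet_mesh()
        ref = precompute_reference(m)
        f = fd_force_oracle(m, ref, np.zeros((4, 3)), mat_nh, step=1e-7)
        assert np.abs(f).max() < 1e-8

    def test_agreement_on_random_smooth_states(self, ball_coarse,
                                               ball_coarse_ref, mat_mr):
        worst = 0.0
        for seed in range(5):
            u = smooth_displacement_field(ball_coarse, seed=seed)
            fa = elastic_forces(ball_coarse, ball_coarse_ref, u, mat_mr)
            fd = fd_force_oracle(ball_coarse, ball_coarse_ref, u, mat_mr,
                                 step=1e-7)
            worst = max(worst, np.abs(fa - fd).max() / np.abs(fa).max())
        assert worst <= 1e-6

    def test_agreement_at_large_deformation(self, mat_mr):
        m = unit_tet_mesh()
        ref = precompute_reference(m)
        u = m.vertices * np.array([-0.5, 0.0, 0.0])  # 50% uniaxial compression
        fa = elastic_forces(m, ref, u, mat_mr)
        fd = fd_force_oracle(m, ref, u, mat_mr, step=1e-7)
        assert np.abs(fa - fd).max() / np.abs(fa).max() <= 1e-5


class TestEnergy:
    def test_energy_descent_along_forces(self, ball_coarse, ball_coarse_ref,
                                         mat_mr):
        u = smooth_displacement_field(ball_coarse, seed=21)
        e0 = total_energy(ball_coarse, ball_coarse_ref, u, mat_mr)
        f = elastic_forces(ball_coarse, ball_coarse_ref, u, mat_mr)
        step = 1e-4 / np.abs(f).max()
        e1 = total_energy(ball_coarse, ball_coarse_ref, u + step * f, mat_mr)
        assert e1 < e0

    def test_energy_scales_linearly_with_modulus(self, ball_coarse,
                                                 ball_coarse_ref):
        u = smooth_displacement_field(ball_coarse, seed=22)
        m1 = material_from_E_nu(100.0, 0.48, 0.5)
        m2 = material_from_E_nu(200.0, 0.48, 0.5)
        e1 = total_energy(ball_coarse, ball_coarse_ref, u, m1)
        e2 = total_energy(ball_coarse, ball_coarse_ref, u, m2)
        assert e2 == pytest.approx(2.0 * e1, rel=1e-12)
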