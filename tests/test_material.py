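"""Material parameterization, invariants and the strain-energy density."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import special_ortho_group

from hypercell import invariants_of, material_from_E_nu, strain_energy_density


def _nh_energy(F, mu, kappa):
    """Independent neo-Hookean implementation: U = mu/2 (I-3) + kappa/2 (J-1)^2."""
    C = F.T @ F
    J = np.linalg.det(F)
    I = np.trace(C) * J ** (-2.0 / 3.0)
    return 0.5 * mu * (I - 3.0) + 0.5 * kappa * (J - 1.0) ** 2


class TestMaterialParams:
    def test_moduli_from_E_nu(self):
        m = material_from_E_nu(120.0, 0.48, w=1.0)
        assert m.mu == pytest.approx(40.5405405, rel=1e-6)
        assert m.kappa == pytest.approx(1000.0, rel=1e-12)
        assert m.mu1 == m.mu and m.mu2 == 0.0

    def test_w_splits_shear_modulus(self):
        m = material_from_E_nu(100.0, 0.3, w=0.25)
        assert m.mu1 == pytest.approx(0.25 * m.mu)
        assert m.mu2 == pytest.approx(0.75 * m.mu)
        assert m.mu1 + m.mu2 == pytest.approx(m.mu, rel=1e-14)

    def test_stiff_parameters_accepted(self):
        m = material_from_E_nu(2250.0, 0.48, w=1.0)
        assert m.kappa > m.mu

    @pytest.mark.parametrize("bad", [
        dict(E=-1.0, nu=0.3, w=1.0),
        dict(E=100.0, nu=0.5, w=1.0),
        dict(E=100.0, nu=-1.0, w=1.0),
        dict(E=100.0, nu=0.3, w=1.5),
        dict(E=100.0, nu=0.3, w=-0.1),
    ])
    def test_invalid_parameters(self, bad):
        with pytest.raises(ValueError):
            material_from_E_nu(**bad)


class TestInvariants:
    def test_identity(self):
        inv = invariants_of(np.eye(3))
        assert (inv.J, inv.I, inv.K) == (1.0, 3.0, 3.0)
        assert (inv.TC, inv.TC2) == (3.0, 3.0)

    def test_rotation_is_identity_strain(self, rng):
        R = special_ortho_group.rvs(3, random_state=np.random.RandomState(3))
        inv = invariants_of(R)
        assert inv.J == pytest.approx(1.0, rel=1e-12)
        assert inv.I == pytest.approx(3.0, rel=1e-12)
        assert inv.K == pytest.approx(3.0, rel=1e-12)

    def test_uniaxial_stretch_values(self):
        inv = invariants_of(np.diag([2.0, 1.0, 1.0]))
        assert inv.J == pytest.approx(2.0)
        assert inv.TC == pytest.approx(6.0)
        assert inv.TC2 == pytest.approx(18.0)
        assert inv.I == pytest.approx(6.0 * 2.0 ** (-2.0 / 3.0), rel=1e-12)
        assert inv.K == pytest.approx(9.0 * 2.0 ** (-4.0 / 3.0), rel=1e-12)

    def test_inverted_element_rejected(self):
        with pytest.raises(ValueError, match="inversion"):
            invariants_of(np.diag([-1.0, 1.0, 1.0]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_first_invariant_at_least_three(self, seed):
        rng = np.random.default_rng(seed)
        F = np.eye(3) + 0.5 * rng.standard_normal((3, 3))
        if np.linalg.det(F) <= 1e-3:
            return
        assert invariants_of(F).I >= 3.0 - 1e-12


class TestStrainEnergy:
    def test_zero_at_identity(self):
        mat = material_from_E_nu(100.0, 0.4, 0.5)
        assert strain_energy_density(invariants_of(np.eye(3)), mat) == 0.0

    def test_neo_hookean_value(self):
        # mu = 2, w = 1, kappa = 2  <->  E = 2*2*(1+nu), nu with kappa = 2
        # choose nu so that kappa = 2: E/(3(1-2nu)) = 2 with E = 4(1+nu)
        nu = 1.0 / 8.0
        mat = material_from_E_nu(4.0 * (1.0 + nu), nu, w=1.0)
        assert mat.mu == pytest.approx(2.0) and mat.kappa == pytest.approx(2.0)
        U = strain_energy_density(invariants_of(np.diag([2.0, 1.0, 1.0])), mat)
        assert U == pytest.approx(1.0 * (6.0 * 2 ** (-2 / 3) - 3.0) + 1.0,
                                  rel=1e-6)
        assert U == pytest.approx(1.77976, abs=2e-5)

    def test_mooney_rivlin_value(self):
        nu = 1.0 / 8.0
        mat = material_from_E_nu(4.0 * (1.0 + nu), nu, w=0.5)
        U = strain_energy_density(invariants_of(np.diag([2.0, 1.0, 1.0])), mat)
        assert U == pytest.approx(1.675708, abs=1e-5)

    def test_matches_independent_neo_hookean(self, rng):
        mat = material_from_E_nu(250.0, 0.45, w=1.0)
        for _ in range(10):
            F = np.eye(3) + 0.3 * rng.standard_normal((3, 3))
            if np.linalg.det(F) <= 0.05:
                continue
            U = strain_energy_density(invariants_of(F), mat)
            assert U == pytest.approx(_nh_energy(F, mat.mu, mat.kappa),
                                      rel=1e-13, abs=1e-15)

    def test_frame_indifference(self, rng):
        mat = material_from_E_nu(100.0, 0.48, w=0.3)
        F = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
        U0 = strain_energy_density(invariants_of(F), mat)
        for seed in range(5):
            R = special_ortho_group.rvs(3, random_state=np.random.RandomState(seed))
            U = strain_energy_density(invariants_of(R @ F), mat)
            assert U == pytest.approx(U0, rel=1e-12)

    def test_affine_in_w(self):
        F = np.diag([1.4, 0.9, 0.85])
        inv = invariants_of(F)
        us = [strain_energy_density(inv, material_from_E_nu(100.0, 0.48, w))
              for w in (0.0, 0.5, 1.0)]
        assert us[1] == pytest.approx(0.5 * (us[0] + us[2]), rel=1e-13)

    def test_nonnegative_near_identity(self, rng):
        mat = material_from_E_nu(100.0, 0.48, 0.5)
        for _ in range(50):
            H = rng.standard_normal((3, 3))
            F = np.eye(3) + 1e-3 * H / np.linalg.norm(H)
            U = strain_energy_density(invariants_of(F), mat)
            assert U >= -1e-18

    def test_strain_hardening_in_compression(self):
        # volume-preserving uniaxial compression to lambda = 1/1.6: the second
        # (K) invariant grows faster than the first, so decreasing w stiffens
        lam = 1.0 / 1.6
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        inv = invariants_of(F)
        us = [strain_energy_density(inv, material_from_E_nu(100.0, 0.48, w))
              for w in (1.0, 0.5, 0.25)]
        assert us[0] < us[1] < us[2]

    def test_small_strain_matches_linear_elasticity(self, rng):
        mat = material_from_E_nu(100.0, 0.48, 0.5)
        eps = 1e-4
        for _ in range(10):
            H = rng.standard_normal((3, 3))
            H /= np.linalg.norm(H)
            U = strain_energy_density(invariants_of(np.eye(3) + eps * H), mat)
            sym = 0.5 * (H + H.T) * eps
            dev = sym - np.trace(sym) / 3.0 * np.eye(3)
            W = mat.mu * np.sum(dev * dev) + 0.5 * mat.kappa * np.trace(sym) ** 2
            assert U == pytest.approx(W, rel=0.01)
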