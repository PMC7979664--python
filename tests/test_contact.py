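"""Virtual compression/indentation experiments and Hertz references."""

import numpy as np
import pytest

from hypercell import (
    CompressionProtocol,
    ForceDeformationCurve,
    build_sphere_mesh,
    fit_curve,
    hertz_indenter,
    hertz_plate,
    material_from_E_nu,
    run_compression,
    run_indentation,
)

R_CELL = 8.6e-6
FAST = CompressionProtocol(increment=0.02, max_deformation=0.2)


@pytest.fixture(scope="module")
def cell_coarse():
    return build_sphere_mesh(R_CELL, subdivisions=2, seed=0)


@pytest.fixture(scope="module")
def curve_fast(cell_coarse):
    mat = material_from_E_nu(140.0, 0.48, 1.0)
    return run_compression(cell_coarse, mat, FAST)


class TestHertz:
    def test_zero_compression(self):
        assert hertz_plate(1000.0, 0.48, 15e-6, 0.0) == 0.0

    def test_three_halves_power_law(self):
        for d in (1e-7, 5e-7, 2e-6):
            ratio = hertz_plate(1000.0, 0.48, 15e-6, 2 * d) / hertz_plate(
                1000.0, 0.48, 15e-6, d)
            assert ratio == pytest.approx(2.0**1.5, rel=1e-12)

    def test_direct_value(self):
        F = hertz_plate(1000.0, 0.48, 15e-6, 3e-6)
        expected = (4.0 / 3.0) * (1000.0 / (1.0 - 0.48**2)) * np.sqrt(15e-6) \
            * (1.5e-6) ** 1.5
        assert F == pytest.approx(expected, rel=1e-12)

    def test_negative_compression_rejected(self):
        with pytest.raises(ValueError):
            hertz_plate(1000.0, 0.48, 15e-6, -1e-9)

    def test_indenter_large_probe_limit_is_plate(self):
        # R_probe >> R_cell: effective radius -> R_cell and the travel splits
        # evenly, recovering the sphere-between-plates expression
        F_ind = hertz_indenter(580.0, 0.48, 40e-6, 40.0, 2e-6)
        F_pl = hertz_plate(580.0, 0.48, 40e-6, 2e-6)
        assert F_ind == pytest.approx(F_pl, rel=1e-4)


class TestCompression:
    def test_curve_starts_at_zero_force(self, curve_fast):
        assert curve_fast.deformation[0] == 0.0
        assert curve_fast.force[0] == 0.0

    def test_curve_invariants(self, curve_fast):
        assert (np.diff(curve_fast.deformation) > 0).all()
        assert (curve_fast.force >= 0).all()
        assert (np.diff(curve_fast.force) > 0).all()

    def test_force_linear_in_E(self, cell_coarse):
        p = CompressionProtocol(increment=0.02, max_deformation=0.1)
        c1 = run_compression(cell_coarse, material_from_E_nu(100.0, 0.48, 0.5), p)
        c2 = run_compression(cell_coarse, material_from_E_nu(200.0, 0.48, 0.5), p)
        np.testing.assert_allclose(c2.force[1:], 2.0 * c1.force[1:], rtol=1e-3)

    def test_contact_stiffness_insensitivity(self, cell_coarse):
        # sharp equilibria (tight residual) so the comparison measures the
        # penalty-stiffness effect, not relaxation scatter
        mat = material_from_E_nu(140.0, 0.48, 1.0)
        c1 = run_compression(cell_coarse, mat, CompressionProtocol(
            increment=0.02, max_deformation=0.2, residual_tol=1e-5))
        c2 = run_compression(cell_coarse, mat, CompressionProtocol(
            increment=0.02, max_deformation=0.2, residual_tol=1e-5,
            contact_stiffness_factor=200.0))
        rms = np.sqrt(np.mean((c2.force[1:] - c1.force[1:]) ** 2))
        assert rms <= 0.02 * np.sqrt(np.mean(c1.force[1:] ** 2))

    def test_quasi_staticity_under_increment_halving(self, cell_coarse):
        mat = material_from_E_nu(140.0, 0.48, 1.0)
        c1 = run_compression(cell_coarse, mat, CompressionProtocol(
            increment=0.02, max_deformation=0.2, residual_tol=1e-5))
        c2 = run_compression(cell_coarse, mat, CompressionProtocol(
            increment=0.01, max_deformation=0.2, residual_tol=1e-5))
        f2 = c2.interpolate(c1.deformation[1:])
        rms = np.sqrt(np.mean((f2 - c1.force[1:]) ** 2))
        assert rms <= 0.01 * np.sqrt(np.mean(c1.force[1:] ** 2))

    def test_invalid_max_deformation(self, cell_coarse):
        with pytest.raises(ValueError):
            run_compression(cell_coarse, material_from_E_nu(140.0, 0.48, 1.0),
                            CompressionProtocol(max_deformation=1.2))


class TestIndentation:
    def test_small_indentation_tracks_hertz(self):
        # hydrogel-particle geometry: 40 um particle, 26.5 um probe.  Compare
        # where the contact patch spans several surface vertices (>= 4%
        # deformation); the residual overshoot is the documented P1-mesh
        # stiffness, shared with plate compression.
        mesh = build_sphere_mesh(40e-6, subdivisions=3, seed=0)
        mat = material_from_E_nu(580.0, 0.48, 1.0)
        p = CompressionProtocol(increment=0.01, max_deformation=0.05)
        curve = run_indentation(mesh, mat, 26.5e-6, p)
        d = curve.deformation
        sel = d >= 0.04
        F_h = hertz_indenter(580.0, 0.48, 40e-6, 26.5e-6, d[sel] * 2 * 40e-6)
        ratio = curve.force[sel] / F_h
        assert (ratio > 0.9).all() and (ratio < 1.6).all()

    def test_huge_probe_approaches_plate_compression(self, cell_coarse):
        mat = material_from_E_nu(140.0, 0.48, 1.0)
        p = CompressionProtocol(increment=0.02, max_deformation=0.1)
        c_probe = run_indentation(cell_coarse, mat, 100.0 * R_CELL, p)
        c_plate = run_compression(cell_coarse, mat, p)
        np.testing.assert_allclose(c_probe.force[1:], c_plate.force[1:],
                                   rtol=0.05)

    def test_invalid_probe_radius(self, cell_coarse):
        with pytest.raises(ValueError):
            run_indentation(cell_coarse, material_from_E_nu(140.0, 0.48, 1.0),
                            -1e-6)


class TestCurveIO:
    def test_csv_roundtrip(self, curve_fast, tmp_path):
        path = tmp_path / "curve.csv"
        curve_fast.to_csv(path)
        assert path.read_text().splitlines()[0] == "deformation,force_N"
        back = ForceDeformationCurve.from_csv(path)
        np.testing.assert_allclose(back.deformation, curve_fast.deformation)
        np.testing.assert_allclose(back.force, curve_fast.force)

    def test_non_monotone_deformation_rejected(self):
        with pytest.raises(ValueError):
            ForceDeformationCurve(np.array([0.0, 0.2, 0.1]), np.zeros(3))


class TestFit:
    def test_noiseless_self_fit_recovers_grid_point(self, cell_coarse):
        mat = material_from_E_nu(140.0, 0.48, 0.5)
        p = CompressionProtocol(increment=0.03, max_deformation=0.3)
        truth = run_compression(cell_coarse, mat, p)
        measured = ForceDeformationCurve(truth.deformation[1:], truth.force[1:])
        e_best, w_best = fit_curve(
            measured, cell_coarse, 0.48,
            E_grid=np.array([100.0, 140.0, 180.0]),
            w_grid=np.array([0.25, 0.5, 1.0]), protocol=p)
        assert (e_best, w_best) == (140.0, 0.5)

    def test_empty_grid_rejected(self, cell_coarse, curve_fast):
        with pytest.raises(ValueError):
            fit_curve(curve_fast, cell_coarse, 0.48, np.array([]),
                      np.array([1.0]))
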