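"""Quasi-static virtual micromechanics: plate compression and colloidal-probe
indentation of the meshed cell, Hertz references and least-squares fitting.

The cell rests on a fixed lower plate; a parallel upper plate (or a rigid
sphere) descends in small increments of the undeformed cell height.  Plates
and probe are rigid half-spaces / spheres exerting a linear penalty force
``k_c * delta`` on penetrating vertices.  After each increment the vertex
displacements are relaxed to quasi-static equilibrium by overdamped
pseudo-dynamics with adaptive step size (FIRE), stopping when the maximum
residual vertex force drops below tolerance; the recorded force is the total
normal contact force on the moving boundary.  Deformation is plate (probe)
travel divided by the undeformed cell height.

All computations run in dimensionless units (lengths by R, stresses by E), so
the recorded force is exactly linear in E at fixed (nu, w, deformation); the
fitter exploits this by simulating once per w and rescaling.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._kernels import relax_fire
from .material import MaterialParams, material_from_E_nu
from .mesh import TetMesh, precompute_reference

__all__ = [
    "ContactGeometry",
    "CompressionProtocol",
    "ForceDeformationCurve",
    "run_compression",
    "run_indentation",
    "hertz_plate",
    "hertz_indenter",
    "fit_curve",
]


@dataclass(frozen=True)
class ContactGeometry:
    """Rigid contact partners of a virtual experiment (dimensionless units).

    ``kind`` is ``plate_pair`` (compression) or ``plate_plus_sphere``
    (indentation); for the latter ``upper`` is the y-coordinate of the probe
    center and ``sphere_radius`` its radius.  ``stiffness`` is the penalty
    constant k_c per vertex.
    """

    kind: str
    lower_plate_y: float
    upper: float
    stiffness: float
    sphere_radius: float = 0.0
    sphere_xz: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class CompressionProtocol:
    """Loading protocol for the quasi-static experiments.

    increment
        Plate/probe travel per step, as a fraction of the undeformed cell
        height (default 0.5%).
    max_deformation
        Final travel as a fraction of the undeformed height (< 1).
    residual_tol
        Convergence threshold on the maximum residual vertex force, in units
        of E R^2.
    max_relax_steps
        Cap on energy-minimization iterations per increment.
    contact_stiffness_factor
        k_c in units of E R (default 100; a numerical, not physical, knob).
    """

    increment: float = 0.005
    max_deformation: float = 0.6
    residual_tol: float = 1e-4
    max_relax_steps: int = 20000
    contact_stiffness_factor: float = 100.0


@dataclass
class ForceDeformationCurve:
    """Force [N] versus dimensionless deformation (travel / cell height)."""

    deformation: np.ndarray
    force: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.deformation = np.asarray(self.deformation, dtype=np.float64)
        self.force = np.asarray(self.force, dtype=np.float64)
        if not (np.diff(self.deformation) > 0).all():
            raise ValueError("deformation values must be strictly increasing")

    def interpolate(self, deformation: np.ndarray) -> np.ndarray:
        """Linear interpolation of the force at given deformations."""
        return np.interp(deformation, self.deformation, self.force)

    def to_csv(self, path: str | os.PathLike) -> None:
        pd.DataFrame(
            {"deformation": self.deformation, "force_N": self.force}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "ForceDeformationCurve":
        df = pd.read_csv(path)
        return cls(df["deformation"].to_numpy(), df["force_N"].to_numpy())


def _equilibrate(mesh, ref, mat_dimless, geom, u0, protocol):
    """Overdamped pseudo-dynamic (FIRE) relaxation to quasi-static
    equilibrium; returns (displacements, residual, normal force on the
    moving boundary).  The entry state is the previous converged increment
    (always inversion-free); the boundary's new overlap is resolved by the
    penalty forces during the relaxation."""
    u = np.ascontiguousarray(u0, dtype=np.float64).copy()
    if geom.kind == "plate_pair":
        mode = 0
        cx = cz = sphere_r = 0.0
    elif geom.kind == "plate_plus_sphere":
        mode = 1
        cx, cz = geom.sphere_xz
        sphere_r = geom.sphere_radius
    else:  # pragma: no cover - guarded upstream
        raise ValueError(f"unknown contact kind {geom.kind!r}")
    residual, fmove, n_iter, status = relax_fire(
        mesh.tets, ref.B, ref.V0, mesh.vertices, u,
        mat_dimless.mu1, mat_dimless.mu2, mat_dimless.kappa,
        mode, geom.lower_plate_y, geom.upper, sphere_r, cx, cz,
        geom.stiffness, protocol.residual_tol, protocol.max_relax_steps)
    if status == 2:
        raise ValueError("persistent element inversion during relaxation")
    if status == 1:
        raise RuntimeError(
            f"relaxation did not converge: residual {residual:.3e} > "
            f"{protocol.residual_tol:.1e} after {n_iter} steps")
    return u, residual, fmove


def _run_quasi_static(mesh, mat, protocol, make_geom, kind_meta):
    if not 0 < protocol.max_deformation < 1:
        raise ValueError("max_deformation must lie in (0, 1)")
    R = mesh.radius
    verts = mesh.vertices / R
    dimless = TetMesh(verts, mesh.tets, mesh.surface_tris, 1.0)
    ref = precompute_reference(dimless)
    mat_hat = material_from_E_nu(1.0, mat.nu, mat.w)
    y_lo = verts[:, 1].min()
    y_hi = verts[:, 1].max()
    h0 = y_hi - y_lo
    k_c = protocol.contact_stiffness_factor
    n_steps = int(round(protocol.max_deformation / protocol.increment))
    u = np.zeros_like(verts)
    deformation = [0.0]
    force = [0.0]
    for s in range(1, n_steps + 1):
        d = s * protocol.increment
        geom = make_geom(d * h0, y_lo, y_hi, k_c, verts)
        u, _, fmove = _equilibrate(dimless, ref, mat_hat, geom, u, protocol)
        deformation.append(d)
        force.append(fmove * mat.E * R**2)
    meta = {
        "kind": kind_meta, "E_Pa": mat.E, "nu": mat.nu, "w": mat.w,
        "radius_m": R, "n_vertices": mesh.n_vertices, "n_tets": mesh.n_tets,
        "increment": protocol.increment,
        "residual_tol": protocol.residual_tol,
        "contact_stiffness_factor": k_c,
    }
    return ForceDeformationCurve(np.array(deformation), np.array(force), meta), u * R


def run_compression(
    mesh: TetMesh, mat: MaterialParams,
    protocol: CompressionProtocol | None = None,
    return_displacements: bool = False,
):
    """Compress the cell between a resting lower and a descending upper plate.

    Returns the :class:`ForceDeformationCurve`; with
    ``return_displacements=True`` also the final vertex displacements [m].
    """
    protocol = protocol or CompressionProtocol()

    def make_geom(travel, y_lo, y_hi, k_c, verts):
        return ContactGeometry("plate_pair", lower_plate_y=y_lo,
                               upper=y_hi - travel, stiffness=k_c)

    curve, u = _run_quasi_static(mesh, mat, protocol, make_geom, "compression")
    return (curve, u) if return_displacements else curve


def run_indentation(
    mesh: TetMesh, mat: MaterialParams, probe_radius: float,
    protocol: CompressionProtocol | None = None,
    return_displacements: bool = False,
):
    """Indent the plate-supported cell with a descending rigid sphere.

    ``probe_radius`` is in meters; deformation is probe travel divided by the
    undeformed cell height.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    protocol = protocol or CompressionProtocol()
    rp = probe_radius / mesh.radius  # dimensionless

    def make_geom(travel, y_lo, y_hi, k_c, verts):
        xz = (float(verts[:, 0].mean()), float(verts[:, 2].mean()))
        return ContactGeometry(
            "plate_plus_sphere", lower_plate_y=y_lo,
            upper=y_hi + rp - travel, stiffness=k_c,
            sphere_radius=rp, sphere_xz=xz)

    curve, u = _run_quasi_static(mesh, mat, protocol, make_geom, "indentation")
    return (curve, u) if return_displacements else curve


def hertz_plate(E: float, nu: float, R: float, d: float | np.ndarray):
    """Hertz force [N] for a sphere of radius R compressed between two plates.

    Each of the two contacts carries half the total compression d, so
    F = (4/3) (E / (1 - nu^2)) sqrt(R) (d/2)^(3/2).  Valid for d << R.
    """
    d = np.asarray(d, dtype=np.float64)
    if (d < 0).any():
        raise ValueError("compression must be non-negative")
    out = (4.0 / 3.0) * E / (1.0 - nu**2) * np.sqrt(R) * (d / 2.0) ** 1.5
    return float(out) if out.ndim == 0 else out


def hertz_indenter(E: float, nu: float, R_cell: float, R_probe: float,
                   d: float | np.ndarray):
    """Hertz force [N] for a plate-supported sphere indented by a rigid probe.

    The probe contact uses the effective radius R_eff = (1/R_cell +
    1/R_probe)^-1, the substrate contact the cell radius; the probe travel d
    splits between the two contacts so that both transmit the same force.
    """
    d = np.asarray(d, dtype=np.float64)
    if (d < 0).any():
        raise ValueError("indentation must be non-negative")
    r_eff = 1.0 / (1.0 / R_cell + 1.0 / R_probe)
    # sqrt(R_eff) dt^1.5 = sqrt(R_cell) db^1.5,  dt + db = d
    ratio = (r_eff / R_cell) ** (1.0 / 3.0)
    dt = d / (1.0 + ratio)
    out = (4.0 / 3.0) * E / (1.0 - nu**2) * np.sqrt(r_eff) * dt**1.5
    return float(out) if out.ndim == 0 else out


def fit_curve(
    measured: ForceDeformationCurve,
    mesh: TetMesh,
    nu: float,
    E_grid: np.ndarray,
    w_grid: np.ndarray,
    protocol: CompressionProtocol | None = None,
    experiment: str = "compression",
    probe_radius: float | None = None,
) -> tuple[float, float]:
    """Least-squares fit of (E, w) to a measured force-deformation curve.

    One forward simulation per w at a reference modulus; force is exactly
    linear in E at fixed (nu, w), so the E axis of the grid is scanned by
    rescaling.  Returns the grid point (E_best, w_best) with the smallest
    sum of squared force residuals at the measured deformations.
    """
    E_grid = np.asarray(E_grid, dtype=np.float64)
    w_grid = np.asarray(w_grid, dtype=np.float64)
    if E_grid.size == 0 or w_grid.size == 0:
        raise ValueError("empty parameter grid")
    d_meas = measured.deformation
    f_meas = measured.force
    max_def = float(d_meas.max())
    protocol = protocol or CompressionProtocol()
    protocol = replace(protocol, max_deformation=min(
        0.95, np.ceil(max_def / protocol.increment) * protocol.increment))
    E_ref = 100.0
    best = (np.inf, None, None)
    for w in w_grid:
        mat = material_from_E_nu(E_ref, nu, float(w))
        if experiment == "compression":
            sim = run_compression(mesh, mat, protocol)
        else:
            sim = run_indentation(mesh, mat, probe_radius, protocol)
        f_ref = sim.interpolate(d_meas)
        sse = ((f_meas[None, :] - (E_grid[:, None] / E_ref) * f_ref[None, :]) ** 2
               ).sum(axis=1)
        i = int(np.argmin(sse))
        if sse[i] < best[0]:
            best = (float(sse[i]), float(E_grid[i]), float(w))
    return best[1], best[2]
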