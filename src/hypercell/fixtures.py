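"""Deterministic fixture and synthetic-data generators.

These are first-class package code: the test suite and the ``fixtures`` CLI
subcommand both use them.  All randomness is controlled by an integer seed,
so regenerated fixtures are bit-identical.

Kinds
-----
unit_tet
    A single right-corner tetrahedron (vertices at the origin and the three
    unit points; the origin is the element's local-origin vertex).
ball_coarse / ball_default
    Spherical cell meshes at subdivision 2 (~300 vertices) and 3 (~2300
    vertices, ~12000 tetrahedra).
affine_states
    Random small displacement-gradient matrices G; the displacement field
    u(x) = G x has the exactly known deformation gradient F = G + I on every
    element.
noisy_curve
    A forward-model compression curve (coarse mesh) with multiplicative
    Gaussian noise, for parameter-recovery tests of the fitter.
"""

from __future__ import annotations

import json
import os

import numpy as np

from .contact import CompressionProtocol, ForceDeformationCurve, run_compression
from .material import material_from_E_nu
from .mesh import TetMesh, build_sphere_mesh, surface_from_tets
from .vtkio import write_mesh

__all__ = [
    "unit_tet_mesh",
    "regular_tet_mesh",
    "affine_displacement",
    "random_affine_gradients",
    "smooth_displacement_field",
    "noisy_synthetic_curve",
    "make_fixtures",
]

KINDS = ("unit_tet", "ball_coarse", "ball_default", "affine_states", "noisy_curve")


def unit_tet_mesh() -> TetMesh:
    """Single right-corner tetrahedron; reference Jacobian is the identity."""
    verts = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0], [0, 0, 0]])
    tets = np.array([[0, 1, 2, 3]], dtype=np.int64)
    return TetMesh(verts, tets, surface_from_tets(verts, tets), 1.0)


def regular_tet_mesh(edge: float = 1.0) -> TetMesh:
    """Single regular tetrahedron with the given edge length."""
    verts = edge * np.array(
        [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
    ) / np.sqrt(8.0)
    tets = np.array([[0, 1, 2, 3]], dtype=np.int64)
    if np.linalg.det(np.stack([verts[k] - verts[3] for k in range(3)], axis=1)) < 0:
        tets = np.array([[1, 0, 2, 3]], dtype=np.int64)
    return TetMesh(verts, tets, surface_from_tets(verts, tets), edge)


def affine_displacement(mesh: TetMesh, G: np.ndarray) -> np.ndarray:
    """Displacement field u(x) = G x, whose exact deformation gradient is
    G + I on every element."""
    return mesh.vertices @ np.asarray(G, dtype=np.float64).T


def random_affine_gradients(n: int, scale: float = 0.05, seed: int = 0) -> np.ndarray:
    """n random small displacement-gradient matrices, shape (n, 3, 3)."""
    rng = np.random.default_rng(seed)
    return scale * rng.standard_normal((n, 3, 3))


def smooth_displacement_field(mesh: TetMesh, seed: int = 0,
                              amplitude: float = 0.04) -> np.ndarray:
    """Smooth random displacement field: affine part plus a long-wavelength
    sinusoid, with displacement-gradient magnitude of order ``amplitude``.

    Unlike per-vertex white noise, a smooth field has a bounded deformation
    gradient everywhere, so it cannot invert badly-shaped elements at small
    amplitude - matching what physical deformation fields look like.
    """
    rng = np.random.default_rng(seed)
    R = mesh.radius
    G = amplitude * rng.standard_normal((3, 3))
    a = amplitude * R * rng.standard_normal(3)
    k = rng.uniform(1.0, 3.0, 3) / R
    ph = rng.uniform(0.0, 2.0 * np.pi, 3)
    return mesh.vertices @ G.T + a * np.sin(mesh.vertices * k + ph)


def noisy_synthetic_curve(
    E: float = 140.0,
    nu: float = 0.48,
    w: float = 0.5,
    radius: float = 8.6e-6,
    sigma: float = 0.02,
    max_deformation: float = 0.6,
    increment: float = 0.01,
    subdivisions: int = 2,
    seed: int = 0,
) -> ForceDeformationCurve:
    """Forward-model compression curve with multiplicative Gaussian noise.

    The zero-deformation point is dropped (a measured curve starts once
    contact is established) and noise is applied as force * (1 + sigma * N).
    """
    mesh = build_sphere_mesh(radius, subdivisions=subdivisions, seed=seed)
    mat = material_from_E_nu(E, nu, w)
    protocol = CompressionProtocol(increment=increment,
                                   max_deformation=max_deformation)
    curve = run_compression(mesh, mat, protocol)
    rng = np.random.default_rng(seed)
    noisy = curve.force[1:] * (1.0 + sigma * rng.standard_normal(len(curve.force) - 1))
    meta = dict(curve.metadata)
    meta.update({"noise_sigma": sigma, "seed": seed, "synthetic": True})
    return ForceDeformationCurve(curve.deformation[1:], noisy, meta)


def make_fixtures(kind: str, seed: int = 0, outdir: str | os.PathLike = ".") -> list[str]:
    """Write the fixture files for ``kind`` into ``outdir``; returns paths."""
    os.makedirs(outdir, exist_ok=True)
    paths: list[str] = []
    if kind == "unit_tet":
        p = os.path.join(outdir, "unit_tet.vtk")
        write_mesh(unit_tet_mesh(), p)
        paths.append(p)
    elif kind == "ball_coarse":
        p = os.path.join(outdir, "ball_coarse.vtk")
        write_mesh(build_sphere_mesh(1.0, subdivisions=2, seed=seed), p)
        paths.append(p)
    elif kind == "ball_default":
        p = os.path.join(outdir, "ball_default.vtk")
        write_mesh(build_sphere_mesh(1.0, subdivisions=3, seed=seed), p)
        paths.append(p)
    elif kind == "affine_states":
        p = os.path.join(outdir, "affine_states.json")
        G = random_affine_gradients(10, seed=seed)
        with open(p, "w") as fh:
            json.dump({"seed": seed, "gradients": G.tolist()}, fh, indent=2)
        paths.append(p)
    elif kind == "noisy_curve":
        p = os.path.join(outdir, "noisy_curve.csv")
        noisy_synthetic_curve(seed=seed).to_csv(p)
        paths.append(p)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {KINDS}")
    return paths
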