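"""Per-element deformation gradients and nodal elastic force assembly.

Forces are obtained by differentiating the total elastic energy
``sum_t V0_t U(F_t)`` with respect to the vertex displacements:
``f_i^a = -V0 dU/du_i^a``.  With linear shape functions the deformation
gradient is constant per element, ``F = A B + I`` where A holds the
displacement differences against the element's 4th (origin) vertex and
B is the inverse reference Jacobian.  The analytic chain-rule assembly is
verified against :func:`fd_force_oracle`, an independent central-difference
gradient of the same energy.
"""

from __future__ import annotations

import numpy as np

from ._kernels import elastic_force_energy
from .material import MaterialParams
from .mesh import ReferenceState, TetMesh

__all__ = [
    "deformation_gradients",
    "elastic_forces",
    "total_energy",
    "elastic_forces_and_energy",
    "fd_force_oracle",
]


def deformation_gradients(
    mesh: TetMesh, ref: ReferenceState, displacements: np.ndarray
) -> np.ndarray:
    """Per-tetrahedron deformation gradient F = A B + I, shape (n_t, 3, 3)."""
    u = np.asarray(displacements, dtype=np.float64).reshape(mesh.n_vertices, 3)
    ut = u[mesh.tets]  # (n_t, 4, 3)
    # A columns k = u^k - u^4
    A = np.stack([ut[:, k] - ut[:, 3] for k in range(3)], axis=2)
    return A @ ref.B + np.eye(3)


def elastic_forces_and_energy(
    mesh: TetMesh, ref: ReferenceState, displacements: np.ndarray,
    mat: MaterialParams,
) -> tuple[np.ndarray, float]:
    """Per-vertex elastic forces [N] and total elastic energy [J].

    Raises
    ------
    ValueError
        On element inversion (det F <= 0), naming the element.
    """
    u = np.ascontiguousarray(
        np.asarray(displacements, dtype=np.float64).reshape(mesh.n_vertices, 3))
    forces = np.zeros_like(u)
    energy, bad = elastic_force_energy(
        mesh.tets, ref.B, ref.V0, u, mat.mu1, mat.mu2, mat.kappa, forces)
    if bad >= 0:
        raise ValueError(f"element inversion in element {bad} (det F <= 0)")
    return forces, float(energy)


def elastic_forces(
    mesh: TetMesh, ref: ReferenceState, displacements: np.ndarray,
    mat: MaterialParams,
) -> np.ndarray:
    """Per-vertex elastic forces [N], assembled over all elements."""
    return elastic_forces_and_energy(mesh, ref, displacements, mat)[0]


def total_energy(
    mesh: TetMesh, ref: ReferenceState, displacements: np.ndarray,
    mat: MaterialParams,
) -> float:
    """Total elastic energy sum_t V0_t U_t [J]."""
    return elastic_forces_and_energy(mesh, ref, displacements, mat)[1]


def fd_force_oracle(
    mesh: TetMesh, ref: ReferenceState, displacements: np.ndarray,
    mat: MaterialParams, step: float | None = None,
) -> np.ndarray:
    """Central-difference gradient of the total energy; test oracle only.

    ``f = -dE/du`` evaluated component-wise with step ``step`` (default
    1e-7 times the cell radius).  Independent of the analytic assembly path.
    """
    if step is None:
        step = 1e-7 * mesh.radius
    u = np.array(displacements, dtype=np.float64).reshape(mesh.n_vertices, 3)
    forces = np.empty_like(u)
    for i in range(mesh.n_vertices):
        for a in range(3):
            orig = u[i, a]
            u[i, a] = orig + step
            ep = total_energy(mesh, ref, u, mat)
            u[i, a] = orig - step
            em = total_energy(mesh, ref, u, mat)
            u[i, a] = orig
            forces[i, a] = -(ep - em) / (2.0 * step)
    return forces
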