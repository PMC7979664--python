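"""Shape diagnostics: inertia tensor, equivalent-ellipsoid semi-axes,
Taylor deformation parameter and net strain.

The deformed cell is summarized by the inertia tensor of its tetrahedra
(uniform unit density, volume-weighted element centroids about the center of
mass).  For a uniform solid ellipsoid the eigenvalues theta_1 >= theta_2 >=
theta_3 relate to the semi-axes a_1 <= a_2 <= a_3 through
theta_i = (M/5)(a_j^2 + a_k^2), so each signed combination
(5 / 2M)(-theta_i + theta_j + theta_k) equals a squared semi-axis; the
implementation takes its positive square root (the sphere round-trip
a_i = R fixes this convention).  The Taylor deformation parameter is
D = (a3 - a1)/(a3 + a1); the net strain compares the maximum vertex-pair
distance with the reference diameter 2R.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

__all__ = [
    "ShapeMetrics",
    "inertia_tensor",
    "semi_axes",
    "taylor_D",
    "net_strain",
    "max_extent",
    "compute_metrics",
]


def _centroids_volumes(vertices, tets):
    v = vertices[tets]
    cent = v.mean(axis=1)
    vol = np.abs(np.einsum(
        "ij,ij->i", np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), v[:, 3] - v[:, 0]
    )) / 6.0
    return cent, vol


def inertia_tensor(mesh, current_positions: np.ndarray) -> np.ndarray:
    """Inertia tensor of the deformed cell (uniform unit density).

    Theta_ij = sum_l V_l (r.r delta_ij - r_i r_j) over element centroids r^l
    relative to the volume-weighted center of mass, V_l the current element
    volume.  Units m^5 (mass = volume for unit density).
    """
    pos = np.asarray(current_positions, dtype=np.float64)
    cent, vol = _centroids_volumes(pos, mesh.tets)
    com = (vol[:, None] * cent).sum(axis=0) / vol.sum()
    r = cent - com
    rr = np.einsum("li,lj->lij", r, r)
    r2 = np.einsum("li,li->l", r, r)
    theta = (vol[:, None, None] * (r2[:, None, None] * np.eye(3) - rr)).sum(axis=0)
    return theta


def semi_axes(theta: np.ndarray, M: float) -> tuple[float, float, float]:
    """Semi-axes (a1 <= a2 <= a3) of the ellipsoid with inertia tensor
    ``theta`` and mass ``M`` (= volume at unit density).

    Raises
    ------
    ValueError
        If an eigenvalue combination is negative ("non-ellipsoidal inertia");
        exact zeros are accepted as the degenerate boundary.
    """
    ev = np.linalg.eigvalsh(theta)[::-1]  # theta1 >= theta2 >= theta3
    t1, t2, t3 = ev
    combos = np.array([-t1 + t2 + t3, t1 - t2 + t3, t1 + t2 - t3])
    s = 2.5 / M * combos
    if (s < 0).any():
        # tolerate tiny negative round-off only
        if (s < -1e-12 * max(abs(s).max(), 1e-300)).any():
            raise ValueError(f"non-ellipsoidal inertia: squared axes {s}")
        s = np.clip(s, 0.0, None)
    a = np.sqrt(s)
    return float(a[0]), float(a[1]), float(a[2])


def taylor_D(mesh, current_positions: np.ndarray) -> float:
    """Taylor deformation parameter D = (a3 - a1)/(a3 + a1); 0 for a sphere."""
    pos = np.asarray(current_positions, dtype=np.float64)
    theta = inertia_tensor(mesh, pos)
    _, vol = _centroids_volumes(pos, mesh.tets)
    a1, _, a3 = semi_axes(theta, float(vol.sum()))
    return (a3 - a1) / (a3 + a1)


def max_extent(positions: np.ndarray) -> float:
    """Exact maximum pairwise vertex distance.

    The maximum is realized on the convex hull, so candidates are reduced to
    hull vertices before the all-pairs sweep.
    """
    pos = np.asarray(positions, dtype=np.float64)
    if len(pos) > 16:
        pos = pos[ConvexHull(pos).vertices]
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def net_strain(current_positions: np.ndarray, R: float) -> float:
    """Net strain (d_max - d_ref)/d_ref with d_ref = 2R.

    A value of 1 corresponds to an elongation of the cell by an additional
    100% of its original size.
    """
    if R <= 0:
        raise ValueError("radius must be positive")
    d_ref = 2.0 * R
    return (max_extent(current_positions) - d_ref) / d_ref


@dataclass(frozen=True)
class ShapeMetrics:
    """Bundle of shape diagnostics for one deformed configuration."""

    theta: np.ndarray
    a1: float
    a2: float
    a3: float
    D: float
    strain: float
    stretch_ratio: float  # d_max / d_ref


def compute_metrics(mesh, current_positions: np.ndarray) -> ShapeMetrics:
    """All shape metrics for one configuration of ``mesh``."""
    pos = np.asarray(current_positions, dtype=np.float64)
    theta = inertia_tensor(mesh, pos)
    _, vol = _centroids_volumes(pos, mesh.tets)
    a1, a2, a3 = semi_axes(theta, float(vol.sum()))
    strain = net_strain(pos, mesh.radius)
    return ShapeMetrics(
        theta=theta, a1=a1, a2=a2, a3=a3,
        D=(a3 - a1) / (a3 + a1),
        strain=strain,
        stretch_ratio=strain + 1.0,
    )
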