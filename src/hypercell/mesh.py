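"""Tetrahedralized spherical cell meshes and per-element reference quantities.

The cell is a ball meshed into tetrahedra: an icosphere provides the
triangulated surface, interior vertices are placed on concentric spherical
shells, and the point cloud is tetrahedralized by a 3D Delaunay construction
(the domain is convex, so the Delaunay mesh fills the ball exactly up to the
polyhedral surface).  All lengths are SI meters.

Local vertex convention inside each tetrahedron: the 4th stored vertex is the
local origin of the shape-function coordinate system, so the reference
Jacobian has columns J[:, k] = x^k - x^4 (k = 1..3) and the displacement
matrix used by the force routine has columns A[:, k] = u^k - u^4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import Delaunay

__all__ = [
    "TetMesh",
    "ReferenceState",
    "build_sphere_mesh",
    "precompute_reference",
    "signed_tet_volumes",
    "surface_from_tets",
    "surface_enclosed_volume",
]

#: minimum acceptable element volume, relative to the mesh mean
SLIVER_REL_TOL = 1e-6


class MeshError(ValueError):
    """Raised for degenerate, inverted or otherwise invalid meshes."""


def signed_tet_volumes(vertices: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volume of each tetrahedron, det(J)/6 with the reference
    Jacobian's column convention J[:, k] = x^k - x^4 (positive for the
    stored ordering)."""
    v = vertices[tets]
    return np.einsum(
        "ij,ij->i", np.cross(v[:, 0] - v[:, 3], v[:, 1] - v[:, 3]), v[:, 2] - v[:, 3]
    ) / 6.0


def surface_from_tets(vertices: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Extract the boundary triangles of a tet mesh, oriented outward.

    A face is on the boundary iff it belongs to exactly one tetrahedron; it is
    oriented so that its normal points away from the opposite vertex of that
    tetrahedron.
    """
    # the four faces of tet (a,b,c,d), each with its opposite vertex
    face_idx = [(1, 2, 3, 0), (0, 3, 2, 1), (0, 1, 3, 2), (0, 2, 1, 3)]
    faces = np.concatenate([tets[:, [i, j, k]] for i, j, k, _ in face_idx])
    opp = np.concatenate([tets[:, [m]] for _, _, _, m in face_idx]).ravel()
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    boundary = counts[inv] == 1
    tris = faces[boundary]
    opp = opp[boundary]
    # orient outward: normal of (v0,v1,v2) must point away from the opposite vertex
    v = vertices[tris]
    n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    inward = np.einsum("ij,ij->i", n, vertices[opp] - v[:, 0]) > 0
    tris[inward] = tris[inward][:, [0, 2, 1]]
    return np.ascontiguousarray(tris)


def surface_enclosed_volume(vertices: np.ndarray, tris: np.ndarray) -> float:
    """Volume enclosed by a closed, outward-oriented triangle surface
    (divergence theorem)."""
    v = vertices[tris]
    return float(
        np.einsum("ij,ij->i", v[:, 0], np.cross(v[:, 1], v[:, 2])).sum() / 6.0
    )


@dataclass
class TetMesh:
    """Reference geometry of one tetrahedralized cell.

    Attributes
    ----------
    vertices : (n_v, 3) float64
        Reference vertex coordinates [m].
    tets : (n_t, 4) int64
        Vertex indices of each tetrahedron, positively oriented; the 4th
        vertex is the local shape-function origin.
    surface_tris : (n_s, 3) int64
        Outward-oriented boundary triangles.
    radius : float
        Nominal cell radius R [m].
    """

    vertices: np.ndarray
    tets: np.ndarray
    surface_tris: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.surface_tris = np.ascontiguousarray(self.surface_tris, dtype=np.int64)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    @property
    def surface_vertices(self) -> np.ndarray:
        """Indices of vertices on the boundary surface."""
        return np.unique(self.surface_tris)

    def volume(self) -> float:
        return float(np.abs(signed_tet_volumes(self.vertices, self.tets)).sum())

    def validate(self) -> None:
        """Check all mesh invariants; raise :class:`MeshError` on violation."""
        if self.n_tets == 0 or self.n_vertices < 4:
            raise MeshError("empty mesh")
        if self.tets.min() < 0 or self.tets.max() >= self.n_vertices:
            raise MeshError("tet vertex index out of range")
        if self.surface_tris.min() < 0 or self.surface_tris.max() >= self.n_vertices:
            raise MeshError("surface vertex index out of range")
        vol = signed_tet_volumes(self.vertices, self.tets)
        if not (vol > 0).all():
            bad = int(np.argmin(vol))
            raise MeshError(
                f"non-positive tetrahedron volume in element {bad} ({vol[bad]:.3e})"
            )
        # closed 2-manifold, consistent orientation: every directed edge of the
        # surface appears exactly once (so each undirected edge twice, in
        # opposite directions)
        edges = np.concatenate(
            [self.surface_tris[:, [0, 1]], self.surface_tris[:, [1, 2]],
             self.surface_tris[:, [2, 0]]]
        )
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        if not (counts == 1).all():
            raise MeshError("surface has duplicated directed edges")
        rev = uniq[:, [1, 0]]
        uset = {tuple(e) for e in uniq}
        if not all(tuple(e) in uset for e in rev):
            raise MeshError("surface is not closed / not consistently oriented")
        vsurf = surface_enclosed_volume(self.vertices, self.surface_tris)
        vtet = vol.sum()
        if abs(vsurf - vtet) > 1e-10 * vtet:
            raise MeshError(
                f"tet volume {vtet:.12e} != surface-enclosed volume {vsurf:.12e}"
            )


@dataclass
class ReferenceState:
    """Per-tetrahedron reference quantities, computed once per mesh.

    ``Jac[t]`` has columns x^k - x^4 [m]; ``B[t] = Jac[t]^{-1}`` [1/m];
    ``V0[t] = det(Jac[t]) / 6`` [m^3].
    """

    V0: np.ndarray
    Jac: np.ndarray
    B: np.ndarray


def precompute_reference(mesh: TetMesh) -> ReferenceState:
    """Reference Jacobians, their inverses and element volumes.

    Raises
    ------
    MeshError
        If any element is degenerate (singular Jacobian).
    """
    x = mesh.vertices[mesh.tets]  # (n_t, 4, 3)
    # columns k = x^k - x^4
    jac = np.stack([x[:, k] - x[:, 3] for k in range(3)], axis=2)
    det = np.linalg.det(jac)
    if not (det > 0).all():
        bad = int(np.argmin(det))
        raise MeshError(f"degenerate or inverted element {bad} (det J = {det[bad]:.3e})")
    v0 = det / 6.0
    b = np.linalg.inv(jac)
    return ReferenceState(V0=v0, Jac=np.ascontiguousarray(jac), B=np.ascontiguousarray(b))


def _fibonacci_shell(n: int, r: float, rng: np.random.Generator) -> np.ndarray:
    """n roughly equidistributed points on a sphere of radius r, with a random
    azimuthal offset so successive shells do not align."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i + rng.uniform(0.0, 2.0 * np.pi)
    return r * np.c_[
        np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)
    ]


def build_sphere_mesh(
    radius: float,
    subdivisions: int = 3,
    shell_factor: float = 1.4,
    seed: int = 0,
    max_attempts: int = 10,
) -> TetMesh:
    """Generate a tetrahedralized ball mesh of the given radius.

    The surface is an icosphere at ``subdivisions`` (default 3: 642 surface
    vertices); interior vertices sit on concentric shells whose spacing is the
    surface edge length divided by ``shell_factor``, with per-shell counts
    scaling as the shell area.  The point cloud is tetrahedralized by 3D
    Delaunay; interior points carry a small deterministic jitter to avoid the
    degenerate cospherical configurations Delaunay dislikes.  At the default
    resolution this yields ~2300 vertices and ~12000 tetrahedra.

    Parameters
    ----------
    radius : float
        Cell radius R > 0 [m].
    subdivisions : int
        Icosphere subdivision level (2 = coarse ~300 vertices, 3 = default).
    seed : int
        Seed for the jitter; generation is reproducible for a fixed seed.

    Raises
    ------
    MeshError
        If sliver elements persist after ``max_attempts`` re-jitters.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    surf = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    surf_pts = np.asarray(surf.vertices, dtype=np.float64)
    n_surf = len(surf_pts)
    h = float(surf.edges_unique_length.mean())
    n_shell = max(2, int(round(shell_factor * radius / h)))
    for attempt in range(max_attempts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        pts = [surf_pts]
        for j in range(1, n_shell):
            r = radius * j / n_shell
            n = max(12, int(round(n_surf * (j / n_shell) ** 2)))
            p = _fibonacci_shell(n, r, rng)
            p = p + rng.normal(0.0, 0.05 * h, p.shape)
            pts.append(p)
        pts.append(np.zeros((1, 3)))
        vertices = np.vstack(pts)
        tets = Delaunay(vertices).simplices.astype(np.int64)
        vol = signed_tet_volumes(vertices, tets)
        neg = vol < 0
        tets[neg] = tets[neg][:, [1, 0, 2, 3]]
        vol = np.abs(vol)
        if vol.min() > SLIVER_REL_TOL * vol.mean():
            tris = surface_from_tets(vertices, tets)
            mesh = TetMesh(vertices=vertices, tets=tets,
                           surface_tris=tris, radius=float(radius))
            mesh.validate()
            return mesh
    raise MeshError(
        f"sliver elements persist after {max_attempts} attempts "
        f"(min/mean volume {vol.min() / vol.mean():.3e})"
    )
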