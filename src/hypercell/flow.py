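"""Plane Couette flow of one or more elastic cells: D3Q19 lattice-Boltzmann
fluid with immersed-boundary coupling.

The fluid is a BGK lattice-Boltzmann solver (Guo forcing) between two
parallel x-z walls realized by half-way bounce-back; the walls move with
x-velocities -+ u_wall = -+ (1/2) H gamma_dot, the box is periodic in x and
z.  Cells are coupled by the immersed-boundary method with a 4-point Peskin
kernel: vertex velocities are interpolated from the lattice, vertices are
advected explicitly, and elastic (+ mutual repulsion) forces are spread back
with the same kernel.  No interior fluid-stress subtraction is applied, so
the cell interior carries the fluid viscosity (viscosity ratio lambda = 1).

Internally everything runs in lattice units (dx = dt = rho = 1).  The
dimensionless group that matters is the capillary number Ca = eta gamma_dot /
mu, which sets the cell's shear modulus relative to the fluid shear stress;
the lattice shear rate is chosen for low Mach and low Reynolds number rather
than to match the physical clock, and the record returned with each run maps
lattice to physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from .forces import elastic_forces_and_energy
from .material import MaterialParams, material_from_E_nu
from .mesh import TetMesh, build_sphere_mesh, precompute_reference, signed_tet_volumes
from .metrics import max_extent, taylor_D

__all__ = [
    "FlowDomain",
    "CouetteLBM",
    "Suspension",
    "ShearFlowResult",
    "capillary_number",
    "run_shear_flow",
]


def capillary_number(eta: float, gamma_dot: float, mu: float) -> float:
    """Capillary number Ca = eta * gamma_dot / mu (viscous shear stress over
    elastic shear modulus)."""
    if mu <= 0:
        raise ValueError("shear modulus must be positive")
    if eta <= 0 or gamma_dot <= 0:
        raise ValueError("viscosity and shear rate must be positive")
    return eta * gamma_dot / mu


@dataclass(frozen=True)
class FlowDomain:
    """Lattice description of the plane Couette channel.

    Fluid nodes sit at (i+1/2, j+1/2, k+1/2); the bounce-back walls lie in
    the planes y = 0 and y = H = ny (lattice units), moving with x-velocities
    u_lo and u_hi.  ``tau`` is the BGK relaxation time, so the kinematic
    viscosity is nu = (tau - 1/2)/3 and the shear rate gamma_dot =
    (u_hi - u_lo)/H.
    """

    nx: int
    ny: int
    nz: int
    tau: float = 1.0
    u_wall: float = 0.0   # half the wall velocity difference
    u_offset: float = 0.0  # common x-velocity added to both walls

    def __post_init__(self):
        if self.tau <= 0.5:
            raise ValueError("tau must exceed 0.5 for BGK stability")
        if abs(self.u_wall) + abs(self.u_offset) > 0.1:
            raise ValueError("wall speed too large (lattice Mach limit)")

    @property
    def H(self) -> float:
        return float(self.ny)

    @property
    def nu_lat(self) -> float:
        return (self.tau - 0.5) / 3.0

    @property
    def eta_lat(self) -> float:
        return self.nu_lat  # rho = 1

    @property
    def gamma_dot_lat(self) -> float:
        return 2.0 * self.u_wall / self.H

    @property
    def u_lo(self) -> float:
        return -self.u_wall + self.u_offset

    @property
    def u_hi(self) -> float:
        return self.u_wall + self.u_offset


class CouetteLBM:
    """D3Q19 BGK solver on a :class:`FlowDomain`.

    ``init='couette'`` starts from the analytic sheared state,
    ``init='rest'`` from a quiescent fluid.
    """

    def __init__(self, domain: FlowDomain, init: str = "couette"):
        self.domain = domain
        shape = (domain.nx, domain.ny, domain.nz)
        self.f = np.empty(shape + (19,))
        self._fnew = np.empty_like(self.f)
        self.rho = np.ones(shape)
        self.u = np.zeros(shape + (3,))
        if init == "couette":
            _kernels.lbm_init_shear(self.f, domain.u_lo, domain.u_hi)
        elif init == "rest":
            _kernels.lbm_init_shear(self.f, 0.0, 0.0)
        else:
            raise ValueError(f"unknown init {init!r}")
        # populate macroscopic fields
        self.step()

    def step(self, force_field: np.ndarray | None = None) -> float:
        """One collision-stream cycle; returns max |u| (lattice units).

        Raises ``FloatingPointError`` on instability (NaN or runaway
        velocity), advising a larger tau or smaller shear rate.
        """
        if force_field is None:
            force_field = np.zeros(self.f.shape[:3] + (3,))
        umax = _kernels.lbm_step(
            self.f, self._fnew, force_field, self.domain.tau,
            self.domain.u_lo, self.domain.u_hi, self.rho, self.u)
        self.f, self._fnew = self._fnew, self.f
        if not np.isfinite(umax) or umax > 0.3:
            raise FloatingPointError(
                f"lattice-Boltzmann instability (max |u| = {umax}); "
                "increase tau or reduce the shear rate")
        return umax

    def velocity_profile(self) -> np.ndarray:
        """x-velocity averaged over x and z, one value per y-row."""
        return self.u[..., 0].mean(axis=(0, 2))


@dataclass
class _Cell:
    center0: np.ndarray        # initial center (lattice)
    positions: np.ndarray      # current vertex positions (lattice)
    volume0: float


@dataclass
class Suspension:
    """One or more identical elastic cells sharing a template mesh.

    The template mesh is centered at the origin in lattice units; each cell
    stores its own current vertex positions.  Initial placements never
    overlap (enforced at seeding time).
    """

    mesh: TetMesh
    mat: MaterialParams
    cells: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        self.ref = precompute_reference(self.mesh)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def volume_fraction(self, domain: FlowDomain) -> float:
        v = sum(c.volume0 for c in self.cells)
        return v / (domain.nx * domain.ny * domain.nz)

    def add_cell(self, center: np.ndarray) -> None:
        pos = self.mesh.vertices + np.asarray(center, dtype=np.float64)
        vol = float(np.abs(signed_tet_volumes(pos, self.mesh.tets)).sum())
        self.cells.append(_Cell(center0=np.asarray(center, float),
                                positions=pos, volume0=vol))

    def elastic_forces(self, cell_index: int) -> np.ndarray:
        c = self.cells[cell_index]
        u = c.positions - (self.mesh.vertices + c.center0)
        f, _ = elastic_forces_and_energy(self.mesh, self.ref, u, self.mat)
        return f


def seed_suspension(mesh, mat, n_cells, domain, radius, seed=0,
                    max_tries=10000) -> Suspension:
    """Place ``n_cells`` cells at non-overlapping random positions.

    A single cell goes to the box center; multiple cells are drawn by
    rejection sampling with a fixed integer seed, keeping centers at least
    2.2 R apart and 1.3 R away from the walls.
    """
    susp = Suspension(mesh=mesh, mat=mat, seed=seed)
    if n_cells == 1:
        susp.add_cell(np.array([domain.nx / 2, domain.ny / 2, domain.nz / 2]))
        return susp
    rng = np.random.default_rng(seed)
    centers: list[np.ndarray] = []
    lo_y, hi_y = 1.3 * radius, domain.ny - 1.3 * radius
    for _ in range(max_tries):
        if len(centers) == n_cells:
            break
        c = np.array([rng.uniform(0, domain.nx),
                      rng.uniform(lo_y, hi_y),
                      rng.uniform(0, domain.nz)])
        ok = True
        for other in centers:
            d = c - other
            d[0] -= domain.nx * np.round(d[0] / domain.nx)
            d[2] -= domain.nz * np.round(d[2] / domain.nz)
            if np.linalg.norm(d) < 2.2 * radius:
                ok = False
                break
        if ok:
            centers.append(c)
    if len(centers) < n_cells:
        raise RuntimeError(
            f"could not place {n_cells} non-overlapping cells in the box")
    for c in centers:
        susp.add_cell(c)
    return susp


def _repulsion_forces(susp, domain, radius, k_rep, cutoff):
    """Short-range penalty repulsion between surface vertices of different
    cells and against the walls (minimum-image in x and z)."""
    out = [np.zeros_like(c.positions) for c in susp.cells]
    surf = susp.mesh.surface_vertices
    # walls
    for fcell, c in zip(out, susp.cells):
        y = c.positions[:, 1]
        low = y < cutoff
        fcell[low, 1] += k_rep * (cutoff - y[low])
        high = y > domain.ny - cutoff
        fcell[high, 1] -= k_rep * (y[high] - (domain.ny - cutoff))
    if susp.n_cells > 1:
        pts = []
        owner = []
        for ci, c in enumerate(susp.cells):
            p = c.positions[surf].copy()
            p[:, 0] %= domain.nx
            p[:, 2] %= domain.nz
            pts.append(p)
            owner.append(np.full(len(p), ci))
        pts = np.vstack(pts)
        owner = np.concatenate(owner)
        tree = cKDTree(pts, boxsize=[domain.nx, 1e9, domain.nz])
        for a, b in tree.query_pairs(cutoff):
            if owner[a] == owner[b]:
                continue
            d = pts[a] - pts[b]
            d[0] -= domain.nx * np.round(d[0] / domain.nx)
            d[2] -= domain.nz * np.round(d[2] / domain.nz)
            r = np.linalg.norm(d)
            if r < 1e-12 or r >= cutoff:
                continue
            fvec = k_rep * (cutoff - r) * d / r
            ia = surf[a % len(surf)]
            ib = surf[b % len(surf)]
            out[owner[a]][ia] += fvec
            out[owner[b]][ib] -= fvec
    return out


@dataclass
class ShearFlowResult:
    """Time series and summary of a shear-flow run.

    ``times`` are in shear times (gamma_dot * t); ``D`` has one column per
    cell.  ``mean_D`` averages all cells and the time span after the
    transient; ``conversion`` records the lattice-to-physical unit mapping.
    """

    times: np.ndarray
    D: np.ndarray
    strain: np.ndarray
    tagged_angle: np.ndarray
    volume_ratio: np.ndarray
    mean_D: float
    final_strain: float
    ca: float
    conversion: dict
    suspension: Suspension
    domain: FlowDomain


def run_shear_flow(
    ca: float,
    n_cells: int = 1,
    box: tuple[int, int, int] = (10, 15, 5),
    resolution: int = 5,
    mesh_subdivisions: int = 2,
    nu_material: float = 0.48,
    w: float = 1.0,
    tau: float = 1.0,
    u_wall: float = 0.04,
    duration: float = 10.0,
    transient: float = 5.0,
    steady_tol: float = 1e-3,
    seed: int = 0,
    record_interval: float = 0.1,
    eta_phys: float = 1e-3,
    rho_phys: float = 1e3,
    gamma_dot_phys: float = 4.0,
    radius_phys: float = 5e-6,
) -> ShearFlowResult:
    """Simulate one or more cells in plane Couette flow at capillary number Ca.

    ``box`` is the domain size in units of the cell radius; ``resolution`` is
    the cell radius in lattice spacings; ``duration`` and ``transient`` are in
    shear times 1/gamma_dot.  The run stops early once the relative change of
    the mean Taylor parameter over one shear time falls below ``steady_tol``
    (never before ``transient`` + 1 shear times).
    """
    if ca <= 0:
        raise ValueError("capillary number must be positive")
    radius = float(resolution)
    domain = FlowDomain(nx=box[0] * resolution, ny=box[1] * resolution,
                        nz=box[2] * resolution, tau=tau, u_wall=u_wall)
    gdot = domain.gamma_dot_lat
    mu_lat = domain.eta_lat * gdot / ca
    E_lat = 2.0 * mu_lat * (1.0 + nu_material)
    mat = material_from_E_nu(E_lat, nu_material, w)
    mesh = build_sphere_mesh(radius, subdivisions=mesh_subdivisions, seed=seed)
    susp = seed_suspension(mesh, mat, n_cells, domain, radius, seed=seed)

    lbm = CouetteLBM(domain, init="couette")
    force_field = np.zeros((domain.nx, domain.ny, domain.nz, 3))
    k_rep = 10.0 * E_lat
    cutoff = 0.1 * radius

    # tagged surface vertex for the tank-treading diagnostic (cell 0)
    surf = mesh.surface_vertices
    rel0 = mesh.vertices[surf]
    tagged = int(surf[np.argmax(rel0[:, 0])])

    n_steps = int(np.ceil(duration / gdot))
    rec_every = max(1, int(round(record_interval / gdot)))
    times, d_rec, s_rec, ang_rec, vol_rec = [], [], [], [], []
    prev_angle = 0.0

    vel = np.empty_like(susp.cells[0].positions)
    for step in range(n_steps):
        force_field[:] = 0.0
        rep = (_repulsion_forces(susp, domain, radius, k_rep, cutoff)
               if n_cells > 1 else None)
        for ci in range(n_cells):
            f = susp.elastic_forces(ci)
            if rep is not None:
                f = f + rep[ci]
            pos = susp.cells[ci].positions.copy()
            pos[:, 0] %= domain.nx
            pos[:, 2] %= domain.nz
            _kernels.ibm_spread(f, pos, force_field)
        lbm.step(force_field)
        for ci in range(n_cells):
            c = susp.cells[ci]
            pos = c.positions.copy()
            pos[:, 0] %= domain.nx
            pos[:, 2] %= domain.nz
            _kernels.ibm_interpolate(lbm.u, pos, vel)
            c.positions = c.positions + vel
            ymin, ymax = c.positions[:, 1].min(), c.positions[:, 1].max()
            if ymin < 0.0 or ymax > domain.ny:
                raise RuntimeError(
                    f"cell {ci} vertex left the channel (y in "
                    f"[{ymin:.2f}, {ymax:.2f}])")
        if (step + 1) % rec_every == 0:
            t_shear = (step + 1) * gdot
            ds = [taylor_D(mesh, c.positions) for c in susp.cells]
            strains = [
                (max_extent(c.positions) - 2 * radius) / (2 * radius)
                for c in susp.cells]
            vols = [
                float(np.abs(signed_tet_volumes(c.positions, mesh.tets)).sum()
                      / c.volume0) for c in susp.cells]
            c0 = susp.cells[0]
            com = c0.positions.mean(axis=0)
            relv = c0.positions[tagged] - com
            ang = np.arctan2(relv[1], relv[0])
            # unwrap against previous sample
            if times:
                while ang - prev_angle > np.pi:
                    ang -= 2 * np.pi
                while ang - prev_angle < -np.pi:
                    ang += 2 * np.pi
            prev_angle = ang
            times.append(t_shear)
            d_rec.append(ds)
            s_rec.append(np.mean(strains))
            ang_rec.append(ang)
            vol_rec.append(vols)
            # steady-state detection on the cell-averaged D
            lookback = int(round(1.0 / record_interval))
            if (t_shear > transient + 1.0 and len(d_rec) > lookback):
                d_now = np.mean(d_rec[-1])
                d_then = np.mean(d_rec[-1 - lookback])
                if abs(d_now - d_then) < steady_tol * max(abs(d_now), 1e-12):
                    break

    times = np.asarray(times)
    d_arr = np.asarray(d_rec)
    mask = times > transient
    if not mask.any():
        mask = times >= times[-1]  # fall back to the final sample
    dx_phys = radius_phys / resolution
    dt_phys = gdot / gamma_dot_phys
    conversion = {
        "dx_m": dx_phys,
        "dt_s": dt_phys,
        "mass_kg": rho_phys * dx_phys**3,
        "gamma_dot_lat": gdot,
        "tau": tau,
        "mu_lat": mu_lat,
        "mu_Pa": eta_phys * gamma_dot_phys / ca,
        "eta_Pa_s": eta_phys,
        "rho_kg_m3": rho_phys,
        "gamma_dot_s": gamma_dot_phys,
        "radius_m": radius_phys,
        "volume_fraction": susp.volume_fraction(domain),
    }
    return ShearFlowResult(
        times=times,
        D=d_arr,
        strain=np.asarray(s_rec),
        tagged_angle=np.unwrap(np.asarray(ang_rec)),
        volume_ratio=np.asarray(vol_rec),
        mean_D=float(d_arr[mask].mean()),
        final_strain=float(s_rec[-1]),
        ca=ca,
        conversion=conversion,
        suspension=susp,
        domain=domain,
    )
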