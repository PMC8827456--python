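"""Steady incompressible blood flow over the instantaneous platelet mass.

A D3Q19 BGK lattice Boltzmann solver relaxed to steady state on the shared
simulation lattice.  Walls and bound platelets are no-slip via half-way
bounce-back.  Two inlet parameterizations are supported:

``constant_shear_inlet``
    a fixed velocity profile (analytic duct/Poiseuille shape scaled to the
    requested inlet wall shear rate) — the microfluidic constant-flow
    condition;
``constant_pressure_drop``
    fixed pressure (density) at inlet and outlet — the physiological
    condition under which a growing thrombus can fully occlude the vessel
    and divert flow.

Blood is Newtonian (microfluidic scales: negligible Reynolds/Womersley
numbers), so the steady Stokes limit is the relevant regime and the
quasi-steady coupling — re-solving flow after the clot has changed — is
accurate.  The solver contract is the analytic oracle suite (rectangular
duct and Poiseuille tube profiles, mass conservation, divergence-free
interior), not the particular scheme.

Units: lengths um, velocities um/s, pressure Pa, shear rates 1/s,
flow rates uL/min.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from thrombosim.geometry import LatticeDomain

__all__ = [
    "FlowParams",
    "FlowField",
    "ShearField",
    "solve_flow",
    "shear_magnitude",
    "flow_rate",
    "wall_shear",
    "is_occluded",
    "duct_profile",
    "poiseuille_tube_profile",
    "inlet_profile",
]

UM3_S_TO_UL_MIN = 60.0 / 1.0e9

# ---------------------------------------------------------------------------
# D3Q19 lattice
# ---------------------------------------------------------------------------

_C = np.array(
    [
        [0, 0, 0],
        [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
        [1, 1, 0], [-1, -1, 0], [1, -1, 0], [-1, 1, 0],
        [1, 0, 1], [-1, 0, -1], [1, 0, -1], [-1, 0, 1],
        [0, 1, 1], [0, -1, -1], [0, 1, -1], [0, -1, 1],
    ],
    dtype=np.int8,
)
_W = np.array([1 / 3] + [1 / 18] * 6 + [1 / 36] * 12, dtype=np.float64)
_OPP = np.array(
    [0, 2, 1, 4, 3, 6, 5, 8, 7, 10, 9, 12, 11, 14, 13, 16, 15, 18, 17],
    dtype=np.int8,
)


@dataclass
class FlowParams:
    """Fluid properties, boundary condition, and solver controls."""

    rho: float = 1060.0  # kg/m^3
    mu: float = 3.5e-3  # Pa s
    bc_kind: str = "constant_shear_inlet"
    inlet_wall_shear: float = 200.0  # 1/s (constant_shear_inlet)
    pressure_drop: float | None = None  # Pa (constant_pressure_drop)
    convergence_tol: float = 1.0e-5  # relative velocity change per check interval
    max_sweeps: int = 60000
    check_every: int = 200
    tau: float = 1.2  # LB relaxation time (lattice units)

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("rho and mu must be > 0")
        if self.bc_kind not in ("constant_shear_inlet", "constant_pressure_drop"):
            raise ValueError(f"unknown bc_kind {self.bc_kind!r}")
        if self.bc_kind == "constant_pressure_drop" and self.pressure_drop is None:
            raise ValueError("constant_pressure_drop requires pressure_drop (Pa)")
        if not 0.5 < self.tau:
            raise ValueError("tau must exceed 0.5")

    @property
    def nu_um2_s(self) -> float:
        """Kinematic viscosity in um^2/s."""
        return self.mu / self.rho * 1.0e12


@dataclass
class FlowField:
    """Velocity/pressure solution on the lattice."""

    velocity: np.ndarray  # (nx, ny, nz, 3) um/s, zero on solids
    pressure: np.ndarray  # (nx, ny, nz) Pa, relative to outlet
    converged: bool
    Q: float  # uL/min at the mid-domain station
    sweeps: int = 0
    residual: float = 0.0
    _f: np.ndarray | None = field(default=None, repr=False)
    _solid: np.ndarray | None = field(default=None, repr=False)


@dataclass
class ShearField:
    """Local shear-rate magnitude gamma = sqrt(2 D:D) (1/s)."""

    gamma: np.ndarray  # (nx, ny, nz), zero on solids


# ---------------------------------------------------------------------------
# analytic inlet profiles
# ---------------------------------------------------------------------------


def duct_profile(y, z, width, height, n_terms: int = 51):
    """Unit-scaled rectangular-duct axial velocity (Fourier series solution
    of Poisson flow in a W x H duct), evaluated at points (y, z).

    Returns the velocity shape for unit pressure-gradient factor; scale
    externally.  ``y in [0, width]``, ``z in [0, height]``.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    u = np.zeros(np.broadcast(y, z).shape)
    for n in range(1, n_terms + 1, 2):
        kn = n * np.pi / height
        term = (
            (1.0 - np.cosh(kn * (y - width / 2.0)) / np.cosh(kn * width / 2.0))
            * np.sin(kn * z)
            / n**3
        )
        u = u + term
    return u


def duct_floor_midline_shear(width, height, n_terms: int = 51) -> float:
    """d(unit duct profile)/dz at the floor midline (y = W/2, z = 0)."""
    s = 0.0
    for n in range(1, n_terms + 1, 2):
        kn = n * np.pi / height
        s += (1.0 - 1.0 / np.cosh(kn * width / 2.0)) * kn / n**3
    return s


def poiseuille_tube_profile(r, radius, wall_shear):
    """Poiseuille axial velocity u(r) = (gamma_w R / 2)(1 - r^2/R^2)."""
    r = np.asarray(r, dtype=float)
    u = wall_shear * radius / 2.0 * (1.0 - (r / radius) ** 2)
    return np.maximum(u, 0.0)


def inlet_profile(domain: LatticeDomain, wall_shear: float) -> np.ndarray:
    """Axial inlet velocity (um/s) on the inlet plane, scaled so that the
    inlet wall shear rate equals ``wall_shear``.

    Channel: rectangular-duct series profile, shear measured at the floor
    midline.  Tube/stenosis: Poiseuille profile at the inlet diameter.
    """
    nx, ny, nz = domain.shape
    h = domain.h
    prof = np.zeros((ny, nz))
    if domain.geometry_kind == "channel":
        width = ny * h
        height = nz * h
        y = (np.arange(ny)[:, None] + 0.5) * h
        z = (np.arange(nz)[None, :] + 0.5) * h
        shape = duct_profile(y, z, width, height)
        scale = wall_shear / duct_floor_midline_shear(width, height)
        prof = shape * scale
    else:
        c = ny * h / 2.0
        y = (np.arange(ny)[:, None] + 0.5) * h - c
        z = (np.arange(nz)[None, :] + 0.5) * h - c
        r = np.hypot(y, z)
        radius = domain.meta.get("diameter", domain.meta.get("inlet_diameter", ny * h)) / 2.0
        prof = poiseuille_tube_profile(r, radius, wall_shear)
    prof = np.where(domain.fluid_mask[0], prof, 0.0)
    return prof


# ---------------------------------------------------------------------------
# LB kernels
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _sweep(f, fnew, solid, cx, cy, cz, cxi, cyi, czi, w, opp, omega):
    """Fused pull-streaming + BGK collision: ``f`` holds post-collision
    populations of the previous step; ``fnew`` receives the next ones.
    Solid neighbors reflect via half-way bounce-back."""
    nx, ny, nz, nq = f.shape
    fin = np.empty(nq)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if solid[i, j, k]:
                    continue
                rho = 0.0
                ux = 0.0
                uy = 0.0
                uz = 0.0
                for q in range(nq):
                    si = i - cxi[q]
                    sj = j - cyi[q]
                    sk = k - czi[q]
                    if si < 0 or si >= nx:
                        # open axial face: value replaced by the BC pass
                        v = f[i, j, k, q]
                    elif sj < 0 or sj >= ny or sk < 0 or sk >= nz or solid[si, sj, sk]:
                        v = f[i, j, k, opp[q]]
                    else:
                        v = f[si, sj, sk, q]
                    fin[q] = v
                    rho += v
                    ux += v * cx[q]
                    uy += v * cy[q]
                    uz += v * cz[q]
                ux /= rho
                uy /= rho
                uz /= rho
                usq = ux * ux + uy * uy + uz * uz
                for q in range(nq):
                    cu = cx[q] * ux + cy[q] * uy + cz[q] * uz
                    feq = w[q] * rho * (1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq)
                    fnew[i, j, k, q] = fin[q] + omega * (feq - fin[q])


@njit(cache=True, fastmath=True)
def _set_equilibrium(f, i, j, k, rho, ux, uy, uz, cx, cy, cz, w):
    usq = ux * ux + uy * uy + uz * uz
    for q in range(f.shape[3]):
        cu = cx[q] * ux + cy[q] * uy + cz[q] * uz
        f[i, j, k, q] = w[q] * rho * (1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq)


@njit(cache=True, fastmath=True)
def _macro_cell(f, i, j, k, cx, cy, cz):
    rho = 0.0
    ux = 0.0
    uy = 0.0
    uz = 0.0
    for q in range(f.shape[3]):
        fq = f[i, j, k, q]
        rho += fq
        ux += fq * cx[q]
        uy += fq * cy[q]
        uz += fq * cz[q]
    return rho, ux / rho, uy / rho, uz / rho


@njit(cache=True, fastmath=True)
def _apply_bc(fnew, solid, u_in, velocity_inlet, rho_in, rho_out, cx, cy, cz, w):
    nx, ny, nz, nq = fnew.shape
    for j in range(ny):
        for k in range(nz):
            if not solid[0, j, k]:
                if velocity_inlet:
                    rho, _, _, _ = _macro_cell(fnew, 0, j, k, cx, cy, cz)
                    _set_equilibrium(fnew, 0, j, k, rho, u_in[j, k], 0.0, 0.0,
                                     cx, cy, cz, w)
                else:
                    ux, uy, uz = 0.0, 0.0, 0.0
                    if nx > 1 and not solid[1, j, k]:
                        _, ux, uy, uz = _macro_cell(fnew, 1, j, k, cx, cy, cz)
                    _set_equilibrium(fnew, 0, j, k, rho_in, ux, uy, uz,
                                     cx, cy, cz, w)
            if not solid[nx - 1, j, k]:
                ux, uy, uz = 0.0, 0.0, 0.0
                if nx > 1 and not solid[nx - 2, j, k]:
                    _, ux, uy, uz = _macro_cell(fnew, nx - 2, j, k, cx, cy, cz)
                _set_equilibrium(fnew, nx - 1, j, k, rho_out, ux, uy, uz,
                                 cx, cy, cz, w)


@njit(cache=True, fastmath=True)
def _macro_fields(f, solid, cx, cy, cz):
    nx, ny, nz, nq = f.shape
    rho = np.zeros((nx, ny, nz))
    u = np.zeros((nx, ny, nz, 3))
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if solid[i, j, k]:
                    rho[i, j, k] = 1.0
                    continue
                r, ux, uy, uz = _macro_cell(f, i, j, k, cx, cy, cz)
                rho[i, j, k] = r
                u[i, j, k, 0] = ux
                u[i, j, k, 1] = uy
                u[i, j, k, 2] = uz
    return rho, u


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def _initial_populations(domain, solid, velocity_inlet, u_in, rho_in):
    """Equilibrium initialization from a cheap guess: the inlet profile
    broadcast along the axis (velocity BC) or a linear axial density ramp
    (pressure BC).  Cuts the relaxation transient substantially."""
    nx, ny, nz = domain.shape
    rho = np.ones((nx, ny, nz))
    u = np.zeros((nx, ny, nz, 3))
    if velocity_inlet:
        u[..., 0] = u_in[None, :, :]
        u[solid] = 0.0
    else:
        ramp = np.linspace(rho_in, 1.0, nx)
        rho = np.broadcast_to(ramp[:, None, None], (nx, ny, nz)).copy()
    f = np.empty((nx, ny, nz, 19))
    usq = (u**2).sum(axis=-1)
    for q in range(19):
        cu = (
            u[..., 0] * _C[q, 0] + u[..., 1] * _C[q, 1] + u[..., 2] * _C[q, 2]
        )
        f[..., q] = _W[q] * rho * (1.0 + 3.0 * cu + 4.5 * cu**2 - 1.5 * usq)
    return f


def _connected_open_path(solid: np.ndarray) -> bool:
    """True if any fluid path connects the inlet face to the outlet face."""
    from scipy import ndimage

    labels, _ = ndimage.label(~solid)
    inlet_labels = np.unique(labels[0][~solid[0]])
    outlet_labels = np.unique(labels[-1][~solid[-1]])
    return bool(np.intersect1d(inlet_labels, outlet_labels).size)


def solve_flow(
    domain: LatticeDomain,
    occupancy: np.ndarray | None,
    params: FlowParams,
    warm_start: FlowField | None = None,
) -> FlowField:
    """Relax the LB populations to steady state over walls + bound platelets.

    ``occupancy`` is a boolean mask of bound-platelet voxels (no-slip).
    ``warm_start`` reuses the populations of a previous solve on the same
    lattice (occupancy may differ) to accelerate quasi-steady re-solves.
    A fully occluded domain returns a zero-velocity, converged field.
    """
    nx, ny, nz = domain.shape
    solid = ~domain.fluid_mask
    if occupancy is not None:
        solid = solid | occupancy
    solid_u8 = solid.astype(np.uint8)

    h = domain.h
    nu_lb = (params.tau - 0.5) / 3.0
    dt = nu_lb * h * h / params.nu_um2_s  # s per LB step
    vel_scale = dt / h  # um/s -> lattice
    # pressure unit: rho_phys * (dx/dt)^2 with dx in metres
    p_unit = params.rho * (h * 1.0e-6 / dt) ** 2

    if not _connected_open_path(solid):
        return FlowField(
            velocity=np.zeros((nx, ny, nz, 3)),
            pressure=np.zeros((nx, ny, nz)),
            converged=True,
            Q=0.0,
            sweeps=0,
        )

    velocity_inlet = params.bc_kind == "constant_shear_inlet"
    if velocity_inlet:
        u_in = inlet_profile(domain, params.inlet_wall_shear) * vel_scale
        rho_in = 1.0
    else:
        u_in = np.zeros((ny, nz))
        rho_in = 1.0 + 3.0 * params.pressure_drop / p_unit
    rho_out = 1.0

    cx = _C[:, 0].astype(np.float64)
    cy = _C[:, 1].astype(np.float64)
    cz = _C[:, 2].astype(np.float64)
    cxi = _C[:, 0].astype(np.int64)
    cyi = _C[:, 1].astype(np.int64)
    czi = _C[:, 2].astype(np.int64)

    if warm_start is not None and warm_start._f is not None:
        f = warm_start._f.copy()
        # voxels newly turned solid keep stale populations; they are skipped
        # by the collision/stream masks, and bounce-back uses neighbors only.
    else:
        f = _initial_populations(domain, solid, velocity_inlet, u_in, rho_in)
    fnew = np.empty_like(f)

    omega = 1.0 / params.tau
    u_prev = None
    converged = False
    residual = np.inf
    sweeps = 0
    while sweeps < params.max_sweeps:
        for _ in range(params.check_every):
            _sweep(f, fnew, solid_u8, cx, cy, cz, cxi, cyi, czi, _W, _OPP, omega)
            _apply_bc(fnew, solid_u8, u_in, velocity_inlet, rho_in, rho_out,
                      cx, cy, cz, _W)
            f, fnew = fnew, f
            sweeps += 1
        rho, u = _macro_fields(f, solid_u8, cx, cy, cz)
        umax = np.abs(u).max()
        if u_prev is not None:
            residual = np.abs(u - u_prev).max() / max(umax, 1e-300)
            if residual < params.convergence_tol:
                converged = True
                break
        u_prev = u

    rho, u = _macro_fields(f, solid_u8, cx, cy, cz)
    velocity = u / vel_scale  # um/s
    velocity[solid] = 0.0
    pressure = (rho - rho_out) / 3.0 * p_unit
    pressure[solid] = 0.0

    field_out = FlowField(
        velocity=velocity,
        pressure=pressure,
        converged=converged,
        Q=0.0,
        sweeps=sweeps,
        residual=float(residual),
        _f=f,
        _solid=solid,
    )
    field_out.Q = flow_rate(field_out, domain, nx // 2, occupancy=occupancy)
    return field_out


def flow_rate(
    flow: FlowField,
    domain: LatticeDomain,
    station: int,
    occupancy: np.ndarray | None = None,
) -> float:
    """Volumetric flow rate (uL/min): surface integral of axial velocity
    over the open voxels of cross-section ``station``."""
    nx = domain.shape[0]
    if not 0 <= station < nx:
        raise IndexError(f"station {station} outside domain of length {nx}")
    open_mask = domain.fluid_mask[station]
    if occupancy is not None:
        open_mask = open_mask & ~occupancy[station]
    elif flow._solid is not None:
        open_mask = ~flow._solid[station]
    q_um3_s = float(
        (flow.velocity[station, :, :, 0] * open_mask).sum() * domain.h**2
    )
    return q_um3_s * UM3_S_TO_UL_MIN


def is_occluded(Q: float, Q0: float, threshold: float = 0.05) -> bool:
    """Occlusion criterion: Q strictly below ``threshold`` of its initial
    value (Q exactly at the threshold is not occlusion)."""
    if Q0 <= 0:
        raise ValueError("Q0 must be > 0")
    return Q < threshold * Q0


# ---------------------------------------------------------------------------
# shear
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _shear_kernel(u, solid, h):
    """gamma = sqrt(2 D:D) with wall-aware one-sided differences.

    At a fluid voxel whose neighbor along an axis is solid, the velocity
    gradient along that axis uses a quadratic fit through the wall face
    (zero velocity half a spacing away), which is exact for locally
    parabolic profiles.
    """
    nx, ny, nz, _ = u.shape
    gamma = np.zeros((nx, ny, nz))
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if solid[i, j, k]:
                    continue
                g = np.zeros((3, 3))
                for axis in range(3):
                    im, jm, km = i, j, k
                    ip, jp, kp = i, j, k
                    if axis == 0:
                        im, ip = i - 1, i + 1
                    elif axis == 1:
                        jm, jp = j - 1, j + 1
                    else:
                        km, kp = k - 1, k + 1
                    # along x the inlet/outlet faces are open (extrapolate);
                    # along y/z out-of-box is wall
                    if axis == 0:
                        lo_solid = im >= 0 and solid[im, jm, km]
                        hi_solid = ip < nx and solid[ip, jp, kp]
                        lo_open = im < 0
                        hi_open = ip >= nx
                    else:
                        lo_solid = (jm < 0 or km < 0) or solid[im, jm, km]
                        hi_solid = (jp >= ny or kp >= nz) or solid[ip, jp, kp]
                        lo_open = False
                        hi_open = False
                    for c in range(3):
                        uc = u[i, j, k, c]
                        if lo_open or hi_open:
                            # one-sided first-order at open axial faces
                            if lo_open and not hi_solid:
                                d = (u[ip, jp, kp, c] - uc) / h
                            elif hi_open and not lo_solid:
                                d = (uc - u[im, jm, km, c]) / h
                            else:
                                d = 0.0
                        elif not lo_solid and not hi_solid:
                            d = (u[ip, jp, kp, c] - u[im, jm, km, c]) / (2.0 * h)
                        elif lo_solid and hi_solid:
                            d = 0.0
                        elif lo_solid:
                            # wall face at half a spacing below: quadratic fit
                            # through (wall, 0), this voxel, and the next one
                            d = (3.0 * uc + u[ip, jp, kp, c]) / (3.0 * h)
                        else:
                            d = -(3.0 * uc + u[im, jm, km, c]) / (3.0 * h)
                        g[c, axis] = d
                s = 0.0
                for a in range(3):
                    for b in range(3):
                        dab = 0.5 * (g[a, b] + g[b, a])
                        s += 2.0 * dab * dab
                gamma[i, j, k] = np.sqrt(s)
    return gamma


def shear_magnitude(flow: FlowField, domain: LatticeDomain) -> ShearField:
    """Shear-rate magnitude field from the strain-rate tensor."""
    solid = flow._solid if flow._solid is not None else ~domain.fluid_mask
    gamma = _shear_kernel(flow.velocity, solid.astype(np.uint8), domain.h)
    return ShearField(gamma=gamma)


def wall_shear(flow: FlowField, domain: LatticeDomain) -> np.ndarray:
    """Wall shear rate estimate at wall-adjacent fluid voxels (1/s).

    Quadratic extrapolation of the tangential speed through the wall face:
    ``gamma_w = (9 u0 - u1) / (3 h)`` with ``u0`` the speed at the
    wall-adjacent voxel and ``u1`` one voxel further along the wall
    normal (exact for a parabolic profile).  Zero elsewhere.
    """
    solid = flow._solid if flow._solid is not None else ~domain.fluid_mask
    speed = np.linalg.norm(flow.velocity, axis=-1)
    h = domain.h
    nx, ny, nz = domain.shape
    out = np.zeros((nx, ny, nz))
    pad_solid = np.pad(solid, 1, mode="constant", constant_values=True)
    # transverse walls only (axes 1, 2): vessel walls and clot surface
    for axis in (1, 2):
        for sgn in (-1, 1):
            shifted = np.roll(pad_solid, -sgn, axis=axis)[1:-1, 1:-1, 1:-1]
            at_wall = shifted & ~solid
            u1 = np.roll(speed, sgn, axis=axis)
            est = (9.0 * speed - u1) / (3.0 * h)
            out = np.where(at_wall, np.maximum(out, est), out)
    return out


def throat_shear(flow: FlowField, domain: LatticeDomain,
                 band_halfwidth: int = 3) -> float:
    """Characteristic wall shear rate at the stenosis throat (1/s): the
    median strain-rate magnitude over wall-adjacent fluid voxels within
    ``band_halfwidth`` axial stations of the domain midpoint (the median is
    robust to staircase-voxelization outliers)."""
    from thrombosim.geometry import wall_adjacent_mask

    gamma = shear_magnitude(flow, domain).gamma
    wa = wall_adjacent_mask(domain)
    nx = domain.shape[0]
    band = slice(max(nx // 2 - band_halfwidth, 0), min(nx // 2 + band_halfwidth, nx))
    vals = gamma[band][wa[band]]
    vals = vals[vals > 0]
    return float(np.median(vals)) if vals.size else 0.0
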