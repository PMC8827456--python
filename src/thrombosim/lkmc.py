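"""Rejection-free lattice kinetic Monte Carlo over the platelet population.

Platelets occupy single lattice voxels (hard exclusion: at most one per
voxel).  A mobile platelet carries six directional motion rates

    Gamma_d = max(v . e_d, 0) / h  +  D_platelet / h^2,

the upwind projection of the local fluid velocity plus an isotropic
diffusive rate representing RBC-enhanced dispersion.  Mobile platelets
adjacent to the collagen patch or to bound platelets additionally carry
attachment rates, and bound platelets carry a detachment rate, both from
:mod:`thrombosim.adhesion` evaluated at the platelet's activation state
and local shear.  The classic direct (rejection-free) algorithm selects
each event with probability rate/Lambda and advances time by an
Exp(Lambda) waiting time.

A bound platelet's bonds are its collagen contact (recorded at
attachment, while it sits on a reactive voxel) plus every face-adjacent
bound platelet.  Detachment releases all bonds at once; the effective
rate combines the per-bond detachment rates in series (breaking n bonds
takes the summed expected times):  Gamma_det = 1 / sum_b(1 / Gamma_b).
A platelet left with zero bonds by a neighbor's detachment becomes
mobile again; detached platelets keep their activation state and keep
releasing agonists while moving.

Inlet injection is Poissonian per inlet voxel with intensity
(axial velocity x voxel area x local concentration), using a near-wall
platelet-excess concentration profile (margination): the concentration is
``wall_excess``-fold the mean within ``margination_layer`` of the wall,
with the core depleted so the flux-weighted mean matches the prescribed
bulk count.  Platelets crossing the outlet face leave the simulation.

The hot loop (motion events) runs in a numba kernel that maintains the
per-platelet total-rate table incrementally; attachment/detachment events
return control to Python.  Tests audit the kernel's incremental table
against a full rebuild (:func:`build_event_table`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from thrombosim import adhesion as adh
from thrombosim.geometry import LatticeDomain

__all__ = [
    "Platelet",
    "Population",
    "EventTable",
    "motion_rates",
    "build_event_table",
    "select_event",
    "execute_event",
    "inject_inlet",
    "advance_kmc",
    "seed_kernel_rng",
    "local_shear_map",
]

_DIRS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)

MOBILE = 0
BOUND = 1

D_PLATELET_DEFAULT = 10.0  # um^2/s, RBC-enhanced platelet dispersion


@dataclass
class Platelet:
    """Snapshot record of one platelet (the engine itself is array-based)."""

    id: int
    voxel: tuple[int, int, int]
    mobility: str  # "mobile" | "bound"
    bond_collagen: bool
    xi: float
    xi_dt: float
    release_triggered: bool
    t_release: float
    created_t: float


class Population:
    """Structure-of-arrays platelet population tied to a domain.

    Rows ``0..n`` are live platelets; removal compacts by swapping the
    last row into the hole (ids in ``ids`` stay stable for bookkeeping).
    """

    def __init__(self, domain: LatticeDomain, n_window: int = 20, capacity: int = 256,
                 F4_init: float = 0.01):
        self.domain = domain
        self.n = 0
        self._next_id = 0
        self.n_window = n_window
        # resting-state activation product F(0)^2 = alpha_min^2: platelets
        # must be able to bind within their first signaling step
        self.F4_init = F4_init
        self.occ = np.full(domain.shape, -1, dtype=np.int32)
        self._alloc(capacity)
        self.n_exited = 0
        self.n_discarded = 0

    def _alloc(self, capacity: int) -> None:
        self.capacity = capacity
        self.ids = np.zeros(capacity, dtype=np.int64)
        self.pos = np.zeros((capacity, 3), dtype=np.int64)
        self.bound = np.zeros(capacity, dtype=np.uint8)
        self.bond_col = np.zeros(capacity, dtype=np.uint8)
        self.created_t = np.zeros(capacity)
        # signaling state
        self.ca = np.zeros(capacity)
        self.aux = np.zeros((capacity, 3))
        self.xi = np.zeros(capacity)
        self.xi_dt = np.zeros(capacity)
        self.ring = np.zeros((capacity, self.n_window))
        self.released = np.zeros(capacity, dtype=bool)
        self.t_release = np.full(capacity, np.nan)
        # cached activation factors for the rate laws
        self.F4 = np.zeros(capacity)

    def _grow(self) -> None:
        old = self.__dict__.copy()
        self._alloc(self.capacity * 2)
        for name in ("ids", "pos", "bound", "bond_col", "created_t", "ca", "aux",
                     "xi", "xi_dt", "ring", "released", "t_release", "F4"):
            getattr(self, name)[: self.n] = old[name][: self.n]

    def add(self, voxel, t: float, ca0: float = 100.0) -> int:
        """Insert a mobile, unactivated platelet at ``voxel``; returns row."""
        voxel = tuple(int(c) for c in voxel)
        if self.occ[voxel] != -1:
            raise ValueError(f"voxel {voxel} already occupied")
        if not self.domain.fluid_mask[voxel]:
            raise ValueError(f"voxel {voxel} is not fluid")
        if self.n == self.capacity:
            self._grow()
        i = self.n
        self.n += 1
        self.ids[i] = self._next_id
        self._next_id += 1
        self.pos[i] = voxel
        self.bound[i] = MOBILE
        self.bond_col[i] = 0
        self.created_t[i] = t
        self.ca[i] = ca0
        self.aux[i] = (0.0, 1.0, 1.0)
        self.xi[i] = 0.0
        self.xi_dt[i] = 0.0
        self.ring[i] = 0.0
        self.released[i] = False
        self.t_release[i] = np.nan
        self.F4[i] = self.F4_init
        self.occ[voxel] = i
        return i

    def remove(self, i: int) -> None:
        """Swap-compact removal of row ``i``."""
        if not 0 <= i < self.n:
            raise IndexError(f"no platelet row {i} (population size {self.n})")
        last = self.n - 1
        self.occ[tuple(self.pos[i])] = -1
        if i != last:
            for name in ("ids", "pos", "bound", "bond_col", "created_t", "ca",
                         "aux", "xi", "xi_dt", "ring", "released", "t_release", "F4"):
                getattr(self, name)[i] = getattr(self, name)[last]
            self.occ[tuple(self.pos[i])] = i
        self.n = last

    def compact_exited(self) -> None:
        """Drop rows marked exited by the kernel (position set to -1)."""
        i = 0
        while i < self.n:
            if self.pos[i, 0] < 0:
                last = self.n - 1
                if i != last:
                    for name in ("ids", "pos", "bound", "bond_col", "created_t",
                                 "ca", "aux", "xi", "xi_dt", "ring", "released",
                                 "t_release", "F4"):
                        getattr(self, name)[i] = getattr(self, name)[last]
                    if self.pos[i, 0] >= 0:
                        self.occ[tuple(self.pos[i])] = i
                self.n = last
            else:
                i += 1

    # -- views ---------------------------------------------------------

    @property
    def n_bound(self) -> int:
        return int(self.bound[: self.n].sum())

    @property
    def n_mobile(self) -> int:
        return self.n - self.n_bound

    def bound_mask_grid(self) -> np.ndarray:
        """Boolean voxel mask of bound platelets (the clot, for the flow solver)."""
        mask = np.zeros(self.domain.shape, dtype=bool)
        sel = self.bound[: self.n] == BOUND
        p = self.pos[: self.n][sel]
        mask[p[:, 0], p[:, 1], p[:, 2]] = True
        return mask

    def snapshot(self) -> list[Platelet]:
        return [
            Platelet(
                id=int(self.ids[i]),
                voxel=tuple(int(c) for c in self.pos[i]),
                mobility="bound" if self.bound[i] else "mobile",
                bond_collagen=bool(self.bond_col[i]),
                xi=float(self.xi[i]),
                xi_dt=float(self.xi_dt[i]),
                release_triggered=bool(self.released[i]),
                t_release=float(self.t_release[i]),
                created_t=float(self.created_t[i]),
            )
            for i in range(self.n)
        ]


# ---------------------------------------------------------------------------
# rates (reference implementations; the kernel mirrors these)
# ---------------------------------------------------------------------------


def motion_rates(v, D_platelet: float, h: float) -> np.ndarray:
    """Six directional motion rates (+x, -x, +y, -y, +z, -z) in 1/s for
    local fluid velocity ``v`` (um/s): upwind convective projection plus
    the isotropic diffusive rate.  Blocking by walls/occupancy is applied
    by the caller."""
    v = np.asarray(v, dtype=float)
    proj = _DIRS @ v
    return np.maximum(proj, 0.0) / h + D_platelet / h**2


@dataclass
class EventTable:
    """Full rate table over the population (audit/reference path)."""

    motion: np.ndarray  # (n, 6)
    attach: np.ndarray  # (n,)
    detach: np.ndarray  # (n,)

    @property
    def per_platelet(self) -> np.ndarray:
        return self.motion.sum(axis=1) + self.attach + self.detach

    @property
    def total_rate(self) -> float:
        return float(self.per_platelet.sum())


def _pair_detach(F4_i, F4_j, E_i, E_j, G_i, G_j, p: adh.AdhesionParams) -> float:
    return p.k_det_platelet / np.sqrt(F4_i * F4_j * E_i * E_j) * np.sqrt(G_i * G_j)


def build_event_table(
    pop: Population,
    velocity: np.ndarray,
    E_loc: np.ndarray,
    G_loc: np.ndarray,
    params: adh.AdhesionParams,
    D_platelet: float = D_PLATELET_DEFAULT,
) -> EventTable:
    """Rebuild the complete event table from scratch (used by tests to audit
    the kernel's incrementally maintained table, and as the reference
    implementation of the rate laws)."""
    dom = pop.domain
    n = pop.n
    motion = np.zeros((n, 6))
    attach = np.zeros(n)
    detach = np.zeros(n)
    h = dom.h
    nx, ny, nz = dom.shape
    for i in range(n):
        x, y, z = pop.pos[i]
        E_i = E_loc[x, y, z]
        G_i = G_loc[x, y, z]
        F4_i = pop.F4[i]
        if pop.bound[i] == MOBILE:
            rates = motion_rates(velocity[x, y, z], D_platelet, h)
            for d in range(6):
                tx, ty, tz = pop.pos[i] + _DIRS[d]
                if tx < 0 or ty < 0 or tz < 0 or ty >= ny or tz >= nz:
                    rates[d] = 0.0
                elif tx >= nx:
                    pass  # outlet exit allowed
                elif not dom.fluid_mask[tx, ty, tz] or pop.occ[tx, ty, tz] != -1:
                    rates[d] = 0.0
            motion[i] = rates
            a = 0.0
            if dom.reactive_mask[x, y, z]:
                a += params.k_att_collagen * F4_i * E_i
            for d in range(6):
                tx, ty, tz = pop.pos[i] + _DIRS[d]
                if 0 <= tx < nx and 0 <= ty < ny and 0 <= tz < nz:
                    j = pop.occ[tx, ty, tz]
                    if j >= 0 and pop.bound[j] == BOUND:
                        E_j = E_loc[tx, ty, tz]
                        a += params.k_att_platelet * np.sqrt(
                            F4_i * pop.F4[j] * E_i * E_j
                        )
            attach[i] = a
        else:
            inv = 0.0
            if pop.bond_col[i]:
                inv += 1.0 / (params.k_det_collagen / (F4_i * E_i) * G_i)
            for d in range(6):
                tx, ty, tz = pop.pos[i] + _DIRS[d]
                if 0 <= tx < nx and 0 <= ty < ny and 0 <= tz < nz:
                    j = pop.occ[tx, ty, tz]
                    if j >= 0 and pop.bound[j] == BOUND:
                        inv += 1.0 / _pair_detach(
                            F4_i, pop.F4[j], E_i, E_loc[tx, ty, tz],
                            G_i, G_loc[tx, ty, tz], params,
                        )
            detach[i] = 1.0 / inv if inv > 0 else 1.0e3
    return EventTable(motion=motion, attach=attach, detach=detach)


def select_event(table: EventTable, rng: np.random.Generator):
    """Direct-KMC selection: event with probability rate/Lambda and an
    exponential waiting time dt = -ln(u)/Lambda.  Returns
    ``((platelet, kind, direction), dt)`` or ``(None, inf)`` when the
    table is empty (quiescent system)."""
    lam = table.total_rate
    if lam <= 0.0:
        return None, np.inf
    dt = -np.log(rng.random()) / lam
    r = rng.random() * lam
    per = table.per_platelet
    cum = np.cumsum(per)
    i = int(np.searchsorted(cum, r, side="right"))
    i = min(i, len(per) - 1)
    r -= cum[i - 1] if i > 0 else 0.0
    sub = np.concatenate([table.motion[i], [table.attach[i], table.detach[i]]])
    cs = np.cumsum(sub)
    k = int(np.searchsorted(cs, min(r, cs[-1] * (1 - 1e-15)), side="right"))
    if k < 6:
        return (i, "move", k), dt
    if k == 6:
        return (i, "attach", -1), dt
    return (i, "detach", -1), dt


def execute_event(pop: Population, event) -> dict:
    """Apply a selected event to the population (reference path).

    Moves honor hard exclusion; a move across the outlet face removes the
    platelet; attach binds (recording a collagen bond when on a reactive
    voxel); detach releases all bonds, demoting newly bond-less neighbors
    to mobile.  Returns a small log dict.
    """
    i, kind, d = event
    dom = pop.domain
    nx, ny, nz = dom.shape
    if kind == "move":
        if pop.bound[i] == BOUND:
            raise RuntimeError("stale event: bound platelet selected for motion")
        tgt = pop.pos[i] + _DIRS[d]
        tx, ty, tz = tgt
        if tx >= nx:
            pop.remove(i)
            pop.n_exited += 1
            return {"kind": "exit"}
        if (tx < 0 or ty < 0 or tz < 0 or ty >= ny or tz >= nz
                or not dom.fluid_mask[tx, ty, tz] or pop.occ[tx, ty, tz] != -1):
            raise RuntimeError(f"stale event: move into blocked voxel {tuple(tgt)}")
        pop.occ[tuple(pop.pos[i])] = -1
        pop.pos[i] = tgt
        pop.occ[tuple(tgt)] = i
        return {"kind": "move"}
    if kind == "attach":
        pop.bound[i] = BOUND
        pop.bond_col[i] = 1 if dom.reactive_mask[tuple(pop.pos[i])] else 0
        return {"kind": "attach"}
    if kind == "detach":
        pop.bound[i] = MOBILE
        pop.bond_col[i] = 0
        # neighbors left without any bond become mobile too
        for dd in range(6):
            t2 = pop.pos[i] + _DIRS[dd]
            if np.all(t2 >= 0) and t2[0] < nx and t2[1] < ny and t2[2] < nz:
                j = pop.occ[tuple(t2)]
                if j >= 0 and pop.bound[j] == BOUND and not _has_bonds(pop, j):
                    pop.bound[j] = MOBILE
                    pop.bond_col[j] = 0
        return {"kind": "detach"}
    raise ValueError(f"unknown event kind {kind!r}")


def _has_bonds(pop: Population, j: int) -> bool:
    if pop.bond_col[j] and pop.domain.reactive_mask[tuple(pop.pos[j])]:
        return True
    nx, ny, nz = pop.domain.shape
    for d in range(6):
        t = pop.pos[j] + _DIRS[d]
        if np.all(t >= 0) and t[0] < nx and t[1] < ny and t[2] < nz:
            k = pop.occ[tuple(t)]
            if k >= 0 and k != j and pop.bound[k] == BOUND:
                return True
    return False


# ---------------------------------------------------------------------------
# inlet injection with margination
# ---------------------------------------------------------------------------


def inject_inlet(
    pop: Population,
    flow,
    mean_concentration: float,
    dt: float,
    rng: np.random.Generator,
    wall_excess: float = 3.0,
    margination_layer: float = 5.0,
    station: int = 0,
    t: float = 0.0,
) -> int:
    """Poisson inlet arrivals over ``dt``; returns the number injected.

    ``mean_concentration`` is the tracked platelet count per uL of blood
    (flux-weighted mean over the inlet).  The local concentration is
    ``wall_excess``-fold the mean within ``margination_layer`` (um) of the
    wall, and the core factor is renormalized so the flux-weighted mean is
    preserved (RBC-driven margination).
    """
    from scipy import ndimage

    dom = pop.domain
    h = dom.h
    fluid2d = dom.fluid_mask[station]
    ux = flow.velocity[station, :, :, 0]
    flux = np.maximum(ux, 0.0) * fluid2d  # um/s
    if flux.sum() == 0:
        return 0
    padded = np.pad(fluid2d, 1, mode="constant", constant_values=False)
    dist = (ndimage.distance_transform_edt(padded)[1:-1, 1:-1] - 0.5) * h
    near = dist <= margination_layer
    factor = np.ones_like(flux)
    flux_tot = flux.sum()
    flux_near = flux[near].sum()
    flux_core = flux_tot - flux_near
    if flux_core > 0:
        core_factor = (flux_tot - wall_excess * flux_near) / flux_core
        core_factor = max(core_factor, 0.0)
    else:
        core_factor = 0.0
    factor[near] = wall_excess
    factor[~near] = core_factor
    # re-normalize exactly (clipping may have shifted the mean)
    mean_factor = (flux * factor).sum() / flux_tot
    factor /= mean_factor
    conc = mean_concentration * 1.0e-9 * factor  # platelets / um^3
    lam = flux * h * h * conc * dt
    counts = rng.poisson(lam)
    n_new = 0
    for (j, k) in zip(*np.nonzero(counts)):
        for _ in range(int(counts[j, k])):
            if pop.occ[station, j, k] == -1:
                pop.add((station, j, k), t=t)
                n_new += 1
            else:
                pop.n_discarded += 1
    return n_new


# ---------------------------------------------------------------------------
# numba kernel: motion-dominated event loop with incremental rate table
# ---------------------------------------------------------------------------


@njit(cache=True)
def _seed(seed):
    np.random.seed(seed)


def seed_kernel_rng(seed: int) -> None:
    """Seed the KMC kernel's RNG (numba's per-process np.random state)."""
    _seed(int(seed) % (2**31 - 1))


@njit(cache=True, fastmath=True)
def _rate_of(i, pos, bound, bond_col, F4, occ, fluid, reactive,
             vx, vy, vz, E_loc, G_loc, h, D,
             kac, kap, kdc, kdp):
    x, y, z = pos[i, 0], pos[i, 1], pos[i, 2]
    if x < 0:
        return 0.0  # exited
    nx, ny, nz = fluid.shape
    E_i = E_loc[x, y, z]
    G_i = G_loc[x, y, z]
    F4_i = F4[i]
    total = 0.0
    if bound[i] == 1:
        inv = 0.0
        if bond_col[i] == 1 and reactive[x, y, z] == 1:
            inv += (F4_i * E_i) / (kdc * G_i)
        for d in range(6):
            tx = x + (1 if d == 0 else -1 if d == 1 else 0)
            ty = y + (1 if d == 2 else -1 if d == 3 else 0)
            tz = z + (1 if d == 4 else -1 if d == 5 else 0)
            if 0 <= tx < nx and 0 <= ty < ny and 0 <= tz < nz:
                jdx = occ[tx, ty, tz]
                if jdx >= 0 and bound[jdx] == 1:
                    g = kdp / np.sqrt(F4_i * F4[jdx] * E_i * E_loc[tx, ty, tz]) \
                        * np.sqrt(G_i * G_loc[tx, ty, tz])
                    inv += 1.0 / g
        return 1.0 / inv if inv > 0.0 else 1.0e3
    # mobile: motion + attach
    v0 = vx[x, y, z]
    v1 = vy[x, y, z]
    v2 = vz[x, y, z]
    diff = D / (h * h)
    att = 0.0
    if reactive[x, y, z] == 1:
        att += kac * F4_i * E_i
    for d in range(6):
        tx = x + (1 if d == 0 else -1 if d == 1 else 0)
        ty = y + (1 if d == 2 else -1 if d == 3 else 0)
        tz = z + (1 if d == 4 else -1 if d == 5 else 0)
        proj = v0 if d == 0 else -v0 if d == 1 else \
        	v1 if d == 2 else -v1 if d == 3 else v2 if d == 4 else -v2
        rate = (proj / h if proj > 0.0 else 0.0) + diff
        if tx >= nx:
            total += rate  # outlet exit
            continue
        if tx < 0 or ty < 0 or ty >= ny or tz < 0 or tz >= nz:
            continue
        jdx = occ[tx, ty, tz]
        if fluid[tx, ty, tz] == 0 or jdx != -1:
            if jdx >= 0 and bound[jdx] == 1:
                att += kap * np.sqrt(F4_i * F4[jdx] * E_loc[x, y, z] * E_loc[tx, ty, tz])
            continue
        total += rate
    return total + att


@njit(cache=True, fastmath=True)
def _sub_rates(i, out, pos, bound, bond_col, F4, occ, fluid, reactive,
               vx, vy, vz, E_loc, G_loc, h, D, kac, kap, kdc, kdp):
    """Fill out[0:8]: 6 motion rates, attach, detach (mirrors _rate_of)."""
    for q in range(8):
        out[q] = 0.0
    x, y, z = pos[i, 0], pos[i, 1], pos[i, 2]
    nx, ny, nz = fluid.shape
    E_i = E_loc[x, y, z]
    G_i = G_loc[x, y, z]
    F4_i = F4[i]
    if bound[i] == 1:
        inv = 0.0
        if bond_col[i] == 1 and reactive[x, y, z] == 1:
            inv += (F4_i * E_i) / (kdc * G_i)
        for d in range(6):
            tx = x + (1 if d == 0 else -1 if d == 1 else 0)
            ty = y + (1 if d == 2 else -1 if d == 3 else 0)
            tz = z + (1 if d == 4 else -1 if d == 5 else 0)
            if 0 <= tx < nx and 0 <= ty < ny and 0 <= tz < nz:
                jdx = occ[tx, ty, tz]
                if jdx >= 0 and bound[jdx] == 1:
                    g = kdp / np.sqrt(F4_i * F4[jdx] * E_i * E_loc[tx, ty, tz]) \
                        * np.sqrt(G_i * G_loc[tx, ty, tz])
                    inv += 1.0 / g
        out[7] = 1.0 / inv if inv > 0.0 else 1.0e3
        return
    v0 = vx[x, y, z]
    v1 = vy[x, y, z]
    v2 = vz[x, y, z]
    diff = D / (h * h)
    if reactive[x, y, z] == 1:
        out[6] += kac * F4_i * E_i
    for d in range(6):
        tx = x + (1 if d == 0 else -1 if d == 1 else 0)
        ty = y + (1 if d == 2 else -1 if d == 3 else 0)
        tz = z + (1 if d == 4 else -1 if d == 5 else 0)
        proj = v0 if d == 0 else -v0 if d == 1 else \
            v1 if d == 2 else -v1 if d == 3 else v2 if d == 4 else -v2
        rate = (proj / h if proj > 0.0 else 0.0) + diff
        if tx >= nx:
            out[d] = rate
            continue
        if tx < 0 or ty < 0 or ty >= ny or tz < 0 or tz >= nz:
            continue
        jdx = occ[tx, ty, tz]
        if fluid[tx, ty, tz] == 0 or jdx != -1:
            if jdx >= 0 and bound[jdx] == 1:
                out[6] += kap * np.sqrt(F4_i * F4[jdx] * E_loc[x, y, z] * E_loc[tx, ty, tz])
            continue
        out[d] = rate


@njit(cache=True, fastmath=True)
def _refresh_neighborhood(center_x, center_y, center_z, R, lam,
                          pos, bound, bond_col, F4, occ, fluid, reactive,
                          vx, vy, vz, E_loc, G_loc, h, D, kac, kap, kdc, kdp):
    nx, ny, nz = fluid.shape
    for d in range(7):
        if d == 6:
            tx, ty, tz = center_x, center_y, center_z
        else:
            tx = center_x + (1 if d == 0 else -1 if d == 1 else 0)
            ty = center_y + (1 if d == 2 else -1 if d == 3 else 0)
            tz = center_z + (1 if d == 4 else -1 if d == 5 else 0)
        if tx < 0 or tx >= nx or ty < 0 or ty >= ny or tz < 0 or tz >= nz:
            continue
        j = occ[tx, ty, tz]
        if j >= 0:
            new = _rate_of(j, pos, bound, bond_col, F4, occ, fluid, reactive,
                           vx, vy, vz, E_loc, G_loc, h, D, kac, kap, kdc, kdp)
            lam += new - R[j]
            R[j] = new
    return lam


@njit(cache=True, fastmath=True)
def _kmc_kernel(n, pos, bound, bond_col, F4, R, occ, fluid, reactive,
                vx, vy, vz, E_loc, G_loc, h, D, kac, kap, kdc, kdp,
                t_start, t_end, max_events):
    """Run the event loop from t_start toward t_end.

    Returns (code, platelet, t, n_exited, n_events):
    code 0 = reached t_end; 1 = attach selected (execute in Python);
    2 = detach selected; 3 = quiescent (no events possible);
    4 = max_events reached.
    """
    sub = np.zeros(8)
    lam = 0.0
    for i in range(n):
        lam += R[i]
    t = t_start
    n_exited = 0
    n_events = 0
    resync = 0
    nx = fluid.shape[0]
    while True:
        if lam <= 1e-12:
            return 3, -1, t_end, n_exited, n_events
        if n_events >= max_events:
            return 4, -1, t, n_exited, n_events
        u = np.random.random()
        dt = -np.log(u + 1e-300) / lam
        if t + dt > t_end:
            return 0, -1, t_end, n_exited, n_events
        t += dt
        r = np.random.random() * lam
        cum = 0.0
        sel = -1
        for i in range(n):
            cum += R[i]
            if r < cum:
                sel = i
                break
        if sel < 0:
            # float drift: resynchronize Lambda and retry
            lam = 0.0
            for i in range(n):
                lam += R[i]
            t -= dt
            continue
        _sub_rates(sel, sub, pos, bound, bond_col, F4, occ, fluid, reactive,
                   vx, vy, vz, E_loc, G_loc, h, D, kac, kap, kdc, kdp)
        tot = 0.0
        for q in range(8):
            tot += sub[q]
        r2 = np.random.random() * tot
        cum2 = 0.0
        kind = 7
        for q in range(8):
            cum2 += sub[q]
            if r2 < cum2:
                kind = q
                break
        n_events += 1
        if kind == 6:
            return 1, sel, t, n_exited, n_events
        if kind == 7:
            return 2, sel, t, n_exited, n_events
        # motion
        x, y, z = pos[sel, 0], pos[sel, 1], pos[sel, 2]
        d = kind
        tx = x + (1 if d == 0 else -1 if d == 1 else 0)
        ty = y + (1 if d == 2 else -1 if d == 3 else 0)
        tz = z + (1 if d == 4 else -1 if d == 5 else 0)
        occ[x, y, z] = -1
        if tx >= nx:
            # outlet exit: mark removed, zero rate
            pos[sel, 0] = -1
            lam -= R[sel]
            R[sel] = 0.0
            n_exited += 1
        else:
            pos[sel, 0] = tx
            pos[sel, 1] = ty
            pos[sel, 2] = tz
            occ[tx, ty, tz] = sel
            lam = _refresh_neighborhood(tx, ty, tz, R, lam,
                                        pos, bound, bond_col, F4, occ, fluid,
                                        reactive, vx, vy, vz, E_loc, G_loc,
                                        h, D, kac, kap, kdc, kdp)
        lam = _refresh_neighborhood(x, y, z, R, lam,
                                    pos, bound, bond_col, F4, occ, fluid,
                                    reactive, vx, vy, vz, E_loc, G_loc,
                                    h, D, kac, kap, kdc, kdp)
        resync += 1
        if resync >= 4096:
            lam = 0.0
            for i in range(n):
                lam += R[i]
            resync = 0


@njit(cache=True, fastmath=True)
def _refresh_all(n, R, pos, bound, bond_col, F4, occ, fluid, reactive,
                 vx, vy, vz, E_loc, G_loc, h, D, kac, kap, kdc, kdp):
    for i in range(n):
        R[i] = _rate_of(i, pos, bound, bond_col, F4, occ, fluid, reactive,
                        vx, vy, vz, E_loc, G_loc, h, D, kac, kap, kdc, kdp)


def local_shear_map(gamma: np.ndarray, fluid_mask: np.ndarray) -> np.ndarray:
    """Per-voxel local shear for the adhesion laws: the maximum shear
    magnitude over the voxel itself and its face-adjacent fluid voxels
    (surface platelets sit in zero-velocity voxels, so the relevant shear
    lives in their fluid neighbors)."""
    g = np.where(fluid_mask, gamma, 0.0)
    out = g.copy()
    for axis in range(3):
        for sgn in (-1, 1):
            shifted = np.roll(g, sgn, axis=axis)
            idx = [slice(None)] * 3
            idx[axis] = 0 if sgn == 1 else -1
            shifted[tuple(idx)] = 0.0
            out = np.maximum(out, shifted)
    return out


def advance_kmc(
    pop: Population,
    velocity: np.ndarray,
    E_loc: np.ndarray,
    G_loc: np.ndarray,
    params: adh.AdhesionParams,
    t_start: float,
    t_end: float,
    D_platelet: float = D_PLATELET_DEFAULT,
    max_events: int = 50_000_000,
) -> dict:
    """Advance the KMC clock from ``t_start`` to ``t_end``.

    Motion events run inside the kernel; attachment/detachment events are
    executed in Python (:func:`execute_event`) and the rate table is then
    rebuilt.  Returns event statistics.
    """
    dom = pop.domain
    stats = {"moves": 0, "attach": 0, "detach": 0, "exited": 0}
    fluid = dom.fluid_mask.astype(np.uint8)
    reactive = dom.reactive_mask.astype(np.uint8)
    vx = np.ascontiguousarray(velocity[..., 0])
    vy = np.ascontiguousarray(velocity[..., 1])
    vz = np.ascontiguousarray(velocity[..., 2])
    t = t_start
    while True:
        n = pop.n
        if n == 0:
            break
        R = np.zeros(n)
        args = (pop.pos, pop.bound, pop.bond_col, pop.F4, pop.occ, fluid,
                reactive, vx, vy, vz, E_loc, G_loc, dom.h, D_platelet,
                params.k_att_collagen, params.k_att_platelet,
                params.k_det_collagen, params.k_det_platelet)
        _refresh_all(n, R, *args)
        code, sel, t, n_ex, n_ev = _kmc_kernel(
            n, *args[:4], R, *args[4:], t, t_end, max_events
        )
        stats["moves"] += n_ev
        stats["exited"] += n_ex
        pop.n_exited += n_ex
        if code in (0, 3):
            break
        if code == 4:
            raise RuntimeError("KMC event budget exhausted within one macro step")
        if code == 1:
            execute_event(pop, (sel, "attach", -1))
            stats["attach"] += 1
            stats["moves"] -= 1
        elif code == 2:
            execute_event(pop, (sel, "detach", -1))
            stats["detach"] += 1
            stats["moves"] -= 1
    pop.compact_exited()
    return stats
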