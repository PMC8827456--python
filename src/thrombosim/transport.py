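"""Soluble agonist transport: ADP and TXA2 convection-diffusion-release.

Explicit finite-volume solver on the shared lattice: first-order upwind
convection with the local flow velocity and central diffusion, advanced
with conservative face fluxes (global mass balance holds to round-off for
closed boundaries).  Transport takes place in the lumen (``fluid_mask``);
bound platelets have zero velocity, so the clot interior exchanges species
by diffusion only.  Walls are zero-flux, the inlet carries agonist-free
blood (C = 0 inflow, no diffusive flux), and the outlet is advective
outflow with zero diffusive flux.

Released amounts are tracked in units of nM um^3 (1 nM um^3 = 1e-24 mol);
concentrations are nM.  A platelet whose cumulative activation has crossed
``xi_crit`` at time ``t_release`` releases species ``j`` at the
exponentially decaying rate

    R_j(t) = (M_j / tau_j) exp((t_release - t) / tau_j),

whose integral is exactly the releasable load ``M_j``; mobile activated
platelets release too (moving sources).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from thrombosim.geometry import LatticeDomain

SPECIES = ("ADP", "TXA2")

__all__ = [
    "SPECIES",
    "TransportParams",
    "ConcentrationField",
    "release_rate",
    "advance",
    "sample_agonists",
]


@dataclass
class TransportParams:
    """Diffusivities, per-platelet releasable loads, and reporting EC50s.

    Defaults: D_ADP = 2.4e-6 cm^2/s, D_TXA2 = 2.1e-6 cm^2/s; releasable
    ADP ~ 2.4e-17 mol/platelet over a ~5 s dense-granule release; TXA2 is
    synthesized de novo (smaller load, slower); EC50s ~ 1 uM (ADP, P2Y
    receptors) and ~ 0.1 uM (TXA2/TP).  See docs/methods.md.
    """

    D: dict = field(default_factory=lambda: {"ADP": 240.0, "TXA2": 210.0})  # um^2/s
    M: dict = field(default_factory=lambda: {"ADP": 2.4e7, "TXA2": 4.0e6})  # nM um^3
    tau: dict = field(default_factory=lambda: {"ADP": 5.0, "TXA2": 10.0})  # s
    EC50: dict = field(default_factory=lambda: {"ADP": 1000.0, "TXA2": 100.0})  # nM
    dt_fvm: float = 0.5  # s, outer transport step (sub-stepped for stability)
    cfl_safety: float = 0.9

    def __post_init__(self) -> None:
        for j in SPECIES:
            if self.D[j] <= 0 or self.tau[j] <= 0:
                raise ValueError("diffusivities and release time constants must be > 0")
            if self.M[j] < 0:
                raise ValueError("releasable amounts must be >= 0")
        if self.dt_fvm <= 0:
            raise ValueError("dt_fvm must be > 0")


@dataclass
class ConcentrationField:
    """Per-species concentration fields (nM) at simulation time ``t``."""

    C: dict  # {"ADP": (nx,ny,nz), "TXA2": (nx,ny,nz)}
    t: float = 0.0

    @classmethod
    def zeros(cls, domain: LatticeDomain) -> "ConcentrationField":
        return cls(C={j: np.zeros(domain.shape) for j in SPECIES}, t=0.0)

    def total_amount(self, domain: LatticeDomain, species: str) -> float:
        """Total dissolved amount of ``species`` in nM um^3."""
        return float(self.C[species].sum()) * domain.h**3


def release_rate(t_release, t: float, species: str, params: TransportParams):
    """Per-platelet release rate (nM um^3 / s) at time ``t``.

    ``t_release`` may be None/NaN (not yet triggered) or an array of
    trigger times; the rate is zero before the trigger.
    """
    M = params.M[species]
    tau = params.tau[species]
    if t_release is None:
        return 0.0
    tr = np.asarray(t_release, dtype=float)
    with np.errstate(invalid="ignore", over="ignore"):
        rate = np.where(
            np.isnan(tr) | (t < tr), 0.0, M / tau * np.exp(np.minimum((tr - t) / tau, 0.0))
        )
    return float(rate) if rate.ndim == 0 else rate


@njit(cache=True, fastmath=True)
def _fvm_substep(C, Cnew, u, medium, h, D, dt):
    """One conservative upwind/central substep; returns outlet flux (nM um^3/s)."""
    nx, ny, nz = C.shape
    out_flux = 0.0
    inv_h = 1.0 / h
    inv_h2 = 1.0 / (h * h)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not medium[i, j, k]:
                    Cnew[i, j, k] = 0.0
                    continue
                c0 = C[i, j, k]
                dc = 0.0
                for axis in range(3):
                    for sgn in (-1, 1):
                        ni, nj, nk = i, j, k
                        if axis == 0:
                            ni += sgn
                        elif axis == 1:
                            nj += sgn
                        else:
                            nk += sgn
                        if ni < 0:
                            # inlet face: agonist-free inflow, no diffusion
                            continue
                        if ni >= nx:
                            # outlet face: advective outflow only
                            uf = u[i, j, k, 0]
                            if uf > 0.0:
                                dc -= uf * c0 * inv_h
                                out_flux += uf * c0 * h * h
                            continue
                        if nj < 0 or nj >= ny or nk < 0 or nk >= nz:
                            continue  # transverse box boundary = wall
                        if not medium[ni, nj, nk]:
                            continue  # wall: zero flux
                        cn = C[ni, nj, nk]
                        uf = 0.5 * (u[i, j, k, axis] + u[ni, nj, nk, axis]) * sgn
                        # uf > 0 means outflow from this cell across the face
                        if uf > 0.0:
                            dc -= uf * c0 * inv_h
                        else:
                            dc -= uf * cn * inv_h
                        dc += D * (cn - c0) * inv_h2
                Cnew[i, j, k] = c0 + dt * dc
    return out_flux


def advance(
    fields: ConcentrationField,
    flow,
    sources: dict,
    dt: float,
    params: TransportParams,
    domain: LatticeDomain,
):
    """Advance all species by ``dt`` (sub-stepped to the stability bound).

    ``sources`` maps species to per-voxel volumetric source terms in nM/s
    (already divided by the voxel volume), held constant over the step.
    Returns ``(fields, diagnostics)`` where diagnostics holds the
    time-integrated outlet flux and source input per species (nM um^3).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    h = domain.h
    medium = domain.fluid_mask
    u = flow.velocity
    umax_ax = np.abs(u[medium]).max(axis=0, initial=0.0)  # per-axis maxima
    diag = {}
    for j in SPECIES:
        D = params.D[j]
        denom = float(umax_ax.sum()) / h + 6.0 * D / (h * h)
        dt_stable = params.cfl_safety / denom if denom > 0 else dt
        n_sub = max(1, int(np.ceil(dt / dt_stable)))
        if n_sub > 100000:
            raise RuntimeError(
                f"transport stability sub-stepping exploded (n_sub={n_sub}); "
                f"umax={umax_ax.max():.3g} um/s, h={h} um"
            )
        dt_sub = dt / n_sub
        C = fields.C[j]
        src = sources.get(j)
        if (src is None or not src.any()) and not C.any():
            # nothing dissolved and no sources: the field stays zero
            diag[j] = {"outlet_flux": 0.0, "source_input": 0.0}
            continue
        Cnew = np.empty_like(C)
        out_total = 0.0
        for _ in range(n_sub):
            out = _fvm_substep(C, Cnew, u, medium, h, D, dt_sub)
            if src is not None:
                Cnew += src * dt_sub
            np.maximum(Cnew, 0.0, out=Cnew)
            C, Cnew = Cnew, C
            out_total += out * dt_sub
        fields.C[j] = C
        src_total = float(src.sum()) * h**3 * dt if src is not None else 0.0
        diag[j] = {"outlet_flux": out_total, "source_input": src_total}
    fields.t += dt
    return fields, diag


def sample_agonists(fields: ConcentrationField, voxel, params: TransportParams, domain: LatticeDomain):
    """Concentrations at a voxel in nM and in EC50 units.

    Rejects wall voxels (agonists are defined in the lumen only).
    """
    voxel = tuple(voxel)
    if not domain.fluid_mask[voxel]:
        raise ValueError(f"voxel {voxel} is a wall voxel")
    out = {}
    for j in SPECIES:
        c = float(fields.C[j][voxel])
        out[j] = c
        out[j + "_ec50"] = c / params.EC50[j]
    return out
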