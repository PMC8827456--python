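"""Coupled multiscale simulation loop, metrics, and scenario presets.

One macro step (default 0.5 s, the signaling step) advances, in order:

1. inlet injection and the KMC event loop (platelet motion/bonding),
2. per-platelet calcium and activation integrals from the local agonist
   exposure (ADP/TXA2 fields, collagen contact, film thrombin),
3. agonist transport with the current release sources,
4. the thin-film coagulation ODEs (when TF is present),
5. a flow re-solve whenever the bound-platelet set changed by more than
   ``flow_resolve_voxels`` voxels or ``flow_resolve_interval`` elapsed,
   refreshing the shear map and adhesion-rate factors,
6. metric recording; termination at ``t_end`` or at occlusion (inlet
   flow below 5% of its initial value, pressure-drop runs).

Runs are deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

from thrombosim import adhesion as adh
from thrombosim import coagulation as coag
from thrombosim import flow as flowmod
from thrombosim import geometry as geom
from thrombosim import lkmc
from thrombosim import signaling as sig
from thrombosim import transport as tra

logger = logging.getLogger(__name__)

__all__ = [
    "ScheduleParams",
    "LKMCParams",
    "SimulationConfig",
    "SimulationResult",
    "run",
    "clot_height_profile",
    "occlusion_time",
    "scenario_presets",
    "pressure_drop_for_shear",
]

TREATMENTS = ("control", "no_TXA2", "no_ADP", "iloprost", "no_TF")


@dataclass
class ScheduleParams:
    t_end: float = 120.0  # s
    signaling_step: float = 0.5  # s (macro step)
    flow_resolve_voxels: int = 20  # bound-voxel change triggering a re-solve
    flow_resolve_interval: float = 1.0  # s, max interval between re-solves
    output_interval: float = 5.0  # s


@dataclass
class LKMCParams:
    D_platelet: float = lkmc.D_PLATELET_DEFAULT  # um^2/s
    mean_concentration: float = 2.0e4  # tracked platelets per uL (desk scale)
    wall_excess: float = 3.0  # margination factor near the wall
    margination_layer: float = 5.0  # um


@dataclass
class SimulationConfig:
    """Complete run configuration (all blocks have sensible defaults)."""

    geometry: dict = field(default_factory=lambda: {"kind": "channel"})
    flow: flowmod.FlowParams = field(default_factory=flowmod.FlowParams)
    transport: tra.TransportParams = field(default_factory=tra.TransportParams)
    activation: sig.ActivationParams = field(default_factory=sig.ActivationParams)
    calcium: sig.CalciumModelParams = field(default_factory=sig.CalciumModelParams)
    coagulation: coag.CoagParams = field(default_factory=coag.CoagParams)
    adhesion: adh.AdhesionParams = field(default_factory=adh.AdhesionParams)
    lkmc: LKMCParams = field(default_factory=LKMCParams)
    schedule: ScheduleParams = field(default_factory=ScheduleParams)
    treatment: str = "control"
    seed: int = 0
    calcium_model: object = None  # plug-in CalciumModel; default surrogate if None
    # for pressure-drop runs: derive the pressure drop from this initial
    # inlet wall shear rate via a platelet-free velocity-inlet solve
    pressure_from_shear: float | None = None
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}")
        if self.schedule.t_end < 0:
            raise ValueError("t_end must be >= 0")

    def build_domain(self) -> geom.LatticeDomain:
        kw = dict(self.geometry)
        kind = kw.pop("kind")
        if self.treatment == "no_TF":
            kw["tf_on"] = False
        builder = {
            "channel": geom.build_channel,
            "tube": geom.build_tube,
            "stenosis": geom.build_stenosis,
        }[kind]
        return builder(**kw)

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                out[f.name] = dataclasses.asdict(v)
            elif f.name == "calcium_model":
                out[f.name] = None if v is None else type(v).__name__
            else:
                out[f.name] = v
        return out


@dataclass
class SimulationResult:
    """Metric time series and final state of a run."""

    times: np.ndarray
    platelet_count: np.ndarray  # bound platelets vs time
    Q: np.ndarray  # uL/min vs time
    thrombin: np.ndarray  # film free thrombin (nM) vs time
    mobile_count: np.ndarray
    injected: np.ndarray  # cumulative
    exited: np.ndarray  # cumulative
    discarded: np.ndarray  # cumulative
    occlusion_time: float | None
    Q0: float
    final_snapshot: list
    bound_mask: np.ndarray
    mean_xi_collagen_thrombin: float
    mean_xi_soluble_only: float
    domain: geom.LatticeDomain
    config: SimulationConfig
    coag_state: coag.CoagState | None
    fields: tra.ConcentrationField | None = None


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def clot_height_profile(bound_mask: np.ndarray, domain: geom.LatticeDomain,
                        band_width: float | None = None) -> np.ndarray:
    """Average aggregate height (um) vs axial station.

    For each axial station, spanwise lines (fixed ``j``) within the
    central band of width ``band_width`` that contain bound platelets
    contribute the height of their topmost bound voxel; the profile is
    the mean over contributing lines (0 where nothing is deposited) —
    the numerical analogue of averaged fluorescence line scans drawn
    along the flow direction.
    """
    nx, ny, nz = domain.shape
    h = domain.h
    if band_width is None:
        j_sel = np.arange(ny)
    else:
        c = ny / 2.0
        half = band_width / (2.0 * h)
        j_sel = np.arange(max(0, int(np.floor(c - half))), min(ny, int(np.ceil(c + half))))
    profile = np.zeros(nx)
    sub = bound_mask[:, j_sel, :]
    any_line = sub.any(axis=2)  # (nx, nj)
    top = (sub * (np.arange(nz)[None, None, :] + 1)).max(axis=2) * h  # heights
    with np.errstate(invalid="ignore"):
        sums = top.sum(axis=1)
        counts = any_line.sum(axis=1)
        profile = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return profile


def occlusion_time(result: SimulationResult, threshold: float = 0.05) -> float | None:
    """First time Q(t) drops strictly below ``threshold * Q0``, linearly
    interpolated between recorded samples; None if never crossed."""
    Q0 = result.Q0
    if Q0 <= 0:
        return None
    target = threshold * Q0
    t = result.times
    Q = result.Q
    below = Q < target
    if not below.any():
        return None
    k = int(np.argmax(below))
    if k == 0:
        return float(t[0])
    t0, t1 = t[k - 1], t[k]
    q0, q1 = Q[k - 1], Q[k]
    if q0 == q1:
        return float(t1)
    return float(t0 + (q0 - target) / (q0 - q1) * (t1 - t0))


def pressure_drop_for_shear(domain: geom.LatticeDomain, params: flowmod.FlowParams,
                            wall_shear: float) -> tuple[float, float]:
    """Pressure drop (Pa) across the platelet-free domain that realizes the
    given inlet wall shear rate, plus the matching flow rate Q0 (uL/min).
    Obtained from a velocity-inlet solve of the clean geometry."""
    p = dataclasses.replace(params, bc_kind="constant_shear_inlet",
                            inlet_wall_shear=wall_shear, pressure_drop=None)
    f = flowmod.solve_flow(domain, None, p)
    inlet_p = f.pressure[0][domain.fluid_mask[0]].mean()
    outlet_p = f.pressure[-1][domain.fluid_mask[-1]].mean()
    return float(inlet_p - outlet_p), f.Q


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------


def run(config: SimulationConfig) -> SimulationResult:
    """Execute a coupled simulation; see module docstring for the loop."""
    rng = np.random.default_rng(config.seed)
    lkmc.seed_kernel_rng(config.seed + 7919)

    domain = config.build_domain()
    sched = config.schedule
    dt = sched.signaling_step
    n_window = max(1, int(round(config.activation.dt_window / dt)))

    flow_params = config.flow
    if config.pressure_from_shear is not None:
        dp, _ = pressure_drop_for_shear(domain, flow_params, config.pressure_from_shear)
        flow_params = dataclasses.replace(
            flow_params, bc_kind="constant_pressure_drop", pressure_drop=dp,
            inlet_wall_shear=config.pressure_from_shear,
        )

    alpha0 = sig.hill_F(0.0, config.activation)
    pop = lkmc.Population(domain, n_window=n_window, F4_init=alpha0 * alpha0)
    fields = tra.ConcentrationField.zeros(domain)
    model = config.calcium_model or sig.default_calcium_model(config.calcium)
    coag_state = coag.CoagState.initial(config.coagulation) if domain.tf_on else None

    # initial (platelet-free) flow solve
    flow = flowmod.solve_flow(domain, None, flow_params)
    if not flow.converged:
        logger.warning("initial flow solve not converged (residual %.2e)", flow.residual)
    Q0 = flow.Q
    shear = flowmod.shear_magnitude(flow, domain)
    gamma_loc = lkmc.local_shear_map(shear.gamma, domain.fluid_mask)
    E_loc = adh.shear_enhancement_E(gamma_loc, config.adhesion)
    G_loc = adh.breakage_G(gamma_loc, config.adhesion)

    times, n_bound_s, Q_s, thr_s, mob_s = [], [], [], [], []
    inj_s, exi_s, dis_s = [], [], []
    injected_total = 0
    last_solve_t = 0.0
    last_bound_set_size = 0
    occl_t = None
    t = 0.0
    next_output = 0.0
    n_steps = int(round(sched.t_end / dt)) if sched.t_end > 0 else 0

    def record():
        times.append(t)
        n_bound_s.append(pop.n_bound)
        Q_s.append(flow.Q)
        thr_s.append(coag_state.thrombin if coag_state is not None else 0.0)
        mob_s.append(pop.n_mobile)
        inj_s.append(injected_total)
        exi_s.append(pop.n_exited)
        dis_s.append(pop.n_discarded)

    record()
    next_output += sched.output_interval

    for step in range(n_steps):
        # (1) injection + KMC
        injected_total += lkmc.inject_inlet(
            pop, flow, config.lkmc.mean_concentration, dt, rng,
            wall_excess=config.lkmc.wall_excess,
            margination_layer=config.lkmc.margination_layer, t=t,
        )
        lkmc.advance_kmc(
            pop, flow.velocity, E_loc, G_loc, config.adhesion,
            t, t + dt, D_platelet=config.lkmc.D_platelet,
        )
        t += dt

        # (2) signaling
        n = pop.n
        if n > 0:
            p = pop.pos[:n]
            vox = (p[:, 0], p[:, 1], p[:, 2])
            adp = fields.C["ADP"][vox]
            txa = fields.C["TXA2"][vox]
            if config.treatment == "no_ADP":
                adp = np.zeros_like(adp)
            if config.treatment == "no_TXA2":
                txa = np.zeros_like(txa)
            thr = np.zeros(n)
            if coag_state is not None:
                thr = np.where(domain.film_mask[vox], coag_state.thrombin, 0.0)
            exposure = {
                "collagen": (pop.bond_col[:n] * pop.bound[:n]).astype(float),
                "ADP": adp,
                "TXA2": txa,
                "thrombin": thr,
                "iloprost": np.inf if config.treatment == "iloprost" else 0.0,
            }
            prev_ca = pop.ca[:n].copy()
            ca_new, aux_new = model.step(prev_ca, pop.aux[:n], exposure, dt)
            pop.ca[:n] = ca_new
            pop.aux[:n] = aux_new
            ring_pos = step % pop.n_window
            xi, xi_dt = sig.accumulate_xi(
                pop.xi[:n], pop.ring[:n], ring_pos, prev_ca, ca_new, dt
            )
            pop.xi[:n] = xi
            pop.xi_dt[:n] = xi_dt
            newly = (~pop.released[:n]) & (xi > config.activation.xi_crit)
            pop.released[:n] |= newly
            pop.t_release[:n][newly] = t
            pop.F4[:n] = sig.hill_F(xi, config.activation) * sig.hill_F(
                xi_dt, config.activation
            )

        # (3) transport with release sources
        sources = {}
        if n > 0 and pop.released[:n].any():
            inv_vol = 1.0 / domain.h**3
            for j in tra.SPECIES:
                rates = tra.release_rate(pop.t_release[:n], t - dt / 2.0, j,
                                         config.transport)
                src = np.zeros(domain.shape)
                np.add.at(src, vox, rates * inv_vol)
                sources[j] = src
        fields, _ = tra.advance(fields, flow, sources, dt, config.transport, domain)

        # (4) coagulation
        if coag_state is not None:
            coag_state = coag.advance_coag(coag_state, config.coagulation, dt)

        # (5) flow re-solve on trigger
        bound_now = pop.n_bound
        if (
            abs(bound_now - last_bound_set_size) >= sched.flow_resolve_voxels
            or t - last_solve_t >= sched.flow_resolve_interval - 1e-9
        ):
            flow = flowmod.solve_flow(domain, pop.bound_mask_grid(), flow_params,
                                      warm_start=flow)
            shear = flowmod.shear_magnitude(flow, domain)
            gamma_loc = lkmc.local_shear_map(
                shear.gamma, domain.fluid_mask & ~pop.bound_mask_grid()
            )
            E_loc = adh.shear_enhancement_E(gamma_loc, config.adhesion)
            G_loc = adh.breakage_G(gamma_loc, config.adhesion)
            last_solve_t = t
            last_bound_set_size = bound_now

        # (6) metrics / termination
        if t >= next_output - 1e-9:
            record()
            next_output += sched.output_interval
            logger.info(
                "t=%6.1f s  bound=%5d  mobile=%4d  Q=%.3g uL/min  thrombin=%.3g nM",
                t, pop.n_bound, pop.n_mobile, flow.Q,
                coag_state.thrombin if coag_state is not None else 0.0,
            )
        if (
            flow_params.bc_kind == "constant_pressure_drop"
            and Q0 > 0
            and flowmod.is_occluded(flow.Q, Q0)
        ):
            record()
            break

    if times[-1] < t:
        record()

    n = pop.n
    mask_ct = np.zeros(n, dtype=bool)
    if n > 0:
        p = pop.pos[:n]
        vox = (p[:, 0], p[:, 1], p[:, 2])
        in_film = domain.film_mask[vox] if domain.tf_on else np.zeros(n, dtype=bool)
        mask_ct = (pop.bond_col[:n] > 0) | in_film
    xi_all = pop.xi[:n]
    mean_ct = float(xi_all[mask_ct].mean()) if mask_ct.any() else np.nan
    mean_sol = float(xi_all[~mask_ct].mean()) if (~mask_ct).any() else np.nan

    result = SimulationResult(
        times=np.array(times),
        platelet_count=np.array(n_bound_s),
        Q=np.array(Q_s),
        thrombin=np.array(thr_s),
        mobile_count=np.array(mob_s),
        injected=np.array(inj_s),
        exited=np.array(exi_s),
        discarded=np.array(dis_s),
        occlusion_time=None,
        Q0=Q0,
        final_snapshot=pop.snapshot(),
        bound_mask=pop.bound_mask_grid(),
        mean_xi_collagen_thrombin=mean_ct,
        mean_xi_soluble_only=mean_sol,
        domain=domain,
        config=config,
        coag_state=coag_state,
        fields=fields,
    )
    if flow_params.bc_kind == "constant_pressure_drop":
        result.occlusion_time = occlusion_time(result)
    return result


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def scenario_presets(full_scale: bool = False) -> dict:
    """Named run configurations for the standard scenarios.

    ``channel_200``: 500x250x60 um microfluidic channel, 250 um collagen/TF
    patch, constant inlet wall shear 200 1/s.  ``tube_100``: 500x60 um
    vessel, semicylindrical injury, 100 1/s.  ``stenosis_{37,50,63,75}``:
    500x60 um vessel, cosine stenosis over the central 250 um with the
    given % lumen-area reduction, constant pressure drop matching an
    initial inlet wall shear of 1000 1/s.  Desk-scale defaults use a
    coarser channel lattice and shorter horizons; ``full_scale`` restores
    lattice spacing 2.5 um and the 400-500 s horizons.
    """
    presets = {}
    h_chan = 2.5 if full_scale else 5.0
    t_chan = 400.0 if full_scale else 120.0
    # coupled-run solver settings: warm-started quasi-steady re-solves need
    # far less precision than the one-off oracle solves
    run_flow = dict(convergence_tol=3.0e-4, check_every=50)
    run_sched = dict(flow_resolve_interval=3.0, flow_resolve_voxels=30,
                     output_interval=10.0)
    presets["channel_200"] = SimulationConfig(
        name="channel_200",
        geometry={"kind": "channel", "length": 500.0, "width": 250.0, "height": 60.0,
                  "patch_start": 125.0, "patch_length": 250.0, "h": h_chan,
                  "tf_on": True},
        flow=flowmod.FlowParams(bc_kind="constant_shear_inlet",
                                inlet_wall_shear=200.0, **run_flow),
        schedule=ScheduleParams(t_end=t_chan, **run_sched),
    )
    presets["tube_100"] = SimulationConfig(
        name="tube_100",
        geometry={"kind": "tube", "length": 500.0, "diameter": 60.0,
                  "patch_arc_fraction": 0.5, "patch_length": 250.0, "h": 2.5,
                  "tf_on": True},
        flow=flowmod.FlowParams(bc_kind="constant_shear_inlet",
                                inlet_wall_shear=100.0, **run_flow),
        schedule=ScheduleParams(t_end=400.0 if full_scale else 120.0, **run_sched),
    )
    for pct in (37, 50, 63, 75):
        presets[f"stenosis_{pct}"] = SimulationConfig(
            name=f"stenosis_{pct}",
            geometry={"kind": "stenosis", "length": 500.0, "inlet_diameter": 60.0,
                      "stenosis_length": 250.0, "area_reduction": pct / 100.0,
                      "collagen_arc_fraction": 0.5, "h": 2.5, "tf_on": False},
            flow=flowmod.FlowParams(bc_kind="constant_pressure_drop",
                                    pressure_drop=1.0, **run_flow),
            pressure_from_shear=1000.0,
            schedule=ScheduleParams(t_end=500.0 if full_scale else 300.0,
                                    **run_sched),
        )
    return presets


def get_preset(name: str, full_scale: bool = False, **overrides) -> SimulationConfig:
    presets = scenario_presets(full_scale)
    if name not in presets:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: {sorted(presets)}"
        )
    cfg = presets[name]
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise AttributeError(f"no config field {k!r}")
        setattr(cfg, k, v)
    return cfg
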