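"""Thin-film reduced coagulation cascade (8 ODEs).

Tissue-factor-driven thrombin production is modeled inside the ~15 um
fibrin-rich film over the reactive patch, treated as a spatially
well-mixed zone whose zymogen supply is held at flowing-plasma levels.
The network lumps the cascade into six reactions:

1. extrinsic tenase / FIXase generation on the TF surface,
2. intrinsic tenase assembly (fed by extrinsic tenase and FXIa),
3. prothrombinase assembly (fed by both tenases),
4. thrombin-feedback activation of FXIa,
5. fibrin generation from fibrinogen by thrombin,
6. thrombin binding to fibrin (sequestration).

Each reaction rate is scaled by a dimensionless *effectiveness factor*
(actual rate / transport-unlimited rate, in (0, 1]).  Transport out of the
film is parameterized by a single first-order elution of the soluble
enzymes (free thrombin, FXIa) with a 2-second half-life.  Thrombin is not
tracked outside the film: platelets sample it only within ``film_mask``.

The published reduced model's rate constants live in an unavailable
supplement, so the constants here are literature-guided defaults owned by
the configuration; the module fixes the network topology and the
integration contract (see docs/methods.md for provenance and
calibration).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = ["CoagParams", "CoagState", "advance_coag", "film_thrombin", "simulate_coag"]

_LN2 = float(np.log(2.0))


@dataclass
class CoagParams:
    """Kinetics of the reduced cascade.  Concentrations nM, times s.

    ``tf_surface_density`` is the dimensionless TF coating level (0 = no
    TF, 1 = the default coated patch); it scales extrinsic initiation.
    """

    # 1. extrinsic tenase generation / inactivation
    k_ext_gen: float = 0.02  # nM/s at unit TF density
    k_ext_inact: float = 0.01  # 1/s
    # 2. intrinsic tenase from extrinsic tenase (FIXa path) and FXIa
    k_int_from_ext: float = 0.01  # 1/s
    k_int_from_xia: float = 1.0  # 1/s
    k_int_inact: float = 0.01  # 1/s
    int_max: float = 30.0  # nM, membrane-site cap on complex assembly
    # 3. prothrombinase from FXa made by either tenase (MM in factor X)
    k_pro_from_ext: float = 0.05  # 1/s
    k_pro_from_int: float = 0.2  # 1/s
    km_x: float = 160.0  # nM
    k_pro_inact: float = 0.01  # 1/s
    pro_max: float = 30.0  # nM
    # 4. FXIa feedback by thrombin (MM in factor XI)
    kcat_xia: float = 1.0e-3  # 1/s
    km_xi: float = 30.0  # nM
    k_xia_inact: float = 1.0e-3  # 1/s
    # 5. thrombin generation (MM in prothrombin) and fibrin generation
    kcat_iia: float = 1.5  # 1/s
    km_ii: float = 1000.0  # nM
    kcat_fib: float = 0.5  # 1/s
    km_fg: float = 3000.0  # nM
    # 6. thrombin-fibrin binding
    k_fib_bind: float = 1.0e-4  # 1/(nM s)
    # effectiveness factors (actual/ideal rate), one per lumped reaction
    eff: dict = field(default_factory=lambda: {
        "ext_tenase": 1.0, "int_tenase": 1.0, "prothrombinase": 1.0,
        "fxia": 1.0, "fibrin": 1.0, "binding": 1.0,
    })
    # transport out of the film
    elution_half_life: float = 2.0  # s, soluble-enzyme washout
    # plasma zymogen levels held constant (film refreshed by flow)
    xi_zymogen: float = 30.0  # nM factor XI
    x_zymogen: float = 170.0  # nM factor X
    ii_zymogen: float = 1400.0  # nM prothrombin
    fg_zymogen: float = 9000.0  # nM fibrinogen
    tf_surface_density: float = 1.0

    def __post_init__(self) -> None:
        for name, v in self.eff.items():
            if not 0 < v <= 1:
                raise ValueError(f"effectiveness factor {name} must lie in (0, 1]")
        if self.elution_half_life <= 0:
            raise ValueError("elution_half_life must be > 0")
        if self.tf_surface_density < 0:
            raise ValueError("tf_surface_density must be >= 0")

    @property
    def k_elu(self) -> float:
        return _LN2 / self.elution_half_life


@dataclass
class CoagState:
    """State of the thin-film ODE system (all nM)."""

    ext_tenase: float = 0.0
    int_tenase: float = 0.0
    prothrombinase: float = 0.0
    fxia: float = 0.0
    thrombin: float = 0.0  # free (eluting) thrombin
    fibrinogen: float = 9000.0
    fibrin: float = 0.0
    thrombin_bound: float = 0.0  # fibrin-sequestered thrombin
    t: float = 0.0

    _FIELDS = (
        "ext_tenase", "int_tenase", "prothrombinase", "fxia",
        "thrombin", "fibrinogen", "fibrin", "thrombin_bound",
    )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self._FIELDS], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray, t: float) -> "CoagState":
        vals = {f: max(float(v), 0.0) for f, v in zip(cls._FIELDS, y)}
        return cls(t=t, **vals)

    @classmethod
    def initial(cls, params: CoagParams) -> "CoagState":
        return cls(fibrinogen=params.fg_zymogen)


def _rhs(t: float, y: np.ndarray, p: CoagParams) -> np.ndarray:
    ext, intt, pro, xia, thr, fg, fn, thrb = np.maximum(y, 0.0)
    e = p.eff
    k_elu = p.k_elu
    x_sat = p.x_zymogen / (p.km_x + p.x_zymogen)
    d_ext = e["ext_tenase"] * p.k_ext_gen * p.tf_surface_density - p.k_ext_inact * ext
    d_int = (
        e["int_tenase"] * (p.k_int_from_ext * ext + p.k_int_from_xia * xia)
        * max(1.0 - intt / p.int_max, 0.0)
        - p.k_int_inact * intt
    )
    d_pro = (
        e["prothrombinase"] * (p.k_pro_from_ext * ext + p.k_pro_from_int * intt)
        * x_sat * max(1.0 - pro / p.pro_max, 0.0)
        - p.k_pro_inact * pro
    )
    d_xia = (
        e["fxia"] * p.kcat_xia * thr * p.xi_zymogen / (p.km_xi + p.xi_zymogen)
        - (p.k_xia_inact + k_elu) * xia
    )
    gen_thr = e["prothrombinase"] * p.kcat_iia * pro * p.ii_zymogen / (p.km_ii + p.ii_zymogen)
    bind = e["binding"] * p.k_fib_bind * thr * fn
    d_thr = gen_thr - k_elu * thr - bind
    gen_fib = e["fibrin"] * p.kcat_fib * thr * fg / (p.km_fg + fg)
    d_fg = -gen_fib
    d_fn = gen_fib
    d_thrb = bind
    return np.array([d_ext, d_int, d_pro, d_xia, d_thr, d_fg, d_fn, d_thrb])


def advance_coag(state: CoagState, params: CoagParams, dt: float) -> CoagState:
    """Integrate the film ODEs over ``dt`` (stiff-safe LSODA).

    Raises ``RuntimeError`` with a state dump if the integrator fails.
    Concentrations are clipped at zero (solver tolerance round-off only).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    sol = solve_ivp(
        _rhs, (state.t, state.t + dt), state.as_array(), args=(params,),
        method="LSODA", rtol=1e-8, atol=1e-10,
    )
    if not sol.success:
        raise RuntimeError(
            f"coagulation ODE integration failed at t={state.t}: {sol.message}; "
            f"state={state}"
        )
    return CoagState.from_array(sol.y[:, -1], state.t + dt)


def simulate_coag(params: CoagParams, t_end: float, dt: float = 1.0):
    """Time series of the film state from rest; returns (times, states)."""
    state = CoagState.initial(params)
    times = [0.0]
    states = [state]
    while state.t < t_end - 1e-9:
        state = advance_coag(state, params, min(dt, t_end - state.t))
        times.append(state.t)
        states.append(state)
    return np.array(times), states


def film_thrombin(state: CoagState, domain, voxel) -> float:
    """Free thrombin seen by a platelet at ``voxel``: the film concentration
    inside ``film_mask`` (TF present), zero everywhere else."""
    if not domain.tf_on:
        return 0.0
    if domain.film_mask[tuple(voxel)]:
        return float(state.thrombin)
    return 0.0
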