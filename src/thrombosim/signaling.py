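"""Per-platelet signaling: calcium dynamics, activation integrals, Hill F.

Each platelet carries a calcium trace sampled at a fixed signaling step.
Its *activation state* is the running time-integral of calcium above the
basal level (100 nM),

    xi(t)      = integral_0^t max([Ca](t') - 100 nM, 0) dt'      (nM s)
    xi_dt(t)   = the same integral over the trailing window Dt,

and the extent of inside-out integrin activation is the Hill-normalized

    F(theta) = alpha_min + (alpha_max - alpha_min) theta^n / (theta^n + theta50^n)

applied identically to theta = xi and theta = xi_dt.  Once xi exceeds the
critical threshold ``xi_crit`` the platelet (irreversibly) starts releasing
ADP and TXA2 (see :mod:`thrombosim.transport`), whether bound or mobile.

The calcium model itself is pluggable: any object with a
``step(ca, aux, exposure, dt) -> (ca, aux)`` method mapping the current
agonist exposure (collagen contact flag, ADP, TXA2, thrombin, GSNO,
iloprost) to the next calcium concentration qualifies.  The shipped
:class:`DefaultCalciumModel` is a phenomenological ODE surrogate for a
patient-trained neural-network model (which is not reproducible here);
it is calibrated to the qualitative behaviours the simulation relies on:
a basal fixed point at 100 nM, sustained ("fast-on, slow-off") responses
to collagen and thrombin, faster-desensitizing responses to ADP/TXA2,
and saturating inhibition by iloprost (IP receptor) and GSNO.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CA_BASAL = 100.0  # nM
N_AUX = 3  # (sustained-drive s, ADP desensitization, TXA2 desensitization)

AGONIST_KEYS = ("collagen", "ADP", "TXA2", "thrombin", "GSNO", "iloprost")

__all__ = [
    "CA_BASAL",
    "ActivationParams",
    "PlateletSignalState",
    "CalciumModelParams",
    "DefaultCalciumModel",
    "default_calcium_model",
    "hill_F",
    "update_activation",
    "accumulate_xi",
]


@dataclass
class ActivationParams:
    """Activation-integral and Hill-normalization parameters.

    Defaults are calibrated (see docs/methods.md) so that a platelet held
    on collagen releases its granules after roughly one minute and is
    near-fully integrin-active at release.
    """

    alpha_min: float = 0.1  # basal integrin activity (unactivated platelet)
    alpha_max: float = 1.0  # fully activated
    n: float = 2.0  # Hill exponent
    theta_50: float = 5.0e3  # nM s, half-activation integral
    xi_crit: float = 2.0e4  # nM s, granule-release threshold
    dt_window: float = 10.0  # s, recent-history window for xi_dt

    def __post_init__(self) -> None:
        if not 0 < self.alpha_min < self.alpha_max:
            raise ValueError("require 0 < alpha_min < alpha_max")
        if self.n <= 0 or self.theta_50 <= 0:
            raise ValueError("n and theta_50 must be > 0")


def hill_F(theta, params: ActivationParams):
    """Hill-normalized integrin activation F(theta), bounded in
    [alpha_min, alpha_max] and monotone in theta (scalar or array)."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0):
        raise ValueError("theta must be >= 0")
    with np.errstate(over="ignore"):
        tn = theta**params.n
        frac = np.where(np.isinf(tn), 1.0, tn / (tn + params.theta_50**params.n))
    out = params.alpha_min + (params.alpha_max - params.alpha_min) * frac
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# activation integrals
# ---------------------------------------------------------------------------


@dataclass
class PlateletSignalState:
    """Signaling state of one platelet (reference scalar implementation).

    The engine keeps the same quantities in flat arrays (see
    :func:`accumulate_xi`); this class defines the contract and backs the
    unit tests.  ``window`` holds ``(dt, increment)`` pairs covering at
    least the trailing ``dt_window``.
    """

    ca: float = CA_BASAL  # last sampled calcium (nM)
    aux: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 1.0]))
    t: float = 0.0
    xi: float = 0.0
    xi_dt: float = 0.0
    release_triggered: bool = False
    t_release: float | None = None
    window: list = field(default_factory=list)


def update_activation(
    state: PlateletSignalState, new_ca: float, dt: float, params: ActivationParams
) -> PlateletSignalState:
    """Advance xi / xi_dt by one signaling step given the next calcium sample.

    Trapezoidal accumulation of ``max(Ca - basal, 0)``; calcium below basal
    contributes nothing (keeps xi nondecreasing).  Latches the release flag
    the first time ``xi > xi_crit``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if new_ca < 0:
        raise ValueError("calcium concentration must be >= 0")
    inc = 0.5 * (max(state.ca - CA_BASAL, 0.0) + max(new_ca - CA_BASAL, 0.0)) * dt
    state.ca = float(new_ca)
    state.t += dt
    state.xi += inc
    state.window.append((dt, inc))
    # trim entries wholly outside the trailing window
    span = 0.0
    keep = 0
    for i in range(len(state.window) - 1, -1, -1):
        span += state.window[i][0]
        keep = i
        if span >= params.dt_window:
            break
    state.window = state.window[keep:]
    state.xi_dt = min(sum(w for _, w in state.window), state.xi)
    if not state.release_triggered and state.xi > params.xi_crit:
        state.release_triggered = True
        state.t_release = state.t
    return state


def accumulate_xi(xi, ring, ring_pos, prev_ca, new_ca, dt):
    """Vectorized one-step xi update over a platelet population.

    ``ring`` is an ``(n_platelets, n_window)`` buffer of per-step
    increments covering the recent-history window; ``ring_pos`` the column
    to overwrite this step.  Returns updated ``xi`` and ``xi_dt``
    (mutating ``ring`` in place).
    """
    inc = 0.5 * (
        np.maximum(prev_ca - CA_BASAL, 0.0) + np.maximum(new_ca - CA_BASAL, 0.0)
    ) * dt
    xi = xi + inc
    ring[:, ring_pos] = inc
    xi_dt = ring.sum(axis=1)
    return xi, np.minimum(xi_dt, xi)


# ---------------------------------------------------------------------------
# default (surrogate) calcium model
# ---------------------------------------------------------------------------


@dataclass
class CalciumModelParams:
    """Parameters of the phenomenological calcium surrogate.

    Concentration scales (EC50s, nM) set the half-maximal drive of each
    soluble agonist; weights set relative potency (thrombin > collagen >
    ADP > TXA2); the sustained-drive variable makes collagen/thrombin
    responses decay ~10x slower than ADP/TXA2 responses after agonist
    removal.  Iloprost and GSNO inputs are in units of their own half-
    inhibitory level (``inf`` = complete inhibition).
    """

    ca_max: float = 600.0  # nM, ceiling of the calcium response
    k_on: float = 0.4  # 1/s, rise rate at unit drive
    k_fast: float = 0.2  # 1/s, decay rate for transient (ADP/TXA2) signaling
    k_slow: float = 0.003  # 1/s, decay rate under sustained signaling
    tau_sustain_on: float = 4.0  # s, onset of the sustained-drive variable
    tau_sustain_off: float = 120.0  # s, relaxation after agonist removal
    w_collagen: float = 1.0
    w_thrombin: float = 1.2
    w_adp: float = 1.2
    w_txa2: float = 0.4
    ec50_adp: float = 1000.0  # nM
    ec50_txa2: float = 100.0  # nM
    ec50_thrombin: float = 1.0  # nM
    k_desens: float = 0.03  # 1/s, ADP/TXA2 receptor desensitization
    k_resens: float = 0.003  # 1/s, recovery


def _hill1(x):
    """Saturating drive x/(1+x) for x >= 0 (x already EC50-normalized)."""
    x = np.maximum(x, 0.0)
    return x / (1.0 + x)


class DefaultCalciumModel:
    """Phenomenological stand-in for a trained patient-specific NN.

    State per platelet: calcium (nM) plus three auxiliary variables
    ``aux = (s, d_adp, d_txa2)``: the sustained-drive memory and the two
    desensitization levels.  The calcium ODE is linear within a step and
    integrated exactly:

        dCa/dt = k_on S (Ca_max - Ca) - k_off(s) (Ca - 100 nM)

    with the total drive ``S`` combining collagen contact, thrombin, and
    desensitizing ADP/TXA2 terms, scaled by ``(1 - I_inh)`` for
    iloprost/GSNO inhibition, and ``k_off`` interpolating between the fast
    and slow decay rates via ``s``.
    """

    def __init__(self, params: CalciumModelParams | None = None):
        self.params = params or CalciumModelParams()

    def initial_aux(self, n: int) -> np.ndarray:
        aux = np.zeros((n, N_AUX))
        aux[:, 1:] = 1.0
        return aux

    def step(self, ca, aux, exposure: dict, dt: float):
        """Advance calcium one signaling step.

        ``ca``: (n,) calcium in nM; ``aux``: (n, 3); ``exposure``: dict
        with keys ``collagen`` (0/1), ``ADP``/``TXA2``/``thrombin`` (nM),
        ``GSNO``/``iloprost`` (normalized).  Returns ``(ca, aux)``.
        """
        p = self.params
        ca = np.asarray(ca, dtype=float)
        aux = np.array(aux, dtype=float, copy=True)
        col = np.asarray(exposure.get("collagen", 0.0), dtype=float)
        adp = _hill1(np.asarray(exposure.get("ADP", 0.0), dtype=float) / p.ec50_adp)
        txa = _hill1(np.asarray(exposure.get("TXA2", 0.0), dtype=float) / p.ec50_txa2)
        thr = _hill1(
            np.asarray(exposure.get("thrombin", 0.0), dtype=float) / p.ec50_thrombin
        )
        # saturating inhibition; x/(x+1) written as 1/(1+1/x) so x = inf -> 1
        ilo = np.asarray(exposure.get("iloprost", 0.0), dtype=float)
        gsn = np.asarray(exposure.get("GSNO", 0.0), dtype=float)
        with np.errstate(divide="ignore"):
            i_ilo = np.where(ilo > 0, 1.0 / (1.0 + 1.0 / np.maximum(ilo, 1e-300)), 0.0)
            i_gsn = np.where(gsn > 0, 1.0 / (1.0 + 1.0 / np.maximum(gsn, 1e-300)), 0.0)
        inhib = 1.0 - (1.0 - i_ilo) * (1.0 - i_gsn)

        s, d_adp, d_txa = aux[..., 0], aux[..., 1], aux[..., 2]
        drive = (
            p.w_collagen * col
            + p.w_thrombin * thr
            + p.w_adp * adp * d_adp
            + p.w_txa2 * txa * d_txa
        ) * (1.0 - inhib)

        # sustained-drive memory: fast onset, slow relaxation
        target = np.minimum(p.w_collagen * col + p.w_thrombin * thr, 1.0) * (1.0 - inhib)
        tau = np.where(target > s, p.tau_sustain_on, p.tau_sustain_off)
        s_new = target + (s - target) * np.exp(-dt / tau)

        k_off = p.k_fast + (p.k_slow - p.k_fast) * s_new
        a = p.k_on * drive * p.ca_max + k_off * CA_BASAL
        b = p.k_on * drive + k_off
        ca_new = a / b + (ca - a / b) * np.exp(-b * dt)

        # receptor desensitization under sustained ADP/TXA2 exposure
        for col_idx, h in ((1, adp), (2, txa)):
            d = aux[..., col_idx]
            kd = p.k_desens * h + p.k_resens
            dst = p.k_resens / kd
            aux[..., col_idx] = dst + (d - dst) * np.exp(-kd * dt)
        aux[..., 0] = s_new
        return ca_new, aux

    # convenience for tests / single-trace exploration -----------------

    def simulate(self, exposures: list[dict], dt: float, ca0: float = CA_BASAL):
        """Run a single-platelet trace through a list of per-step exposures;
        returns the sampled calcium trace (including the initial value)."""
        ca = np.array([ca0])
        aux = self.initial_aux(1)
        trace = [float(ca[0])]
        for exp in exposures:
            ca, aux = self.step(ca, aux, exp, dt)
            trace.append(float(ca[0]))
        return np.array(trace)


def default_calcium_model(params: CalciumModelParams | None = None) -> DefaultCalciumModel:
    """Build the shipped phenomenological calcium model."""
    return DefaultCalciumModel(params)
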