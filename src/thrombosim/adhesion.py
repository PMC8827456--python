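"""Shear-dependent platelet adhesion kinetics.

Closed-form coarse-grained rate laws for platelet attachment to the
collagen surface and to other platelets, and for detachment, as functions
of the integrin-activation levels ``F`` (from the signaling module) and
the local shear rate ``gamma`` (1/s):

* ``E(gamma)`` — VWF-mediated enhancement of capture: 1 below 3000 1/s,
  ramping linearly to a 20-fold enhancement at 8000 1/s and saturating
  there (globular-to-stretched VWF conformational change at pathological
  shear).
* ``G(gamma)`` — Bell-model exponential acceleration of bond breakage,
  with characteristic shear rates ``gamma_c`` (below 1000 1/s) and
  ``gamma_c_prime`` (above).

Attachment rates scale with activation and ``E``; detachment rates scale
with the reciprocal of activation and ``E`` (a metric of how many bonds
must be broken) times ``G``.  Platelet-platelet rates use the geometric
mean over the pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AdhesionParams",
    "shear_enhancement_E",
    "breakage_G",
    "attach_rate_collagen",
    "attach_rate_platelet",
    "detach_rate_collagen",
    "detach_rate_platelet",
]


@dataclass
class AdhesionParams:
    """Adhesion rate constants (defaults calibrated to the venous-channel
    growth dynamics; see docs/methods.md).

    ``G_continuous_variant`` switches the high-shear branch of ``G`` from
    the printed ``exp(1000/gamma_c) * exp(gamma/gamma_c')`` to
    ``exp(1000/gamma_c) * exp((gamma-1000)/gamma_c')`` which is continuous
    at the 1000 1/s breakpoint.
    """

    k_att_collagen: float = 2.0e3  # 1/s, fully activated platelet on collagen
    k_att_platelet: float = 2.0e3  # 1/s, fully activated pair
    k_det_collagen: float = 2.0e-3  # 1/s
    k_det_platelet: float = 1.5e-1  # 1/s
    gamma_c: float = 1000.0  # 1/s
    gamma_c_prime: float = 4000.0  # 1/s
    vwf_enhancement_on: bool = True
    G_continuous_variant: bool = False

    def __post_init__(self) -> None:
        for name in ("k_att_collagen", "k_att_platelet", "k_det_collagen",
                     "k_det_platelet", "gamma_c", "gamma_c_prime"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


def _check_gamma(gamma) -> np.ndarray:
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma < 0):
        raise ValueError("shear rate must be >= 0")
    return gamma


def shear_enhancement_E(gamma, params: AdhesionParams | None = None):
    """VWF capture enhancement E(gamma): 1 for gamma <= 3000 1/s, linear ramp
    ``1 + 19 (gamma - 3000)/5000`` up to 8000 1/s, and 20 beyond.

    With ``vwf_enhancement_on`` False (the VWF-ablation study) E is 1
    everywhere.  Accepts scalars or arrays.
    """
    params = params or AdhesionParams()
    gamma = _check_gamma(gamma)
    if not params.vwf_enhancement_on:
        out = np.ones_like(gamma)
        return float(out) if out.ndim == 0 else out
    out = np.where(
        gamma <= 3000.0,
        1.0,
        np.where(gamma <= 8000.0, 1.0 + 19.0 * (gamma - 3000.0) / 5000.0, 20.0),
    )
    return float(out) if out.ndim == 0 else out


def breakage_G(gamma, params: AdhesionParams | None = None):
    """Bell-model bond breakage factor G(gamma).

    Printed form (default): ``exp(gamma/gamma_c)`` for gamma <= 1000 1/s and
    ``exp(1000/gamma_c) * exp(gamma/gamma_c')`` above, which is
    discontinuous at the breakpoint; the continuity-corrected variant uses
    ``exp((gamma - 1000)/gamma_c')`` in the second branch.
    """
    params = params or AdhesionParams()
    gamma = _check_gamma(gamma)
    hi = gamma - 1000.0 if params.G_continuous_variant else gamma
    out = np.where(
        gamma <= 1000.0,
        np.exp(np.minimum(gamma, 1000.0) / params.gamma_c),
        np.exp(1000.0 / params.gamma_c) * np.exp(hi / params.gamma_c_prime),
    )
    return float(out) if out.ndim == 0 else out


def attach_rate_collagen(F_xi, F_xidt, gamma, params: AdhesionParams | None = None):
    """Attachment rate of a platelet to the reactive collagen surface:
    ``k_att_collagen * F(xi) * F(xi_dt) * E(gamma)``."""
    params = params or AdhesionParams()
    return params.k_att_collagen * F_xi * F_xidt * shear_enhancement_E(gamma, params)


def attach_rate_platelet(F_i, F_j, gamma_i, gamma_j, params: AdhesionParams | None = None):
    """Attachment rate between platelets i and j: geometric mean of the two
    platelets' activation and shear-enhancement factors.

    ``F_i``/``F_j`` are ``(F(xi), F(xi_dt))`` pairs.
    """
    params = params or AdhesionParams()
    prod = (
        F_i[0] * F_j[0] * F_i[1] * F_j[1]
        * shear_enhancement_E(gamma_i, params)
        * shear_enhancement_E(gamma_j, params)
    )
    return params.k_att_platelet * np.sqrt(prod)


def detach_rate_collagen(F_xi, F_xidt, gamma, params: AdhesionParams | None = None):
    """Detachment rate from collagen:
    ``k_det_collagen / (F(xi) F(xi_dt) E(gamma)) * G(gamma)``."""
    params = params or AdhesionParams()
    if np.any(np.asarray(F_xi) <= 0) or np.any(np.asarray(F_xidt) <= 0):
        raise ValueError("activation factors must be > 0 (alpha_min > 0)")
    return (
        params.k_det_collagen
        / (F_xi * F_xidt * shear_enhancement_E(gamma, params))
        * breakage_G(gamma, params)
    )


def detach_rate_platelet(F_i, F_j, gamma_i, gamma_j, params: AdhesionParams | None = None):
    """Detachment rate between platelets i and j: reciprocal geometric mean
    of the six activation/enhancement factors times the geometric mean of
    the two breakage factors."""
    params = params or AdhesionParams()
    prod = (
        F_i[0] * F_j[0] * F_i[1] * F_j[1]
        * shear_enhancement_E(gamma_i, params)
        * shear_enhancement_E(gamma_j, params)
    )
    if np.any(np.asarray(prod) <= 0):
        raise ValueError("activation factors must be > 0")
    Gg = breakage_G(gamma_i, params) * breakage_G(gamma_j, params)
    return params.k_det_platelet / np.sqrt(prod) * np.sqrt(Gg)
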