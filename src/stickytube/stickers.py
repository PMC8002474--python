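"""Sticker open/close kinetics.

Two channels govern sticker exchange: direct association--dissociation
(2 S1 <-> S2, rates ka / kd) and bond swapping (S1 + S2 -> S2 + S1, rate
kbs).  The effective opening and closing rates seen by one sticker are

    k_close = ka*[S1] + kbs*[S2],      k_open = kd + kbs*[S1],

with [S1] = (1-p)[S] and [S2] = p[S]/2 at a closed fraction p.  Chain
tension accelerates dissociation Bell-style: the activation energy
E_act0 (in kBT) is reduced by ell*F and clipped at zero, so the opening
rate saturates at the attempt frequency nu = exp(E_act0)/tau_s0.

Energies are carried in kBT units throughout; temperature never appears
explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StickerKineticsParams",
    "StickerRates",
    "effective_rates",
    "equilibrium_closed_fraction",
    "calibrate_association",
    "opening_rate_under_force",
    "stretch_dependent_lifetime",
]


@dataclass(frozen=True)
class StickerKineticsParams:
    """Rate coefficients of the sticker reaction network.

    ``ka`` and ``kbs`` are per concentration per time, ``kd0`` is the
    force-free dissociation rate 1/time, ``S_total`` the total sticker
    concentration [S].  ``nu_attempt`` may be given instead of (or along
    with) ``kd0``; when both are given they must satisfy
    kd0 = nu_attempt*exp(-E_act0).
    """

    ka: float
    kd0: float | None = None
    kbs: float = 0.0
    S_total: float = 1.0
    nu_attempt: float | None = None
    E_act0: float = 8.0
    ell: float = 0.1          # nm

    def __post_init__(self) -> None:
        if self.ka < 0 or self.kbs < 0 or self.S_total < 0:
            raise ValueError("rates and concentrations must be >= 0")
        if self.E_act0 < 0:
            raise ValueError("activation energy must be >= 0")
        if self.ell <= 0:
            raise ValueError("dissociation length must be positive")
        kd0, nu = self.kd0, self.nu_attempt
        if kd0 is None and nu is None:
            raise ValueError("specify kd0 or nu_attempt")
        if kd0 is None:
            object.__setattr__(self, "kd0", nu * math.exp(-self.E_act0))
        elif nu is None:
            object.__setattr__(self, "nu_attempt", kd0 * math.exp(self.E_act0))
        else:
            if not math.isclose(kd0, nu * math.exp(-self.E_act0), rel_tol=1e-6):
                raise ValueError(
                    "inconsistent kinetics: kd0 != nu_attempt*exp(-E_act0)"
                )
        if self.kd0 <= 0:
            raise ValueError("dissociation rate must be positive")


@dataclass(frozen=True)
class StickerRates:
    """Effective opening/closing rates at a given closed fraction."""

    k_open: float
    k_close: float
    p: float


def effective_rates(params: StickerKineticsParams, p: float) -> StickerRates:
    """Effective rates k_close = ka[S1]+kbs[S2], k_open = kd0+kbs[S1]."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"closed fraction p={p} outside [0, 1)")
    S1 = (1.0 - p) * params.S_total
    S2 = p * params.S_total / 2.0
    return StickerRates(
        k_open=params.kd0 + params.kbs * S1,
        k_close=params.ka * S1 + params.kbs * S2,
        p=p,
    )


def equilibrium_closed_fraction(ka: float, kd0: float, S_total: float) -> float:
    """Closed fraction p solving 2p/(1-p)^2 = (ka/kd0)*[S].

    The quadratic K p^2 - 2(K+1) p + K = 0 (K = ka[S]/kd0) always has
    exactly one root in [0, 1); it is returned in closed form.
    """
    if ka <= 0 or kd0 <= 0 or S_total <= 0:
        raise ValueError("ka, kd0 and S_total must be positive")
    K = ka * S_total / kd0
    # physical root of K(1-p)^2 = 2p, written cancellation-free
    return K / (K + 1.0 + math.sqrt(2.0 * K + 1.0))


def calibrate_association(p_target: float, kd0: float, S_total: float) -> float:
    """Association rate ka reproducing a target quiescent closed fraction.

    Inverse of :func:`equilibrium_closed_fraction`; lets simulations be
    parameterised by p directly.
    """
    if not 0.0 < p_target < 1.0:
        raise ValueError("p_target must be in (0, 1)")
    if kd0 <= 0 or S_total <= 0:
        raise ValueError("kd0 and S_total must be positive")
    return kd0 * 2.0 * p_target / ((1.0 - p_target) ** 2 * S_total)


def opening_rate_under_force(F, params: StickerKineticsParams):
    """Force-accelerated dissociation rate nu*exp(-max(0, E_act0 - ell*F)).

    ``F`` is the magnitude of the conformational force at the sticker in
    kBT/nm (ell in nm makes ell*F dimensionless).  The rate rises
    exponentially with force and saturates at the attempt frequency once
    ell*F >= E_act0.  Accepts scalars or arrays.
    """
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise ValueError("pass the force magnitude (F >= 0)")
    barrier = np.maximum(0.0, params.E_act0 - params.ell * F)
    out = params.nu_attempt * np.exp(-barrier)
    return float(out) if out.ndim == 0 else out


def stretch_dependent_lifetime(lam: float, lambda_max: float, ell: float,
                               a: float, tau_s0: float, *,
                               E_act0: float = 8.0, capped: bool = True):
    """Sticker lifetime tau_s0*exp(-(3 ell/a) ks(lambda) lambda).

    The exponent is the Bell factor for the tension 3 kBT ks lambda / a
    carried by a stretched tube segment; ks is the finite-extensibility
    spring correction.  With ``capped`` (default) the acceleration is
    clipped at exp(E_act0), the floor implied by a vanishing barrier, so
    the lifetime never falls below tau_s0*exp(-E_act0).
    """
    from .tube import fene_factor  # deferred: tube imports this module

    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("stretch ratio must be >= 0")
    if np.any(lam >= lambda_max):
        raise ValueError("lambda >= lambda_max: tension diverges")
    if ell <= 0 or a <= 0 or tau_s0 <= 0:
        raise ValueError("ell, a and tau_s0 must be positive")
    ks = fene_factor(lam, lambda_max)
    expo = 3.0 * ell / a * ks * lam
    if capped:
        expo = np.minimum(expo, E_act0)
    out = tau_s0 * np.exp(-expo)
    return float(out) if np.ndim(out) == 0 else out
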