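"""Sticky dumbbell in shear flow.

Shear acts along the tube only over distances of order the tube diameter,
so the extensional drag gamma_dot*zeta*R_i is replaced by a drag that
saturates: gamma_dot*zeta*(R_i - R_cm) for |R_i - R_cm| < a/2 and
gamma_dot*zeta*(a/2)*sign(R_i - R_cm) beyond.  The chain is reduced to a
two-bead dumbbell whose two end stickers are synchronised (one shared
open/closed state), springs are harmonic (no finite extensibility) and
sticker dissociation is force-independent.

Reduced units: kBT = 1, tube diameter a = 1, dumbbell relaxation time
tau_R = 1 (its terminal relaxation time with stickers disabled).  The
rest separation is a*Ze, the spring constant 3/(a^2*Ze) reproduces the
equilibrium stretch fluctuation 1/sqrt(3*Ze) of the full chain, and the
bead friction follows from tau_R = zeta/(2*kappa).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import numpy as np

from .params import ChainParams
from .tube import StretchDistribution

__all__ = [
    "DumbbellConfig",
    "DumbbellResult",
    "capped_shear_force",
    "simulate_shear_dumbbell",
    "stress_observable",
    "strain_to_steady",
]


@dataclass(frozen=True)
class DumbbellConfig:
    """Protocol for a sticky-dumbbell shear run (times in units of tau_R).

    Finite extensibility and force-accelerated dissociation are
    structurally absent from the dumbbell; there are no flags to enable
    them.
    """

    gamma_dot: float = 0.0        # shear rate [1/tau_R]
    p: float = 0.9                # closed-sticker fraction
    tau_s0: float = 100.0         # sticker lifetime [tau_R]
    duration: float | None = None  # total simulated time [tau_R]
    t_burn: float | None = None   # discard for stationary sampling [tau_R]
    n_chains: int = 1000
    seed: int = 0
    dt: float = 0.02              # [tau_R]

    def __post_init__(self) -> None:
        if self.gamma_dot < 0:
            raise ValueError("shear rate must be >= 0")
        if not 0.0 <= self.p < 1.0:
            raise ValueError("closed fraction p must be in [0, 1)")
        if self.tau_s0 <= 0 or self.dt <= 0:
            raise ValueError("tau_s0 and dt must be positive")
        if self.dt > 0.1:
            raise ValueError("dt > 0.1 tau_R under-resolves the spring")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    def replace(self, **kw) -> "DumbbellConfig":
        return replace(self, **kw)

    def asdict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class DumbbellResult:
    """Stationary stretch samples and stretch/stress trajectories."""

    distribution: StretchDistribution
    strain: np.ndarray        # gamma_dot * t at each record
    mean_lambda: np.ndarray   # ensemble-mean stretch
    stress: np.ndarray        # dimensionless stress <lambda^2>
    config: DumbbellConfig


def capped_shear_force(R_i, R_cm, a: float, gamma_dot: float):
    """Saturating shear drag per unit friction.

    gamma_dot*(R_i - R_cm) inside the tube-diameter core |R_i - R_cm| <
    a/2, constant gamma_dot*(a/2)*sign(R_i - R_cm) outside; continuous at
    the crossover.
    """
    return gamma_dot * np.clip(np.asarray(R_i, dtype=float) - R_cm,
                               -a / 2.0, a / 2.0)


def stress_observable(samples) -> float:
    """Dimensionless stress sigma* = <ks*lambda^2>; ks = 1 for the dumbbell."""
    lam = np.asarray(samples, dtype=float)
    if lam.size == 0:
        raise ValueError("no stretch samples")
    return float(np.mean(np.square(lam)))


def simulate_shear_dumbbell(params: ChainParams,
                            config: DumbbellConfig) -> DumbbellResult:
    """Brownian dynamics of the synchronised sticky dumbbell in shear.

    When closed, both beads only advect with the (capped) flow; when
    open, the full Langevin dynamics applies.  The sticker pair toggles
    as one two-state Markov chain with k_open = 1/tau_s0 and
    k_close = p/((1-p)*tau_s0), so the equilibrium closed fraction is p
    and free diffusion occupies a fraction (1-p) of the time.
    """
    a = 1.0
    Ze = params.Ze
    delta0 = a * Ze
    kappa = 3.0 / (a * a * Ze)
    zeta = 2.0 * kappa             # tau_R = zeta/(2*kappa) = 1
    p, gd, dt = config.p, config.gamma_dot, config.dt
    tau_relax = 1.0 / (1.0 - p) if p > 0 else 1.0  # sticky-slowed terminal time
    duration = (config.duration if config.duration is not None
                else max(30.0 * config.tau_s0, 20.0 * tau_relax))
    t_burn = (config.t_burn if config.t_burn is not None
              else min(duration / 3.0, max(10.0 * config.tau_s0,
                                           5.0 * tau_relax)))

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_chains
    # equilibrium start: separation N(delta0, 1/kappa), sticker closed w.p. p
    delta = rng.normal(delta0, math.sqrt(1.0 / kappa), size=n)
    Rcm = np.zeros(n)
    R1 = Rcm - delta / 2.0
    R2 = Rcm + delta / 2.0
    closed = rng.random(n) < p

    k_open = 1.0 / config.tau_s0
    k_close = p / ((1.0 - p) * config.tau_s0) if p > 0 else 0.0
    p_open = -math.expm1(-k_open * dt)
    p_close = -math.expm1(-k_close * dt)
    amp = math.sqrt(2.0 * dt / zeta)

    n_steps = int(round(duration / dt))
    record_every = max(1, n_steps // 600)
    strain, mean_lam, stress = [], [], []
    samples = []
    sample_every = max(1, int(round(max(tau_relax, 1.0) / dt)))

    for s in range(n_steps):
        Rcm = 0.5 * (R1 + R2)
        f1 = capped_shear_force(R1, Rcm, a, gd)
        f2 = capped_shear_force(R2, Rcm, a, gd)
        open_ = ~closed
        spring = kappa * (R2 - R1 - delta0)  # force on bead 1; -spring on 2
        R1 += dt * f1
        R2 += dt * f2
        if np.any(open_):
            xi = rng.standard_normal((2, n))
            R1[open_] += (dt / zeta * spring[open_]
                          + amp * xi[0, open_])
            R2[open_] += (-dt / zeta * spring[open_]
                          + amp * xi[1, open_])
        u = rng.random(n)
        closed ^= (closed & (u < p_open)) | (open_ & (u < p_close))

        t = (s + 1) * dt
        if s % record_every == 0:
            lam = (R2 - R1) / delta0
            strain.append(gd * t)
            mean_lam.append(float(lam.mean()))
            stress.append(stress_observable(lam))
        if t >= t_burn and s % sample_every == 0:
            samples.append((R2 - R1) / delta0)

    dist = StretchDistribution(np.concatenate(samples), Ze=Ze)
    return DumbbellResult(distribution=dist,
                          strain=np.asarray(strain),
                          mean_lambda=np.asarray(mean_lam),
                          stress=np.asarray(stress),
                          config=config)


def strain_to_steady(strain: np.ndarray, mean_lambda: np.ndarray,
                     frac: float = 0.8) -> float:
    """Strain at which the mean stretch first reaches ``frac`` of its rise.

    The plateau is the average over the final fifth of the trajectory;
    the trajectory is lightly smoothed before thresholding so noise does
    not trigger early.
    """
    lam = np.asarray(mean_lambda, dtype=float)
    strain = np.asarray(strain, dtype=float)
    if lam.size < 10:
        raise ValueError("trajectory too short")
    w = max(1, lam.size // 50)
    kernel = np.ones(w) / w
    smooth = np.convolve(lam, kernel, mode="same")
    plateau = float(np.mean(lam[-lam.size // 5:]))
    target = 1.0 + frac * (plateau - 1.0)
    idx = np.flatnonzero(smooth >= target)
    if idx.size == 0:
        return float(strain[-1])
    return float(strain[idx[0]])
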