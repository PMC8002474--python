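"""1D Brownian dynamics of an entangled sticky chain in its tube.

The chain's curvilinear coordinates R_i along the aligned tube obey the
overdamped Langevin equation

    zeta dR_i/dt = F_thermal,i + F_conf,i + eps_dot * zeta * (R_i - R_cm),

where F_conf is the (optionally FENE-corrected) discrete spring force and
the flow term is written in the centre-of-mass frame.  A closed sticker
is kinetically trapped: it neither diffuses nor responds to spring
forces and only advects with the flow.  Stickers open with a
force-accelerated Bell rate and close with a constant rate calibrated to
the quiescent closed fraction p.

Reduced units: kBT = 1, tube diameter a = 1, entanglement time tau_e = 1.
With N_bonds = Ze*(n_beads_per_strand + 1) bonds, the spring constant
kappa = 3*N_bonds/Ze reproduces the equilibrium contour variance a^2*Ze/3
and the bead friction zeta = 3*pi^2*Ze/N_bonds gives a strand relaxation
time tau_e and a chain (Rouse) time Ze^2*tau_e.  Public APIs accept
physical units (nm, s) and convert here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields, replace

import numpy as np
from scipy import stats

from .params import ChainParams, stability_timestep, tube_diameter

__all__ = [
    "SimulationConfig",
    "ChainState",
    "StretchDistribution",
    "ExtensionResult",
    "TubeSimulator",
    "fene_factor",
    "init_equilibrium_state",
    "conformational_force",
    "euler_step",
    "update_stickers",
    "simulate_extension",
    "stretch_distribution",
]


# ---------------------------------------------------------------------------
# Configuration and state containers


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical protocol for one extensional-flow simulation.

    Times are in seconds on the same clock as ``ChainParams.tau_e`` (so a
    reduced-unit parameter set with tau_e = 1 takes reduced times).  When
    ``dt`` is None the step is chosen adaptively each step as
    min(stability bound, 0.1/k_open_max, 0.1/k_close) -- the explicit-Euler
    strand criterion and the requirement that sticker transitions are
    resolved.
    """

    n_beads_per_strand: int = 3
    dt: float | None = None        # s; None -> adaptive
    rate: float = 0.0              # extensional strain rate [1/s]
    t_burn: float | None = None    # s; None -> 3 terminal times
    t_sample: float | None = None  # s; None -> 5 terminal times
    sample_every: float | None = None  # s between retained samples
    n_chains: int = 256
    seed: int = 0
    fene_on: bool = True
    force_dissociation_on: bool = True
    literal_eq5: bool = False      # thermal noise also on closed stickers

    def __post_init__(self) -> None:
        if self.n_beads_per_strand < 0:
            raise ValueError("n_beads_per_strand must be >= 0")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.rate < 0:
            raise ValueError("strain rate must be >= 0")
        for name in ("t_burn", "t_sample", "sample_every"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)

    def asdict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_weissenberg(cls, params: ChainParams, *,
                         Wi_bare: float | None = None,
                         Wi_sticky: float | None = None,
                         **kw) -> "SimulationConfig":
        """Build a config with the rate set through a Weissenberg number."""
        if (Wi_bare is None) == (Wi_sticky is None):
            raise ValueError("give exactly one of Wi_bare, Wi_sticky")
        if Wi_bare is not None:
            rate = Wi_bare / (params.tau_e * params.Ze ** 2)
        else:
            if params.Zs == 0:
                raise ValueError("Wi_sticky undefined for a chain without stickers")
            rate = Wi_sticky / (params.tau_s0 * params.Zs ** 2)
        return cls(rate=rate, **kw)


@dataclass
class ChainState:
    """Bead coordinates, sticker flags and the simulation clock.

    ``R`` has shape (n_chains, n_beads) in units of the tube diameter;
    ``closed`` has shape (n_chains, Zs) (empty for a non-sticky chain) and
    refers to the beads listed in ``sticker_beads``.  Non-sticky beads are
    permanently open by construction.
    """

    R: np.ndarray
    closed: np.ndarray
    sticker_beads: np.ndarray
    t: float = 0.0

    def stretch(self, Ze: int) -> np.ndarray:
        """Chain stretch ratio lambda = (R_last - R_first)/(a*Ze)."""
        return (self.R[:, -1] - self.R[:, 0]) / Ze

    def copy(self) -> "ChainState":
        return ChainState(self.R.copy(), self.closed.copy(),
                          self.sticker_beads.copy(), self.t)


@dataclass
class StretchDistribution:
    """Sampled chain stretch ratios with summary accessors."""

    samples: np.ndarray
    Ze: int
    lam_ref: float = 1.0   # stretch of the Gaussian reference

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()

    def mean(self) -> float:
        return float(np.mean(self.samples))

    def sd(self) -> float:
        return float(np.std(self.samples, ddof=1))

    def quantile(self, q) -> np.ndarray | float:
        return np.quantile(self.samples, q)

    def reference_sd(self, lam: float | None = None) -> float:
        """Gaussian contour-fluctuation width sqrt(lam/(3*Ze)) in lambda units."""
        lam = self.lam_ref if lam is None else lam
        return math.sqrt(lam / (3.0 * self.Ze))

    def gaussian_reference(self, x, lam: float | None = None):
        """Equilibrium Gaussian reference density at stretch ``lam``."""
        lam = self.lam_ref if lam is None else lam
        return stats.norm.pdf(x, loc=lam, scale=self.reference_sd(lam))

    def excess_tail_mass(self, threshold: float = 2.0) -> float:
        """P(lambda > threshold) relative to a Gaussian fitted to the mean."""
        emp = float(np.mean(self.samples > threshold))
        ref = float(stats.norm.sf(threshold, loc=self.mean(),
                                  scale=self.reference_sd(self.mean())))
        return emp / max(ref, np.finfo(float).tiny)

    def histogram(self, bins=50):
        """Density-normalised histogram (density, edges)."""
        if self.samples.size < 100:
            raise ValueError("need at least 100 samples for a histogram")
        density, edges = np.histogram(self.samples, bins=bins, density=True)
        return density, edges

    def summary(self) -> dict:
        q = self.quantile([0.01, 0.25, 0.5, 0.75, 0.99])
        return {
            "n": int(self.samples.size),
            "mean": self.mean(),
            "sd": self.sd(),
            "cv": self.sd() / self.mean(),
            "q01": float(q[0]), "q25": float(q[1]), "median": float(q[2]),
            "q75": float(q[3]), "q99": float(q[4]),
            "excess_tail_mass_2": self.excess_tail_mass(2.0),
        }


@dataclass
class ExtensionResult:
    """Output of an extensional-flow run."""

    distribution: StretchDistribution
    t_series: np.ndarray        # sample times [s]
    mean_series: np.ndarray     # ensemble-mean stretch at each sample time
    lam_series: np.ndarray      # (n_samples, n_chains) retained stretches
    params: ChainParams
    config: SimulationConfig
    dt_mean: float              # average time step actually taken [s]


# ---------------------------------------------------------------------------
# Elementary operations


def fene_factor(lam, lambda_max: float):
    """Finite-extensibility spring correction, normalised to ks(1) = 1.

    ks = [(3*lm^2 - l^2)/(lm^2 - l^2)] / [(3*lm^2 - 1)/(lm^2 - 1)];
    equals 1 at unit stretch, increases monotonically for |lambda| > 1 and
    diverges as |lambda| -> lambda_max.
    """
    if lambda_max <= 1.0:
        raise ValueError("lambda_max must exceed 1")
    lam2 = np.square(np.asarray(lam, dtype=float))
    lm2 = lambda_max ** 2
    if np.any(lam2 >= lm2):
        raise ValueError("local stretch reached lambda_max")
    norm = (3.0 * lm2 - 1.0) / (lm2 - 1.0)
    out = (3.0 * lm2 - lam2) / (lm2 - lam2) / norm
    return float(out) if out.ndim == 0 else out


def sticker_bead_indices(Zs: int, n_beads: int) -> np.ndarray:
    """Zs sticker beads equally spaced along the chain interior."""
    if Zs == 0:
        return np.empty(0, dtype=np.intp)
    if Zs > n_beads - 2:
        raise ValueError("more stickers than interior beads")
    idx = np.rint(np.arange(1, Zs + 1) * (n_beads - 1) / (Zs + 1)).astype(np.intp)
    idx = np.clip(idx, 1, n_beads - 2)
    if np.unique(idx).size != Zs:
        raise ValueError("discretisation too coarse to place distinct stickers")
    return idx


# ---------------------------------------------------------------------------
# Simulator


class TubeSimulator:
    """Precomputed constants and stepping kernels for one (params, config)."""

    def __init__(self, params: ChainParams, config: SimulationConfig):
        self.params = params
        self.config = config
        nb = config.n_beads_per_strand
        self.n_bonds = params.Ze * (nb + 1)
        self.n_beads = self.n_bonds + 1
        self.kappa = 3.0 * self.n_bonds / params.Ze
        self.zeta = 3.0 * math.pi ** 2 * params.Ze / self.n_bonds
        self.dR_eq = params.Ze / self.n_bonds
        self.lambda_max = params.lambda_max
        self.a_nm = tube_diameter(params.N, params.b, params.Ze)
        self.ell_hat = params.ell / self.a_nm
        self.sticker_beads = sticker_bead_indices(params.Zs, self.n_beads)
        # reduced-time quantities (units of tau_e)
        self.rate_hat = config.rate * params.tau_e
        self.tau_s0_hat = params.tau_s0 / params.tau_e
        self.k_open0 = 1.0 / self.tau_s0_hat
        self.nu_attempt = math.exp(params.E_act0) * self.k_open0
        if params.Zs > 0 and params.p > 0:
            self.k_close = params.p / ((1.0 - params.p) * self.tau_s0_hat)
        else:
            self.k_close = 0.0
        self.dt_stab = stability_timestep(1.0, nb)
        if config.dt is not None:
            dt_hat = config.dt / params.tau_e
            if dt_hat > self.dt_stab * (1 + 1e-12):
                raise ValueError(
                    f"dt={config.dt:g} s exceeds the Euler stability bound "
                    f"{self.dt_stab * params.tau_e:g} s")
            self.dt_fixed = dt_hat
        else:
            self.dt_fixed = None

    # -- state ------------------------------------------------------------

    def init_state(self, rng: np.random.Generator) -> ChainState:
        """Equilibrium start: Gaussian bonds, stickers closed w.p. p.

        Bond increments are independent N(dR_eq, kBT/kappa), which gives
        the chain the exact equilibrium contour statistics (mean a*Ze,
        relative width 1/sqrt(3*Ze)).
        """
        p, cfg = self.params, self.config
        bonds = rng.normal(self.dR_eq, math.sqrt(1.0 / self.kappa),
                           size=(cfg.n_chains, self.n_bonds))
        R = np.concatenate(
            [np.zeros((cfg.n_chains, 1)), np.cumsum(bonds, axis=1)], axis=1)
        R -= R.mean(axis=1, keepdims=True)
        closed = rng.random((cfg.n_chains, p.Zs)) < p.p
        return ChainState(R=R, closed=closed,
                          sticker_beads=self.sticker_beads.copy(), t=0.0)

    # -- forces -----------------------------------------------------------

    def bond_tensions(self, R: np.ndarray) -> np.ndarray:
        """Tension kappa*ks*dR of every bond (kBT/a units)."""
        T, _ = self._tensions(np.diff(R, axis=1))
        return T

    def _tensions(self, bonds: np.ndarray) -> tuple[np.ndarray, float]:
        """(tensions, max |bond stretch|) for an array of bond lengths."""
        if not self.config.fene_on:
            return self.kappa * bonds, float(np.max(np.abs(bonds))) / self.dR_eq
        lam2 = np.square(bonds / self.dR_eq)
        lam_abs_max = math.sqrt(float(lam2.max()))
        lm2 = self.lambda_max ** 2
        if lam_abs_max >= self.lambda_max:
            raise RuntimeError("bond stretch reached lambda_max; reduce dt")
        norm = (3.0 * lm2 - 1.0) / (lm2 - 1.0)
        ks = (3.0 * lm2 - lam2) / (lm2 - lam2) / norm
        return self.kappa * ks * bonds, lam_abs_max

    def _divergence(self, T: np.ndarray) -> np.ndarray:
        F = np.empty((T.shape[0], T.shape[1] + 1))
        T_ghost = self.kappa * self.dR_eq
        F[:, 1:-1] = T[:, 1:] - T[:, :-1]
        F[:, 0] = T[:, 0] - T_ghost
        F[:, -1] = T_ghost - T[:, -1]
        return F

    def conf_force(self, R: np.ndarray) -> np.ndarray:
        """Discrete divergence of the bond tension, with ghost bonds.

        Ghost bonds of rest length dR_eq at both ends impose the
        fixed-gradient boundary condition dR/di = a*Ze/N_bonds.
        """
        return self._divergence(self.bond_tensions(R))

    # -- sticker rates ----------------------------------------------------

    def open_rates(self, F_stick_abs: np.ndarray) -> np.ndarray:
        """Per-sticker opening rate (1/tau_e) given |force| at the sticker."""
        if not self.config.force_dissociation_on:
            return np.full_like(F_stick_abs, self.k_open0)
        expo = np.minimum(self.ell_hat * F_stick_abs, self.params.E_act0)
        return self.k_open0 * np.exp(expo)

    def _pick_dt(self, k_open: np.ndarray, F: np.ndarray,
                 lam_abs_max: float) -> float:
        if self.dt_fixed is not None:
            return self.dt_fixed
        dt = self.dt_stab
        if self.k_close > 0:
            dt = min(dt, 0.1 / self.k_close)
        if k_open.size:
            kmax = float(k_open.max())
            if kmax > 0:
                dt = min(dt, 0.1 / kmax)
        if self.config.fene_on and lam_abs_max > 0.8 * self.lambda_max:
            # keep the per-step motion well inside the FENE divergence
            gap = 0.25 * (self.lambda_max - lam_abs_max) * self.dR_eq
            v = float(np.max(np.abs(F))) / self.zeta
            if v > 0:
                dt = min(dt, gap / v)
            dt = min(dt, gap * gap * self.zeta / 2.0)
            dt = max(dt, self.dt_stab / 256.0)  # retries handle the rest
        return dt

    # -- stepping ---------------------------------------------------------

    def step(self, state: ChainState, rng: np.random.Generator,
             dt: float | None = None, xi: np.ndarray | None = None) -> float:
        """One Euler step plus one sticker update; returns the dt used."""
        R = state.R
        bonds = np.diff(R, axis=1)
        T, lam_abs_max = self._tensions(bonds)
        F = self._divergence(T)
        stick = self.sticker_beads
        if stick.size:
            k_open = self.open_rates(np.abs(F[:, stick]))
            open_mask = ~state.closed
        else:
            k_open = self._EMPTY
        if dt is None:
            dt = self._pick_dt(k_open, F, lam_abs_max)

        if xi is None:
            xi = rng.standard_normal(R.shape)
        if stick.size:
            F[:, stick] *= open_mask
            if not self.config.literal_eq5:
                xi[:, stick] *= open_mask

        danger = (self.config.fene_on
                  and lam_abs_max > 0.9 * self.lambda_max)
        for attempt in range(12):
            drift = F * (dt / self.zeta)
            if self.rate_hat:
                drift += (dt * self.rate_hat) * (
                    R - R.mean(axis=1, keepdims=True))
            drift += math.sqrt(2.0 * dt / self.zeta) * xi
            if not danger:
                R += drift
                break
            R_try = R + drift
            new_lam = np.max(np.abs(np.diff(R_try, axis=1))) / self.dR_eq
            if new_lam < self.lambda_max:
                state.R = R_try
                R = R_try
                break
            dt *= 0.5  # overshot the FENE divergence: retry smaller
            xi = rng.standard_normal(R.shape)
            if stick.size and not self.config.literal_eq5:
                xi[:, stick] *= open_mask
        else:
            raise RuntimeError(
                "bond stretch pinned at lambda_max; step rejected 12 times")
        if not np.all(np.isfinite(R[:, -1])):
            raise FloatingPointError(
                "bead coordinates overflowed; reduce dt or the strain rate")

        if stick.size:
            u = rng.random(state.closed.shape)
            p_open = -np.expm1(-k_open * dt)
            p_close = -math.expm1(-self.k_close * dt)
            opening = state.closed & (u < p_open)
            closing = open_mask & (u < p_close)
            state.closed ^= opening | closing
        state.t += dt
        return dt

    _EMPTY = np.empty((0, 0))

    # -- full run ---------------------------------------------------------

    def run(self, progress: bool = False) -> ExtensionResult:
        p, cfg = self.params, self.config
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
        state = self.init_state(rng)

        terminal = p.tau_s0 * p.Zs ** 2 if p.Zs else p.tau_e * p.Ze ** 2
        if cfg.rate > 0:
            # flow slows the approach to the stationary state near Wi ~ 1
            bare = p.tau_e * p.Ze ** 2
            terminal = max(terminal, bare / max(1e-2, abs(1.0 - cfg.rate * bare)))
        t_burn = (cfg.t_burn if cfg.t_burn is not None else 3.0 * terminal) / p.tau_e
        t_samp = (cfg.t_sample if cfg.t_sample is not None else 5.0 * terminal) / p.tau_e
        every = (cfg.sample_every / p.tau_e if cfg.sample_every is not None
                 else max(t_samp / 400.0, self.dt_stab))

        t_end = t_burn + t_samp
        next_sample = t_burn
        times, lam_rows = [], []
        n_steps = 0
        block, bsize = None, 64
        k = bsize
        shape = (cfg.n_chains, self.n_beads)
        while state.t < t_end:
            if k == bsize:  # refill the noise block
                block = rng.standard_normal((bsize,) + shape)
                k = 0
            self.step(state, rng, xi=block[k])
            k += 1
            n_steps += 1
            if state.t >= next_sample:
                lam_rows.append(state.stretch(p.Ze).copy())
                times.append(state.t)
                next_sample += every

        lam_series = np.asarray(lam_rows)
        mean_series = lam_series.mean(axis=1)
        self._check_stationarity(mean_series)
        dist = StretchDistribution(lam_series.ravel(), Ze=p.Ze)
        return ExtensionResult(
            distribution=dist,
            t_series=np.asarray(times) * p.tau_e,
            mean_series=mean_series,
            lam_series=lam_series,
            params=p, config=cfg,
            dt_mean=(state.t / n_steps) * p.tau_e,
        )

    @staticmethod
    def _check_stationarity(mean_series: np.ndarray) -> None:
        """Warn if the two halves of the sampling window drifted apart."""
        n = mean_series.size
        if n < 20:
            return
        a, b = mean_series[: n // 2], mean_series[n // 2:]
        # crude block-corrected scale: blocks of one tenth of a half
        blocks_a = [x.mean() for x in np.array_split(a, 5)]
        blocks_b = [x.mean() for x in np.array_split(b, 5)]
        se = math.hypot(np.std(blocks_a, ddof=1) / math.sqrt(5),
                        np.std(blocks_b, ddof=1) / math.sqrt(5))
        if se > 0 and abs(a.mean() - b.mean()) > 5.0 * se:
            warnings.warn(
                "mean stretch drifted between sampling halves; the run may "
                "not be stationary -- increase t_burn", stacklevel=3)


# ---------------------------------------------------------------------------
# Functional surface (thin wrappers over TubeSimulator)


def init_equilibrium_state(params: ChainParams, config: SimulationConfig,
                           seed: int | None = None) -> ChainState:
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return TubeSimulator(params, config).init_state(rng)


def conformational_force(state: ChainState, params: ChainParams,
                         config: SimulationConfig) -> np.ndarray:
    return TubeSimulator(params, config).conf_force(state.R)


def euler_step(state: ChainState, params: ChainParams,
               config: SimulationConfig, rng: np.random.Generator,
               dt: float | None = None) -> ChainState:
    """Advance ``state`` in place by one step (dt in seconds if given)."""
    sim = TubeSimulator(params, config)
    sim.step(state, rng, dt=None if dt is None else dt / params.tau_e)
    return state


def update_stickers(state: ChainState, params: ChainParams,
                    config: SimulationConfig, rng: np.random.Generator,
                    dt: float) -> ChainState:
    """Apply only the sticker open/close update over a time dt [s]."""
    sim = TubeSimulator(params, config)
    if not sim.sticker_beads.size:
        return state
    F = sim.conf_force(state.R)
    k_open = sim.open_rates(np.abs(F[:, sim.sticker_beads]))
    dt_hat = dt / params.tau_e
    u = rng.random(state.closed.shape)
    opening = state.closed & (u < -np.expm1(-k_open * dt_hat))
    closing = ~state.closed & (u < -math.expm1(-sim.k_close * dt_hat))
    state.closed ^= opening | closing
    state.t += dt_hat
    return state


def simulate_extension(params: ChainParams,
                       config: SimulationConfig) -> ExtensionResult:
    """Run the extensional-flow BD simulation and collect stretch statistics."""
    return TubeSimulator(params, config).run()


def stretch_distribution(samples, Ze: int, lam_ref: float = 1.0,
                         bins=50):
    """Histogram of stretch samples plus the Gaussian reference overlay.

    Returns (density, edges, reference) where ``reference`` is the
    equilibrium Gaussian evaluated at the bin centres.
    """
    dist = StretchDistribution(samples, Ze=Ze, lam_ref=lam_ref)
    density, edges = dist.histogram(bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return density, edges, dist.gaussian_reference(centers)
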