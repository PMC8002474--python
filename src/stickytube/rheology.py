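"""Rheology models fitted to oscillatory and temperature-sweep data.

Two empirical descriptions used for native silk feedstock:

* a multi-mode Maxwell model for the dynamic moduli,
      G'(w)  = sum_i g_i (w tau_i)^2 / (1 + (w tau_i)^2),
      G''(w) = sum_i g_i (w tau_i)   / (1 + (w tau_i)^2),
  fitted in log space because the data span decades;
* an Arrhenius law for the temperature dependence of the viscosity,
      eta(T) = A exp(E_act / R T),
  fitted by linear regression of ln eta on 1/T.

Both follow the Model/Results pattern: build the model from a dataset,
call ``.fit()``, inspect the returned results object.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.constants import R as GAS_CONSTANT  # J/(mol K)

__all__ = [
    "RheoDataset",
    "MaxwellSpectrum",
    "ArrheniusFit",
    "maxwell_moduli",
    "MaxwellModel",
    "MaxwellResults",
    "fit_maxwell",
    "arrhenius_viscosity",
    "ArrheniusModel",
    "ArrheniusResults",
    "fit_arrhenius",
    "synth_maxwell_data",
    "synth_arrhenius_data",
]

OSC_COLUMNS = ("omega_rad_s", "G_prime_Pa", "G_dprime_Pa")
VISC_COLUMNS = ("T_K", "eta_Pa_s")


@dataclass(frozen=True)
class RheoDataset:
    """Tabular rheology data: oscillatory (omega, G', G'') or (T, eta)."""

    omega: np.ndarray | None = None
    G_prime: np.ndarray | None = None
    G_double_prime: np.ndarray | None = None
    T: np.ndarray | None = None
    eta: np.ndarray | None = None

    def __post_init__(self) -> None:
        osc = self.omega is not None
        visc = self.T is not None
        if osc == visc:
            raise ValueError("dataset must be oscillatory XOR viscosity")
        if osc:
            if self.G_prime is None or self.G_double_prime is None:
                raise ValueError("oscillatory data needs G_prime and G_double_prime")
            w = np.asarray(self.omega, float)
            gp = np.asarray(self.G_prime, float)
            gpp = np.asarray(self.G_double_prime, float)
            if w.shape != gp.shape or w.shape != gpp.shape:
                raise ValueError("omega, G_prime, G_double_prime must align")
            if np.any(w <= 0) or np.any(gp <= 0) or np.any(gpp <= 0):
                raise ValueError("frequencies and moduli must be positive")
            if np.any(np.diff(w) <= 0):
                raise ValueError("frequency grid must be strictly increasing")
            object.__setattr__(self, "omega", w)
            object.__setattr__(self, "G_prime", gp)
            object.__setattr__(self, "G_double_prime", gpp)
        else:
            if self.eta is None:
                raise ValueError("viscosity data needs eta")
            T = np.asarray(self.T, float)
            eta = np.asarray(self.eta, float)
            if T.shape != eta.shape:
                raise ValueError("T and eta must align")
            if np.any(T <= 0) or np.any(eta <= 0):
                raise ValueError("temperatures and viscosities must be positive")
            object.__setattr__(self, "T", T)
            object.__setattr__(self, "eta", eta)

    @property
    def kind(self) -> str:
        return "oscillatory" if self.omega is not None else "viscosity"

    def truncate(self, omega_min: float) -> "RheoDataset":
        """Drop low-frequency points (e.g. the omega >= 0.4 rad/s cut)."""
        if self.kind != "oscillatory":
            raise ValueError("truncate applies to oscillatory data")
        keep = self.omega >= omega_min
        return RheoDataset(omega=self.omega[keep], G_prime=self.G_prime[keep],
                           G_double_prime=self.G_double_prime[keep])

    # -- delimited-text I/O ------------------------------------------------

    def to_csv(self, path) -> None:
        if self.kind == "oscillatory":
            df = pd.DataFrame(dict(zip(OSC_COLUMNS,
                                       (self.omega, self.G_prime,
                                        self.G_double_prime))))
        else:
            df = pd.DataFrame(dict(zip(VISC_COLUMNS, (self.T, self.eta))))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RheoDataset":
        df = pd.read_csv(path)
        cols = set(df.columns)
        if set(OSC_COLUMNS) <= cols:
            return cls(omega=df[OSC_COLUMNS[0]].to_numpy(),
                       G_prime=df[OSC_COLUMNS[1]].to_numpy(),
                       G_double_prime=df[OSC_COLUMNS[2]].to_numpy())
        if set(VISC_COLUMNS) <= cols:
            return cls(T=df[VISC_COLUMNS[0]].to_numpy(),
                       eta=df[VISC_COLUMNS[1]].to_numpy())
        raise ValueError(
            f"{path}: expected columns {OSC_COLUMNS} or {VISC_COLUMNS}, "
            f"found {sorted(cols)}")


@dataclass(frozen=True)
class MaxwellSpectrum:
    """Discrete relaxation spectrum: modes (g_i [Pa], tau_i [s])."""

    g: np.ndarray
    tau: np.ndarray

    def __post_init__(self) -> None:
        g = np.atleast_1d(np.asarray(self.g, float))
        tau = np.atleast_1d(np.asarray(self.tau, float))
        if g.shape != tau.shape or g.ndim != 1 or g.size == 0:
            raise ValueError("g and tau must be equal-length 1-D arrays")
        if np.any(g <= 0) or np.any(tau <= 0):
            raise ValueError("moduli and relaxation times must be positive")
        order = np.argsort(tau)[::-1]
        object.__setattr__(self, "g", g[order])
        object.__setattr__(self, "tau", tau[order])

    @classmethod
    def from_modes(cls, modes) -> "MaxwellSpectrum":
        g, tau = zip(*modes)
        return cls(np.asarray(g, float), np.asarray(tau, float))

    @property
    def modes(self) -> list[tuple[float, float]]:
        return list(zip(self.g.tolist(), self.tau.tolist()))

    @property
    def n_modes(self) -> int:
        return self.g.size

    def canonicalize(self, merge_ratio: float = 1.2) -> "MaxwellSpectrum":
        """Merge near-degenerate modes (tau ratio < merge_ratio)."""
        g, tau = list(self.g), list(self.tau)
        i = 0
        merged = False
        while i < len(tau) - 1:
            if tau[i] / tau[i + 1] < merge_ratio:
                gm = g[i] + g[i + 1]
                tau[i] = (g[i] * tau[i] + g[i + 1] * tau[i + 1]) / gm
                g[i] = gm
                del g[i + 1], tau[i + 1]
                merged = True
            else:
                i += 1
        if merged:
            warnings.warn("merged near-degenerate Maxwell modes", stacklevel=2)
        return MaxwellSpectrum(np.asarray(g), np.asarray(tau))


def maxwell_moduli(omega, spectrum: MaxwellSpectrum):
    """Storage and loss moduli (G', G'') of a discrete Maxwell spectrum."""
    w = np.atleast_1d(np.asarray(omega, float))
    if np.any(w <= 0):
        raise ValueError("omega must be positive")
    wt = w[:, None] * spectrum.tau[None, :]
    wt2 = wt * wt
    Gp = (spectrum.g * wt2 / (1.0 + wt2)).sum(axis=1)
    Gpp = (spectrum.g * wt / (1.0 + wt2)).sum(axis=1)
    if np.ndim(omega) == 0:
        return float(Gp[0]), float(Gpp[0])
    return Gp, Gpp


@dataclass
class MaxwellResults:
    """Fitted Maxwell spectrum with residual diagnostics."""

    spectrum: MaxwellSpectrum
    resid_norm: float        # RMS of log10-moduli residuals
    converged: bool
    message: str
    n_obs: int

    def predict(self, omega):
        return maxwell_moduli(omega, self.spectrum)

    def summary(self) -> str:
        lines = [
            f"Maxwell fit: {self.spectrum.n_modes} modes on {self.n_obs} "
            f"frequencies, RMS log10 residual {self.resid_norm:.4g}"
            + ("" if self.converged else "  [NOT CONVERGED]"),
            f"{'mode':>4} {'g [Pa]':>12} {'tau [s]':>12}",
        ]
        for i, (g, tau) in enumerate(self.spectrum.modes, 1):
            lines.append(f"{i:>4} {g:>12.4g} {tau:>12.4g}")
        return "\n".join(lines)


class MaxwellModel:
    """Least-squares multi-mode Maxwell fit on log moduli.

    The objective is the sum of squared residuals of log10 G' and
    log10 G'', equally weighted; fitting in log space keeps the terminal
    zone from being swamped by the high-frequency decades.  The mode
    count is fixed by the caller.  Optimisation is multi-start over
    log-spaced initial relaxation times.
    """

    def __init__(self, data: RheoDataset, n_modes: int = 4,
                 omega_min: float | None = None):
        if data.kind != "oscillatory":
            raise ValueError("MaxwellModel needs oscillatory data")
        if omega_min is not None:
            data = data.truncate(omega_min)
        if n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        span = data.omega[-1] / data.omega[0]
        if span < 100.0:
            raise ValueError("need at least two decades of frequency")
        self.data = data
        self.n_modes = n_modes

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(x, -150.0, 150.0)  # keep wild multistart steps finite
        g = 10.0 ** x[: self.n_modes]
        tau = 10.0 ** x[self.n_modes:]
        wt = self.data.omega[:, None] * tau[None, :]
        wt2 = wt * wt
        Gp = (g * wt2 / (1.0 + wt2)).sum(axis=1)
        Gpp = (g * wt / (1.0 + wt2)).sum(axis=1)
        return np.concatenate([
            np.log10(Gp) - np.log10(self.data.G_prime),
            np.log10(Gpp) - np.log10(self.data.G_double_prime),
        ])

    def fit(self, n_starts: int = 8, seed: int = 0) -> MaxwellResults:
        w = self.data.omega
        lo, hi = math.log10(1.0 / w[-1]), math.log10(1.0 / w[0])
        g_scale = math.log10(float(np.max(self.data.G_double_prime)))
        rng = np.random.default_rng(seed)
        best = None
        for trial in range(n_starts):
            tau0 = np.linspace(hi, lo, self.n_modes)
            g0 = np.full(self.n_modes, g_scale)
            if trial > 0:
                tau0 = tau0 + rng.uniform(-0.5, 0.5, self.n_modes)
                g0 = g0 + rng.uniform(-1.0, 0.5, self.n_modes)
            x0 = np.concatenate([g0, tau0])
            try:
                sol = optimize.least_squares(self._residuals, x0,
                                             method="lm", max_nfev=20000)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("all Maxwell fit starts failed")
        spectrum = MaxwellSpectrum(10.0 ** best.x[: self.n_modes],
                                   10.0 ** best.x[self.n_modes:])
        resid = math.sqrt(2.0 * best.cost / best.fun.size)
        converged = bool(best.success)
        if not converged:
            warnings.warn("Maxwell fit did not converge; returning best "
                          "parameters found", stacklevel=2)
        return MaxwellResults(spectrum=spectrum, resid_norm=resid,
                              converged=converged, message=best.message,
                              n_obs=w.size)


def fit_maxwell(data: RheoDataset, n_modes: int = 4, *,
                omega_min: float | None = None, n_starts: int = 8,
                seed: int = 0) -> MaxwellResults:
    return MaxwellModel(data, n_modes, omega_min).fit(n_starts=n_starts,
                                                      seed=seed)


# ---------------------------------------------------------------------------
# Arrhenius viscosity


@dataclass(frozen=True)
class ArrheniusFit:
    """eta(T) = A * exp(E_act_eta/(R T)); E in kJ/mol, A in Pa s."""

    A: float
    E_act_eta: float

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("prefactor A must be positive")


def arrhenius_viscosity(T, fit: ArrheniusFit):
    """Viscosity [Pa s] at temperature(s) T [K]."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    out = fit.A * np.exp(fit.E_act_eta * 1e3 / (GAS_CONSTANT * T))
    return float(out) if out.ndim == 0 else out


@dataclass
class ArrheniusResults:
    """Flow activation energy from ln(eta) vs 1/T regression."""

    fit: ArrheniusFit
    se_E: float              # standard error of E [kJ/mol]
    se_lnA: float
    r_squared: float
    n_obs: int

    @property
    def A(self) -> float:
        return self.fit.A

    @property
    def E_act_eta(self) -> float:
        return self.fit.E_act_eta

    def predict(self, T):
        return arrhenius_viscosity(T, self.fit)

    def summary(self) -> str:
        return (
            f"Arrhenius fit on {self.n_obs} temperatures\n"
            f"  E_act,eta = {self.E_act_eta:.3g} +/- {self.se_E:.2g} kJ/mol\n"
            f"  A         = {self.A:.4g} Pa s (se of ln A {self.se_lnA:.2g})\n"
            f"  R^2(ln eta ~ 1/T) = {self.r_squared:.5f}"
        )


class ArrheniusModel:
    """Linear regression of ln(eta) on 1/T."""

    def __init__(self, data: RheoDataset):
        if data.kind != "viscosity":
            raise ValueError("ArrheniusModel needs (T, eta) data")
        if data.T.size < 3:
            raise ValueError("need at least 3 temperature points")
        self.data = data

    def fit(self) -> ArrheniusResults:
        x = 1.0 / self.data.T
        y = np.log(self.data.eta)
        reg = stats.linregress(x, y)
        E = reg.slope * GAS_CONSTANT / 1e3     # kJ/mol
        return ArrheniusResults(
            fit=ArrheniusFit(A=math.exp(reg.intercept), E_act_eta=E),
            se_E=reg.stderr * GAS_CONSTANT / 1e3,
            se_lnA=reg.intercept_stderr,
            r_squared=reg.rvalue ** 2,
            n_obs=self.data.T.size,
        )


def fit_arrhenius(data: RheoDataset) -> ArrheniusResults:
    return ArrheniusModel(data).fit()


# ---------------------------------------------------------------------------
# Synthetic-data generators (test fixtures for the fitting paths)


def synth_maxwell_data(spectrum: MaxwellSpectrum, omega,
                       noise_level: float = 0.0,
                       seed: int | None = 0) -> RheoDataset:
    """Oscillatory moduli from a spectrum with multiplicative log-normal noise.

    ``noise_level`` is the standard deviation of the log residuals;
    deterministic for a fixed seed.
    """
    w = np.asarray(omega, dtype=float)
    Gp, Gpp = maxwell_moduli(w, spectrum)
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        Gp = Gp * np.exp(noise_level * rng.standard_normal(w.size))
        Gpp = Gpp * np.exp(noise_level * rng.standard_normal(w.size))
    return RheoDataset(omega=w, G_prime=Gp, G_double_prime=Gpp)


def synth_arrhenius_data(fit: ArrheniusFit, T, noise_level: float = 0.0,
                         seed: int | None = 0) -> RheoDataset:
    """Arrhenius viscosities with multiplicative log-normal noise."""
    T = np.asarray(T, dtype=float)
    eta = arrhenius_viscosity(T, fit)
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        eta = eta * np.exp(noise_level * rng.standard_normal(T.size))
    return RheoDataset(T=T, eta=eta)
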