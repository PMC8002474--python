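"""Gaussian-chain theory of sticker registration.

A chain of ``Ze`` entanglement strands stretched by a factor ``lambda``
has tube contour length <R> = a*lambda*Ze with Gaussian fluctuations of
relative width 1/sqrt(3*lambda*Ze).  Applying the same statistics to the
substrand joining a sticker to its n-th neighbour gives a sum of
Gaussians whose normalised superposition is the sticker pair-correlation
function along the flow direction: flat at lambda = 1, increasingly
oscillatory ("crystal-like") as the chain stretches.  Chain-end effects
are ignored (the n-sum runs over an unbounded chain).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CorrelationCurve",
    "contour_pdf",
    "contour_cv",
    "sticker_correlation",
]


@dataclass(frozen=True)
class CorrelationCurve:
    """Sticker correlation C(r) on a radial grid, with its parameters."""

    r: np.ndarray       # distances from a sticker [nm]
    C: np.ndarray       # correlation values, -> 1 at large r
    lam: float          # stretch ratio
    Zs: int
    Ze: int
    a: float            # tube diameter [nm]
    n_max: int          # truncation order of the neighbour sum

    def first_peak(self) -> tuple[float, float]:
        """(location, height) of the first local maximum of C."""
        C = self.C
        interior = np.flatnonzero((C[1:-1] > C[:-2]) & (C[1:-1] >= C[2:])) + 1
        if interior.size == 0:
            i = int(np.argmax(C))
            return float(self.r[i]), float(C[i])
        i = int(interior[0])
        return float(self.r[i]), float(C[i])


def contour_pdf(R, mean: float, sigma: float):
    """Gaussian density of the tube contour length (equilibrium CLF statistics)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return stats.norm.pdf(R, loc=mean, scale=sigma)


def contour_cv(lam: float, Ze: int) -> float:
    """Relative contour-length fluctuation sigma_R/<R> = 1/sqrt(3*lambda*Ze).

    Decreasing in both arguments: fluctuations become irrelevant for long
    or strongly stretched chains.
    """
    if lam <= 0:
        raise ValueError("stretch ratio must be positive")
    if Ze < 1:
        raise ValueError("Ze must be >= 1")
    return 1.0 / math.sqrt(3.0 * lam * Ze)


def sticker_correlation(r_grid, lam: float, Ze: int, Zs: int, a: float,
                        n_max: int | None = None, *,
                        sigma_scale: float = 1.0) -> CorrelationCurve:
    """Sticker correlation function C(r) of the stretched Gaussian chain.

    The n-th neighbour sticker sits at mean distance
    R_n = n*a*lambda*Ze/(Zs+1) with standard deviation
    sigma_n = a*sqrt(n*lambda*Ze/(3*(Zs+1))) (the contour-fluctuation rule
    applied to a fraction n/(Zs+1) of the chain; ``sigma_scale`` rescales
    all widths, e.g. sqrt(2) for the alternative width convention).  The
    self-term n = 0 is excluded and negative n contribute through the
    mirrored Gaussian.  Normalisation by the asymptotic sticker line
    density M = (Zs+1)/(a*lambda*Ze) makes C -> 1 at large r.
    """
    r = np.asarray(r_grid, dtype=float)
    if r.ndim != 1 or r.size < 2:
        raise ValueError("r_grid must be a 1-D grid")
    if np.any(r <= 0) or np.any(np.diff(r) <= 0):
        raise ValueError("r_grid must be positive and strictly ascending")
    if lam <= 0 or a <= 0:
        raise ValueError("lam and a must be positive")
    if Ze < 1 or Zs < 0:
        raise ValueError("need Ze >= 1 and Zs >= 0")
    if sigma_scale <= 0:
        raise ValueError("sigma_scale must be positive")

    R1 = a * lam * Ze / (Zs + 1)
    if n_max is None:
        # smallest truncation whose last term is >~6 sigma past the grid edge
        n_max = max(Zs + 1, int(np.ceil(r[-1] / R1)) + 1)
        while (n_max * R1 < r[-1] + 6.0 * sigma_scale * a
               * math.sqrt(n_max * lam * Ze / (3.0 * (Zs + 1)))):
            n_max += 1
    if n_max < Zs + 1:
        raise ValueError(f"n_max={n_max} smaller than Zs+1={Zs + 1}")
    sigma_edge = sigma_scale * a * math.sqrt(n_max * lam * Ze / (3.0 * (Zs + 1)))
    if n_max * R1 < r[-1] + 6.0 * sigma_edge:
        warnings.warn(
            f"n_max={n_max} may be too small to converge C(r) at the grid "
            f"edge r={r[-1]:g}; increase n_max", stacklevel=2)

    n = np.arange(1, n_max + 1)[:, None]
    Rn = n * R1
    sigma_n = sigma_scale * a * np.sqrt(n * lam * Ze / (3.0 * (Zs + 1)))
    # positive and mirrored negative neighbours
    dens = (stats.norm.pdf(r[None, :], loc=Rn, scale=sigma_n)
            + stats.norm.pdf(-r[None, :], loc=Rn, scale=sigma_n)).sum(axis=0)
    M = (Zs + 1) / (a * lam * Ze)
    return CorrelationCurve(r=r, C=dens / M, lam=lam, Zs=Zs, Ze=Ze, a=a,
                            n_max=int(n_max))
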