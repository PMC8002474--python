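"""Molecular parameters of the coarse-grained sticky-tube chain and derived scales.

The chain is described by ``N`` Kuhn monomers of length ``b``, confined to an
entanglement tube with ``Ze`` entanglement strands, and decorated with ``Zs``
reversibly binding stickers.  All user-facing lengths are in nm, times in
seconds; the Brownian-dynamics modules work in reduced units (kBT = 1, a = 1,
tau_e = 1) and convert at their boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

__all__ = [
    "ChainParams",
    "DerivedScales",
    "FlowConditions",
    "radius_of_gyration",
    "tube_diameter",
    "max_stretch_ratio",
    "relaxation_times",
    "stability_timestep",
    "derive_scales",
    "scaled_params",
]


@dataclass(frozen=True)
class ChainParams:
    """Molecular parameters of one chain species.

    Defaults describe the native *Bombyx mori* silk feedstock: a fibroin
    chain of 5524 amino acids (Kuhn length 0.4 nm) with ten entanglements
    and five calcium-bridge stickers, a quiescent sticker lifetime of
    10 ms against an entanglement time of 0.1 us, 90% of stickers closed
    at rest, and a Bell-type dissociation barrier of 8 kBT.
    """

    N: int = 5524              # Kuhn monomers per chain
    b: float = 0.4             # Kuhn length [nm]
    Ze: int = 10               # entanglements per chain
    Zs: int = 5                # stickers per chain
    tau_e: float = 1e-7        # entanglement relaxation time [s]
    tau_s0: float = 1e-2       # quiescent sticker lifetime [s]
    p: float = 0.9             # quiescent closed-sticker fraction
    E_act0: float = 8.0        # sticker activation energy [kBT]
    ell: float = 0.1           # sticker dissociation length [nm]
    kbs: float = 0.0           # bond-swap rate coefficient (off by default)

    def __post_init__(self) -> None:
        if self.N < 1 or self.Ze < 1:
            raise ValueError("need N >= 1 and Ze >= 1")
        if self.N < self.Ze:
            raise ValueError(
                f"Ze={self.Ze} exceeds N={self.N}: a chain cannot have more "
                "entanglements than monomers"
            )
        if self.Zs < 0:
            raise ValueError("Zs must be >= 0")
        if self.tau_e <= 0 or self.tau_s0 <= 0:
            raise ValueError("relaxation times must be positive")
        if not 0.0 <= self.p < 1.0:
            raise ValueError(f"closed fraction p={self.p} outside [0, 1)")
        if self.ell <= 0:
            raise ValueError("dissociation length ell must be positive")
        if self.E_act0 < 0:
            raise ValueError("activation energy must be >= 0")
        if self.kbs < 0:
            raise ValueError("bond-swap rate must be >= 0")

    def replace(self, **kw) -> "ChainParams":
        return replace(self, **kw)

    def asdict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    # Convenience accessors -------------------------------------------------

    @property
    def tube_diameter(self) -> float:
        """Tube diameter a = b*sqrt(N/Ze) [nm]."""
        return tube_diameter(self.N, self.b, self.Ze)

    @property
    def lambda_max(self) -> float:
        """Maximum stretch ratio relative to the aligned-tube state."""
        return max_stretch_ratio(self.N, self.Ze)

    def scales(self, *, alpha: float = 10.0, tau0: float | None = None,
               nu: float = 0.5, n_beads_per_strand: int = 3) -> "DerivedScales":
        return derive_scales(self, alpha=alpha, tau0=tau0, nu=nu,
                             n_beads_per_strand=n_beads_per_strand)


@dataclass(frozen=True)
class DerivedScales:
    """Every length and time scale derived from :class:`ChainParams`."""

    a: float            # tube diameter [nm]
    lambda_max: float   # maximum stretch ratio
    Rg: float           # radius of gyration [nm]
    Re: float           # equilibrium end-to-end distance [nm]
    L_full: float       # fully extended contour length N*b [nm]
    tau_R: float        # bare Rouse time tau_e*Ze^2 [s]
    tau_SR: float       # sticky Rouse time tau_s0*Zs^2 [s]
    tau_rep: float      # reptation time tau_s0*Zs^2*Ze/alpha [s]
    tau_Zimm: float     # dilute Zimm time tau0*N^(3 nu) [s]
    dt_max: float       # explicit-Euler stability bound [s]

    def as_rows(self) -> list[tuple[str, float, str]]:
        return [
            ("a", self.a, "nm"),
            ("lambda_max", self.lambda_max, ""),
            ("Rg", self.Rg, "nm"),
            ("Re", self.Re, "nm"),
            ("L_full", self.L_full, "nm"),
            ("tau_R", self.tau_R, "s"),
            ("tau_SR", self.tau_SR, "s"),
            ("tau_rep", self.tau_rep, "s"),
            ("tau_Zimm", self.tau_Zimm, "s"),
            ("dt_max", self.dt_max, "s"),
        ]


@dataclass(frozen=True)
class FlowConditions:
    """A flow protocol characterised by its Weissenberg numbers.

    ``Wi_bare`` uses the bare Rouse time tau_e*Ze^2; ``Wi_sticky`` the sticky
    Rouse time tau_s0*Zs^2, which is the group that controls stretching of the
    associating chain.
    """

    kind: str                  # "extension" or "shear"
    rate: float                # strain rate [1/s]
    Wi_bare: float = field(default=0.0)
    Wi_sticky: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("extension", "shear"):
            raise ValueError(f"unknown flow kind {self.kind!r}")
        if self.rate < 0:
            raise ValueError("strain rate must be >= 0")

    @classmethod
    def from_rate(cls, params: ChainParams, kind: str, rate: float) -> "FlowConditions":
        tau_R = params.tau_e * params.Ze ** 2
        tau_SR = params.tau_s0 * params.Zs ** 2
        return cls(kind=kind, rate=rate, Wi_bare=rate * tau_R,
                   Wi_sticky=rate * tau_SR)


# ---------------------------------------------------------------------------
# Operations


def radius_of_gyration(N: int, b: float) -> float:
    """Ideal-chain (theta-solvent) radius of gyration b*sqrt(N/6) [nm]."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if b <= 0:
        raise ValueError("Kuhn length must be positive")
    return b * math.sqrt(N / 6.0)


def tube_diameter(N: int, b: float, Ze: int) -> float:
    """Entanglement tube diameter a = b*sqrt(N/Ze) [nm]."""
    if Ze < 1:
        raise ValueError("Ze must be >= 1")
    if N < Ze:
        raise ValueError(
            f"Ze={Ze} exceeds N={N}: fewer than one monomer per "
            "entanglement strand"
        )
    if b <= 0:
        raise ValueError("Kuhn length must be positive")
    return b * math.sqrt(N / Ze)


def max_stretch_ratio(N: int, Ze: int) -> float:
    """Maximum stretch ratio N*b/(Ze*a) = sqrt(N/Ze).

    Defined relative to the aligned-tube state (contour length a*Ze); no
    additional pre-stretch factor is applied.
    """
    if Ze < 1:
        raise ValueError("Ze must be >= 1")
    if N < Ze:
        raise ValueError(f"Ze={Ze} exceeds N={N}")
    return math.sqrt(N / Ze)


def relaxation_times(params: ChainParams, *, alpha: float = 10.0,
                     tau0: float | None = None, nu: float = 0.5) -> dict:
    """Rouse, sticky-Rouse, reptation and Zimm times [s].

    Parameters
    ----------
    alpha : contour-length-fluctuation parameter in the reptation-time
        estimate tau_rep = tau_s0*Zs^2*Ze/alpha.
    tau0 : monomeric relaxation time; if None it is inferred from
        tau_R = tau0*N^2 = tau_e*Ze^2.
    nu : solvent-quality exponent for the Zimm time tau0*N^(3 nu)
        (1/3 poor, 1/2 theta, 0.585 good).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if not 0.3 < nu < 0.6:
        raise ValueError("nu outside the physical range (0.3, 0.6)")
    tau_R = params.tau_e * params.Ze ** 2
    if tau0 is None:
        tau0 = tau_R / params.N ** 2
    if tau0 <= 0:
        raise ValueError("tau0 must be positive")
    tau_SR = params.tau_s0 * params.Zs ** 2
    return {
        "tau_R": tau_R,
        "tau_SR": tau_SR,
        "tau_rep": params.tau_s0 * params.Zs ** 2 * params.Ze / alpha,
        "tau_Zimm": tau0 * params.N ** (3.0 * nu),
    }


def stability_timestep(tau_e: float, n_beads_per_strand: int) -> float:
    """Explicit-Euler stability bound 12*tau_e/(pi*(n_beads+1))^2 [s].

    ``n_beads_per_strand`` counts the beads discretising one entanglement
    strand; the bound is the strand-level criterion and is independent of
    chain length.
    """
    if tau_e <= 0:
        raise ValueError("tau_e must be positive")
    if n_beads_per_strand < 0:
        raise ValueError("n_beads_per_strand must be >= 0")
    return 12.0 * tau_e / (math.pi * (n_beads_per_strand + 1)) ** 2


def derive_scales(params: ChainParams, *, alpha: float = 10.0,
                  tau0: float | None = None, nu: float = 0.5,
                  n_beads_per_strand: int = 3) -> DerivedScales:
    """Assemble the full :class:`DerivedScales` table for one parameter set."""
    a = tube_diameter(params.N, params.b, params.Ze)
    times = relaxation_times(params, alpha=alpha, tau0=tau0, nu=nu)
    Rg = radius_of_gyration(params.N, params.b)
    return DerivedScales(
        a=a,
        lambda_max=max_stretch_ratio(params.N, params.Ze),
        Rg=Rg,
        Re=math.sqrt(6.0) * Rg,
        L_full=params.N * params.b,
        dt_max=stability_timestep(params.tau_e, n_beads_per_strand),
        **times,
    )


def scaled_params(ratio: float = 100.0, **overrides) -> ChainParams:
    """Desk-scale parameter set in reduced time units (tau_e = 1).

    The physical sticker-to-entanglement lifetime ratio tau_s0/tau_e = 1e5
    makes direct simulation long-running; the desk default compresses it to
    ``ratio`` (100) while keeping every other silk parameter, so the regime
    ordering tau_e << tau_R << tau_SR survives.
    """
    kw = dict(tau_e=1.0, tau_s0=float(ratio))
    kw.update(overrides)
    return ChainParams(**kw)
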