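# Methods

## The model

A single entangled chain is reduced to its curvilinear coordinate along
an aligned entanglement tube.  The chain has `N` Kuhn segments of
length `b`, `Ze` entanglement strands (tube diameter `a = b√(N/Ze)`,
rest tube length `a·Ze`) and `Zs` associating stickers.  Bead
coordinates R_i obey the overdamped Langevin equation

    ζ dR_i/dt = F_thermal,i + F_conf,i + ε̇ ζ (R_i − R_cm),

with ⟨F_th⟩ = 0, ⟨F_th(t) F_th(t′)⟩ = 2 kBT ζ δ(t−t′), and the
conformational force the discrete divergence of the bond tension
κ k_s Δ R.  The finite-extensibility factor

    k_s(λ) = [(3λ_max² − λ²)/(λ_max² − λ²)] / [(3λ_max² − 1)/(λ_max² − 1)]

is normalised to 1 at unit stretch and diverges as the local bond
stretch approaches λ_max = √(N/Ze) (defined relative to the
aligned-tube state; no extra pre-stretch factor).  Fixed-gradient
boundary conditions ∂R/∂i = a·Ze/N_bonds are imposed through ghost
bonds of rest length at both ends, representing the equilibrium tension
with which the tube re-feeds the chain ends.

A **closed sticker is kinetically trapped**: it neither diffuses nor
responds to spring forces, and only advects with the flow.  We apply
the trapping to both the conformational *and* the thermal force (a
pinned sticker cannot diffuse); `literal_eq5=True` restores the variant
in which only the conformational force is switched off.  Stickers close
at a constant rate and open at a Bell rate

    k_open = ν exp(−max(0, E_act0 − ℓ·F)),   ν = e^{E_act0}/τ_s0,

where `F` is the magnitude of the net conformational force at the
sticker bead and `ℓ` the dissociation length.  The rate therefore
saturates at ν once ℓF ≥ E_act0; equivalently the stretch-dependent
lifetime τ_s(λ) = τ_s0 exp(−3(ℓ/a) k_s λ) is floored at
τ_s0 e^{−E_act0}.  Transition probabilities per step use the exact
exponential form 1 − exp(−k·Δt).

Per-sticker rates at quiescence are k_open = 1/τ_s0 and
k_close = k_open·p/(1−p): detailed balance of the tagged two-state
sticker then gives a closed fraction exactly `p`.  (The ensemble rate
algebra of the association–dissociation network carries an additional
pair-stoichiometry factor — at equilibrium k_close(1−p) = 2 k_open p —
because one association event closes two stickers; it is implemented
separately, together with the bond-swap channel, for the analytic rate
curves.)  Bond swapping is disabled in all simulations (`kbs = 0`).

## Reduced units and the discretisation mapping

Internally kBT = 1, a = 1, τ_e = 1.  With N_bonds = Ze·(n_b + 1) bonds
(n_b beads per entanglement strand), the mapping

    κ = 3 N_bonds / Ze,   ζ = 3π² Ze / N_bonds,   dR_eq = Ze / N_bonds

reproduces (i) the equilibrium contour variance a²Ze/3, i.e. the
relative contour fluctuation 1/√(3Ze) ≈ 0.183 for Ze = 10; (ii) a
strand relaxation time τ_e; and (iii) a chain stretch-relaxation (Rouse)
time Ze²τ_e.  The explicit-Euler step obeys the strand stability bound
Δt < 12 τ_e/[π(n_b+1)]², and is additionally capped adaptively at
0.1/k for the fastest current sticker rate (including its e^{E_act0}
saturation value) and shrunk near the FENE divergence, where an
overshooting step is rejected and retried at Δt/2.

**Choice of discretisation.**  The steady ensemble-mean stretch of the
harmonic chain under extension has a closed form.  In the continuum
limit it is λ(Wi) = tan(x)/x with x = (π/2)√Wi (Wi = ε̇ τ_R), which
lies below the pre-averaged single-mode law 1/(1 − Wi) by up to 16% at
Wi = 0.75; a dumbbell (one internal mode) reproduces 1/(1 − Wi)
exactly.  A discrete chain interpolates between the two.  The default
`n_beads_per_strand = 3` resolves sub-strand relaxation while keeping
the low-mode stretch response within ~4% of the single-mode law over
Wi ≤ 0.75 (exact values 1.299, 1.926, 4.102 at Wi = 0.25, 0.5, 0.75,
solved by linear algebra and used as a simulator oracle in the tests).
Finer discretisations converge to tan(x)/x; users comparing against
single-mode predictions at high Wi should be aware of this model
property.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| N | Kuhn segments per chain | 5524 | — |
| b | Kuhn length | 0.4 | nm |
| Ze | entanglements per chain | 10 | — |
| Zs | stickers per chain | 5 | — |
| τ_e | entanglement relaxation time | 1e−7 | s |
| τ_s0 | quiescent sticker lifetime | 1e−2 | s |
| p | quiescent closed fraction | 0.9 | — |
| E_act0 | dissociation barrier | 8 | kBT |
| ℓ | dissociation length | 0.1 (range 0.1–100) | nm |

Energies are carried in kBT units; temperature never appears in the
simulator.  The solvent exponent ν enters only the Zimm-time estimate
(default 1/2, θ conditions); concentration dependence of a and Ze is
out of scope.

## Desk-scale study conditions

The physical lifetime ratio τ_s0/τ_e = 10⁵ puts the sticky Rouse time
five decades above the integration step; direct simulation at that
ratio is impractically long for routine runs.  `scaled_params()`
therefore compresses the ratio to τ_s0/τ_e = 100 (keeping every other
silk parameter), which preserves the ordering
τ_e ≪ τ_R = 100 τ_e ≪ τ_SR = 2500 τ_e.  Consequences to keep in mind:

* the sticky/bare separation is τ_SR/τ_R = 25 instead of 2.5·10⁴, so at
  sticky Weissenberg numbers ε̇τ_SR ≳ 1 the *baseline* stretch of a
  momentarily free chain is already 1.3–1.6.  High-stretch tails are
  therefore heavier than the mean-fitted Gaussian reference by factors
  of order 2–10, not by the many orders of magnitude expected at the
  physical ratio where free chains relax fully to λ ≈ 1;
* the orderings are robust at desk scale and are what the tests assert:
  tail mass grows with rate, and the stretch distribution truncates
  near λ_max for small ℓ (finite-extensibility-triggered dissociation)
  but at much smaller stretch for ℓ = 100 nm (99th-percentile ratio
  ≈ 7 between ℓ = 0.1 nm and ℓ = 100 nm runs).

The shear dumbbell similarly uses τ_s0 = 100 τ_R (physical ratio 1000)
so that an open interval (1−p)τ_s0/p ≈ 11 τ_R comfortably exceeds the
relaxation time — chains relax fully between binding events, producing
the characteristic peak at λ = 1 coexisting with a broad stretched
component beyond the sticky Weissenberg number γ̇τ_R/(1−p) = 1.

Typical test/acceptance ensembles are 40–1000 chains sampled over a few
terminal times; these sizes put Monte-Carlo errors comfortably inside
the asserted tolerances.

## Synthetic rheology data

The fitting paths are exercised on generated fixtures: Maxwell moduli
on the experimental frequency window 0.13–126 rad/s from a four-mode
spectrum of feedstock-like magnitudes, and Arrhenius viscosities with
activation energies in the tens of kJ/mol, both with multiplicative
log-normal noise of set level.  The generators emulate the *format and
noise character* of cone-plate oscillatory and temperature-ramp data;
they do not emulate instrument compliance, inertia artefacts,
evaporation drift or the onset of flow-induced gelation, so passing
recovery tests demonstrates correctness of the fitting machinery, not
robustness to every failure mode of real rheometry.  A config flag
reproduces the ω ≥ 0.4 rad/s truncation used when comparing against
terminal-zone-sensitive models.  The sticky-reptation linear
viscoelasticity model itself is not implemented; only the derived
reptation-time formula τ_rep = τ_s Zs² Ze/α is exposed.

## Numerical choices

* Maxwell fits minimise squared residuals of log10 G′ and log10 G″
  (equal weight) with multi-start Levenberg–Marquardt over log-spaced
  initial relaxation times; mode count is fixed by the caller, and
  near-degenerate recovered modes (τ ratio < 1.2) are merged with a
  warning.
* Arrhenius fits are ordinary linear regression of ln η on 1/T; the
  activation energy is the slope times the gas constant (kJ/mol).
* The registration sum truncates at the smallest n_max whose last term
  lies ≳6σ past the grid edge; normalisation uses the analytic sticker
  line density (Zs+1)/(aλZe) rather than tail rescaling, so C(r) → 1
  exactly as r → ∞.  The width convention σ_n = a√(nλZe/3(Zs+1)) is
  used; `sigma_scale` exposes the alternative (e.g. √2) convention.
  The n = 0 self-term is excluded.
* All randomness flows from one `numpy.random.SeedSequence` per run;
  replicas are lockstep-vectorised, and outputs are reproducible from
  (config, seed).
* Degenerate inputs fail loudly: Ze > N, p outside [0,1), λ ≥ λ_max,
  non-monotone frequency grids and malformed data rows raise with the
  offending field or line number.

## Known limitations

* The tube is one-dimensional and pre-aligned: no reptation-driven tube
  renewal, no constraint release, no 3D orientation dynamics, and no
  tensorial stress — the shear model is explicitly a toy.
* The extensional steady state of the *multimode* harmonic chain
  deviates from the single-mode law 1/(1 − Wi) near Wi → 1 (see the
  discretisation note above).
* Force-accelerated dissociation uses the net discrete bead force,
  whose fluctuation amplitude grows with refinement (√κ); comparisons
  across discretisations should hold ℓ·√(2κ) in mind.  The analytic
  lifetime formula uses the smooth tension 3 kBT k_s λ/a instead.
* Desk-scale lifetime ratios compress the regime separation as
  described; quantitative tail exponents at the physical ratio are out
  of desk reach.
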