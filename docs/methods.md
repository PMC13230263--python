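# Methods

`rbcdem` simulates dilute suspensions of red blood cells (RBCs) in
microchannels with an unresolved CFD–DEM approach: the plasma is a continuum
solved by a finite-volume method on a structured grid, each RBC is a sub-grid
sphere of equivalent volume tracked by a discrete element method, and the
physics lost by not resolving the membrane — deformation, deformability-aware
drag and lift — is reintroduced through closure correlations fitted on
resolved single-cell simulations. This note records the model, its numerical
realization, the choices made where the design was open, and what the built-in
validations do and do not demonstrate.

## Closure models and their envelope

Three quantities are modelled per cell from the local dimensionless flow
state, with γ̇⁺ = γ̇R_c²/ν the dimensionless shear rate, u_r⁺ = (u_p−u)·ê/u_av
the signed dimensionless slip and Re_p = d_p|u_p−u|/ν the particle Reynolds
number:

* deformation index
  DI = γ̇⁺³ / (γ̇⁺³(10 + u_r⁺³) + 0.117 γ̇⁺²(u_r⁺ − u_r⁺⁴) + 0.0026),
  clamped to [10⁻³, 0.999]; a non-positive denominator (outside the fitted
  range) returns the floor with a warning rather than extrapolating;
* drag coefficient C_d = (169 Re_p²(DI+1) + 0.00146)/Re_p³;
* lift coefficient C_l = −3.19 DI⁴/Re_p + 2.48 DI/Re_p + 0.0008 Re_p/DI³.

Forces: F_drag = 0.125 C_d ρ π d_p² |u−u_p|(u−u_p) and
F_lift = C_l ρ d_p⁴ (γ̇² + |u_p−u|²/d_p²) r̂, with r̂ the unit vector from the
particle toward the channel axis. The fit does not state the orientation of
r̂; pointing it centerward makes the dominant positive C_l term drive the
migration that produces the cell-free layer, which is the only convention
consistent with the Fåhraeus–Lindqvist validation.

The correlations are rational fits valid on the campaign envelope
γ̇⁺ ∈ [0.02, 0.35], Re_p ∈ [0.01, 0.12], |u_r⁺| ≤ 1, which maps to
DI ∈ [~0.003, ~0.12]. Outside that envelope the raw expressions are not just
inaccurate but dynamically destructive:

* C_d → 0.00146/Re_p³ as Re_p → 0, so the drag *force* diverges as 1/|slip|
  and a freely advected cell would be rigidly locked to the fluid — no lateral
  migration, no Fåhraeus effect;
* 0.0008 Re_p/DI³ diverges as DI → 0; at small DI the lift grows like slip³
  while the drag grows like slip², an unconditional feedback runaway for
  near-axis cells.

`ClosureModel` therefore evaluates the *coefficients* with (DI, Re_p) clamped
into the envelope box and caps the slip magnitude entering both coefficients
and force formulas at u_av (|u_r⁺| ≤ 1), while the force formulas keep the
true slip *direction*, so forces vanish smoothly with vanishing slip. These
clamps are the single most consequential numerical decision in the package;
all defaults are exposed on `ClosureModel`.

The reported DI (population statistics, snapshots) is the clamped-to-[10⁻³,
0.999] value, not the envelope-boxed one used for coefficients.

## Fluid solver

The plasma obeys the volume-fraction incompressible Navier–Stokes equations
(∂φ/∂t + ∇·(φu) = 0 and the φ-weighted momentum equation with −φ∇p, φμ∇²u and
the exchange term −R_pf, i.e. a "Model A"-like form with φ outside the
operators). Discretization:

* staggered structured grid, axisymmetric (r, z) for cylindrical channels or
  planar (y, z) with solid masks for branched/constricted demos; DEM particles
  live in full 3D inside the true geometry and particle–grid transfers are
  azimuthally averaged in axisymmetric mode;
* periodic streamwise boundaries driven by a constant axial body force φG
  standing in for the mean pressure gradient;
* implicit diffusion and implicit exchange diagonal (backward Euler), explicit
  first-order upwind advection (advection is negligible at Re ≤ 0.5 in fully
  developed flow);
* wall shear discretized with a quadratic three-point wall flux, which makes
  the scheme nodally exact for parabolic profiles — the Hagen–Poiseuille
  benchmark is recovered to machine precision at any resolution, so the
  relative-viscosity metric carries no discretization bias from the reference
  flux;
* PISO-style predictor plus two pressure-correction passes; the
  variable-coefficient Poisson system (face mobilities φ/(ρφ/Δt + K)) is
  solved by sparse LU with the pressure gauge pinned and iterative refinement,
  verified to 10⁻⁸ relative residual each pass;
* Courant numbers above 1 and non-converged pressure solves raise immediately
  rather than degrade silently; the operating Courant target is 0.15.

The fluid volume fraction is clamped below at 0.3 to keep the momentum matrix
well conditioned under local crowding.

## Particle phase

Spheres of the RBC-equivalent volume (d_p = 5.6 μm, ~90 fL; the undeformed
discocyte diameter 7.82 μm is *not* the right sphere diameter) with
ρ_p = 1100 kg/m³, m = ρ_p π d³/6, I = m d²/10. Velocity-Verlet integration
with Hertz–Mindlin soft-sphere contacts: Hertz normal stiffness, damping set
by the restitution coefficient, tangential spring with history capped by
Coulomb friction, and walls treated as rigid bodies of infinite mass. The DEM
step obeys Δt_DEM < 0.1·min(t_Ray, t_Her) with the Rayleigh time
t_Ray = πR√(ρ_p/G)/(0.1631ν_P + 0.8766) and the Hertz pair-contact time
t_Her = 2.87(m_eff²/(R_eff E*² v))^0.2 (v floored at the bulk velocity).

The closure drag is far stiffer than any contact (cell–fluid relaxation time
~10⁻⁷ s): inside each substep the drag plus the frozen lift/pressure/viscous
forces are integrated with the exact constant-coefficient relaxation toward
u_eq = u_f + F_other/β, so a cell approaches its equilibrium velocity
monotonically and can never overshoot it regardless of Δt. Contacts remain in
the symplectic half-kicks (an e = 1 head-on impact conserves energy to <1% at
Δt = t_Her/50).

Contact parameters are a soft-cell surrogate: `ContactParams` defaults to
E = 1 kPa (Poisson 0.3, e = 0.5, μ_f = 0.1), but the packaged straight-channel
benchmark raises the stiffness to E = 5 kPa. The stiffness is not a free
runtime knob: the lift-compressed, sheared cell core carries drag-driven
contact-chain loads of order 10⁻⁹ N per contact, and at 1 kPa and below those
loads push overlaps to more than half a diameter — volume exclusion collapses
entirely (the union volume of the cells drops to a quarter of the summed
volumes) and every volume-based metric degrades. At 5 kPa overlaps stay near
4% and the union/sum ratio is 1.01. Softer values only buy time step; the
benchmark accepts the smaller Rayleigh step (≈0.7 μs) and compensates with a
longer coupling interval (n_coupling = 134) so the CFD step sits at the
Courant target (0.2 for the benchmark, the upper end of common practice).

## Coupling

Per coupling step (Δt_CFD = n_coupling Δt_DEM, default n_coupling = 10):
deposit the void fraction, interpolate the fields to the particle centres,
evaluate the closures and the four-term fluid force
(F_pressure = −V_p∇p with the periodic pressure field, F_viscous = V_p μ∇²u,
plus closure drag and lift), assemble the momentum-exchange field, advance the
fluid, then run the DEM substeps against the post-advance fluid velocity
(Gauss–Seidel staggering, which damps the mutual relaxation mode of the tight
cell–fluid coupling).

Because the channel is driven by a body force on the fluid phase, the mean
driving gradient does not act on the particles; the particle phase is instead
retarded by F_viscous ≈ −V_p G, sustains a small axial slip, and the exchange
sink this produces is precisely what raises the apparent viscosity above the
pure-plasma value. This is the mechanism by which the model reproduces the
Pries μ_rel.

Deposition uses a divided scheme — 32 equal-weight satellite points filling
each sphere, binned to (r, z) cells, one conservative smoothing pass — and the
void fraction is relaxed in time at the rate a particle transits its own
diameter, preventing impulsive continuity sources in the near-axis rings whose
volume is smaller than a particle.

The exchange coefficient follows
K = |Σ(F_drag + F_lift)| / (V_cell |u − ⟨u_p⟩|) (norm of the vector sum,
denominator regularized by ε_u = 10⁻¹² m/s) with the slip measured between the
fluid interpolated at the particles and the particle mean. Two adjustments
make this robust on grids that under-resolve the particle:

* the implicit coefficient actually applied is capped at 10 ρφ/Δt — beyond
  that it only means "relax fully within one step" while destroying the
  pressure-correction mobility;
* the explicit side uses u_p,eff = ⟨u_p⟩ + (u_cell − ⟨u@p⟩): in the strict
  unresolved limit (cells ≫ particles) this is identical to ⟨u_p⟩, and on fine
  grids it removes the spurious shear contribution of the cell/particle scale
  mismatch, so the quasi-steady exchange equals the summed closure forces —
  the momentum audit (fluid momentum removed vs. drag impulse) holds to <1%.

## Metrics and steadiness

Fluxes are measured on a fixed interior cross-section: plasma as Σφu_zA over
the plane, cells by counting signed particle crossings weighted by V_p. Then
Ht_d = ⟨Q_RBCs⟩/⟨Q_blood⟩ and μ_rel = Q_plasma,theory/⟨Q_blood⟩ with
Q_plasma,theory = πGR⁴/8μ the Hagen–Poiseuille flux at the case's driving.
The Pries reference correlations (diameter in micrometers) supply Ht_d and
μ_rel benchmarks, compared via the percentage error 100|x_sim − x_ref|/x_ref.
A run is steady when Ht_d and μ_rel drift by <1% between two consecutive
windows of 20 domain flow-through times; final values average the last two
windows. The hematocrit skewness S_H integrates a profile over half the cut
by trapezoidal quadrature; DI statistics use 20 uniform bins on [0, 1).

## The benchmark case as synthetic-data generator

The packaged validation conditions are: D = 50 μm, L = 200 μm, Re = 0.5
(the largest campaign Reynolds number — fastest migration, shortest physical
transient), Ht_c = 5%, ρ = 1000 kg/m³, μ = 1.2 mPa·s, ~214 cells seeded
uniformly without overlap at fixed count (periodic channel), 16×32
axisymmetric cells, E = 5 kPa contacts, n_coupling = 134, Courant target 0.2. The stenosis demo (inlet injection realized as periodic
recycling with a fresh cross-sectional draw at the inlet) and the planar
bifurcation masks reuse the same machinery.

What this emulates: dilute-suspension transport, deformability-induced
migration, volume exclusion, the flux bias that raises Ht_d, and the
retardation that raises μ_rel. What it does not: membrane dynamics and cell
shape (beyond the DI closure), orientation (no closure exists for it),
cell–cell hydrodynamic interactions (closures are single-cell; hematocrits
above ~5% warn, above 15% error), inertial regimes (Re > 0.5), and any
quantitative 3D branched-device flow (the bifurcation is a planar geometric
stand-in; S_H on it is qualitative only). Passing tests therefore certify the
coupled numerics and the closure pipeline under dilute, low-Re conditions —
not the behaviour of dense or high-shear blood.

## Problem sizes and determinism

Default test and acceptance runs use the sizes above (hundreds of cells,
O(10⁴–10⁵) coupling steps, minutes on one core); they are the package's chosen
desk scale, a reduced version of a full diameter sweep. All randomness
(seeding, inlet recycling) flows from the single case seed; identical
configuration and seed reproduce bit-identical trajectories on the same
platform.

## What the validation benchmark actually shows

Run to the strict steadiness criterion, the benchmark develops the correct
qualitative Fåhraeus–Lindqvist structure — a cell-rich core inside r* ≈ 0.5, a
clean cell-free layer, Ht_d well above Ht_c and μ_rel above 1 — but the core
is *more concentrated* than the empirical Pries correlations imply: at
(D = 50 μm, Ht_c = 5%) the measured Ht_d ≈ 0.091 vs the Pries 0.0754 (~20%
high) and μ_rel ≈ 1.01 vs 1.11 (~9% low). The cause is structural: the lift
closure points centerward everywhere and the model contains no dispersive
counter-mechanism (cell–cell hydrodynamic interactions and
hematocrit-dependent closure corrections are explicitly out of scope), so the
only true steady state is a contact-supported core, and contact packing alone
concentrates the cells beyond the empirical distribution. The windowed
metrics pass through the empirical values (Ht_d ≈ 0.075–0.081,
μ_rel ≈ 1.04–1.08) at roughly 10–25 flow-through times, before the slow
compaction creep completes; the package reports the strict steady state
rather than a transient window. Quantitative agreement with the microvessel
correlations at steady state therefore awaits a dispersion/closure-correction
mechanism, not tighter numerics.

## Known limitations

* The envelope clamps make out-of-envelope behaviour saturate rather than
  extrapolate; flows that genuinely live outside γ̇⁺ ∈ [0.02, 0.35] are not
  modelled, merely kept finite.
* Grid cells smaller than the particle stretch the unresolved-coupling
  assumptions; the u_p,eff correction restores force consistency but the
  deposited φ remains a smoothed surrogate.
* Periodic z-neighbour detection ignores contact pairs straddling the periodic
  boundary (a ~d_p/L effect at dilute loading).
* The planar topology carries walls on both sides and is intended for masked
  demos, not quantitative rheology.
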