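# rbcdem

Unresolved CFD–DEM simulation of red-blood-cell suspensions in microchannels.

Cell-resolved blood simulation is accurate but prohibitively expensive beyond
a few thousand cells; single-phase non-Newtonian models are cheap but blind to
everything the cells do (the Fåhraeus–Lindqvist effect, margination,
deformation damage). `rbcdem` implements the middle road: each red blood cell
(RBC) is a sub-grid sphere of equivalent volume, two-way coupled to a
volume-fraction incompressible finite-volume plasma solver, with the lost
membrane physics reintroduced through closure correlations fitted on resolved
single-cell simulations. It is aimed at computational hemodynamics work on
microfluidic geometries — straight capillaries, constrictions, simple branched
devices — in the dilute (≲5% hematocrit), low-Reynolds (Re ≲ 0.5) regime where
the closures are valid.

## Model

With γ̇⁺ = γ̇R_c²/ν the dimensionless shear rate, u_r⁺ = (u_p − u)·ê/u_av the
dimensionless slip and Re_p = d_p|u_p − u|/ν the particle Reynolds number, the
per-cell closures are

    DI  = γ̇⁺³ / (γ̇⁺³(10 + u_r⁺³) + 0.117 γ̇⁺²(u_r⁺ − u_r⁺⁴) + 0.0026)
    C_d = (169 Re_p²(DI + 1) + 0.00146) / Re_p³
    C_l = −3.19 DI⁴/Re_p + 2.48 DI/Re_p + 0.0008 Re_p/DI³

feeding the drag and lift forces

    F_drag = 0.125 C_d ρ π d_p² |u − u_p| (u − u_p)
    F_lift = C_l ρ d_p⁴ (γ̇² + |u_p − u|²/d_p²) r̂        (r̂ toward the axis)

The particles obey soft-sphere (Hertz–Mindlin) DEM dynamics; the fluid obeys
the volume-fraction Navier–Stokes equations with the momentum-exchange field
R_pf = K u − K⟨u_p⟩, K = |Σ(F_drag + F_lift)|/(V_cell|u − ⟨u_p⟩|), closed by a
PISO-style pressure–velocity coupling on a staggered axisymmetric or planar
grid. Validation metrics — discharge hematocrit Ht_d = Q_RBCs/Q_blood,
relative apparent viscosity μ_rel = Q_plasma/Q_blood, the Pries microvessel
reference correlations, hematocrit skewness S_H and deformation-index
statistics — are built in. See `docs/methods.md` for the numerical details
and the validity envelope.

## Worked example

Closure evaluation at a campaign point (γ̇⁺ = 0.35, the envelope maximum):

```sh
$ rbcdem closures eval --gamma-plus 0.35 --re-p 0.05
DI,C_d,C_l
0.0993972,3727.64,4.96461
```

A cell at the highest fitted shear deforms to DI ≈ 0.099 (the closure's
saturation value is 0.1); at Re_p = 0.05 it experiences a drag coefficient of
about 3.7·10³ — roughly eight times the Stokes value, reflecting confinement
and deformation — and a positive lift coefficient, i.e. a centerward push.

Period reduction of an oscillating (tumbling-cell) drag trace:

```sh
$ python examples/period_detection.py
true period    : 12.000 ms
detected period: 12.052 ms  (error 0.44%)
period 0: mean C_d = 3192.9
...
grand mean C_d = 3195.4  (the single value a campaign point contributes)
```

The flagship run — the Fåhraeus–Lindqvist benchmark
(`examples/straight_channel_validation.py`, a few minutes) — simulates a
periodic 50 μm channel at 5% hematocrit with ~214 cells until the flux metrics
are steady and compares them with the Pries correlations. It reproduces the
qualitative structure (discharge hematocrit above the channel hematocrit, a
cell-free layer, apparent viscosity above plasma); at its strict steady state
the cell core is more concentrated than the empirical correlations imply —
the closure set has no dispersive counter-force to its centerward lift — so
the discharge hematocrit overshoots by ~20% (see `docs/methods.md`, "What the
validation benchmark actually shows"). Other examples cover single-cell
lateral migration (`single_cell_migration.py`), deformation through a stenosis
(`stenosis_deformation.py`), the closure surface over the campaign grid
(`campaign_closures.py`) and bifurcation geometry with the skewness index
(`bifurcation_geometry.py`).

Simulations can also be driven from a YAML case file:

```sh
rbcdem scenario build --config case.yaml
rbcdem run --config case.yaml --seed 1 --out out/
```

which writes `metrics.csv`, VTK field/particle snapshots and a JSON manifest
echoing the resolved configuration.

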