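# Methods

`glymphsim` simulates solute clearance through a single idealised
arteriole–venule unit of the brain's glymphatic system, and predicts how
focused-ultrasound blood–brain-barrier opening (FUS BBBO) changes that
clearance.  This note records the model, its assumptions, the numerical
choices, and what the synthetic study conditions do and do not represent.

## Model

### Geometry

The unit is a rectangular parenchyma box crossed by two parallel cylindrical
vessels (axes along z): an arteriole (diameter 20 µm) and a venule (30 µm),
280 µm apart centre-to-centre, each wrapped by a 10 µm annular perivascular
space (periarterial PAS, perivenous PVS) and a 1 µm glia-limitans shell.  The
axial length is 100 µm.  Vessel lumens are excluded from the computational
domain (no-slip walls; blood flow is not modelled).  Cross-sections are
annular, not elliptical — a deliberate idealisation.

The outer box is not a physiological boundary and its size is a genuinely
open choice: the default places the boundary 60 µm beyond each glia shell
(long axis ≈ 447 µm, transverse ≈ 172 µm).  The box is held fixed between
baseline and FUS runs (it is computed from the *unscaled* shells) so paired
comparisons share one domain and one grid.  `box_margin` is a config knob and
the sweep driver can quantify its influence; the FUS-to-baseline ratios do
depend on it, because it sets how much perimeter inlet area a given unit
volume receives (see *Known limitations*).

### Flow

Steady incompressible Brinkman flow for the superficial (Darcy) velocity u
and pressure p:

    −∇p + (µ/ε) ∇²u − (µ/κ) u = 0,     ∇·u = 0

with CSF water-like (µ = 1 mPa·s, ρ = 1 g/mL).  Inertia is negligible
(Re ≈ 1e−6) and no pulsatility is modelled, so the flow is solved once per
condition and frozen for the transport.  Region properties: parenchyma
ε = 0.20, κ = 1e−12 m², tortuosity λ = 1.7; glia limitans ε = 0.003,
κ = 5e−14 m²; the perivascular spaces are fluid-dominated Brinkman regions
(ε = 1, κ = 1e−9 m²), which makes one equation set cover the whole domain
while behaving as near-Stokes channels there.

Boundary conditions (default `bc_mode: velocity`): the pial face (z = L)
carries the periarterial CSF inflow (18.7 µm/s, into the PAS annulus) and the
perivenous outflow (3 µm/s, out of the PVS annulus); every other boundary is
open at the reference pressure, so the arteriole-to-venule pressure gradient
*emerges* rather than being imposed.  In `bc_mode: mixed` the PVS outlet is
instead an open boundary offset by the literature trans-vessel gradient
(3 mmHg/m × 280 µm ≈ 0.11 Pa) and the perivenous velocity emerges.

### FUS BBBO perturbation

FUS is parametric, not acoustic: (i) both perivascular widths scale by 1.75;
(ii) exposed parenchyma porosity ×1.67 and permeability ×3.0 (glia
unchanged — the reported increases name the parenchyma only); (iii) the
exposed *lateral* perimeter becomes a CSF inlet at 0.8 µm/s.  "X% increase"
values are interpreted multiplicatively (175% → ×1.75): the additive reading
would push porosity past physical bounds under modest sweeps.  The two axial
faces always stay open: with the whole boundary turned into velocity inlets
the incompressible system would admit no solution, and the axial faces are
where the vessels (and their perivascular channels) continue into tissue.
Edge-of-focus scenarios replace the 0.9 mm focal disc edge by a plane through
the midpoint between the vessels (the focal diameter is ≈3× the unit size, so
the arc's curvature is negligible at this scale); only the exposed half
receives any of the three perturbations.

### Transport

Intrinsic concentration c with superficial velocity u:

    ε ∂c/∂t + ∇·(u c) = ∇·(ε D_eff ∇c),     D_eff = D/λ²,   M = ∫ ε c dV

Free diffusion coefficients: tracer 1e−9, amyloid-β 1.8e−10, α-synuclein
7.8e−10 m²/s.  The glia limitans inherits λ = 1.7 (no measured value exists);
its porosity (0.003) is what throttles diffusive passage.  No reactions,
binding or aggregation.  Open boundaries let mass advect out freely, carry
zero diffusive normal flux, and deliver solute-free CSF on inflow.  Initial
condition: either a cylindrical bolus (default radius 40 µm, chosen to sit
comfortably inside the parenchyma midway between the vessels; all headline
metrics are ratios and are linear in c0, hence independent of c0) or a
uniform load of the whole parenchyma.  Runs end at 95% mass clearance; t95 is
interpolated linearly on the remaining-mass record.

### Metrics

The global Péclet number is Pe(t) = ∫|u c| dV / ∫|ε D_eff ∇c| dV — the ratio
of volume-integrated convective to diffusive flux magnitudes.  This is the
single largest interpretive choice in the package: a printed "Péclet number"
could equally be a terminal or peak value, so the scalar summary is the time
average over [0, t95] and the terminal and peak values are also reported.
Percent changes are (new − old)/old × 100.  Per-region flux decompositions
(PAS/PVS/parenchyma) are available for spatial contrasts.

## Numerics

* **Discretisation.**  Uniform staggered (MAC) Cartesian grid; default cell
  size 6 µm.  Cells carry the region label of their centre; sub-cell sampling
  supplies fluid volume fractions for integrals.  The 1 µm glia shell is far
  thinner than a cell and is represented by *series-resistance face
  coefficients*: both the hydraulic (κ) and diffusive (εD_eff) face values
  are harmonic means sampled along each cell-centre-to-centre segment, so the
  shell's full resistance acts on every crossing face without being meshed.
* **Flow solver.**  Faces with κ ≤ 1e−11 m² (parenchyma, glia) use the pure
  Darcy balance — there the Brinkman screening length √(κ/ε) ≲ 2 µm is far
  below the mesh size, so the viscous term only adds unresolvable boundary
  layers — and their velocities are eliminated analytically into the pressure
  system.  Perivascular faces keep full Brinkman momentum rows (drag +
  viscous + pressure), with no-slip vessel walls and mirror ghosts at solid
  boundaries.  The resulting sparse system (pressure everywhere + velocity in
  the perivascular spaces) is solved by direct LU factorisation; the
  discrete boundary flux balance closes to ≤1e−6 by construction check.
* **Transport scheme.**  Cell-centred finite volume; hybrid central/upwind
  advective faces (central wherever the face Péclet |q|/G < 2, which holds
  essentially everywhere in this parameter range), implicit (backward Euler)
  stepping.  The operator is an M-matrix, so concentrations stay
  non-negative.  The time step doubles geometrically but is capped at 3% of
  elapsed time, resolving the early transient finely while bounding the
  number of LU refactorisations; t95 moves <1% under dt halving.
* **Conservation audit.**  Backward-Euler fluxes evaluated at the new state
  make the discrete balance exact: cleared mass equals the time-integrated
  boundary outflux to solver precision; every run records the residual.
* **Verification oracles.**  Degenerate configurations of the production
  kernels against closed forms: Darcy column (exact), plane-Poiseuille limit
  (≈2.5% at 32 cells across), Gaussian variance growth (<0.1%), and
  95%-clearance of a disc in an absorbing square against a 60×60-mode
  eigenfunction series (≈1.5%).

## Study conditions and problem sizes

The canonical suite runs six paired comparisons (centralized tracer,
distributed tracer, amyloid-β, α-synuclein, PAS-only and PVS-only
edge-of-focus) at the defaults above.  The quantitative headline comparisons
run at the default 6 µm resolution (≈37 000 fluid cells); directional and
robustness checks in the test suite run at 10–14 µm, where every qualitative
ordering is already mesh-stable.  All pipelines are deterministic — there is
no stochastic component anywhere.

## Known limitations

* The outer-box margin (and hence the FUS perimeter-inlet area per unit
  tissue volume) is not constrained by any measured quantity; FUS/baseline
  clearance *ratios* shift systematically with it.  The package reports its
  influence via the sweep driver rather than hiding the dependence.
* Single straight vessel pair; no branching, curvature, pulsatility,
  fluid–structure interaction, parenchymal anisotropy, or elliptical
  perivascular cross-sections.
* FUS is a static perturbation: no BBB-recovery dynamics, no acoustic or
  microbubble physics, no transvascular drug delivery.
* The staircase vessel-wall representation is first-order accurate at the
  wall; imposed-velocity boundary integrals are exact on the meshed annuli
  but the meshed annulus area differs from the analytic one by O(h).
* At the default 6 µm cells the 10 µm perivascular annuli span only ~2 cells
  transversely.  Their throughput is still flux-exact (set by the Dirichlet
  inlet/outlet) and their exchange with the tissue rides on the sampled face
  resistances, but the transverse velocity profile inside the annuli is
  crude; resolving it properly needs ≲3 µm cells and ~8× the runtime.
* The global Péclet ratio converges slowly with mesh refinement (the |∇c|
  integrals feel the staircase interfaces at first order); the t95 ratios
  are far more mesh-stable than the Péclet summaries.
* Peclet magnitudes inherit the whole-domain flux-integral definition;
  region-restricted definitions give different absolute values (the paired
  FUS/baseline contrasts are far less sensitive).
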