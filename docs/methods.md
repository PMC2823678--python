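# Methods

`clotflow` simulates the onset of tissue-factor (TF)-initiated blood
coagulation in a two-dimensional perfused channel and quantifies how wall
shear rate gates clotting through the positive feedback of factor VII
activation by factor Xa.

## Model

### Geometry and flow

The domain is a rectangle of height h = 1000 μm and length 6000 μm, with a
TF-covered activator patch (default 1000 μm, starting 1000 μm from the
inlet) on the bottom wall.  Plasma is driven by a fixed pressure drop
("constant pressure" perfusion): as the growing clot obstructs the channel
the flux falls, the pressure drop does not rise.

Because the Reynolds number at these scales is ≪ 1, the flow solver treats
the steady Stokes (creeping-flow) limit on a marker-and-cell staggered
grid, with no-slip walls, fixed inlet/outlet pressures, and a volume
penalization (large Darcy drag) that drives the velocity inside gelled
cells below ~10⁻³ of the clean-channel mean.  The imposed pressure drop is
parameterized by the clean-channel wall shear rate γ_w through plane
Poiseuille flow, γ_w = 6·U_mean/h, which makes the plasma viscosity cancel
exactly for the unobstructed channel; internally μ = 1.  The flow is
re-solved whenever gelation changes the permeability mask, throttled to at
most one solve per 5 simulated seconds — clot growth is quasi-static on the
flow-relaxation timescale.

### Chemistry

The reaction network is declarative (YAML; nM / s / μm units) and the
packaged default encodes the TF pathway: reversible TF binding of VII and
VIIa; extrinsic tenase (TF·VIIa) activation of X and IX on the patch; the
positive feedback, Xa-catalysed conversion of TF·VII to TF·VIIa; the
two-step Xa-dependent TFPI mechanism (TFPI·Xa formation, then capture of
TF·VIIa into an inert quaternary complex); intrinsic tenase (IXa·VIIIa) and
prothrombinase (Xa·Va); thrombin feedback activation of V, VII, VIII, XI;
fibrinogen cleavage to fibrin; reversible thrombin adsorption onto fibrin;
AT-III inactivation of IIa, Xa, IXa; and spontaneous VIIIa decay.  Protein
C / APC are carried as species (so convection-class toggles can name them)
but have no activation route — the channel walls bear no thrombomodulin.

Surface-bound species (TF and its complexes) live only in wall-adjacent
activator cells in a thin-layer representation: a surface density σ
(nmole/mm²) appears as a volumetric concentration σ/Δx, so surface and bulk
chemistry share one rate evaluation and the surface↔bulk exchange is
implicit.  The TF loading is 10⁻⁷ nmole/mm² (10 fmol/cm², in the range of
in-vitro fibroblast / relipidated-TF surface densities).

Plasma composition (nM): II 1400, V 20, VII 10, VIII 0.7, IX 90, X 170,
XI 30, PC 60, fibrinogen 7600, VIIa 0.1 (1 % of VII), TFPI 2.5,
AT-III 3400.  All are config-overridable.

### Gelation

Fibrin below the gel point (450 nM) leaves permeability at 1; at or above
it, permeability drops to 0 (the gel does not hinder diffusion, only flow).
Fibrin at or above 3800 nM (half the fibrinogen pool) marks "solid" clot.
Both masks are monotone in time (no fibrinolysis).  The lagtime is the
first time solid clot covers half of the wall-adjacent activator row,
linearly interpolated between steps.

### Numerics

Operator splitting per step: (1) conservative first-order upwind advection
for every species with its convection toggle on (CFL ≤ 0.8); (2) explicit
5-point diffusion (default D = 50 μm²/s for all proteins; fibrin and
fibrin-bound thrombin immobile); (3) chemistry via an adaptive embedded
Bogacki–Shampine 3(2) Runge–Kutta sub-stepper (rtol 2·10⁻⁷, atol 10⁻¹⁰ nM)
with a step size shared across the grid and controlled by the worst local
error.  Negative excursions are clipped to zero with the removed mass
logged; a run aborts if the logged error exceeds 0.1 % of any conservation
group.  Concentrations below 10⁻³⁰ nM are flushed to zero — far below one
molecule per cell, and it keeps products of small fields out of the
subnormal floating-point range.  Boundary conditions: inlet Dirichlet at
plasma composition, advective (zero-gradient) outflow, zero-flux walls; a
closed-box mode switches all boundaries reflective for verification runs.
Hot loops run through numba-compiled kernels; bit-compatible pure-numpy
implementations remain as fallback and as test oracles.

The default grid is Δx = 25 μm; all packaged experiments and acceptance
runs use the coarse tier Δx = 50 μm (40 × 120 cells), where the
clean-channel Poiseuille error is 0.3 % and the measured wall shear is
within 3 % of nominal.

## Calibration and the shear scale

No complete, self-consistent constant listing exists for spatial clotting
in phospholipid-free flowing plasma; the packaged scheme assembles
literature-typical constants for that regime.  Exactly two constants were
then calibrated so that the control scenario in stagnant plasma reaches
half-activator solid-clot coverage at 2.5 min: the extrinsic-tenase kcat
for X activation (0.2 s⁻¹ — an effective value absorbing unmodelled
surface-site detail) and the thrombin–fibrinogen kcat (30 s⁻¹).

A consequence of this particular ensemble is the absolute position of the
shear scale: the window in which clotting resists flow ends near
γ_w ≈ 4–6 s⁻¹, whereas other constant choices can push it to
10–20 s⁻¹.  The shape-level phenomena are robust — lagtime grows
monotonically and super-linearly with shear; disabling enzyme convection
makes the curve flat at the stagnant value; the solid-clot threshold has no
effect on the curve; flow prolongs the lifetime of active TF; smaller
activators clot later (hyperbolically in size) and below a minimum size not
at all.  Shear sweeps in the tests and packaged experiments therefore use
grids inside the model's own resistance window, and flow-influence
intervals truncate at the first no-clot point of either curve (which is
why reported R values carry their i–j interval with them).

## Analysis layer

* **Lagtime curve** L(γ_w), with a no-clot sentinel for runs capped at the
  end time (default cap 150 min; packaged experiments use shorter caps
  stated per run).
* **Exponential fit** y = y0 + A·e^(R·x) by deterministic nonlinear least
  squares (fixed initial-guess rule, so identical curves give bit-identical
  fits).  A curve whose range is under 2 % of its mean is flagged
  degenerate: the exponent of a flat response is undefined.
* **Flow-influence coefficient** over a shear interval [i, j]:
  R = ∫ᵢʲ[L_pert − L_pert(0)]dx / ∫ᵢʲ[L_ctrl − L_ctrl(0)]dx (trapezoidal on
  the shared grid).  The printed form of this coefficient is not in the
  extracted text; this reconstruction is the simplest functional matching
  every stated anchor — control vs itself = 1, a flow-insensitive
  perturbation = 0, and interval truncation where curves become
  incomputable.
* **Sensitivity ratio** R′ = R_pert/R_ctrl from the fitted exponents; not
  computable when the perturbed fit is degenerate.
* **Integral extrinsic tenase**: line integral of TF·VIIa surface density
  along the activator per unit channel depth (nmole/mm); likewise the
  active-TF series (TF + TF·VII + TF·VIIa) for inhibition kinetics.

## Verification

Analytic oracles are generated at test time, never stored: translated
Gaussians for upwind advection (tolerance budgeting first-order smearing),
heat kernels for diffusion, closed forms for reaction motifs (first-order
decay, reversible-binding equilibrium), and a well-mixed reference
trajectory of the full cascade integrated by LSODA at rtol 10⁻¹⁰ on a
naive per-reaction rate loop — independent of both the compiled rate
evaluator and the spatial sub-stepper it checks (agreement required to
0.1 %).  Closed-box runs must conserve every stoichiometric group (X-core,
II-core, …) to 10⁻⁶ relative drift.  Each analytic tolerance is also
checked to be non-vacuous: the measured error must exceed 1 % of it.

## Known limitations

* Deliberate scope limits: no platelets, no thrombomodulin/heparan-sulfate
  wall inhibition, no fibrinolysis, no explicit fibrin polymer kinetics,
  2D geometry, Newtonian steady flow.
* The thin-layer surface representation makes boundary-cell kinetics mildly
  grid-dependent; the grid-convergence tests bound the effect (lagtime
  shifts ≲ 10 % between Δx = 50 and 25 μm).
* The shear-scale sensitivity above: absolute γ_w values depend on the
  constant ensemble; ratios and curve shapes are the robust quantities.
* First-order upwind advection smears sharp fronts; thresholds and ratios,
  not front profiles, are the quantities of interest here.
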