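# Methods

This note records the model equations as implemented, the parameter
choices and their rationale, the numerical schemes, and the limits of what
the shipped scenarios can demonstrate.

## Units

Internal units are micrometres, seconds and nanomolar. The Carman–Kozeny
constant C_CK = 10⁶ mm⁻² is exactly 1 μm⁻². Pressure is kinematic
(μm²/s²). Surface densities (the SE enzyme E0) are carried as
concentration × length (nM·μm); 1 nM = 10⁻²⁴ mol/μm³ =
0.60221 molecules/μm³, which converts per-platelet binding-site counts into
site concentrations.

## Fluid

Incompressible Navier–Stokes–Brinkman on a staggered (MAC) grid: x-velocity
on vertical faces, y-velocity on horizontal faces, pressure at cell
centers. This arrangement suppresses checkerboard pressure modes without
Rhie–Chow interpolation; the trade-off is that the solver requires the
uniform rectangular grids of the shipped cases.

Each time step performs one implicit momentum solve — backward-Euler
diffusion, implicit Darcy drag −ν α(θ_B) u with α evaluated from the
*previous* step's bound fraction, explicit centrally-differenced advection,
lagged pressure gradient — followed by `n_correctors` (default 2)
incremental pressure projections. The projection uses the face mobility

    d = 1 / (1/Δt + ν α_f),

the inverse of the diagonal (time + Darcy) part of the momentum operator.
Two properties motivate this choice. First, d bounds the true velocity
response to a pressure gradient from above (the viscous stencil only adds
to the operator), which makes the projection iteration contractive — a
mobility that also includes the viscous diagonal is unstable at plasma
viscosity on micrometre grids, where ν/Δx² dominates 1/Δt by orders of
magnitude. Second, d shrinks wherever the Darcy drag is large, so cells
inside the platelet mass receive proportionally less corrective flux. The
projection is solved with a direct sparse factorization, so the discrete
divergence after correction is at machine precision (normalized tolerance
10⁻⁸, observed ~10⁻¹⁴).

Verification: steady Poiseuille flow on 32 cells across the channel is
within 0.1 % of the parabola (2nd-order grid convergence); a uniformly
clotted channel matches the analytic Brinkman profile, including the
mid-channel Darcy limit G/(να); inflow equals outflow to 10⁻¹⁰ relative.

The channel inlet is a parabolic profile parameterized by the wall shear
rate γ_w (u_max = γ_w H/4). Default γ_w = 100 s⁻¹ — the low-arterial /
venous regime used as the baseline in continuum thrombosis modelling;
plasma kinematic viscosity ν = 1.2 × 10⁶ μm²/s (μ ≈ 1.2 mPa·s,
ρ ≈ 10³ kg/m³). The outlet holds a fixed pressure with zero-gradient
velocity; walls are no-slip.

## Platelets

Four number-density fields (plt/μm³). P_max = 0.0667 plt/μm³ is the
close-packing density of 3 μm spheres at solid fraction ≈ 0.6, consistent
with the factor 0.6 θ_B appearing in the Carman–Kozeny law. Inlet mobile
platelet density 2.5 × 10⁻⁴ plt/μm³ (2.5 × 10⁵/μL, mid-physiologic);
platelet diffusivity D_P = 25 μm²/s (shear-enhanced effective value).

The hindrance function is W(θ_T) = tanh(π(1 − θ_T))/tanh(π) for θ_T < 1 and
0 beyond: smooth, W(0) = 1 exactly (the normalization by tanh(π) enforces
this), monotone, vanishing at the packing limit. A `linear` form (1 − θ_T)₊
is available by configuration. Per-face hindrance multipliers are W of the
*downwind*-interpolated θ_T for advection (flux into a location throttled
by the fullness of the receiving side) and W of the *localMax*-interpolated
θ_T for diffusion (exchange with a packed cell is limited by the packed
side); exactly-zero face fluxes fall back to linear interpolation. Together
with the saturation factor (1 − θ_T)₊ in every binding source, these keep
θ_T ≤ 1; the shipped 30 s channel run peaks at θ_T ≈ 0.18 with the bound
never challenged beyond 1 + 10⁻¹⁰.

Source terms (all transfers, so total platelet number is conserved
exactly):

* activation: mobile-unactivated → mobile-activated at
  A_ADP(c) + A_thr(c), Hill functions with k_pla = 0.34 s⁻¹,
  c* = 1000 nM for ADP and k_pla = 0.5 s⁻¹, c* = 1 nM for thrombin
  (E2 + E2b as agonist concentration); the two agonist rates add.
* adhesion: mobile platelets within the adhesion region H_adh (the sharp
  indicator of cells whose center is within P_diam = 3 μm of an
  injuryWalls face) bind to the SE at k_adh = 2 s⁻¹, limited by the
  remaining SE capacity (monolayer density 0.14 plt/μm² spread over the
  P_diam adhesion layer → cap 0.047 plt/μm³) and by (1 − θ_T)₊;
  unactivated platelets activate upon adhesion.
* cohesion: mobile-activated → bound at k_coh·g(η)·θ_B·(1 − θ_T)₊, i.e.
  requiring existing bound platelets locally (the local form of the
  proximity requirement; a nonlocal kernel could be substituted).
  g(η) = η/(η* + η) with η the bound-thrombin concentration E2b and
  η* = 0.5 nM; g ≡ 1 is available for tests.

## ADP release

R(τ) is the Gaussian bell centered at 3 s with unit mass on τ ≥ 0. The
printed prefactor π^(−1/2) leaves a residual mass erfc(3)/2 ≈ 1.1 × 10⁻⁵
on τ < 0; since the model's defining property is the unit normalization,
the kernel divides by Z = (1 + erf(3))/2, keeping the peak value 0.56420
within 10⁻⁵ of π^(−1/2).

The newly-bound rate P_max·Δθ_B/Δτ is sampled every Δτ = 0.05 s into a
ring buffer of ⌊τ_f/Δτ⌋ + 1 = 121 snapshots (τ_f = 6 s; R(6) ≈ 10⁻⁴ of the
peak, so truncation is negligible). σ_release is the trapezoid sum of
Â·R(t−τ_k)·B(τ_k), held piecewise-constant between buffer updates — which
is why the ADP equation sits outside the fractional-step reaction loop.
Negative sampled rates (net unbinding) are clipped to zero inside the
quadrature (release is irreversible) and counted in diagnostics.
Â = 2.4 × 10⁻¹⁷ mol/platelet, the dense-granule ADP content scale;
D_ADP = 250 μm²/s (small-molecule diffusivity).

## Coagulation network

Twelve species: fluid-phase S1, E1, S2, E2 (diffusivity 50 μm²/s, protein
scale); platelet-bound E1b, S2b, E2b, the inhibited E1b_inh, E2b_inh, and
the free-site pools Z1, Z2; SE-bound E0. The free sites are explicit
species: newly bound platelets create N1 = 1000 class-1 and N2 = 3000
class-2 sites each, so site conservation (Z1 + E1b + E1b_inh = const, and
similarly for class 2) holds *exactly* along trajectories, and all
platelet-bound kinetics vanish identically where no platelets have bound.

Reactions (mass action; units 1/(nM·s) for bimolecular, 1/s otherwise):
E1 + Z1 ⇌ E1b (0.01, 0.1); S2 + Z2 ⇌ S2b (0.01, 0.1); E1b-catalyzed
S2b → E2b (0.01); E2b-catalyzed S2b → E2b, the positive feedback (0.05);
E2b → E2 + Z2 release (0.02); E1b, E2b inhibition (0.005, 0.01). On-rates
are the 10⁷ M⁻¹s⁻¹ protein-binding scale; the inhibition rates correspond
to bound-enzyme half-lives of minutes. The SE reaction is a
Michaelis–Menten surface flux q = k_cat·E0·S1/(K0 + S1) (k_cat = 2 s⁻¹,
K0 = 170 nM, E0 = 10 nM·μm ≈ 1 fmol/cm²) applied in the wall-adjacent
cells with the face-area/volume factor; the S1 consumed equals the E1
produced, instantaneously and in time-integral. E0 is a catalyst and is
not consumed. Inlet concentrations: S1 = 170 nM (zymogen at the factor-X
scale), S2 = 1400 nM (prothrombin scale).

Catalysis is direct bimolecular (no tracked Michaelis complexes on the
platelet surface), so production of E2b is exactly linear in E1b at fixed
S2b when the feedback is off. The feedback rate constant is the single
knob that separates graded from burst-like thrombin generation; lag time
decreases monotonically in it.

Extension recipe: new chemistry is added as data — a species entry
(category, diffusivity, inlet value) plus reactions (rate function +
integer stoichiometry). `add_inhibitor_extension` demonstrates it with a
fluid-phase inhibitor I + E2 → E2_inh at −k_I·[I]·[E2]; conservation of
I + E2_inh is automatic from the stoichiometry.

## Time stepping and coupling

Per step: (1) α from the previous step's θ_B; (2) momentum predictor and
pressure correctors; (3) transport of mobile platelets (hindered) and
fluid-phase chemicals (upwind advection, implicit backward-Euler
diffusion) with Δt; (4) M_rxn = 2 coupled RK4 reaction sub-steps of size
Δt/M_rxn covering the cascade, the surface reaction and the platelet
source terms (ADP enters as a frozen agonist field); (5) at the Δτ cadence,
a release-history push and σ_release refresh; (6) the ADP step.
Everything is deterministic; identical configurations give bit-identical
results, and a run checkpointed at its midpoint resumes to within 10⁻¹²
of the unsplit run.

Numerical properties verified by the suite: implicit diffusion conserves
mass to 10⁻¹² relative per step on closed boxes; the platelet transport
budget (boundary influx + clipping) closes to ~10⁻¹⁶ relative per step on
the shipped case and the reaction stage transfers without loss at the same
level; RK4 shows its 4th-order Richardson estimate (≥ 3.9 on the full
network at the finest step pair); the spatial diffusion stencil is 2nd
order on a sine profile; the transport/reaction splitting is 1st order in
Δt, as expected for Lie splitting with backward-Euler diffusion.

Negative concentrations from advective under/overshoot are clipped to zero
at the end of each transport step; the clipped mass is logged and stays at
rounding level (≲10⁻¹⁵ of the total) in the shipped cases. The advective
CFL is monitored (warn above Co = 0.9; strict mode aborts); the shipped
channel runs at Co ≈ 0.3.

Operator caching: the sparse factorizations of the momentum, pressure and
hindered-diffusion systems are reused between steps and rebuilt when the
coefficient fields (α, face hindrances) drift beyond a tolerance — 0 means
rebuild on any change; the shipped channel cases use 10⁻³, an
operator-coefficient lag of the same character as the model's lagged θ_B
in the Darcy term. With clot growth of ~10⁻⁵ per step in θ_B, rebuilds
occur every few hundred steps and the induced coefficient error is ≲0.1 %.

## Shipped scenarios and problem sizes

* Channel thrombosis, full: 240 × 60 μm, 128 × 32 cells (1.875 μm ≤
  P_diam), 90 μm injuryWalls patch centered below, end time 200 s.
* Channel thrombosis, reduced: identical physics on 96 × 24 cells
  (2.5 μm), end time 30 s — the size used by the regression and
  conservation checks in the test suite, chosen so a complete run stays in
  desk-scale minutes.
* Well-mixed burst box: closed box with a pre-formed platelet surface
  (P_ba = 0.02 plt/μm³ with consistent site pools) initiated by a 0.05 nM
  E1 bolus. Initiating through the bolus rather than the SE ramp makes the
  sigmoidal/graded distinction crisp: with wall initiation the upstream
  enzyme supply itself ramps, and even feedback-free curves acquire an
  apparent lag. A curve is classified sigmoidal when its 10 % → 50 % rise
  is faster than its lag.

## What the shipped cases do and do not show

The 30 s reduced run demonstrates boundedness, localization of adhesion,
conservation, the onset of surface-driven coagulation and ADP-mediated
recruitment — not a mature occlusive clot: θ_B reaches ~0.17 at the wall
by 30 s, so the Darcy feedback on the flow is still mild and the
θ_B ≥ 0.5 clot-area metric is still zero. Longer runs of the full case
grow denser aggregates; the clot-area threshold 0.5 is a reporting
convention, not a model constant.

Known limitations: 2D only; uniform rectangular grids (the mesh layer
validates general conforming multi-block input, but the flow solver
requires uniform spacing); no shear-dependent aggregation or embolization;
no fibrin; the reduced cascade's rate constants are order-of-magnitude
physiologic choices, not a fitted parameter set — quantitative thrombin
levels should be read as scales, not predictions.
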