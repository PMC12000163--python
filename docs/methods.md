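# Methods

## The model

A rigid sphere of radius r_P and density ρ_P in a buffer of density
ρ_B and dynamic viscosity η settles at the Stokes terminal velocity
v_T = 2g·r_P²(ρ_B − ρ_P)/(9η); the velocity is signed, negative
downward for particles denser than the buffer. The momentum
relaxation time (2/9)ρ_P r_P²/η is of order microseconds for
micron-scale particles in aqueous buffers, so everywhere in the
package a particle's velocity is taken as the local fluid velocity
plus v_T, with no inertia ("inertialess advection").

In a horizontal cylindrical barrel of radius R_S, all suspended
particles translate downward together, so the region of the
cross-section still occupied by particles is the initial disk
intersected with itself shifted down by the settling path d_T =
|v_T|·t. The concentration inside that region stays constant;
what decays is its area:

* **Lens (upper-boundary) model** — every suspended particle is
  deliverable. A_E(d) is the two-circle lens; C_E/C₀ =
  (2/π)[acos x − x√(1−x²)] with x = d_T/(2R_S), reaching zero at
  d_T = 2R_S.
* **Segment (lower-boundary) model** — with a concentric nozzle and
  no vertical flow, particles below the nozzle can never leave;
  A_E(d) is the circular segment above height d_T; same functional
  form with y = d_T/R_S, reaching zero at d_T = R_S.

Both boundary curves cross one half at the same root u* ≈ 0.40397
of acos u − u√(1−u²) = π/4 (solved by bisection to 1e−12; the
function is monotone on [0, 1]), giving half-life coefficients
0.4040 (segment) and exactly twice that, 0.8079 (lens). Real
operating points interpolate: t₁/₂ = K_S·R_S/|v_T| with the
empirical sedimentation constant K_S between about 0.4 (low
flow-rate) and 0.8 (high flow-rate). `half_life_estimate` defaults
to the published one-decimal boundary value K_S = 0.4 rather than
the full-precision root, matching how the boundary coefficient is
quoted and used in practice.

Degenerate inputs: ρ_P = ρ_B gives v_T = 0 and an infinite
half-life (a sentinel, not an error — density matching is the
recommended mitigation, not a failure mode). acos arguments are
clamped to [−1, 1] and ratios to [0, 1] against floating-point
round-off; times past depletion return exactly 0. Floating
particles (v_T > 0) are handled by mirroring the vertical axis,
under which the geometry and model are symmetric.

`fit_sedimentation_constant` regresses pooled (t₁/₂, R_S/|v_T|)
points through the origin — the model has no intercept — and
reports R² against the zero-intercept model.

The Einstein dilute-suspension relation Δη = 2.5·φ·η (φ the volume
fraction) is included to verify that working concentrations
(~10⁶ particles/ml) leave the buffer viscosity unchanged to better
than 10⁻³ mPa·s.

## Flow-field backends

The barrel is oriented with z along the axis (plunger at z = 0,
outlet on the end wall at z = L_S), y vertical. The outlet is a
tube of radius R_O whose centre sits at height `outlet_offset` on
the end wall (0 = concentric, ±(R_S − R_O) = eccentric).

**superposition** (default): Poiseuille flow in the bulk plus a
half-space point sink of strength Q at the outlet centre. The sink
is smoothly tapered to zero two barrel radii upstream (smoothstep),
and at every axial station the Poiseuille amplitude is rescaled by
1 − F_sink(z)/Q (F_sink computed by polar quadrature at
construction) so the net axial flux equals Q through every
cross-section to better than 2%. The sink magnitude is capped
inside a quarter outlet radius: the cap bounds the advection step
of tracked particles but leaves the sink carrying essentially the
whole flow through the outlet disk — a cap as large as R_O starves
the outlet and pushes the flux correction into the end wall, which
visibly distorts low-flow-rate throughput curves. The sink term
does not satisfy wall no-slip; this backend trades that for speed
and for supporting eccentric outlets.

**stokes_axisym**: the axisymmetric creeping-flow stream-function
problem E⁴ψ = 0 solved as the coupled system E²ψ = χ, E²χ = 0 with
second-order finite differences on a 64×256 (r, z) grid
(non-dimensionalized by R_S and Q/2π — essential for conditioning)
and one sparse direct solve. Boundary conditions: regularity on the
axis (ψ = χ = 0); ψ = Q/2π and ∂ψ/∂r = 0 on the barrel wall (Thom
ghost-node closure for the wall vorticity); Poiseuille inflow
profile at the plunger; Poiseuille outflow into the outlet tube on
the end wall, no-slip elsewhere on it. Verified properties: flux
constant in z to 0.5%, wall speed < 1% of the mean axial velocity,
mid-barrel profile within 1% of Poiseuille. Concentric outlets
only; it serves as the physically complete cross-check for the
superposition closure (the two agree to a few percent in the bulk).

## Particle tracking

2000 particles by default (configurable) are seeded i.i.d. uniform
in the barrel volume and advanced with velocity = fluid + v_T·ŷ at
dt = 0.05 s (forward Euler by default; RK4 available — the fields
are smooth and the two agree, and halving dt from 0.1 to 0.05
moves the extracted half-life by < 0.5%). A particle whose centre
reaches the barrel wall is captured (particle radius neglected,
r_P ≪ R_S); one crossing the outlet-entrance disk has exited and is
counted; one reaching the end wall outside the outlet slides along
it. Captured particles never re-suspend; particles do not interact
or act back on the flow. The outlet tube itself is not simulated.

With Q = 0 the scheme is exact (constant velocity) and is, by
construction, a Monte-Carlo sampling of the lens model: uniform
seeding + rigid settling + wall capture. The suspended fraction
then matches the closed-form curve within binomial error — the
simulator's primary oracle.

With flow, the measurement mimics the counting experiment: exits
are binned per second, the rate normalized by its mean over the
first 20 s after the first exit (an explicit definition of
"normalize to the initial value", needed because the raw rate has
no plateau marker), smoothed with a centered 21-bin moving average,
and the half-life read at the first downward crossing of 0.5 by
linear interpolation. Window and smoothing are configurable.

### Known divergence from the finite-element reference behaviour

With either flow backend, the simulated throughput half-life at the
reference geometry sits near the *upper* model boundary at all
flow-rates (K_S ≈ 0.73–0.77 at both 0.5 and 50 µl/min), rather than
climbing from ~0.4 at low Q. The mechanism is robust in this model:
the region where the sink inflow beats settling (radius
√(Q/2π|v_T|), about 0.6 mm at 0.5 µl/min) keeps harvesting
particles that settle past the nozzle, so the outlet rate does not
drop to half its initial value until the depletion front approaches
the nozzle height. Any near-orifice field with the correct far-field
sink strength produces this; the axisymmetric Stokes solution and
the superposition closure agree on it. A reference FEM study of the
same system, with a mesh of ~300 µm elements around a 500 µm
orifice and a counter placed beyond a 5 mm outlet tube (in which,
at low flow, settling removes essentially every particle before
transit), reports instead half-lives at or below the lower
boundary at low flow-rate. The package reports what its model
computes; the geometry comparisons (eccentric vs concentric,
barrel-radius scaling) and all closed-form results are insensitive
to this difference.

## Signal analysis

Trace → zero-phase 4th-order Butterworth low-pass (100 Hz default;
zero-phase preserves peak times) → peak detection at baseline +
5σ (median/MAD estimates, robust to the pulses themselves) with a
1 ms refractory separation → per-second counts → coincidence
correction → normalization over the first 20 s → 21-bin moving
average → half-life readout.

The coincidence (dead-time) correction is the standard
non-paralyzable form λ = λ_d/(1 − λ_d·τ): after the 100 Hz filter,
two transits closer than about one filtered pulse width merge into
one detected peak, so the chain undercounts at high rates exactly
like a counter with dead time τ. τ is estimated per trace as the
median half-height width of the detected peaks (≈ 6 ms at a 100 Hz
cutoff). Without the correction the recovered half-life is biased
late by ~7% at 30 events/s and ~25% at 100 events/s.

## Synthetic traces

`synthetic_data` closes the loop: λ(t) = rate₀ · (C_E/C₀)(t) from
any model curve, arrivals sampled by Poisson thinning (the bound is
the probed maximum of the piecewise-linear rate, exact for such
rates), and a trace of Gaussian pulses (FWHM 2 ms default —
a realistic transit pulse that also survives the chain's own
100 Hz filter; sub-millisecond pulses would be attenuated ~8× and
detected unreliably near SNR 5) over unit-variance Gaussian noise,
with SNR defined as pulse amplitude over baseline σ.

What the generator does *not* emulate: scattering-amplitude
dependence on particle size, pulse-shape variability, doublets,
baseline drift. Passing round-trip tests therefore demonstrates
correctness of the counting chain, not robustness to real-detector
artefacts.

Recovery accuracy is rate-limited at both ends: Poisson noise of
the arrivals gives ~±8% half-life scatter per trace at
20–30 events/s, and pile-up grows beyond ~40 events/s (partially
removed by the coincidence correction). Validation therefore runs
at 30 events/s and checks the three-seed mean against ground truth
to 10%, with each single trace within the single-trace scatter.

## Problem sizes

Closed-form results are exact. Simulation-based results use 2000
particles for the no-flow oracle (the reference population size),
100 000 at 0.5 µl/min (exits are rare at low flow: ~0.7% of the
population; the larger population keeps the normalization window
populated), and 8000–12 000 elsewhere; dt = 0.05 s throughout.
Even at 100 000 particles the low-flow throughput half-life remains
seed-sensitive (about ±40%): the normalized rate plateaus within
two noise standard deviations of the 0.5 threshold, so the
first-crossing statistic is intrinsically ill-conditioned there —
a property of the measurement definition, not of the integrator.
Seeds are always explicit and recorded in outputs; identical seeds
reproduce results bit-for-bit.

## Limitations

No Brownian motion (5 µm particles: Péclet ≫ 1), no hindered
settling or particle–particle interactions, no non-Newtonian
buffers, no plunger-motion transients, no outlet-tube transport,
single particle species per run.
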