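# Methods

This note records the model, its reductions, the numerical choices and the
limits of what the test suite demonstrates.

## Problem and reduction

The physical system is a 10 cm titanium blood conduit (the heat exchanger)
embedded in an aluminum housing on the descending aorta, heated by a
cylindrical waste-heat source (64 W TAH-class over a 4.6 cm × 1 cm lateral
surface, or 24 W LVAD-class over 2.8 cm × 1 cm), with optional titanium
fins in the lumen and an optional 0.25 cm copper heat guide wrapped around
the conduit.  Resolving this in 3-D is a cluster-scale job; `hemotherm`
replaces the 3-D domain with two reduced surrogates that keep every
governing equation and every material zone:

* **Planar channel** (default for all four designs): a 2-D (x, y) channel
  of height equal to the lumen diameter (2.2 cm, the mid-range of the
  tapering descending aorta), with independent solid stacks on the near
  side (facing the source) and the far side.  An effective out-of-plane
  depth of half the lumen perimeter (πD/2) carries the full descending
  flow and the full source power, which preserves the mixed-temperature
  rise P₀/(ρ_b c_p Q̄) — the quantity that controls systemic heating.  The
  planar mode is the default for the base designs too (not only for
  fins/guide) so that near/far asymmetry exists everywhere and the four
  designs are compared like-for-like.
* **Axisymmetric pipe**: a 2-D (x, r) pipe with annular solid layers; used
  by the validation suite (Poiseuille, Womersley, Graetz, cylinder-volume
  oracles) and available as an alternative base-design surrogate.

The domain is the 23 cm descending/abdominal segment with the exchanger
centred; the source band (length = source diameter) is centred at 50% of
the exchanger length.  The 3-D surface flux P₀/A is re-normalised onto the
surrogate band so the deposited power is exactly P₀.

Solid stacks (lumen outward): 1 mm titanium conduit wall (the wall
thickness is not tabulated anywhere; 1 mm is chosen so the copper guide's
0.15 cm lumen standoff remains geometrically consistent, and it is
configurable), then aluminum to the full conductor thickness (3.1 cm, or
4.3 cm for the guided design).  The guided design inserts the 0.25 cm
copper sheet 0.15 cm from the lumen with 1 cm uncovered margins at both
exchanger ends; since the sheet physically wraps around the conduit, the
near-side and far-side copper strips are coupled by per-column conductance
links G = 2 k_Cu t_Cu Δx / (πD/2) representing the two circumferential
conduction paths.

The two perpendicular full-diameter fins become a single 2 mm titanium
splitter at mid-channel spanning the exchanger window — the planar analog
of one fin per symmetry half-plane.  The reduced velocity profile is a
function of y only, so the split (two sub-channel) profile is applied over
the whole domain; the mid-channel band outside the exchanger window is
stagnant fluid.  This keeps row-wise mass and enthalpy conservation exact
at the splitter's leading and trailing edges at the cost of a small
stagnant wake that real flow would not have.

## Flow solver

Fully developed parallel flow: u = u(y, t) x̂ makes the convective term
vanish identically, leaving ρ_b ∂u/∂t = g(t) + ∂/∂y(μ_b(|∂u/∂y|) ∂u/∂y)
with no-slip walls, Carreau–Yasuda viscosity at the single strain component
|∂u/∂y|, and g(t) = −∂p/∂x determined at every instant by the integral flow
constraint (the pressure level itself is dynamically irrelevant in a rigid
incompressible vessel, so no outlet pressure waveform is modelled).  With
fins, the two sub-channels share one g(t), i.e. equal axial pressure
gradient across parallel paths.

Discretisation: finite volumes on a wall-clustered transverse grid
(cosine clustering; ~48 cells across the lumen at production settings),
BDF2 in time (backward Euler for the first step) with Picard iteration on
the viscosity, step 2.5 ms, outputs saved every 10 ms.  The flow constraint
is eliminated analytically per step (two linear solves), so continuity
holds to round-off at every saved instant.  Cycles are marched from the
steady profile until two consecutive cycles agree to 1e-4 m/s (about 7
cycles for the cardiac waveform).

Validation: Newtonian centreline ratios (2.0 pipe / 1.5 channel),
Womersley α ≈ 15 oscillatory pipe flow within 1% RMS of the Bessel-function
solution, second-order transverse convergence, monotone viscous decay, and
a shear-thinning pipe profile against a brute-force stress-inversion
oracle (the steady stress is exactly linear in r).

## Synthetic inlet waveform

No tabulated waveform exists, so the generator synthesises one: a raised
cosine systolic lobe (centre 15%, width 30% of the cycle), an optional
early-diastolic reverse lobe, and three small seeded zero-mean harmonics;
the result is normalised so the discrete mean equals `mean_q` exactly and
the peak equals `peak_ratio · mean_q` exactly.  Defaults: period 1 s
(consistent with the reported intra-cycle instants), inlet mean 5/0.7 L/min
with a 0.7 descending-aorta fraction — i.e. a descending mean of exactly
5 L/min (8.333e-5 m³/s) — peak ratio 4, reverse fraction 0.05.  The
generator is a pure function of its arguments; it emulates the shape of a
physiological aortic pulse, not any specific recording, so agreement with
measured waveforms is out of scope.

## Energy solver

One temperature field spans fluid and solids: upwind axial advection in
the blood (both flow directions; the brief reverse lobe re-admits 37 °C
blood at the outlet), central diffusion with harmonic-mean face
conductivity (exactly conservative across material interfaces), implicit
Euler in time at the 10 ms output step, fixed 37 °C inflow, zero-diffusion
advective outflow, prescribed-flux source band and perfect insulation
elsewhere.  Temperatures are handled in °C throughout (the equations are
shift-invariant).

The solid stack's thermal time constant is O(minutes) while a cycle is
1 s, so plain cycle marching to the periodic state is impractically slow
(≈0.8% residual decay per cycle).  The solver therefore uses the two-step
procedure — a steady solve with the cycle-mean velocity profile as the
initial state — followed by periodic shooting: the cycle map is affine in
the temperature vector, so the periodic fixed point solves a linear system
that GMRES handles matrix-free (one matvec = one source-free cycle).  A
few plain cycles are then run to produce the saved output and verify
periodicity (cycle-to-cycle tolerance 0.02 °C by default).  Plain cycling
remains available (`accelerate=False`).

Energy accounting: at the periodic regime the cycle-averaged advected
enthalpy gain (outlet minus inlet, upwinded exactly as the scheme does)
closes on the source power to well under 1% for both power levels; the
instantaneous interface heat flux oscillates above the source power during
systole and below it in late diastole.

Validation: developed-region Nusselt numbers within 2% of the Graetz
closed forms (4.364 pipe constant-flux, 5.385 one-side-heated parallel
plates, evaluated at low Péclet so the low-resolution domain is thermally
developed), a transient solid slab against the eigenfunction series
solution (<1%), exact linearity of the temperature excess in source power,
a discrete maximum principle in the fluid, and steady interface flux equal
to the source power within 0.5%.

## Cell tracking and TEI

Platelets (3 µm) and red blood cells (7 µm), density 1050 kg/m³, respond
to the fluid through Stokes drag only; the response time uses the local
Carreau–Yasuda viscosity by default (configurable to a constant).  Because
τ_p ≈ 1e-7 s is far below any flow step, the linear drag ODE is advanced
with its exact exponential update — no stiffness, no sub-stepping; the
trajectory step is 1 ms with temperatures sampled every 10 ms by
NaN-aware bilinear interpolation of the final-cycle fields.  Wall
collisions reflect specularly (speed-preserving); in the parallel-flow
reduction the fluid velocity has no transverse component, so collisions are
rare and cells keep their seeded wall distance — near-wall residence is if
anything over-, not under-estimated.  Cells are seeded once on the
exchanger-inlet cross-section: platelets with areal density ∝ (distance
from axis)³ — radial CDF (r/R)⁵ in the pipe, |y−c|³ density in the channel
(the areal reading of the cubic margination law; the marginal-pdf reading
is selectable) — red cells uniform.  Tracking runs 10 cycles, discards the
first, and stops at an outlet surface.

TEI integrates the absolute temperature (°C), not the excess over 37:
sub-second transits then produce the small single-digit s·°C minima that a
population table shows, which an excess reading could not.  An optional
weighting function w(T) (identity default) is the hook for
threshold-weighted variants; none is invented.  Exposure reports accumulate
time above each hyperthermia threshold using interval-midpoint
temperatures.

## Study conditions and problem sizes

Production/acceptance scale: 6 axial cells/cm (23 cm domain), 48
transverse fluid cells plus the solid stacks (≈10⁴ cells), flow step
2.5 ms, thermal step 10 ms, periodicity tolerance 0.02 °C, 500 + 500
tracked cells for 10 cycles.  The test suite uses 4 cells/cm and 36
transverse cells so the whole suite runs in minutes; grid-refinement
checks (8 → 16 cells/cm steady) confirm the peak interface temperature is
resolution-stable to <1%.

## What the surrogate does and does not show

* It reproduces conservation exactly, the supra-physiological interface
  temperatures of the base designs, the downstream shift of the
  temperature peak (convective heat transport), the near-side/far-side
  asymmetry, the benefit ordering base > fins ≥ fins+guide in both peak
  interface temperature and maximum TEI, and platelet-vs-RBC exposure
  differences driven by margination.
* The 3-D fins shed vortices and mix the boundary layer; a parallel-flow
  reduction cannot represent that.  The surrogate recovers only the
  geometric part of the fins' benefit (doubled wall shear in the
  sub-channels thins the thermal boundary layer by the Lévêque γ^{1/3}
  factor), so the fins' temperature reduction is systematically
  understated: the surrogate gives a ~4–5 °C drop in the maximum
  cell-sampled temperature where the 3-D analysis reports more than 8 °C.
  For the same reason the outlet-plane temperature SD ordering holds for
  the systolic SD peak but not for the cycle mean (the near sub-channel
  carries all the heat with half the flow, and the mixing that would
  homogenise it is absent).  No mixing closure is invented.
* The steep temperature gradient at the exchanger's distal end (insulation
  discontinuity) appears qualitatively; its magnitude is mesh-dependent
  and is reported, not matched.
* Heat leakage to perivascular tissue, neovascularisation, fluid-structure
  interaction, secondary flows, turbulence and cell-cell interactions are
  out of scope.

## Numerical details worth knowing

* Degenerate inputs: zero source power yields a uniform 37 °C field; a
  fully insulated solid-only steady problem is rejected as singular
  (transient integration of the same configuration is fine).
* The Carreau–Yasuda asymptote approach is slow for a = 0.64: the law is
  within 1e-4 of μ₀/μ∞ at shear rates 1e-8/1e8 1/s but needs 1e-12/1e12 to
  be within 1e-6.
* Solid densities (not tabulated with the heat capacities) use handbook
  values — Al 2700, Ti 4506, Cu 8960 kg/m³; steady results are independent
  of them, they only set transient storage.
* The source area uses the lateral cylinder surface πdh; end caps can be
  included via `include_caps`.
* Tie-breaks: the interface-profile argmax reports the first maximal
  column; a flat (zero-power) profile reports `None`.
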