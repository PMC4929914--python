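# Methods

`flapsim` models the aerodynamics of a calliope hummingbird
(*Selasphorus calliope*) in fast forward flight at U = 8.3 m/s. The
pipeline has four stages: a synthetic wing-kinematics generator standing in
for wind-tunnel marker tracking, surface reconstruction, kinematic
descriptors, and an immersed-boundary incompressible Navier-Stokes solver
with force/power/vortex post-processing.

## Coordinate frame and flight parameters

Bird-fixed wind-tunnel frame: +X downstream along the freestream, +Z up,
+Y to the bird's left, origin at the shoulder midpoint. Thrust is the -X
force. The default `FlightConfig` carries the morphology and wingbeat of
the study subject: body mass M = 2.8 g, wingbeat frequency f = 45.5 Hz,
stroke-plane angle beta = 67.9 deg, stroke amplitude Phi = 102.5 deg, wing
length R = 4.51 cm, mean single-wing area S = 5.18 cm^2, body angle
chi_b = 12 deg, chord Reynolds number Re = U c/nu = 3000 with
c = S/R = 1.149 cm, and a production time step of 5 us (about 4400 steps
per wingbeat). Air density is fixed at rho = 1.2 kg/m^3 and g = 9.81
m/s^2; with these, the power coefficient worked example reproduces the
aerodynamic power to the printed 0.1 mW.

## Synthetic kinematics (what it emulates, what it does not)

The generator emulates nine tracked markers per wing (five leading-edge,
one wingtip, three trailing-edge) sampled 22 frames per cycle. The wing is
a zero-thickness membrane with an elliptic chord distribution pitching
about a straight leading-edge spar. The kinematic program prescribes, as
periodic functions of cycle phase (phase 0 = top of stroke; the first half
cycle is the downstroke):

- a cosine stroke sweep of amplitude Phi/2 within the stroke plane;
- optional out-of-plane deviation (default zero);
- the parasagittal chord angle psi per spanwise station, linear in r/R
  between a proximal (r/R = 0.15) and a distal (r/R = 0.9) series:
  psi_p = 17 + 3 sin(2 pi phi) and twist psi_d - psi_p =
  7.5 - 32.5 sin(2 pi phi) degrees, so the twist peaks at -25 deg at
  mid-downstroke and +40 deg at mid-upstroke, the proximal chord angle and
  effective angle of attack stay positive through the whole cycle, and the
  distal section pitches leading-edge-down near mid-downstroke (thrust
  with lift) and strongly leading-edge-up near mid-upstroke, where its
  effective angle of attack is negative (thrust at the cost of negative
  lift) — the qualitative flight style the package studies;
- a sinusoidal area modulation of amplitude 4.85% chosen so the
  downstroke/upstroke conditional mean areas are 5.34 / 5.03 cm^2 around
  the 5.18 cm^2 mean;
- isotropic Gaussian marker noise, default sd 0.2 mm (sub-pixel scale for
  1000 Hz videography of a 4.5 cm wing).

The prescribed pitch is defined as the *projected* (parasagittal) chord
angle; the generator solves a small closed-form trigonometric equation per
station so that the metrics stage recovers the prescription exactly, which
makes parameter-recovery tests meaningful. Deliberately not emulated:
spanwise bending and camber (the membrane is harmonically flat), feather
gaps, tracking dropouts, and cycle-to-cycle variability of a live bird.
Passing recovery tests therefore demonstrates correctness of the
reconstruction/metrics operators, not robustness to every artefact of real
videography.

## Surface reconstruction

Per frame, a closed periodic cubic spline is fitted through the nine
markers in anatomical order. The spline uses centripetal
(square-root-chord) parameterization: on an ellipse oracle the chord-length
variant overshoots up to ~3% of the semi-major axis near the
high-curvature tip, while the centripetal fit stays below 1%, which is the
accuracy the outline contract asks for.

The planform interior is triangulated once, in the best-fit-plane
projection of the first frame: the outline is resampled uniformly in the
spline parameter, interior points are seeded on a hexagonal lattice sized
so the triangle count lands near the requested target (default 1335
elements, the reference reconstruction scale; CFD profiles use a few
hundred), and a Delaunay triangulation filtered by polygon containment
gives the connectivity, which is then fixed for all frames. Every frame
lifts the same parameter nodes to 3-D by solving a cotangent-weighted
Laplace (harmonic) problem with the frame's 3-D outline as Dirichlet data.
A harmonic membrane slightly underestimates the area of a twisted outline
(observed 2-3%), well inside the 5% contract.

The shoulder position needed for spanwise stations is recovered as the
static point minimizing the summed squared distance to every frame's spar
line (the five LE markers plus the tip are collinear on the spar); this
least-squares line intersection reproduces the generator's shoulder to
machine precision on noiseless data.

Node trajectories are refined in time with periodic cubic splines (the
series is an integer number of cycles; a wrap frame closes the period),
and nodal velocities are the analytic spline derivative. Stroke
segmentation places cycle boundaries at maxima of tip elevation in the
stroke plane (start of downstroke), with endpoint extrema honoured;
downstroke runs from each maximum to the following minimum.

The body is a watertight fusiform surface of revolution (about 3500
triangles, 8 cm long, max radius 1.1 cm) pitched nose-up by chi_b, nose
upstream, centred slightly below and behind the shoulders.

## Kinematic descriptors

Chord angle psi: signed angle between the LE->TE chord, projected to the
parasagittal (X-Z) plane, and the flight direction; positive
leading-edge-up. The projection is used because the flight direction is a
single axis; the 3-D chord makes an ambiguous angle with it. Effective
angle of attack alpha adds the upwash angle of the relative wind
(freestream minus the leading-edge velocity, the LE point being the
stated reference), so alpha = psi for a motionless wing, and a wing
plunging at the flight speed sees alpha = psi + 45 deg. Angle series are
unwrapped in time and reported in (-180, 180]. Cycle summaries: mean tip
speed U_tip in the body-fixed frame (we read the study's tip-speed figure
as body-relative, since the printed mean 8.14 m/s is below the flight
speed and yields advance ratio J = U/U_tip = 1.02), conditional mean areas
per half-stroke, and twist extremes per half-stroke.

With nine markers the reconstruction attenuates the distal twist somewhat
(prescribed -25/+40 deg recovered as about -23/+37 at the default marker
layout); uniform-pitch programs are recovered to better than 0.2 deg.

## Flow solver

Incompressible Navier-Stokes on a staggered, non-uniform single-block
Cartesian grid. The grid has a uniform fine block around the wings and
geometrically stretched outer regions with adjacent-cell ratio <= 1.1;
outer faces may overshoot the requested extents by up to one cell so the
stretching stays exact, and cell counts are padded to multiples of four to
keep the multigrid hierarchy deep.

Time integration is a fractional-step scheme: explicit Adams-Bashforth-2
convection (divergence form, central second-order interpolation) and
diffusion (explicit is adequate at desk Reynolds numbers, where the
advective CFL is the binding constraint; the configured limit is
CFL <= 1 with runs targeted at ~0.4), immersed-boundary direct forcing on
the provisional velocity, then a pressure projection. Boundary conditions:
uniform inflow at the upstream face, convective outflow advected at the
mean exit speed with a uniform flux correction enforcing global mass
balance, free-slip lateral walls; or fully periodic (verification mode).
The stored pressure is kinematic (p/rho).

The pressure Poisson equation is solved by a geometric multigrid V(2,2)
cycle: re-discretized coarse operators on coarsened face arrays (axes with
odd counts are simply not coarsened at that level), volume-weighted
restriction, trilinear prolongation, and — on non-periodic stretched grids,
where point relaxation stalls on high-aspect outer cells —
alternating-direction zebra line smoothing (vectorized Thomas solves);
periodic grids use red-black Gauss-Seidel. The singular all-Neumann
problem is made compatible by removing the volume-weighted rhs mean
(reported; an error above a relative threshold raises instead) and the
gauge is fixed to zero mean. Iteration counts are grid-size independent
(about 10 cycles to 1e-10 on uniform grids); per-step solves warm-start
from the previous pressure at a relative tolerance of 3e-5.

Verification: the z-invariant Taylor-Green vortex (an exact Navier-Stokes
solution, energy ~ exp(-4 nu t)) is reproduced with <1% energy error after
one advective period at 64^3; manufactured solutions show second-order
convergence of both the Poisson operator and the momentum discretization;
a uniform stream with no bodies is preserved exactly.

## Immersed boundary

Sharp-interface direct forcing. The watertight body marks interior cells
by ray parity (a structured-lattice rasterization: each triangle is
projected onto the z-ray columns it covers and crossing parities are
counted — no general ray caster is needed on a lattice). Every staggered
velocity face inside the body, or within 0.55 fine cells of the body skin
or of a wing membrane, is set to the local surface velocity (barycentric
interpolation at the nearest surface point, found with a k-d tree over
triangle centroids plus an exact vectorized point-triangle distance).
Membranes are zero-thickness, so the forcing shell is the mechanism that
transmits their motion to the fluid; the subsequent projection perturbs
the forced values at first order in the cell size, which is the standard
behaviour of non-iterated direct forcing. Fresh cells (solid to fluid, for
moving closed bodies) are refilled by the same forcing; the bird's body is
static, so in the flapping runs fresh cells arise only in tests.

Surface traction is sampled per triangle from the grid: pressure and
viscous stress (mu (grad u + grad u^T)) are trilinearly interpolated at
probes 1.4 and 2.8 fine cells along the normal and linearly extrapolated
back to the surface (exact for linear fields, removing the probe-offset
bias); closed surfaces use the outer side only, membranes carry the jump
between sides. Force coefficients normalize by (1/2) rho U^2 S and the
power coefficient by (1/2) rho U^3 S with S always the *reference* area
5.18 cm^2 — this normalization choice is what makes the power worked
example reproduce P = (1/2) C_P rho U^3 (2S) = 94.5 mW exactly from
C_P = 0.266. The aerodynamic power integrand is the stress exerted *by*
the wing on the fluid dotted with the body-frame wing velocity, so
consumed power is positive.

## Grid profiles and what desk runs can claim

The production-scale configuration (25 x 20 x 16 cm^3 domain, ~1/60 cm
spacing, 704 x 842 x 560 points, Re = 3000, seven cycles) is documented as
the `production-emulation` profile and deliberately refuses to run without
an explicit opt-in: it needs hundreds of millions of points and is a
multi-core, multi-day computation. (The printed "160 cm" resolution in the
source description is physically impossible for a 25 cm domain and is read
as 1/60 cm, consistent with the stated point counts.)

Two desk profiles run the same physics scaled down, on one CPU:

- `desk`: fine spacing c/16, Re = 300, multi-million-cell grids — hours.
- `mini`: fine spacing c/4.5 (about 2.6 mm), Re = 300, a 68 x 68 x 56 grid
  (~260k cells), 427 steps per cycle, 2 cycles with the first discarded as
  the impulsive-start transient, ~300-element wings. This is the profile
  the automated verification runs use; a full-configuration plus an
  isolated-body run complete in roughly ten minutes on one CPU. The
  resolution is the finest for which that pair of runs stays within the
  package's verification time envelope; a c/6 control run reproduces the
  same conclusions.

At mini resolution the chord carries only ~4-5 cells, so boundary layers
and leading-edge vortices are under-resolved, and at Re = 300 viscous drag
is several times larger than at the production Re = 3000. Desk runs
therefore support *directional* statements — downstroke-dominant vertical
force (the simulated C_Z down/up split of roughly 1.06 / 0.07 mirrors the
production-scale pattern), positive aerodynamic power dominated by the
downstroke, and wing-body interaction roughly tripling body lift over the
isolated-body run — and not production force magnitudes. One directional
property does *not* survive the Reynolds reduction: the cycle-mean wing
thrust. At Re = 300 the exaggerated profile drag exceeds the forward tilt
of the lift vector and the net wing C_T comes out negative, with the same
sign at finer-grid control resolutions, i.e. it is a Reynolds effect, not
a resolution artefact. The thrust mechanism itself
(distal negative angle of attack on the upstroke redirecting the force
forward) is visibly present in the sectional kinematics and the pressure
fields, and the corresponding acceptance check is left failing rather than
weakened. The isolated-body experiment keeps the identical body,
orientation and grid and only removes the wings, so the body-lift
comparison isolates the interaction effect.

## Numerical choices and degenerate inputs

- Poisson compatibility defects are removed and reported; defects above a
  relative threshold (default 1e-3) raise.
- Cell classification jitters lattice coordinates by ~4e-7 cells to avoid
  edge-on ray intersections; triangles projected edge-on are skipped
  (their crossings are closed by neighbours on a watertight mesh).
- Outline fitting rejects duplicate or collinear markers; triangulation
  rejects self-intersecting outlines; chord extraction rejects stations
  outside [0, 1] and degenerate (zero-projection) chords; the angle of
  attack is undefined (raises) when the relative wind vanishes.
- Marker-table parsing names the frame and column of the first offending
  row; a frame without exactly the nine canonical markers is an error.
- The CFL guard raises with the offending time rather than silently
  producing an unstable field.

## Known limitations

- The wing is an inextensible-in-connectivity harmonic membrane: no
  camber, no aeroelastic feedback (kinematics are imposed, as in the
  marker-driven study design).
- Direct forcing is first-order accurate at the interface; global
  quantities remain second-order away from surfaces.
- The advective outflow condition reflects a small transient at impulsive
  start; the first cycle is discarded before averaging.
- Phase-conditional averages use equal-duration half-strokes from the
  tip-elevation segmentation; the whole-cycle mean is time-weighted and
  equals the half-stroke mean only for equal durations (checked on
  symmetric inputs).
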