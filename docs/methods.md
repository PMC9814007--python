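# Methods

`ventriflow` is a desk-scale toolkit for studying left-ventricular (LV)
hemodynamics with a moving mitral valve (MV) under the Chimera (overset-mesh)
modeling paradigm.  It does **not** solve the Navier–Stokes equations.
Instead it provides (i) fully parametric, reproducible 4D geometry and valve
kinematics, (ii) the overset-domain bookkeeping a Chimera solver would
consume, (iii) a kinematically constructed incompressible-looking flow field
that stands in for a solver, and (iv) the complete hemodynamic
post-processing suite (energy loss, vorticity, wall shear stress, particle
residence time, cycle statistics).  The design goal is that every
post-processing operator can be validated against closed-form oracles, and
the full three-scenario comparison (LV with torsion, LV+MV without torsion,
LV+MV with torsion) runs in minutes on one CPU.

## Coordinate and unit conventions

Apex at the origin, long axis along +z toward the base.  Geometry in mm,
time in s, velocity in m/s, pressure in Pa (mmHg converted at 133.322 Pa),
dissipation in W/m³, energy in J.  Metric kernels convert mm→m internally.

## LV geometry and kinematics (`ventriflow.lv`)

The endocardium is a truncated prolate spheroid capped with a flat basal
disk.  Defaults: basal opening radius 24 mm, apex-to-base distance 80 mm,
removed-cap height 20 mm, 48×32 surface sampling — an end-diastolic cavity
of ≈163 ml.  The template mesh is fixed; each frame applies
`diag(s, s, s^0.5)` so radial shortening dominates longitudinal shortening,
as in a normal ventricle, and the same vertex index is the same material
point in every frame (1-to-1 vertex correspondence).  The per-frame scale
`s` is solved with a bracketed root find (tolerance 1e-10) directly on the
divergence-theorem mesh volume, so the mesh tracks the volume curve to
~1e-12 relative rather than the 1 % contract.

The volume curve is periodic with cycle duration 0.87 s (0.87 = 290 frames
× 3 ms, the resampling the toolkit reproduces), systole occupying the first
third.  Systole is a raised-cosine decay EDV→ESV; diastole is the sum of two
integrated raised-cosine bumps centred at the E-peak (0.42 s) and A-peak
(0.78 s), with the E/A split parametrised by the ratio of peak filling rates
(default 2.0).  Defaults EDV 162.7 ml / ESV 53.7 ml give the reference
ejection fraction 0.67 and stroke volume 109 ml.

Torsion is a rigid rotation of every frame about the axis through the mitral
annulus centroid and the apex.  The angle is a two-segment piecewise-linear
ramp: 0 → γ over systole (twist), γ → 0 over diastole (untwist), γ = 13° by
default.  Rigid rotation leaves the enclosed volume and all vertex–axis
distances unchanged to round-off; tests enforce 1e-10 relative.

Temporal resampling fits a cubic spline per vertex coordinate, natural end
conditions by default ("periodic" available as an option).  When the mesh
declares a cycle duration, the frame at t = 0 is re-appended at t = T before
fitting so the sampled window covers the whole cycle; an aperiodic sequence
is splined as-is.  Natural end conditions on a periodic motion introduce a
small end-of-cycle curvature error — the periodic option removes it; the
default is kept natural because that is the convention the resampled frame
count (290 at 3 ms) is defined against.

Surface quality uses equiangular skewness
`max((θmax−60)/120, (60−θmin)/60)`; hexahedral cells use the corner-wise
scaled Jacobian.  Thresholds 0.9 / 0.02 flag failed elements.

## Mitral valve (`ventriflow.mitral`)

The annulus is static — the pointwise temporal mean of its 4D configurations
— a closed polyline with centroid and best-fit (SVD) plane.  The leaflet
mid-surface is a linear loft from the annulus to the free-edge profile (the
A-wave capture surrogate: annulus scaled to 35 % and dropped 9 mm), with a
2 mm physical thickness stored for ± half-thickness offset surfaces.  The
sheet splits along the commissural diameter into anterior and posterior
sheets sharing a 15° overlap band on both sides (mutual sheet contact is
allowed; self-intersection of one sheet is not — the overset method
tolerates inter-grid intersection only).

Opening angles are shaped by zone: anterior leaflet (station ±60°), front
commissure (60–120°), posterior leaflet (120–240°), posterior commissure
(240–300°), defaults 55/25/40/25° at peak opening.  The shaping function is
a periodic cardinal blend: tent (linear) functions of the four zone centres
softened by a ±5° moving average — a partition of unity with no overshoot
and the smallest slope an interpolating blend can have between centres 90°
apart.  The four control values are solved from a 4×4 linear system so the
*mean* of the assigned angles over each zone equals the prescribed zone mean
exactly; continuity on a 128-point annulus stays under 2° per vertex step.
Commissures open less than leaflets, preserving wall clearance where the
cavity is narrowest.

Leaflet motion rotates each circumferential station rigidly about its local
annulus-tangent hinge by `shaped_angle × f(t)`; `f` opens with a smoothstep
in early diastole, relaxes in diastasis, re-opens at the A-wave, closes at
end-diastole, and keeps an 8 % residual gap in systole (the valve is not
sealed).  The opening rotation sign is chosen per station as the one moving
the free edge toward the local outward radial direction, never through the
long axis.  Clearance against the LV wall is a signed point-to-surface
distance (positive inside the cavity), reported per zone with per-vertex
violations.

## Overset bookkeeping (`ventriflow.overset`)

Background cells are classified against closed wall surfaces into the four
Chimera categories.  Inside/outside testing casts one +z ray per (x, y)
column of the lattice and classifies all z stations by crossing parity; ties
are broken by a deterministic 1e-9 mm jitter.  Cells on the non-fluid side
are *dead* (unless a cut-control pair exempts that wall/fluid-zone
combination); fluid cells within one cell (configurable) of a dead cell are
*receptors*; fluid neighbours of receptors are *donors*; the rest *solve*.
The four labels always partition the grid.

Interpolation stencils are trilinear over the cell centres of an overlapping
component grid — by default the background grid offset by half a spacing, so
every receptor centre is strictly interior to a donor block.  Weights are
non-negative, sum to one to 1e-12, and reproduce affine fields exactly.  A
receptor whose donor block leaves the component grid or touches a
dead/receptor cell is an *orphan*, reported with its location — the
operational signature of the "vanishing zone" failure mode; a separate
detector flags any zone whose solve-cell count drops to zero (or by more
than a configurable fraction) between frames.

## Synthetic cycle flow (`ventriflow.flow`)

The velocity field is kinematically constructed, not solved:

* **Wall-conforming deformation.**  Frames share vertex correspondence and
  deform near-affinely, so the material motion
  `u = (ṡ_r/s_r)(x, y) + (ṡ_z/s_z) z ẑ` (rates estimated from rms
  radius/height of consecutive frames) is included every frame.  This is
  what lets Lagrangian tracers ride the moving wall instead of being
  overrun by it.
* **Diastole.**  A raised-cosine transmitral jet from the mitral orifice
  toward the apex (exponential decay with depth, stagnating before the apex)
  plus a Gaussian-core vortex ring built from an azimuthal vector potential
  (exactly solenoidal in the continuum).  The ring sheds at the leaflet-tip
  depth when a valve is present and at the annulus otherwise, self-propagates
  apex-ward at 120 mm/s, and its circulation tracks the instantaneous
  filling rate.  Ring velocity is damped near the wall by a mask-erosion
  distance proxy (an image-vorticity surrogate).
* **Systole.**  A softened point sink at the outflow tract, damped near the
  apex so ejection drains the basal/mid cavity and leaves a low-motility
  apical pool.
* **Torsion.**  An optional azimuthal swirl `ω(t) r` with depth decay,
  driven by the torsion ramp rate.

Each frame the dominant (jet or sink) component is rescaled so the discrete
base-plane volume flux equals dV/dt of the volume curve — mass bookkeeping
is exact by construction at the base plane, and the cycle-integrated
inflow/outflow imbalance stays under 2 %.  The field is **not**
wall-conforming beyond the deformation part; the median wall-normal velocity
at the wall is measured per frame and reported in the field metadata rather
than forced to zero.  Boundary phases follow the on-off schedule (inlet
pressure 7 mmHg / outlet wall in diastole; outlet 120 mmHg / inlet wall in
systole); at no time are both ports open.

Canonical analytic fields (Couette, pipe Poiseuille, rigid rotation, Hill's
spherical vortex) are generated on the same container and serve as oracles
for every metric.  Note the polynomial velocity of these fields makes
central differences exact, so discrete divergence/vorticity errors sit at
round-off in the interior and first-order only in one-sided cells at mask
boundaries.

## Metrics (`ventriflow.metrics`)

Gradients are central differences inside the in-domain mask, one-sided at
mask boundaries.  The dissipation rate is
`Φ_V = ½ μ Σ_i Σ_j (∂u_i/∂x_j + ∂u_j/∂x_i)²` evaluated exactly in that
form (pure shear at 100 1/s with μ = 0.003 gives 30 W/m³ by hand), and the
energy loss integrates `Σ Φ_V V_i dt` with trapezoidal time weights (weights
sum exactly to the covered span, making EL additive over time partitions).
Against closed forms: Couette EL is exact to round-off (linear profile);
pipe Poiseuille EL matches pressure-drop × flow-rate within 1 % on a 64³
grid.  Vorticity magnitude is the discrete curl; the Q-criterion
(½(‖Ω‖²−‖S‖²)) is provided to localise vortex cores against shear sheets —
it is what the pipeline uses to measure the ring-shedding depth, because
|ω|² is dominated by the jet's shear layer.

Velocity/vorticity class fractions are area-weighted histograms on analysis
planes — LA (the y≈0 long-axis plane through apex, MV centroid and outlet)
and SA1/SA2/SA3 (short-axis at 75/50/25 % of the apex–base extent, top to
bottom).  Default class edges: velocity {0, 0.25, 0.5, 1.0, ∞} m/s,
vorticity {0, 250, 500, 750, ∞} 1/s; both config-overridable.  Fractions sum
to 1 to 1e-12.

WSS probes the velocity one grid spacing δ inside the wall along the inward
normal: `τ = μ‖u_t(δ)‖/δ` — a first-order estimate, accurate to ~5 % for a
linear near-wall profile; vertices whose probe exits the mask are flagged
and excluded from aggregates.  The 17-sector endocardial bull's-eye follows
the standard convention (6 basal, 6 mid, 4 apical sectors and an apex cap;
axial bands at 20/45/70 % of the apex–base axis, angular origin on +x,
configurable).  Sector aggregates are area-weighted means and maxima with
barycentric vertex areas, so sector areas sum exactly to the surface area;
difference maps are sector-wise `a − b` (positive where the first case
dominates).

## Particle transport (`ventriflow.particles`)

Massless tracers, classical RK4 in space with linear interpolation of the
field in time, 4 sub-steps per frame interval by default.  Velocity is
trilinear in space.  Convergence order measured on a solid-body-rotation
closed orbit is 4.0; one period returns to the start within 1e-6 of the
domain radius at 8 sub-steps per frame.

Inlet release: particles at the nodes of a triangulated inlet disk (default
4,500; exact node counts are met by subsampling or seeded barycentric
augmentation), released at the start of a diastole.  With a periodic
synthetic field any cycle start is equivalent, so release uses the first
cycle.  Ejection is the first outlet-plane crossing with outward velocity
during a systolic phase (or being carried outward above the plane within the
outlet radius — the plane sits inside the *minimum* basal height, which the
base descends past during systole).  Beat index = ⌈(t−t_release)/T⌉.  A
particle leaving the mask anywhere else becomes `escaped_mask`: these are
numerical leakage through the imperfectly wall-conforming synthetic field
(≈10 % of seeds in the demo), are excluded from residence-time denominators
and reported separately.  Residence time is the three-way classification
(direct flow / second beat / residual after two beats); counts always sum to
the seeded total.  Residual motility is counted against a strict
`speed < 0.5 m/s` threshold.  An apical-release variant seeds uniformly
(seeded rejection sampling) in the cavity below a given axial fraction.

## Cycle statistics (`ventriflow.cyclestats`)

Three spherical probe clouds (1,000 points, 5 mm radius) at 25/50/75 % of
the MV-centroid–apex axis, uniform-in-ball sampling from a seeded generator.
Per frame: 5th/50th/95th percentiles of velocity magnitude and components,
vorticity magnitude and (when present) pressure.  Cross-cycle variation is
the per-pixel sample (n−1) standard deviation on the LA plane at a fixed
phase (default the E-peak), phase-aligned by snapping to the nearest frame
modulo the cycle (frames are commensurate with the cycle by construction).
A strictly periodic field gives exactly zero; cycle-to-cycle solver
transients are emulated only when a seeded `cycle_perturbation` is enabled,
in which case cycles are tiled explicitly.  The closed-form check: one pixel
perturbed by ε in one of four cycles gives std ε/2.

## Demo pipeline and reproducibility

`run_pipeline` executes the three scenarios on a shared coarse 48³ Cartesian
grid: geometry (24 key frames resampled to 30 ms), valve construction,
overset classification spot-checks with vanishing-zone detection, one
periodic cycle of synthetic flow (wrapped in time for the two-beat particle
advection), energy loss over the cycle, E-peak class fractions and WSS
bull's-eye, ring-shedding depth via the Q-criterion, inlet-released
residence time (4,500 particles), probe percentiles and cross-cycle std.
The mitral/outlet port layout is sized to the minimum (end-systolic) basal
radius so both ports stay inside the cavity at every phase.  One global seed
fans out to per-module seeds through SHA-256 (all below 2³¹); the summary
JSON is byte-identical for a fixed seed (wall-clock timing is logged, not
embedded).  A full default run takes ≈4–5 min on one CPU; the acceptance
script uses 60 ms frames and 1,500 particles (≈50 s per run) — problem sizes
chosen so the whole validation suite stays interactive.

What the synthetic data does *not* emulate: pressure–velocity coupling,
turbulence/transitional dynamics (so cross-cycle variation is exactly zero
unless injected), torsion's effect on residence time (the swirl is purely
azimuthal here, so torsion leaves RT essentially unchanged — in a real
solve torsion redistributes transport), chordae/papillary anatomy,
patient-specific wall detail, and any solver-specific printed magnitudes.
Passing tests therefore validate the *operators* and the *bookkeeping*, not
patient-specific physiology.

## Known limitations

* The synthetic field is divergence-controlled only at the base plane;
  interior divergence is not forced to zero.
* WSS is first-order in the probe distance; bull's-eye values on coarse
  demo grids are indicative only.
* `escaped_mask` leakage (~10 %) is inherent to advecting through a
  non-wall-conforming kinematic field; real solver fields would not leak.
* STL round-trips merge duplicate vertices and drop data arrays (the format
  carries geometry only); VTK XML files are written in ASCII by a minimal
  in-repo serializer.
* The natural-spline default is kept for frame-count compatibility even
  though periodic end conditions are kinematically cleaner (available via
  `end_conditions="periodic"`).
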