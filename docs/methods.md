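# Methods

`gastroflow` simulates the flow of liquid gastric contents in a
stomach–pylorus–duodenum geometry whose wall motion is prescribed, and
measures how the coordination between pyloric closure and the antral
contraction wave controls gastric emptying, rapid (dumping-like) emptying,
and retrograde (bile-reflux-like) transpyloric flow.

## Geometry

The lumen is a tube of revolution around a smooth centerline: a J-shaped
gastric centerline (cubic spline through control points; antrum low,
corpus/fundus rising against gravity `-z`) joined at the pyloric midpoint
(arclength `s = 0`) to a straight duodenal tube along `+x`.  The rest
radius `r0(s)` interpolates monotone-cubically between knots.  Bulk
dimensions are physiological: stomach volume calibrated to 650 ml by a
single rescaling of the corpus/fundus radius knots (solved with Brent's
method on the Pappus volume integral), mean antral diameter `D = 50` mm,
pyloric diameter 9 mm when open.  Quantities the literature does not fix —
corpus length, centerline curvature, pyloric canal length (12 mm),
duodenal calibre (25 mm) and length (120 mm) — are package defaults
exposed in `GeometryParams` and documented as assumptions, not literature
values.  Voxelization is node-centred (a node is lumen iff its rest signed
distance is negative); each node caches its nearest-centerline arclength
and radial distance, which is all the moving-wall update needs because the
walls only ever move radially inward from rest.

The stomach is partitioned into `n` regions (default 13) by equal-width
centerline-arclength bins measured from the pylorus; region 1 is the
terminal antrum.

## Wall motion

Each cycle (period `T = 20` s) consists of peristaltic contraction,
terminal antral contraction (TAC) and antral relaxation.  A front is
initiated at the mid-corpus every `T` and travels toward the pylorus with
speed `V(d)` (`d` = centerline distance from the pylorus): `V = 2.5` mm/s
outside the terminal zone, ramping to `7 V` at the pylorus inside the last
30 mm, so the 30 mm TAC transit takes ~0.2 `T` and the phase chart matches
the published description (front enters the TAC zone at `t/T = 0.6`, TAC
ends near 0.8, relaxation occupies [0.8, 1.0]).  The occlusion field of a
front at distance `d_f` is

```
eps_eff(s, t) = eps(d_f) * g((s - d_f) / w(d_f)) * A(age)
```

with `g` a C1 cos^2 unit bump, occlusion depth `eps` rising linearly from
0.3 at the origin to 0.9 at the pylorus, and width `w` growing from 18 mm
to 54 mm inside the terminal 30 mm.  Depth and width are properties of
the wave *at its position* — this concentrates the terminal squeeze in
the TAC window; evaluating them at the field point instead pre-compresses
the terminal antrum while the front is still proximal and destroys the
phase-coordination effects the model exists to study.  `A(age)` ramps in
over 0.2 `T` when a wave initiates (a contraction cannot appear
instantaneously) and decays as cos^2 over 0.2 `T` after the front reaches
the pylorus (antral relaxation; the wall recoil is what lowers antral
pressure and drives retrograde flow).  Concurrent fronts combine by
elementwise maximum and the occlusion is capped at 0.95: the antral lumen
never fully closes; only the pylorus may.  The occlusion also fades out
over 6 mm above the pyloric sphincter: the canal's calibre is governed
solely by the open/close schedule (a wave crushing the canal would defeat
the permanently-open `T_C = 0` design and trap liquid against a closed
pylorus).

The pylorus closes on an independent trapezoidal schedule: the closure
interval per cycle is `[0.6 T + T_D, + T_C)`, with linear ramps of width
0.1 `T` *following* each endpoint ("begins to close" / "begins to
open"), which makes the time-averaged open fraction exactly `1 - T_C/T`.
The ramp width is a modelling choice (no transition time is established
for the sphincter); shorter ramps demand venting pressures from the
closing canal that scale with viscosity and leave the lattice pressure
range at the viscous end of the sweep.
The healthy control is `T_C/T = 2/3`, `T_D = 0`.  Pyloric closure scales
the local radius to zero over the sphincter length with a cos^2 axial
profile.  Two bookkeeping predicates — "open during TAC" and "open during
more than half of relaxation" — are computed from `(T_C, T_D)` by
interval arithmetic and annotate every sweep cell.

The lumen radius is `r(s,t) = r0(s) (1 - eps_eff) * pf(s,t)` with `pf`
the pyloric factor; the radial wall velocity is the central-difference
time derivative of this analytic field (the derivative is exact to the
10^-3 s stencil, far below the flow time scales).

## Fluid solver

D3Q19 multiple-relaxation-time lattice Boltzmann, collision performed in
velocity space with the precomputed matrix `A = M^-1 S M`; equilibrium
moments are the moments of the second-order Maxwellian, so equal rates
reduce exactly to BGK (used as a unit-test oracle).  Only the shear rate
is physics-bound (`s_nu = 1/tau`); the odd-moment rates default to the
TRT "magic" value with Lambda = 3/16, which removes the
viscosity-dependent slip of bounce-back walls (verified to push plane
Poiseuille error to round-off and tube flux error below 2% at 7.5-cell
radius); the remaining even rates take common stabilizing values.  Body
forces use Guo forcing.

Walls are realized by linear-interpolated (Bouzidi) bounce-back with the
moving-wall momentum term; the link-cut fraction comes from the level set
`psi = d - r(s, t)` evaluated at the two link ends.  A half-way-only
variant (exactly mass conserving) is a config switch.  Cells covered by
the advancing wall give their mass to a global reservoir; cells uncovered
next to wet cells are re-activated as liquid at the local mean density
and charged against the same reservoir; the reservoir is redistributed
uniformly over interface cells with a rate cap of 0.05 cell-mass per
step, so wall-displaced volume reappears smoothly at the free surface.
Three sphincter-region guards handle sub-grid closure at coarse
lattices: the canal snaps fully shut once its radius falls below 1.2
cells (a discretely sealed sub-grid tube would trap and compress its
remaining liquid); the occluded *antral* radius is floored at 0.5 cells
for kinematic viscosities below 50 mm^2/s and at 2.0 cells above (the
pressure needed to vent a deep squeeze scales with viscosity and must
stay within the lattice pressure range); the pyloric plane flux is exactly
zero whenever the canal is shut because the plane cells are then wall.
Because the floor differs between the viscosity extremes, the low- and
high-viscosity ends of the sweep are not run under identical numerical
guards -- cross-viscosity comparisons of absolute Q carry that caveat.

The free surface is a single-phase (liquid-only) interface-cell model:
interface cells carry a partial mass updated from streaming exchanges,
convert to liquid/gas when they over-fill or empty (with closed-layer
repair and excess-mass redistribution), and reconstruct their
gas-side populations from the atmospheric equilibrium at the local
velocity.  Gravity is handled in hydrostatic-equilibrium mode: no bulk
body force (a quiescent state has exactly zero transpyloric pressure
difference, so emptying is attributable to motility alone); gravity
enters only as an interface-flattening acceleration
`a_z = -k (z - h_ref) - c u_z` on interface cells, with `k = 50` 1/s^2
in gastric runs, critical damping `c = 2 sqrt(k)`, a dead band of 0.6
cells (the voxelized surface can only sit on node levels), and a cap of
0.002 lattice units; box fixtures default to a stiffer `k = 300`.  The force reference `h_ref` is the current
mass-weighted mean interface height — the force enforces *flatness*, and
the absolute level floats to conserve volume (it rises intra-cycle when
the contraction displaces lumen volume and falls as the stomach
empties).  The reported mean interface height `h_bar(t)` is the
bookkeeping level implied by the emptied volume and the rest
cross-section table.  Anchoring the force to the emptied-volume level
instead fights volume conservation at coarse resolution and churns the
surface; both references agree to within a cell in practice.

The duodenal outlet is a constant-pressure non-reflecting boundary
(non-equilibrium extrapolation at the reference density) on the last open
slice; outflow accumulates into the emptied volume.  The oesophagus is
closed wall (no refilling).  80% of the stomach (by height) and the
whole duodenum start as liquid; the rest of the stomach is gas.

Lattice units: `dx` is fixed per mode (1.5 mm full, 3 mm reduced); `dt`
is the minimum of the Mach bound (cap 0.05 against the expected peak
fluid speed, default 30 mm/s — pyloric jets exceed the ~9 mm/s peak wall
speed) and the `tau <= 2.5` bound, which governs for the viscous end of
the sweep (`mu` up to 4.2 Pa s).  Runs refuse to start outside the
admissible envelope and abort with a diagnostic if the density leaves
[0.5, 2].

## Outputs

* **Emptying**: transpyloric flux `q(t)` is the lattice-plane integral of
  the axial velocity over wet pyloric cells at `x = 0` (positive toward
  the duodenum; exactly zero when the pylorus is closed because the plane
  is then wall).  Cycle averages over an integer number of trailing
  cycles give `Q`, the anterograde/retrograde split `Q+ = <max(q,0)>`,
  `Q- = <min(q,0)>` (identity `Q = Q+ + Q-` enforced to round-off), and
  the dimensionless rate `q* = Q / (D^2 V)`.
* **Pressure probes** sit on the centerline 5 mm to either side of the
  pyloric midpoint; samples with a dry probe cell are NaN.
  `dp = p_antral - p_duodenal` is positive when driving anterograde flow.
* **Mixing efficiency** `M` is the liquid-average of the strain-rate
  magnitude `sqrt(2 S:S)` (the common reading of the second invariant;
  the algebraic `II_S` convention is selectable), time-averaged over >= 20
  velocity snapshots spanning one cycle, on interior liquid nodes only.
* **Tracers**: passive particles advected by RK4 through the trilinearly
  interpolated velocity field (default cadence: every 10 solver steps);
  wall penetrations are projected back along the local radial direction
  (count logged).  A particle is *emptied* while it is on the duodenal
  side of the pyloric midplane (`s < 0`); returning clears the flag, so
  retrograde returns are not counted.  The regional emptying probability
  is the per-region fraction emptied by each horizon.
* St = D/(VT), Re = rho V D / mu.

## Problem sizes and what the tests show

Test-suite and acceptance runs use the reduced 3 mm lattice (~2.1 x 10^4
wet cells; 2700 steps per cycle at the water-like end with the timestep
set by an expected 20 mm/s peak fluid speed at Mach cap 0.05, 4300 steps
per cycle at the tau-bound viscous end) with 2-3 cycles for rate averages
(first discarded as transient; the cycle-to-cycle Q difference is a few
percent by the second cycle), 9 cycles for the 3-minute tracer horizon,
and 2000 tracers.  These sizes resolve the
antrum with ~17 cells across but the open pylorus with only 3, so
absolute emptying rates converge from below: refining 3 mm -> 2.25 mm
raises the control Q by ~25%, and the remaining deficit against
full-resolution values is a factor ~1.5–2.5.  Sign structure, phase
timing, coordination ratios (e.g. Q(T_D/T = 1/8)/Q(control)) and
monotonic trends are robust to this; absolute band comparisons for the
control case must be read with the resolution deficit in mind.  The
synthetic geometry also replaces an anatomically segmented stomach with
a parametric tube of revolution: results about anatomical asymmetries
(e.g. greater- vs lesser-curvature emptying paths) are only qualitative
here.

## Known limitations

* Newtonian liquid only; no solid/particulate contents, no
  fluid–structure interaction, no tonic (fundic) contractions, no
  duodenal peristalsis, no nutrient feedback — all outside the model.
* Free-surface closure keeps the interface flat by construction;
  sloshing physics beyond flattening is not represented.
* Bouzidi interpolation is not exactly mass conserving; with the moving
  antral wall the global balance error is ~0.7% of the liquid volume per
  cycle at 3 mm, measured with the pylorus closed so no transpyloric flow
  is involved (outlet bookkeeping itself is exact, by overwrite-delta
  accounting).  The half-way switch restores exact conservation but is
  unstable against the moving antral wall at this resolution.
* Cycle-averaged emptying rates converge from below with resolution: at
  3 mm the healthy control yields ~2.5 ml/min at the water-like end
  (literature-scale values are 3-8) and ~3.2 ml/min at the viscous end
  (literature ~3); the always-open pylorus yields ~9 ml/min (literature
  10-30); the delayed-closure-to-control ratio is ~1.6 (literature 2-3).
  Sign structure, phase timing and monotonic trends are robust; absolute
  band and ratio comparisons at 3 mm must be read with this deficit in
  mind.
* The contraction-ratio and TAC-speed profiles are figure-derived
  approximations, exposed in `WaveParams`.
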