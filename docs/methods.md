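# Methods

## Physical model

The temperature field `T(x, t)` in the myocardium, the blood pool and the
applicator hardware is governed by the Pennes bioheat equation

    rho C(x,T) dT/dt = div( lambda(x,T) grad T ) + Q_p(x,T) + Q_m(x,T)

with density `rho` (kg/m3), effective volumetric heat capacity `rho C`
(J/m3/degC), thermal conductivity `lambda` (W/m/degC), a perfusion heat term
`Q_p` and a metabolic heat term `Q_m` (W/m3).

**Phase change.** Freezing is modelled with the effective-heat-capacity
method: the fusion enthalpy `L` is spread uniformly over the phase-transition
range between the solidus (-10 degC) and liquidus (0 degC) temperatures, so

    rho C_eff(T) = rho [ c(T) + L / (T_liq - T_sol) ]   for T_sol < T < T_liq

where `c(T)` interpolates linearly between the frozen and liquid specific
heats.  A liquid fraction `f(T)` ramps linearly from 0 at the solidus to 1 at
the liquidus; conductivity blends as
`lambda(T) = lambda_frozen + (lambda_liquid - lambda_frozen) f(T)`.

**Sources.** `Q_p = f(T) w (T_body - T)` with the volumetric perfusion
coefficient `w` (W/m3/degC) and `Q_m = f(T) q_m`: frozen tissue is neither
perfused nor metabolically active, and both shut down linearly across the
transition range, consistent with the capacity treatment.

## Geometry

The main model is a true-to-scale idealisation of a 9 Fr (3 mm diameter),
8 mm-tip cryoapplicator applied side-on to a planar myocardial slab of 6 mm
transmural thickness.  The tip is represented as a hollow rectangular metal
shell whose footprint on the endocardium equals the configured contact-patch
area (default 20 mm2, i.e. 8 x 2.5 mm; flat-contact tips of this class have
contact areas of this order) and whose height equals the tip diameter.  The
free surfaces of the tip are wrapped by a 3 mm blood layer; the slab extends
laterally 15 mm from the axis.  Coordinates are millimetres with +z transmural
(endocardium at z = 0, epicardium at z = 6 mm).

Boundary facets are labelled: `a` blood far field, `b` tissue far field,
`c` epicardial face, and `d/e/f` the interior (refrigerant chamber) surfaces
of the shell (tissue-near face, side walls, top).  A verification variant
replaces the slab with a 20 x 20 x 10 mm block ("wood_slab") for the in-vitro
bench comparison.

The mesh is a structured, graded hexahedral grid split into conforming
tetrahedra (Kuhn subdivision).  Grid lines coincide with all material
interfaces, so region volumes and the contact-patch area are exact at every
resolution.  The default "reduced" preset uses 0.9 mm edges near the
applicator (coarsening 4x toward the far field), giving ~49 000 tets and
~9 400 vertices; the "paper" preset (0.4 mm) gives a production-scale mesh of
~3e5 tets.  All headline numbers in the acceptance artefacts are computed at
the reduced preset; the convergence checks below bound the discretisation
error of that choice.

## Boundary conditions

Far-field surfaces carry Robin (convective) conditions `q = alpha (T - T_ext)`:

| label | main model            | slab bench        |
|-------|-----------------------|-------------------|
| a, b  | 1500 W/m2/degC, 36.5 degC (flowing blood / closed chest) | 700 W/m2/degC, 37 degC (water at rest) |
| c     | 200 W/m2/degC, 36.5 degC (closed-chest epicardium)       | unchanged |

**Refrigerant law.** The chamber surfaces exchange heat with the boiling
refrigerant (N2O, reservoir temperature -88 degC) through a Robin law whose
coefficient is modulated by a phase envelope: during a freeze it ramps up as
`1 - exp(-t/tau_fill)` while the supply lines fill (`tau_fill` = 10 s); after
deactivation the flux decays from its switch-off value as `exp(-t/tau_drain)`
while the residual refrigerant drains (`tau_drain` = 2 s).  The drain constant
is chosen so that the integrated post-switch cooling is small against the
thaw time scale — the rewarming delay is *slight*, matching the qualitative
behaviour of the hardware; a longer constant would make the drain dominate
the early thaw.

The single free magnitude `h_steady` is fixed by the documented calibration:
bisection in log h until a 150 s freeze reaches a minimum tissue temperature
of -82.6 degC (tolerance 0.5 degC).  On the reduced mesh this lands near
5e4 W/m2/degC.  This is the only quantity tuned against a published number;
every other parameter keeps its documented default.

## Material parameters

Values are literature-typical averages for myocardium/blood; all are
config-overridable.

| quantity | tissue | blood | applicator | units |
|---|---|---|---|---|
| rho | 1060 | 1060 | 8000 | kg/m3 |
| c liquid / frozen | 3600 / 1800 | 3600 / 1800 | 500 / 500 | J/kg/degC |
| lambda liquid / frozen | 0.5 / 2.0 | 0.5 / 2.0 | 15 / 15 | W/m/degC |
| latent heat L | 2.5e5 | 2.5e5 | 0 | J/kg |
| perfusion w | 5e4 | 5e5 | 0 | W/m3/degC |
| metabolic q_m | 700 | 0 | 0 | W/m3 |

Tissue perfusion corresponds to resting myocardial flow of ~0.8 mL/min/g.
The blood *region* is a stand-in for the flowing pool: solving no flow
problem, it carries an enhanced perfusion coefficient instead.  Its magnitude
is set by a consistency argument, not by fitting: the layer's equivalent
surface conductance `w * thickness` must not exceed the convective
coefficient used for flowing blood at the far-field boundary
(5e5 W/m3/degC x 3 mm = 1500 W/m2/degC = alpha_a).  A much larger value would
let the stand-in deliver heat faster than the convection it replaces, which
visibly suppresses lateral iceball growth and collapses the latent-heat
plateau of the contact trace during thawing.

## Discretisation and numerics

* Linear (P1) tetrahedral finite elements; lumped capacity and lumped
  boundary mass.  Stiffness row sums vanish identically, which makes the
  discrete energy ledger close exactly.
* Crank-Nicolson time stepping, default dt = 0.1 s at reduced resolution.
  Material coefficients are lagged at the previous time level (one linear
  solve per step).  With rates bounded by a few degC/s, a node crosses the
  10 degC transition range in dozens of steps, so the lagged effective
  capacity integrates the latent heat accurately; the dt-halving check below
  guards this.
* The symmetric positive definite system is solved by Jacobi-preconditioned
  conjugate gradients to relative residual 1e-10 (deterministic: fixed
  ordering, no randomised components; reruns are bit-identical).
* Energy ledger: per step, stored enthalpy change `1^T M dT` is accounted
  against Robin/refrigerant boundary fluxes and volumetric sources evaluated
  at the Crank-Nicolson midpoint.  The residual is bounded by the linear
  solver tolerance (observed ~1e-9 relative over full runs).

Verified numerical properties (enforced by the test suite): equilibrium
preservation; analytic single-element stiffness; second-order observed
convergence of the time integrator on a single-DOF relaxation; steady
conduction through a Robin-ended rod; the erf similarity solution for sudden
surface cooling within 2 %; a discrete maximum principle for source-free
constant-property problems; contact-trace change < 0.2 degC under dt halving
and -10 degC isotherm-depth change < 0.15 mm under mesh halving.

## Protocols

The catalogue encodes the studied freeze-thaw scenarios: single freezes of
90/150/210 s with rewarming (A1-A3, cryoadhesion analysis), a 300 s reference
freeze (B1), double freeze-thaw cycles 150 s + interim thaw 5/10/15/20 s +
150 s (C1-C4), and 90/150/210 s + 10 s thaw + remainder to 300 s cumulated
freezing (D1-D3).  Terminal rewarming is an observation window (default
120 s).  Schedules validate mode alternation and the 300 s cumulated-freeze
constraint of the C/D families.

## Metrics

* **Transmural profile** — temperatures sampled at <= 0.1 mm spacing along
  the straight path from the contact-patch centre to the coldest epicardial
  point (located at the end of the last freeze; ties resolve to the axis).
* **Isotherm depth** — deepest crossing of a given temperature along the
  profile (linear interpolation).  A 3-D variant (maximum depth of the
  isotherm anywhere in tissue) is computed as a diagnostic; the path-based
  value is primary — for this symmetric geometry the two coincide on-axis.
* **Ice volume** — tissue volume below the -10 degC solidus by linear
  level-set clipping of each tetrahedron (exact for P1 fields; a cruder
  nodal-fraction method is available).  Frozen blood is tallied separately
  and excluded.
* **Cryoadhesion** — from the area-weighted mean temperature of the
  contact-patch tissue surface, the first crossings of -10 degC and 0 degC
  after thaw start.
* **Cooling/thawing rates** — per depth (0.25 mm grid), the span of the
  comparison interval divided by the time the phase trace needs to traverse
  it.  The comparison interval is the central 60 % of the local rewarming
  span `T_rise = max(T_1T) - min(T_1F)`; this discards the slow shoulder at
  the start of the second freeze.  Traversal convention: first entry to last
  exit within the phase (downward for freezes, upward for the thaw) — robust
  to small oscillations near phase switches; depths where a phase does not
  fully traverse the interval report the rate as undefined (NaN).
* **Quasi-static check** — maximum nodal |dT/dt| in tissue by central
  differencing of stored snapshots.  It is evaluated inside a continued
  freeze (the 300 s instant of a freeze extended to 304 s), because at the
  scheduled freeze/thaw switch a central difference would measure the drain
  transient instead.

## Synthetic trace fixtures

`make_trace_fixture` builds piecewise-linear transmural traces with exactly
known extrema and traversal times, resampled on the union of breakpoint
times so linear interpolation preserves them exactly.  These fixtures
exercise the rate metrics against closed-form values.  They emulate the
*shape* of freeze-thaw traces, not solver output: passing fixture tests
demonstrates the metric algebra is correct, not that simulated traces are
physiological — that is what the scenario-level checks are for.

## Known limitations

* The rectangular-shell tip and planar slab ignore tissue indentation,
  curved chamber geometry and catheter shaft conduction; the contact patch
  is a flat rectangle of configurable area (the dominant geometric lever for
  iceball size — halving it shrinks the 300 s ice volume markedly).
* Blood advection is a perfusion-type stand-in, not a flow solution; wall
  shear, pulsatility and large-vessel heat sinks are absent.
* The refrigerant model is phenomenological (one calibrated magnitude, two
  fixed time constants); internal two-phase flow is not resolved.  The
  earliest thaw seconds are the least constrained part of the model, and the
  simulated contact patch stays below the solidus noticeably longer than the
  published ~12 s before entering the melt plateau.
* Exact material values used by the reference simulations were not published;
  the defaults here are literature-typical, so scenario outputs reproduce
  published values only to scaled-down tolerances, not exactly.
* Cell-viability/lesion prediction is out of scope; outputs are temperatures
  and derived thermal metrics only.
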