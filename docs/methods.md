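# Methods

## Scope and model

`fdanozzle` implements a lattice-Boltzmann (LB) pipeline for transitional
flow in the FDA sudden-expansion nozzle benchmark: unit scaling, geometry
and voxelization, a D3Q19 solver with curved-wall treatment and open
boundaries, turbulence characterization, and comparison against PIV-style
reference profiles.  The production campaigns this pipeline mirrors run
45M–2.9B cells on clusters; the package executes the same chain at desk
scale (thousands to hundreds of thousands of cells), where the physics is
laminar, and verifies the solver on canonical flows instead.

The solver evolves particle distribution functions `f_i` on the D3Q19
stencil,

    f_i(r + c_i, t + 1) = f_i(r, t) + Omega_ij (f_j^eq - f_j)(r, t),

with the second-order Maxwell–Boltzmann equilibrium

    f_i^eq = w_i rho (1 + c_i.u/cs^2 + (c_i.u)^2/(2 cs^4) - u^2/(2 cs^2)),

`cs^2 = 1/3`.  Collision is formulated in the d'Humières moment basis
(multiple relaxation times).  The viscous moments always relax at the
principal rate `Omega`, which fixes the kinematic viscosity
`nu_lattice = cs^2 (1/Omega - 1/2)`; conserved moments have rate zero.

## Unit scaling

Physical flows are prescribed by fluid density and viscosity (defaults:
the blood-analog 1056 kg/m^3, 3.5 mPa s), a throat Reynolds number
`Re = u_mean d / nu` on the 4 mm throat, a grid spacing and `Omega`.
Diffusive scaling couples the time step to the grid,
`dt = nu_lattice dx^2 / nu`, and the lattice velocity `u dt/dx` must stay
below a Mach guard of 0.15.  `build_case` verifies that the Reynolds number
recomputed from lattice quantities equals the physical one to 1e-10.

The flow-through time uses the *inlet-section* mean velocity (throat mean
divided by the 9:1 inlet:throat area ratio) with the 0.04 m throat length
as reference length; this convention reproduces the benchmark's published
development times (0.217 s at Re 2000, 0.124 s at Re 3500) and is recorded
in the scaling metadata.  Note that the published production-scale
parameter sets imply throat-mean lattice velocities above the 0.15 guard
(0.33 at Re 2000 on the 80 um grid); `build_case` therefore refuses such
configurations by default and only echoes them under `mach="warn"`.

## Geometry and voxelization

The nozzle is analytic: a 12 mm pipe, a conical contraction with 10 degree
half-angle, a 4 mm x 40 mm throat ending at the sudden-expansion plane
`z = 0`, and a 12 mm outlet pipe; full axial extent (-0.14, 0.253) m, with
configurable truncation for desk-scale runs.  Twelve measurement stations
(z1…z12 from -0.088 to 0.08 m) address radial profiles and centreline
samples.  Voxelization is cell-centred with the axis on a cell corner, so a
throat of `d/dx = 50` spans exactly 50 cells on the centre row.  An
optional STL path parses triangulated surfaces with `trimesh` and decides
containment with an internal even-odd ray-crossing test (the environment's
trimesh build lacks the spatial-index extension its own containment needs).

Wall links store the cut fraction `q in (0, 1]` from the fluid-cell centre
to the analytic surface, found by bisection on the inside/outside predicate
(52 iterations, ~2e-16 of the link length); tests check cut links against
closed-form ray–cylinder intersections and a dense marching oracle.

## Boundary conditions

* **Walls** — linear interpolated (Bouzidi-type) bounce-back using `q`;
  at `q = 1/2` the scheme reduces algebraically to half-way bounce-back,
  which the tests assert to 1e-14.  Moving walls add the standard momentum
  term (Couette is then exact to 1e-10).  Where the second fluid neighbour
  needed by the `q < 1/2` branch is unavailable, the link falls back to
  half-way bounce-back.
* **Inlet** — velocity bounce-back on the face links with the parabolic
  target `2 u_mean (1 - (r/R)^2)` evaluated at each cut-link midpoint, and
  a linear ramp from zero over a configurable startup window (default:
  about one flow-through) to avoid the initial pressure shock.
* **Outlet** — default: first-order extrapolation of the outlet-layer
  populations from the last interior plane with the layer density pinned to
  the reference (zero gauge pressure).  A truncated outlet that is reached
  by the recirculating jet makes this scheme unstable (the production
  campaigns report the same failure mode at their outflow); for such runs
  an equilibrium-reconstruction variant is provided (`outlet_order = 0`):
  the layer is set to `f^eq(rho_0, u_neighbour)` with re-entrant axial
  velocity suppressed.  Both variants pass uniform flow unchanged and hold
  the outlet at zero gauge.

Ordering per step: collide → outlet fill → stream (boundaries are applied
inside the pull-streaming pass); ghost handling is by flag, not by halo.

## Collision defaults and performance

The moment-space collision matrix is precomputed as
`A = M^-1 diag(s) M`; when no explicit rate vector is given the solver
takes an algebraically identical BGK fast path.  The desk-scale runs use
equal rates (the single-relaxation reduction); the classical stabilized
d'Humières rate set is available via `dhumieres_rates(omega)` and the
equal-rate reduction is kept testable (equal-rate moment-space collision
tracks BGK to 1e-12 over 100 steps).  Kernels are numba-compiled, double
precision, no fast-math; interior cells with an all-fluid neighbourhood
take a branch-free gather path.  Per-cell density and momentum are
conserved by construction (periodic-box mass drift < 1e-12 over 1000
steps).

## Derived fields

Shear stress comes from the non-equilibrium second moments,
`tau_ab = -(1 - Omega/2) sum_i c_ia c_ib (f_i - f_i^eq)` (deviatoric),
local per cell, rescaled to Pa by `rho_phys (dx/dt)^2`; Couette reproduces
`mu gamma` to 1%, and the pipe's linear stress profile matches the analytic
slope to 2%.  Vorticity uses second-order central differences (one-sided at
boundaries); multiplied by `Re` in units of `u_mean/d` it reproduces the
0–2Re display convention used for instantaneous snapshots.

## Characterization

Reynolds decomposition is an arithmetic time mean over the averaging
window; defaults average the final 80% of a run (the production protocol
discards a development window of similar proportion).  TKE is
`0.5 <u'_x^2 + u'_y^2 + u'_z^2>`.  Spectra use Welch's periodogram — Hann
window, 8 segments, 50% overlap by default, all recorded in the result —
on a Strouhal abscissa `St = f d / u_mean`; the one-sided density integral
reproduces the series variance within 2% on white-noise fixtures, and a
synthetic signal with a -5/3 band is recovered within +-0.2 of slope.

Kolmogorov scales are computed from the time-averaged invariant
`S = 2 s'_ij s'_ij` of the fluctuating strain rate (central differences),
nondimensionalized by `u_mean` and `d`:
`eta = (Re^2 S)^(-1/4)`, `tau = S^(-1/2)`, `u_eta = (S/Re^2)^(1/4)`, so
`eta u_eta Re = 1` and `tau = eta/u_eta` identically.  Dimensional forms
use `eta d`, `tau d/u_mean`, `u_eta u_mean`; resolution quality is
`l+ = dx/eta`, `t+ = dt/tau`.  For nozzle runs the invariant is averaged
over the centreline between stations z8 and z12 before forming scales.
The published reference microscales per production campaign are carried as
data (inputs to the l+/t+ arithmetic); their printed *dimensional* eta/tau
values are not mutually consistent with `tau = eta^2/nu`, so the package
verifies only the self-consistent l+/t+ quotients and documents its own
dimensionalization convention above.

## Comparison observables

Centreline profiles sample the mean axial velocity at 86 (configurable)
uniform stations, averaging the four cell columns nearest the axis; radial
profiles run along the diameter rows of a station plane.  Section-averaged
pressure uses all wetted cells of the plane; the normalized drop is
`(p_z - p_z0) / (0.5 rho u_throat^2)`.  Shear profiles are normalized by
their mean magnitude.  Agreement with reference data is the simple relative
percentage error `|(U_ref - U_h)/U_ref| x 100`.

Jet breakdown is localized operationally: the first axial position
downstream of the expansion where centreline TKE exceeds a threshold
(default 10%) of its downstream maximum, reported with the bracketing
measurement stations; profiles whose maximum stays below a detectability
floor (default `1e-3 u_mean^2`) are laminar ("none").  The threshold is
monotone by construction (raising it never moves the estimate upstream).

## Synthetic data

Generators are pure functions of parameters and a seed: analytic
Hagen–Poiseuille profiles; emulated multi-laboratory PIV datasets
(multiplicative lab offset ~N(0, 5%) plus pointwise noise ~N(0, 3% of the
profile RMS) by default, matching the qualitative interlaboratory spread of
the five benchmark experiments); random-phase signals with a prescribed
spectral power law inside a band; and linear shear fields whose strain
invariant is exact.  PIV files use a long-format CSV
(`experiment, quantity, z_m, r_m, value`; quantities `u_z_m_s`, `p_Pa`,
`tau_Pa`), tolerate missing pressure blocks, and round-trip losslessly.

## Desk-scale study conditions

* **Poiseuille verification** — axially periodic force-driven pipe, fixed
  lattice Reynolds number (~5) under diffusive scaling, `Omega = 1.2`,
  run for 30 decay times of the slowest radial mode.  Because the wall
  error of an interpolated bounce-back depends on how the circle happens to
  cut the lattice (a plane channel at fixed fractional wall offset shows
  clean second order), the convergence study averages the L2 error over
  three sub-voxel axis placements per resolution (10, 20, 40 cells per
  diameter) before fitting the order.  The L2 error compares the
  density-rescaled velocity, since interpolated bounce-back leaks mass very
  slowly in closed systems.  Measured: 0.24% at 20 cells/diameter,
  fitted order 2.12.
* **Open pipe** — 20 cells/diameter, parabolic inflow, extrapolation
  outflow; mass-flux imbalance < 0.03% at steady state, centreline-to-mean
  ratio 2.001.
* **Scaled nozzle** — Re_th = 500 (the benchmark's laminar case), 12 cells
  across the throat, domain truncated to 8 mm of inlet pipe, the full
  contraction and throat, and 20 mm beyond the expansion; throat-mean
  lattice velocity 0.06 (keeping the laminar centreline peak below the
  Mach guard), ramp 1500 steps, 15 000 steps total with statistics over the
  final 40%; equilibrium outlet.  The run is stable and laminar (peak
  centreline TKE ~1e-4 u^2, breakdown "none"), the throat:inlet
  mean-velocity ratio is 9 within 2%, and the normalized pressure falls
  monotonically through the contraction.

These desk-scale fixtures exercise the full numerical chain but not
transitional physics: jet breakdown at Re 2000/3500 and the station
brackets of the turbulent cases require the cluster-scale resolutions and
are documented qualitative targets only.

## Known limitations

* The throat centreline-to-mean ratio of the Re 500 nozzle is 1.82, not
  the Poiseuille value 2: the contraction flattens the incoming profile
  and the laminar development length (~0.056 Re d ≈ 28 diameters) far
  exceeds the 10-diameter throat.  This is entrance-flow physics, matching
  standard developing-flow solutions (u_c/u_mean ≈ 1.8 at
  x+ = L/(d Re) = 0.02), and consistent with the blunt throat profiles the
  benchmark experiments report; a fully parabolic throat core should not
  be expected from this geometry at Re 500.
* The equilibrium outlet suppresses backflow and therefore slightly
  distorts the last plane of a recirculating field; statistics are never
  taken there.
* The linear Bouzidi scheme loses its sub-cell accuracy on links whose
  second fluid neighbour is missing (narrow gaps at coarse resolution).
* MRT with distinct auxiliary rates is supported but roughly 2x slower
  than the equal-rate fast path; desk defaults use equal rates.
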