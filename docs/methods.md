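# Methods

## The model

A single bridging vein (BV) joining the superior sagittal sinus (SSS) is
represented in the junction symmetry plane: the sinus is a straight 2-D
channel of width `d_ss` (flow in +x), the vein a straight channel of width
`d_bv` whose centerline pierces the upper sinus wall at the *dural
entrance*, the origin of all coordinates. The entry angle α is measured
between the vein's inflow direction and the **upstream** sinus direction, so
α < 90° means the vein discharges against the sinus stream. This convention
was fixed empirically: posterior bridging veins — the ones with small
printed angles — anatomically enter against the sinus flow, and only the
against-stream configuration reproduces the reported junction phenomenology
(a near-zero WSS minimum on the downstream sinus wall several millimetres
from the entrance, and on the vein wall adjoining the upstream corner). In
consequence the vein wall named BVU (the one carrying the deep minima)
shares the *upstream* junction corner with SSU, and BVD shares the
downstream corner with SSD.

Blood is Newtonian and incompressible (ρ = 1050 kg/m³, μ = 4.24×10⁻³ Pa·s).
Boundary conditions: mean inlet speeds 0.15 m/s (sinus) and 0.10 m/s (vein),
plug profiles by default (parabolic available), zero gauge pressure at the
outlet, no slip at walls. The intracranial ambient pressure (1333 Pa) is an
additive constant in an incompressible rigid-wall flow — it cannot change
velocities or WSS — and is carried as metadata only. Reynolds numbers are
ρUd/μ ≈ 297 (sinus) and ≲ 150 (vein): laminar; a guard refuses Re ≥ 2000.

Where the source anatomy is silent the geometry defaults are explicit
modelling assumptions, surfaced in the run configuration: sinus caliber
`d_ss` = 8 mm (literature-typical), vessel lengths `l_up`/`l_down`/`l_bv` =
30/60/20 mm at full scale and 14/28/16 mm in the desk-scale profile.

## Flow solver

The reference scheme is a single-relaxation-time (BGK) D2Q9 lattice
Boltzmann method marched to steady state on the rasterized junction
(uniform grid, ≥ 8 cells across the narrowest channel; default spacing
`d_bv/10` capped at 0.25 mm, `d_bv/8` in the desk profile):

* **walls** — halfway bounce-back (second order, wall half a cell beyond the
  last fluid cell);
* **open faces** — nonequilibrium extrapolation (Guo): inlets impose the
  velocity and extrapolate density, the outlet imposes density and
  extrapolates velocity;
* **vein inlet mass-flow control** — the vein inlet is an oblique staircase
  of Dirichlet cells, which by itself under-delivers the nominal flux by
  tens of percent. The solver therefore measures the *exact* lattice mass
  flux gained across the mouth (difference of plane fluxes through the sinus
  lumen on the two flanks, anchored symmetrically at the entrance) and
  rescales the imposed inlet speed until the delivered flux equals
  `u_bv·d_bv`, making the vein inlet a mass-flow inlet. Delivered fluxes are
  recorded in the field metadata;
* **scaling** — by default the time step maps the fastest inlet to lattice
  speed 0.05 (Mach ≈ 0.09), which at the default spacings pins the
  relaxation time just above ½ (τ ≈ 0.51–0.53); the automatic choice is
  capped at τ = 1.0 because the bounce-back wall-location error grows with
  τ. Fixing `relaxation_time` in the config selects diffusive scaling
  instead; the grid-convergence validation uses the slip-free value
  τ = ½ + √(3/16), at which halfway bounce-back has no Poiseuille slip and
  the measured spatial order is ≈ 2;
* **convergence** — relative L2 velocity change per 1000 steps < 10⁻⁶, at
  most 2×10⁵ steps (7×10⁴ in the desk profile). Several junction
  configurations are genuinely unsteady in 2-D (slow transients or laminar
  shedding off the mouth): the residual stalls near 10⁻⁵. The solver then
  time-averages a trailing 2×10⁴-step window and returns the mean flow with
  `converged=False` — the steady approximation of a periodic laminar flow.
  The scheme is deterministic throughout: identical inputs give bit-identical
  fields, and a mirrored mask yields the mirrored field to ~10⁻¹⁰.

## WSS extraction and profile statistics

τ(s) = μ|∂u_t/∂n| is evaluated at wall samples (spacing = grid spacing) by a
one-sided quadratic fit through the no-slip wall value and bilinear velocity
samples at 0.5h and 1.5h along the inward normal — exact for parabolic
profiles; the straight-channel plateau reproduces the plane-Poiseuille
closed form 6μU/h within 2 %. Samples within two spacings of an open face
are excluded from statistics.

The **stable value** of a wall is the *median* of τ over the wall after
excluding (a) within `inlet_widths` local channel widths of the wall's own
vessel inlet (developing flow) and (b) within `entrance_spans` mouth spans
(`d_bv/sin α`) of the dural entrance (junction disturbance). The median
rather than the mean makes the plateau robust to residual junction tails.
Defaults are 5 widths and 3 spans; these leave no window at all for
large-diameter, shallow-angle veins at desk-scale lengths, so the desk
profile uses 2 widths and 1 span, and per-wall plateaus that still have no
window are reported as unavailable with the reason rather than invented.

The **minimum** is the smallest sampled τ over the wall (junction region
included; ties break toward the entrance), its **position** the unsigned
arc-length distance to the dural entrance. Where the flow separates, the
continuum minimum of |τ| is exactly zero at a reattachment point between two
samples, so the sampled minimum is bounded by the local slope times the
sample offset; every minimum therefore carries an **uncertainty** equal to
its largest neighbour-sample gap (the standard error bound of a discrete
extremum). Minima in the deep-deficit regime saturate at this floor — they
are "zero to within sampling" — and comparisons between them are only
meaningful outside their combined uncertainties. The trend checks on the
stratified 12-model subset assert exactly that: minima non-increasing with
diameter (at 43°) and non-decreasing with opening angle (at 3 mm) up to the
per-minimum uncertainties, plus a strict order-of-magnitude contrast between
the harmful (3 mm, 43°: minima ≤ 0.1× plateau) and benign (3 mm, 135°:
minima ≥ 0.2× plateau) configurations so the comparison cannot pass
vacuously.

The **demarcation threshold** over a set of per-model minima sorts them
ascending, finds the adjacent pair with the largest ratio and places the
threshold at that pair's geometric mean; if the largest ratio is below 2 the
result explicitly reports "no demarcation". Ratios rather than differences
are used because the minima span more than two orders of magnitude. The
detector is scale-equivariant by construction.

## Synthetic cohort

Only group summaries of the anatomy are available: mean ± SD with a hard
observed range, per group and variable. The generator samples a normal
distribution truncated to the printed range whose underlying (μ, σ) are
solved so the *truncated* moments match the printed ones (naive truncation
would bias both); sampling is by inverse CDF of the truncated distribution
(exact support, bit-reproducible under a fixed seed). Diameter and angle are
independent by default; a Gaussian-copula correlation knob exists because
posterior veins are jointly larger and shallower.

Truncated normals are log-concave, so their SD on a finite interval is
bounded; the posterior entry-angle row (43 ± 25° on [10°, 90°]) lies outside
the attainable set — the supremum at that mean is ≈ 22.5°. The strict solver
(`solve_truncnorm_params`) raises in that case; cohort generation falls back
(configurably) to matching the mean exactly with the closest attainable SD.
Sample means are unbiased for the printed means in either case; the
recovered SD for that one variable sits ~1 SE below the printed value.

The generator emulates marginal group distributions only. It does not model
per-cadaver clustering (the six donors), measurement rounding, or any true
diameter–angle dependence, so passing cohort-level tests says nothing about
those features of real data.

## What the desk-scale runs can and cannot show

The study this pipeline re-implements used a commercial 3-D solver on
geometries whose sinus caliber and vessel lengths are not reported, so its
absolute WSS magnitudes are not reproducible and are not targeted. The 2-D
junction preserves the mechanisms under study — merging-flow WSS deficits,
their scaling with vein diameter and entry angle, and the near-entrance
predilection zone — and at the harmful morphology the desk-scale minima land
close to the reported ones (e.g. SSD ≈ 0.006–0.008 Pa several millimetres
downstream of the entrance). A 2-D slit vein carries proportionally more
flux per unit depth than a 3-D circular vein of the same diameter, so
small-vein effects are exaggerated relative to the 3-D study (a 1 mm vein
already depresses the wall WSS at 43° here). Group-table statistics on the
synthetic cohort inherit all of the above plus the generator's independence
assumptions.

Problem sizes used by the shipped tests: a 12-model stratified subset
(d ∈ {1, 2, 3, 4.5} mm × α ∈ {43°, 90°, 135°}) on the desk-scale geometry,
a 32×8 mm validation channel, and three-channel resolutions (10/20/40 cells
across) for the convergence order; the full 137-vein sweep at full-scale
geometry runs through the same code path via `bridgeflow run-sweep --full`.
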