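# Methods

## Scope and model summary

`rootca` models the two-dimensional root-system architecture of three
cotton plants sharing a 110 cm × 60 cm soil cross-section irrigated from
one side wall.  It is an occupancy model: the state is a binary lattice of
0.5 cm cells (root present / absent), not a topological root description.
Root diameters, branch orders, segment angles and mortality are outside the
model; what it predicts is *where root material accumulates*, at the
resolution of the sampling slabs used for validation.

Three empirical inputs drive the model:

1. the van Genuchten retention curve θ(S) linking suction to water content
   (θr = 0.219, θs = 0.447, α = 7253.248 MPa⁻¹, n = 1.313 for the test
   soil — note the very large α implies essentially zero air-entry suction,
   which is physically odd but adopted verbatim from the fitted soil);
2. a root-length-density (RLD) vs normalized-suction law per growth stage
   and planting spacing — logarithmic `a·ln(S)+b` for 30 cm spacing,
   exponential `c·e^{d·S}` for 15 cm, both decreasing in suction;
3. RWD→RLD conversions (axis: `831.37·ln(RWD)−1685.51`; lateral:
   `83.12·RWD^0.71`) used when only root weights are available.

Suction fields are min–max normalized before entering a driving law, so a
law fitted on relative suction transfers across containers whose absolute
suction ranges differ.

## Growth rule

Cells switch 0→1 irreversibly, only on the *frontier*: empty cells
reachable from an occupied cell through one of the five non-upward Moore
directions (W, E, SW, S, SE).  Excluding upward moves is the model's
gravitropism; all moisture response enters through the sampling weights.
One step flips up to `cells_per_step` (default 25) frontier cells, drawn
without replacement with probability proportional to a per-cell weight.

The weight field is refreshed every step from two terms:

* **Tile capacity.**  The domain is partitioned into square tiles
  (`capacity_tile_cm`, default 5 cm).  Each tile holds a quota of root
  cells proportional to its summed clamped driving weight
  `max(0, RL(S_norm))^γ`; a frontier cell's base weight is its tile's
  unfilled quota.  The driving law thus acts as a local carrying capacity:
  wherever growth can reach, occupied density converges toward the RLD
  profile, which is what the validation metric measures.  A frontier cell
  in a full tile has base weight zero.
* **Lateral-axis extension.**  Candidates whose only occupied "parent"
  (a cell able to grow into them) is a horizontal neighbour backed by a
  second collinear cell continue an existing horizontal axis and receive an
  additional weight `lateral_boost · quota` (default boost 1.0); candidates
  starting a new lateral off a flank receive `sprout_rate · quota`
  (default 0.01).  This reproduces the observed morphology — a few long,
  nearly horizontal laterals rather than many stubs — and is the mechanism
  that lets the connected structure traverse tiles whose quota is already
  filled.

Setting `capacity_tile_cm: null` recovers a simpler rule (static weights
equal to the clamped driving RLD), which produces compact Eden-like
accretion around the taproots; it is kept as a baseline because it is the
most literal reading of "roots seek moisture", but it neither tracks the
density profile nor shows system-level hydrotropism, which is why the
capacity rule is the default.

Plants share one pooled frontier; competition between neighbouring root
systems emerges from the shared field and quotas rather than an explicit
interaction term.  Growth stops at an occupancy target
`round(κ · mean clamped RLD · n_cells)`; κ (cells per unit RLD, default
2.1·10⁻⁵) is a calibration constant chosen so the default boll-stage
scenario fills ≈8 % of the lattice (2071 of 26 400 cells), a deliberately
sparse regime in which the architecture remains readable in renders.  Each
plant is seeded as a surface cell plus a pre-occupied vertical taproot
column (default depth 40 cm, 0 disables); the taproot is input, not
simulated, because the vertical main axis is established before the lateral
system that the CA actually models.

Time is an abstract step counter — stages are simulated independently with
stage-specific coefficients, not as one continuous growth history.

## Synthetic study conditions

No measured wetting fields or slab densities ship with the package; the
`synth` module generates both.

* **Wetting bulb**: `S(x,y) = s_min + (s_max−s_min)·min(1, r^e)` with
  elliptic radius r around a source on the irrigation wall (default depth
  10 cm).  Two presets bracket the irrigation cycle: `12h` (large fresh
  bulb: radii 100×55 cm, s 0.02–2.5 MPa, e = 1.5) and `3d` (shrunken dry
  state: radii 45×25 cm, s 0.3–4.0 MPa, e = 1.2).  Level sets are ellipses;
  real wetting fronts are neither elliptic nor noise-free, so passing tests
  on these fields demonstrates internal consistency of the pipeline, not
  predictive skill on field data.
* **Layouts**: stems at 25/55/85 cm (30 cm spacing) or 20/35/50 cm (15 cm
  spacing) from the irrigation wall, matching the distance brackets of the
  experimental design; exact stem coordinates are config-overridable since
  they were never published numerically.
* **Observed profiles**: per-block means of the clamped driving RLD,
  multiplied by unit-mean lognormal noise of relative sd σ
  (σ_log = √ln(1+σ²), exact unit mean).  σ = 0 gives the noise-free
  self-consistency reference.

## Validation metric

Simulated grids are aggregated over 15 cm × 10 cm blocks (the slab volume
used for root sampling; the 110 cm width leaves a flagged 5 cm edge
column, compared on a per-area basis).  Both profiles are min–max
normalized — the published comparison is between *relative* densities — and
the error is `100 · mean|sim_norm − obs_norm|`: zero iff the normalized
profiles coincide, symmetric, and invariant to affine rescaling of either
profile.  How the original 6.03 %/15.04 % figures were averaged (blocks,
columns or stages) is not recoverable, so this package fixes the simplest
definition and applies it uniformly.

## Numerical choices and degenerate inputs

* Retention inversion is closed-form; the roundtrip is exact to <10⁻⁹ over
  (θr+10⁻⁶, θs].  θ ≤ θr raises (suction unbounded), θ > θs raises.
* `fit_retention` uses bounded least squares (n > 1, contents in [0, 1]),
  initialized from the data extrema ±5 %, α from the mid-saturation
  suction, n = 1.5.  Fewer than 5 distinct suctions, or a span under one
  decade, is rejected as under-determined.
* The logarithmic driving law floors normalized suction at 10⁻³ (normalized
  fields contain exact zeros at the wettest cell).  Raw law values may be
  negative; clamping to zero happens only when building weights, so the
  printed coefficients remain directly checkable.
* Min–max normalization of a constant array raises a degenerate-range error
  rather than returning NaNs; a uniform suction field is therefore rejected
  up front, and a fully stalled run (all frontier weights zero) warns and
  stops instead of spinning.
* Field refinement is bilinear on the coarse measurement lattice (exact at
  samples, bounded by local extrema); queries outside the sample bounding
  box clamp to the nearest lattice value, and non-rectangular sample sets
  fall back to inverse-distance weighting with a warning.
* Sampling without replacement uses `numpy.random.Generator.choice` on the
  normalized frontier weights; a run is bit-reproducible given its seed
  (asserted in tests), though not across numpy generations.

## Problem sizes

Default runs use the full 220×120 lattice and finish in well under a second
(≈80 steps of 25 cells).  The stochastic suite sizes — 10 seeds per spacing
for self-consistency, 20 seeds for noisy parameter recovery, 50 seeds for
hydrotropism, 10⁵ replicates for the sampling-kernel check — keep the whole
test suite around a minute on one CPU while leaving the Monte-Carlo
tolerances comfortably above sampling error.

## Known limitations

* The model is 2-D and occupancy-based: no root topology, diameters or
  age structure; stage transitions are re-parameterizations, not dynamics.
* Water movement is not simulated; fields are static inputs (the `12h` and
  `3d` presets are snapshots, not a redistribution model).
* With three seed columns and an 8 % occupancy budget, a connected root
  structure cannot span every sampling block of the domain.  Because the
  logarithmic law keeps substantial RLD even at maximal suction, the
  noise-free observed profile is non-zero everywhere, and the 30-cm-spacing
  self-consistency error plateaus near 20 % — above the ≤15 % achieved by
  the 15-cm preset.  Raising κ does not help: once coverage converges to
  the quota everywhere, the far plant's lateral centre of mass is pulled
  toward its wide dry-side wing and the per-plant hydrotropic asymmetry
  disappears.  The defaults keep the sparse regime; the residual 30-cm
  profile mismatch is a documented property of the model class, not a
  tunable artifact.
* The fitted α and the mixed suction conventions of the source data are
  used as-is; suction is treated as MPa throughout.
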