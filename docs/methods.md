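# Methods

This note documents the statistical model behind every metric `micromix`
computes, the conventions adopted where the literature is ambiguous, the
synthetic generators used for validation, and known limitations.

## Concentration-field statistics

A micrograph ROI is an m×n grid of concentrations obtained by dividing 8-bit
intensities by 255 (no gamma correction; an optional normalization against an
unmixed-entrance CoV₀ is provided via `normalize_by_reference`).  Coordinates
are 0-based with the origin at the top-left; `x` indexes columns, `y` rows;
ROIs are half-open rectangles.

**Intensity of segregation.**  With mean `Cm` and *population* standard
deviation σ (1/N denominator — the concentration grid is the entire
measured population at that scale of resolution, not a sample from it):

* `CoV = σ/Cm` (undefined for `Cm = 0`);
* mixing index `M = 1 − CoV`, **not clamped**: experimental CoV can exceed 1
  near an inlet, making M negative until normalized by CoV₀;
* Danckwerts intensity `I = σ²/(Cm(1−Cm))`, defined only for `0 < Cm < 1`;
  for any {0,1}-valued field σ² = Cm(1−Cm) identically, so I = 1 in the
  fully segregated limit and 0 for a homogeneous field.

**Scale of segregation.**  The field is standardized
(`Cˢ = (C − Cm)/σ`, population σ; constant fields are rejected) and the
one-axis empirical variogram computed for integer lags h:

    γ(h) = 1 / (2 N(h)) · Σ (Cˢ(x) − Cˢ(x+h))²,

every unordered within-grid pair counted once, pairs accumulated across all
rows (horizontal) or columns (vertical), so `N(h) = rows·(cols−h)` on a full
grid.  For standardized data the sill is 1; spatial correlation is exhausted
where γ reaches it.  The mean length scales LH/LV are read off as the
smallest lag (linearly interpolated between integer lags) at which γ first
reaches `fraction · sill`, default fraction 0.95: an exact-sill criterion is
brittle because the empirical γ fluctuates around 1 with deviation
≈ √(2/N(h)).  If the threshold is never reached within the computed lags the
largest lag is returned flagged `attained=False`.  `max_lag` defaults to half
the axis extent so every reported lag keeps at least half the available
pairs.

**Exposure.**  With unit contact area and unit interaction strength, the
half on ordered neighbour pairs cancels the double count, so
`E = Σ |C_i − C_j|` over unordered 4-neighbour cell pairs — the total
concentration difference across cell interfaces, a proxy for the
instantaneous diffusive driving force.  Interior cells contribute 4
interfaces, edges 3, corners 2.

## Particle-pattern statistics

Particle data are sub-pixel (x, y) centroids inside a region of area
`A = width·height`; all distances are in pixels (reports carry micrometres
too when a pixel pitch is supplied).

* **Quadrant CoV**: the region is tiled into m×n equal half-open rectangles
  (boundary particles fall to the lower-index quadrant; the far edges fold
  into the last quadrant so every particle is counted once); the *sample*
  variance (1/(mn−1)) of quadrant concentrations `P_q/A_q` about the global
  `P/A`, rooted and divided by `P/A`.  The population/sample asymmetry with
  the concentration-field σ is deliberate: each formula is kept exactly as
  conventionally printed.
* **PNN distribution**: each particle's Euclidean distance to its nearest
  neighbour (k-d tree internally; validated against an O(P²) scan).
  Coincident particles yield zero distances with a warning.
* **Index of dispersion** (distance-based, pixels): population variance of
  the PNN distances over their mean.  Zero for a lattice; *small* for tight
  aggregates too, because aggregation shrinks every distance — see the
  quadrat variant below.
* **Quadrat index of dispersion** (dimensionless):
  variance-to-mean ratio of quadrat counts, the classical departure-from-CSR
  test — ≈1 random, <1 regular, ≫1 clustered.  This is the variant used for
  clustering-vs-randomness decisions; the distance-based variant is the one
  consumed by the mixing index because the published reference statistics
  are of that form.
* **σ_fpp** (filtered point–particle deviation, pixels): PNN distances are
  clipped from below at `X_R` and the root of `Σ(X_i − X_R)²/(P−1)` taken,
  so only particles *farther* from a neighbour than the homogeneous ideal
  contribute.  The deviation is squared even though some printed forms omit
  the square — the quantity is a variance and its reported value a root.
  `X_R` defaults to the equal-density uniform-grid spacing `√(A/P)`; a
  literal "minimum of the PNN distribution" policy (`xr="min"`) is provided
  but makes the clipping vacuous by construction.
* **Maximum striation thickness** (pixels): coordinates along one axis
  (default across-flow, i.e. x) are binned at `bin_px` (default 1); the
  longest contiguous run of bins holding ≥ `min_count` particles, times the
  bin width.
* **SR**: the published reference tables report an "SR" statistic without a
  definition.  The package defaults to the mean PNN distance — the natural
  "spatial resolution" of the pattern — and the mixing index consumes
  whatever SR value a `SegregationSummary` carries, so any alternative
  definition can be substituted without touching the index.

## The normalized particle mixing index

    m_p = 1 − (Idisp/Idisp₀ + SR/SR₀ + σ_fpp/σ_fpp₀) / 3

with the subscript-0 statistics from the unmixed reference image of the same
color.  The ratios normalize away differences in magnification, particle
count and target-area size between the two images, which is precisely why
the index suits multi-inlet devices where each color has its own inlet
state.  `m_p = 0` at the reference itself; it increases strictly as each
statistic falls and is deliberately not clamped: negative values flag states
more segregated than the reference.  Reference components must be strictly
positive.

**Limitation.**  Because all three components are nearest-neighbour
statistics, m_p responds to *de-aggregation*, not to pure spreading: if the
unmixed state is particles confined to part of the region at the same count,
confinement makes the local density higher and every PNN statistic smaller,
so a uniform re-scatter *raises* the component ratios and drives m_p
negative even though mixing plainly improved.  We verified this across the
full aggregation continuum of the half-segregated generator (aggregate sizes
2–25 beads, spreads 1.5–8 px, free fractions 0.08–0.45): the mean-NN ratio
never falls below ≈1.7 and m_p stays negative in every regime.  In real
unmixed/mixed image pairs the effect is masked by differing counts, zoom and
target areas — the very differences the index normalizes — but at fixed
count and region m_p should be read as a de-clustering index.  Large-scale
spreading is better captured by the quadrant CoV and the quadrat dispersion
index, both reported alongside.

## Detection chain

RGB → HSV (8-bit convention: hue `round(deg/2) mod 180` in 0–179,
saturation/value 0–255; the modular rounding keeps noisy near-red hues on
either side of 0° adjacent, which a naive [0,180) float scale does not) →
per-color window mask (red uses two hue intervals, [0,10] and [170,179],
both with saturation ≥ 70 and value ≥ 50; green [40,80]; blue [100,130]; all
overridable) → ROI crop → morphological opening (square kernel, default 3×3,
one erosion and one dilation) → 8-connectivity connected components with an
inclusive pixel-area filter → sub-pixel centroids (mean member-pixel
coordinates), sorted by (y, x) for determinism.

Defaults suit saturated fluorescence on a dark background.  The kernel must
fit the mask; low-resolution images therefore force small kernels.  Opening
never creates components, so counts are monotone non-increasing in the
iteration counts.  Disks overlapping by more than about a radius merge into
one blob — an inherent limitation of single-frame connected-component
detection.

## Synthetic generators

All randomness flows through `numpy.random.default_rng(seed)`; identical
(spec, seed) gives bit-identical output.

* `csr`: uniform independent positions; optional hard-core minimum
  separation by rejection (used to build non-overlapping render benchmarks).
* `grid`: centered lattice closest to the requested count, optional uniform
  jitter, clipped to the region.
* `thomas_cluster`: uniformly placed parents (default 10 per 256×256),
  offspring assigned uniformly to parents with isotropic Gaussian spread
  (default 3 px), resampled until inside the region.  Defaults give a
  quadrat dispersion index far above the CSR baseline for clear test
  contrast.
* `striated`: particles confined to evenly pitched vertical bands (default
  4 bands covering half the width) — laminar lamellae before transverse
  mixing.
* `half_segregated`: the inlet state — all particles in the upper half, 90%
  in small aggregates (mean 3 beads, Gaussian spread 4 px, the
  doublet/triplet aggregation typical of bead suspensions) and 10% free.
* Fields: binary half/half, alternating lamellae, uniform, and uniform plus
  clipped Gaussian noise.
* Renderer: anti-aliased disks (per-pixel coverage `clip(r + ½ − d, 0, 1)`,
  brightness saturating on overlap) of a chosen RGB color on a dark
  background (default 8 counts), optional additive Gaussian sensor noise;
  ground-truth centroids are returned for recall/precision scoring.
  Multi-color overlays compose several sets on one canvas.

What the generators deliberately do **not** emulate: optical blur and
point-spread functions, depth-of-field and out-of-focus beads, uneven
illumination, chromatic cross-talk beyond ideal RGB, motion streaks, and
hydrodynamic particle advection.  Detection scores on rendered images are
therefore upper bounds on real-micrograph performance; the metric
implementations themselves are validated independently against brute-force
oracles and are unaffected by these simplifications.

## Numerical conventions and degenerate inputs

* Population (1/N) variance for field σ and PNN variance; sample
  (1/(mn−1), 1/(P−1)) for quadrant CoV and σ_fpp — each as conventionally
  printed for that quantity.
* Variogram pairs counted once per unordered pair; lag interpolation is
  linear; a never-reached sill returns the largest lag flagged.
* Constant fields: intensity statistics defined (σ=0), standardization and
  variogram rejected.  `Cm = 0` rejects CoV; `Cm ∈ {0,1}` rejects I.
* Empty particle sets are valid detection output; all pattern statistics
  require P ≥ 1 or 2 and raise otherwise.  Coincident particles warn.
* Blob ordering ties broken by (y, x); quadrant boundary particles go to the
  lower-index quadrant.
* Reynolds helper: `Re = L·V·ρ/μ`, water defaults ρ = 998 kg·m⁻³,
  μ = 1.01×10⁻³ kg·m⁻¹·s⁻¹ (20 °C); all parameters strictly positive.

## Problem sizes used in validation

Oracle-equivalence checks run on 50×50 random fields (intensity statistics),
30×30 grids with lags to 15 (variogram), and up to 500-point patterns (PNN);
white-noise sill behaviour on 10⁴-cell fields; detection benchmarks on
twenty 640×640 renders of 200 non-overlapping radius-3 beads with 4-count
sensor noise; trend checks on 50–100 seeded replicates.  These sizes give
sampling errors comfortably below the asserted tolerances while keeping the
full suite fast.
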