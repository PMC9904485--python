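# Methods

`monodom` measures whether, how fast, and in which directions patches of
single-species-dominated ("monodominant") forest expand into surrounding
mixed forest, from repeated stem-census tables of the kind produced by
large (10-ha) forest dynamics plots.  This note documents the models and
procedures, the parameters that matter, the synthetic data used to
validate the chain, the numerical choices, and the known limitations.

## From stems to intensity surfaces

Each census is reduced to the focal species' living stems with valid
diameters.  Basal area is the standard forestry conversion
`BA = pi (DBH/200)^2` (DBH in cm, BA in m²).  Stems lacking coordinates
but carrying a 20 m quadrat index are placed uniformly at random within
the quadrat (both axes randomised; imputed locations are resampled until
distinct; one fixed draw per seed).

BA is summed into a 1 m² raster over the plot (exactly conservative).
Because moving windows near the plot edge would otherwise see emptiness
that is really unmeasured forest, the raster is mirrored across every
edge (boundary-inclusive reflection; cardinal strips first, corner
blocks by the double mirror) before windowed statistics, and cropped
afterwards.  A circular focal sum of radius 56.42 m — the disc of area
one hectare (pi·56.42² = 10000.37 m²) — converts per-cell BA to
m² BA ha⁻¹, and a 3×3 mean lightly smooths the result to tame isoline
sinuosity.  Disc membership is by cell-centre distance (raster
focal-statistics convention; no partial-cell weighting).

For the vector-field analysis a smoother surface is built instead by
mark-weighted Gaussian kernel intensity estimation: each stem carries an
isotropic Gaussian bump (bandwidth = 25 m standard deviation) weighted
by its BA, with a uniform (mass-renormalising) boundary correction that
divides each stem's kernel by the fraction of its mass inside the plot
window, so the surface integral recovers total BA to within about 1%
(lattice error).  The estimate is computed by binning corrected weights
on the 1 m lattice and convolving with a truncated Gaussian; at a 25 m
bandwidth the sub-metre binning error is negligible.

## Patch delineation

A patch is the region where the windowed BA intensity meets or exceeds
a site threshold — 20 m² BA ha⁻¹ for well-developed monodominance, 10
for younger sites (the threshold is a config item; the choice of level
is acknowledged to be judgement-driven).  Cells exactly at the level
count as inside (deterministic ties).  Boundaries are marching-squares
isolines with linear interpolation, computed in the cell-centre frame;
saddle cells are resolved by scikit-image's cell-mean rule.  To close
contours that run off the plot, the surface is wrapped in a one-cell
ring of sub-level values just outside the plot; crossings into that ring
are snapped outward onto the plot rectangle, so a patch truncated by the
plot adopts the plot boundary (rectangle corners are chamfered at the
half-cell scale).  Interior low-intensity pockets become polygon holes
(retained by default, fillable by flag).

For boundary tracking, patches below 300 m² are discarded (transient
features) and patches whose boundary-to-boundary distance is under 30 m
are merged into one multipart unit: seed dispersal in these forests is
effectively bounded near 30 m, so nearer neighbours are functionally one
patch.  Merging (rather than deletion) keeps the unit's full geometry;
the operation is idempotent.  Units are tracked across censuses by
maximal polygon-overlap area.

## Radius of gyration

For the landscape-scale view, the raw threshold raster (no area or
isolation filtering; queen/8-neighbour connectivity; single cells count)
is decomposed into connected components.  A component's radius of
gyration is the mean distance from its cell centres to their centroid;
the area-weighted mean across components (= correlation length) is the
expected distance a point dropped at random in monodominant forest can
travel before leaving its patch.  Differencing between censuses and
dividing by the census interval (nominal decimal years, default 1995.0
and 2007.0, Δt = 12 y) gives a rate in m yr⁻¹.

That rate is a landscape metric, not a boundary speed: for a uniform
disc the mean cell-to-centroid distance is 2R/3, so a disc whose
boundary advances at `r` gains area-weighted mean radius of gyration at
only (2/3)·r.  `boundary_rate_from_awm` applies the inverse disc factor
(3/2) to convert the metric's rate into a boundary-advance estimate for
compact patches; both numbers are reported.

## Boundary movement regression

Within each tracked unit, every census-3 boundary vertex is paired with
a census-1 vertex in two passes: an unconstrained nearest-neighbour
query, then a second pass in descending order of that distance in which
each census-3 vertex claims its nearest census-1 vertex still below the
reuse cap (2 by default, 3 for strongly expanding sites; the pipeline
widens the cap when the vertex-count ratio forces it).  The most
displaced points therefore choose first.  Pairs are grouped into
cardinal half-planes about the census-1 centroid (meridian and parallel
splits; labels from the census-3 vertex; ties go east/north).

Each group's coordinate (northing for N/S, easting for E/W) is
regressed on census year with a separate residual variance per census
stratum (a δ-parameterised variance model: δ₁ = 1, δ₂ = later/earlier
residual-sd ratio).  Because the two year values coincide with the two
strata, the generalised least squares solution is closed-form: the
slope is the difference of stratum means over Δt regardless of the
variance estimates — the fit is exact and non-iterative, and the slope
is the group's movement rate in m yr⁻¹.  Residual sds use the n divisor
within strata.

A group is a half-boundary, so for a disc advancing radially by δ the
mean coordinate displacement over the semicircle is (2/π)·δ.
`radial_rate_from_group_mean` (π/2) inverts that obliquity for
disc-like patches; the pipeline reports the raw group rates (the
field-comparable numbers) and the π/2-corrected mean as the radial
advance estimate.

### Uncertainty and significance

* **Bootstrap.**  Matched pairs are case-resampled (default 10 000
  replicates) and the rate refitted; intervals are bias-corrected,
  accelerated (BCa, via `scipy.stats.bootstrap`).  On a Gaussian
  displacement simulation the intervals cover the true rate at 95% ± 3%.
* **Pairing permutation test.**  Early-census vertices are randomly
  reassigned to the late vertices (same reuse cap) before refitting;
  the p-value is the observed slope's two-sided extremity about the null
  mean, with the add-one rule.  This validates that nearest-vertex
  pairing conveys non-random structure — a structured boundary yields a
  small p even when nothing moved, so it is *not* a movement test.
* **Movement permutation test.**  Census labels are flipped within
  matched pairs (exchangeable under a no-movement null).  With
  independent pair displacements this test is exactly calibrated
  (uniform p under the null).  Isoline vertices are not independent:
  the focal window smooths the surface over ~113 m, so displacements
  along the boundary are autocorrelated with roughly three independent
  patches of noise per half-boundary.  Per-pair flips are then
  anticonservative; block flips along the boundary (`n_blocks`) help
  but cannot fully repair it — with at most four exchangeable blocks no
  permutation can reach p < 0.05 at all.  A patch-level variant pools
  radially-projected displacements over the whole boundary
  (`radial_movement_test`, default six blocks).  Significance claims on
  single smoothed isolines should therefore lean on effect sizes and
  bootstrap intervals rather than these p-values; with several
  independent patches, patch-level rates can be compared directly.

The tail convention everywhere is two-sided about the null centre with
the add-one correction; one-sided alternatives are available.

## Vector fields of BA change

The census-1 kernel surface is subtracted from census-3's and the
difference treated as topography: Horn's 3×3 finite-difference gradient
(the raster standard) gives a slope (vector magnitude) and a downslope
compass aspect per cell, so arrows at a growing patch point away from
the region of greatest gain; aspect is undefined (NaN) on flat cells.
Border cells see a one-cell reflection pad.  For the plot-level number,
the difference grid is reflection-padded, windowed by the one-hectare
focal sum, cropped, and its pixels case-resampled (percentile CI; BCa
is reserved for the movement models).  Resampled means are computed by
multinomial weight draws, one O(n) draw per replicate.

## Cross-table summaries

Per-quadrant rates are *oriented* (sign flipped for S and W) so that
positive always means expansion, averaged by direction and overall; the
overall mean carries a t-based 95% margin of error (t quantile at
df = n−1 times the standard error — the convention that reproduces the
published margins).  Published advance rates from other ecotone studies
ship as a packaged CSV (ranges enter as midpoints); global means are
taken over the flagged subsets with the four directional means of this
method appended.  The study-vs-literature comparison is a one-sided
Welch test labelled "interpretation": the samples are neither
independent draws from defined populations nor measured on a common
protocol, so it contextualises rather than tests.

## Synthetic stem maps

The generator imposes known dynamics so every stage is verifiable
without field data.  Census 1 is a homogeneous Poisson pattern of
target-species stems (default 0.127 stems m⁻²) inside one or more
disc patches (default: one disc of radius 60 m at the centre of a
200 m × 500 m plot), over a Poisson background of mixed-species stems
(0.08 m⁻²) that the analysis ignores by species selection.  DBH is
lognormal, truncated at the 1 cm census threshold: median 14 cm,
sigma 0.6 inside patches (≈40 m² BA ha⁻¹, twice the 20 m² ha⁻¹
threshold — with intensity at 2× the threshold, a straight boundary
sits exactly on the threshold isoline); median 8 cm outside.  The
in-patch law deliberately concentrates BA in canopy-sized stems: a
much heavier tail would hand the one-hectare window intensity to rare
giant stems (CV ≈ 19%), destabilising delineation topology; at the
default the CV is ≈6%.

Census 3 advances each boundary by `rate · (1 + a·u) · Δt` in direction
`u` (anisotropy vector `a` emulates wind-biased dispersal; zero by
default).  Survivors grow (N(0.15 cm yr⁻¹·Δt, 0.5 cm), floored at
zero); a fraction die, defaulting to the closed-form demographic
balance `m = 1 − E[d²]/E[(d+g)²]` (~14% per 12 y, ~1.2% yr⁻¹) at which
expected BA loss offsets growth gain, keeping the mature interior
stationary so the imposed boundary is the sole source of isoline
motion; mortality gaps are left unfilled (interior recruits would be
too small to register in BA).  The newly colonised annulus is filled at
full in-patch density, and a band of small stems (1 cm + Exp(1 cm))
recruits just beyond the new boundary, mimicking elevated seedling
survival past the mast zone.  Discrete gap events can remove (large)
stems at chosen spots.  Tags persist across censuses; dead stems stay
in the table with status `dead`.

The generator also returns closed-form truth: for a uniform-intensity
disc the focal-sum value at distance d from the centre is the
disc-window lens overlap times the intensity, so the expected isoline
radius is a one-dimensional root-find on the lens-area formula
(cross-checked against numeric windowing in the tests).  Because the
lens offset shrinks as the disc grows, the threshold isoline moves
somewhat *faster* than the boundary — an amplification of ≈1.19 at the
default intensity-to-threshold ratio (0.59 vs 0.50 m yr⁻¹), declining
slowly as the intensity margin grows.  This is an inherent property of
windowed delineation and is visible in both estimators.

What passing recovery tests show: at the validation seeds the chain
recovers imposed radial advance within ±0.15 m yr⁻¹ at rates
0–0.5 m yr⁻¹ under Poisson sampling noise, demographic turnover, and
edge recruitment.  Two noise/bias terms dominate the error budget: the
lens amplification above (≈ +0.1 m yr⁻¹ at the highest rate), and
world-level fluctuation of the realized census-to-census intensity
balance (the basal area removed by mortality is concentrated in few
large stems, so the inter-census intensity shift has ≈2% sd, worth
roughly ±0.07 m yr⁻¹ on a five-world mean).  What the tests do not
show: robustness to clustered (masting) recruitment, species
misidentification, DBH measurement error, or non-disc patch geometry;
the generator has an optional anisotropy control but recruitment is
Poisson.

## Numerical choices

* Focal sums via FFT convolution (tiny negatives from round-off are
  clamped for nonnegative inputs); brute-force disc scans verify
  exactness on small grids.
* Kernel truncation at 6 sd; evaluation on the 1 m lattice.
* Isoline vertices interpolate the bilinear surface to 1e-6·level.
* Reuse-capped matching processes vertices in descending pass-1
  distance with a KD-tree; ties broken by index order, so results are
  invariant to input row order up to exact distance ties.
* Seed policy: one master seed; all stage substreams derived from it
  deterministically, so reports are bit-identical across reruns.
* Degenerate inputs: empty stem sets yield zero surfaces (warning);
  constant surfaces yield no isolines (warning); contours with fewer
  than three distinct vertices are dropped (warning); all-identical
  pair displacements short-circuit the bootstrap to a zero-width
  interval.

## Limitations

* The 10/20 m² ha⁻¹ patch definition is threshold-dependent; rates at a
  different level describe a different stem-age cohort of the same
  front.
* Windowed delineation makes isolines move slightly faster than the
  underlying boundary for convex patches (lens-offset effect above).
* Nearest-vertex matching shrinks displacements along wiggly
  boundaries; rates are mild underestimates when boundary noise is
  comparable to true displacement.
* Vertex-level permutation p-values on single smoothed isolines are
  anticonservative (autocorrelation; see above).
* Plot truncation biases boundary rates wherever a patch meets the plot
  edge; the vector fields partially compensate by showing intensity
  gains at the margins.
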