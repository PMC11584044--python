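# Methods

This note documents the models and procedures implemented in `leafmorph`,
the parameter choices that matter, and what the synthetic generator does and
does not emulate.

## Pseudo-landmark representation

A traced outline runs from one corner of the cut petiole end, around the
blade, to the other corner. The base is detected as the vertex nearest the
midpoint of the first and last trace points; the tip as the vertex at
maximal *arc-length* distance from the base along the closed contour
(ties break to the lowest index). The arc-length rule is the default
because it is robust to strongly recurved lobes, where the Euclidean
farthest point can sit on a lobe rather than the apex; a `euclidean` rule is
available via `tip_rule`.

The outline is re-indexed to start at the base, translated so the base is
at the origin, rotated so base→tip lies along +y, and its winding
normalized counter-clockwise (so mirrored traces superimpose consistently).
Each of the two sides cut by the tip is then resampled by piecewise-linear
arc-length interpolation to S points (default S = 100). Sides are
half-open — side 1 spans base (inclusive) to tip (exclusive), side 2 tip
(inclusive) back toward base (exclusive) — so tip and base each appear
exactly once and no landmark is double-weighted in superimposition. No
smoothing spline is applied: inputs are hand-traced polylines and the
resampler respects them.

## Shape descriptors

Circularity `4π·A/P²` uses the shoelace area and closed polygonal
perimeter of the *raw* traced polygon, petiole included, since the trace
convention includes the petiole. Length is the extent of vertex projections
onto the unit base→tip axis, width the extent on its perpendicular; both
are therefore rotation-invariant (unlike image-axis bounding boxes, which
would depend on how a specimen was mounted). Aspect ratio is
length/width — the orientation under which larger values mean longer,
narrower leaves and typical values exceed 1.

## Procrustes superimposition

Full Procrustes is used: every configuration is centered and scaled to unit
centroid size, and rotation comes from the SVD of the cross-covariance with
the determinant forced to +1 (reflection is not a leaf-shape equivalence;
a flag enables it, in which case the better of the raw and reflected
alignments is taken). Size is deliberately removed — it is carried by the
descriptors instead.

The generalized scheme initializes the mean as the (normalized) first
configuration, superimposes all leaves onto it, replaces the mean by the
coordinate-wise average renormalized to unit centroid size (preventing
scale drift), and repeats until the Procrustes distance between successive
means falls below 1e-6 (`gpa_tolerance`) or 100 iterations. The summed
squared distance to the mean is non-increasing across iterations (each mean
update maximizes the summed inner products for fixed rotations, and the
rotation step can only improve); the test suite asserts this per iteration.
Hitting `max_iter` returns results with `converged=False` and a warning
rather than raising, so long runs degrade gracefully.

Pairwise distance matrices re-superimpose each pair independently, which
makes them exactly symmetric, rather than measuring distances in the common
GPA frame.

## Morphospace

PCA is computed on the covariance basis of the flattened aligned
coordinates (x0, y0, x1, y1, ...), with no tangent-space projection —
Procrustes-aligned leaf shapes occupy a small neighborhood of the mean, so
the flat approximation is standard practice. Loading signs are fixed by
making each loading's largest-magnitude element positive, which makes
scores reproducible across runs and library versions. The inverse map
`mean + Σ score_j·loading_j` reconstructs configurations exactly at full
rank and renders theoretical leaves elsewhere; the morphospace grid spans
the observed min/max of PC1 and PC2 (a ±k·sd span is available via
`span_sd`).

## Archetype classification

The Shull (Simplex, Rhomboidea, Tenius, Heteris — "Hetersis" accepted as an
alias) and Iannetta (panels 1a–1d, 2a–2b, 3/4, 5, 6, 7a–7b) archetypes are
shipped as *synthetic stand-ins*: documented generator presets spanning
lobe counts 0–7 and depths 0–0.85, pushed through the same landmarking
pipeline as the leaves they classify. They are not digitizations of any
published silhouettes, so type frequencies obtained with them characterize
the synthetic presets, not historical type prevalence. Users with their own
digitized archetypes can load them from outline text files and build an
`ArchetypeSet` directly. Classification superimposes the leaf pairwise onto
each archetype and takes the smallest distance; exact ties break to the
canonical scheme order. The eleven Iannetta panels can be collapsed to the
seven coarse types via `IANNETTA_COARSE` for reporting.

## Weather windows and models

Daily series are averaged across stations per site and date (a variable
missing from every station stays missing), and archive integer units are
converted as tenths: temperatures /10 → °C, precipitation /10 → inches.

Windows anchored on the collection date: GS = 6 calendar months back
(same day-of-month, clamped at month ends) through the collection date
inclusive; YL = 365 days back; DOC = the collection date alone. AT, MAX,
MIN are means of daily TAVG/TMAX/TMIN over non-missing window days — except
YL's AT, which is (hottest calendar-month mean + coldest calendar-month
mean)/2, computed over the year-month groups inside the window. AP is
log1p of the mean daily precipitation (log1p rather than log so zero-rain
windows stay finite). Coverage is the fraction of window days with a
non-missing TAVG; below `min_coverage` (default 0.5) the summary is NaN
with a warning, and a collection date outside the series entirely is an
error.

Per descriptor, nine OLS models are fitted on the same complete cases:
additive AT+MAX+MIN+AP per window with the climate-region categorical
(treatment-coded, alphabetically first region as reference), the same three
without region, and three interaction variants adding AT×AP. AIC is
`2k − 2·logLik` with k counting the residual variance along with the mean
parameters; ΔAIC is relative to the best model in the compared set.
Design matrices are checked for rank before fitting, and a fit with no more
observations than mean parameters is rejected. p-values are reported
unadjusted except Tukey HSD's own family-wise adjustment. The χ² test
behind Cramér's V uses no continuity correction (the correction would break
the V = 1 identity on a perfectly associated table).

## The synthetic generator

The generator defines the package's study conditions; its defaults are
fixed, not tuning knobs.

**Leaves.** Blade half-width at proximal-distal position t (0 = tip,
1 = base) is `h(t) = W·sin(πt)·(1 − d·sin²(c·πt))` with lobe count c and
depth d < 0.95 (keeping the lamina positive everywhere), mirrored about the
midrib with per-vertex Gaussian half-width noise (`asymmetry_sd`, relative
to W) and floored just off the midrib, plus a rectangular petiole stub of
length `petiole_frac`·L. W = L/(2·elongation), blade length L = 100 px.
Circularity is monotonically non-increasing in depth and aspect ratio
strictly increasing in elongation (asserted over parameter grids). A noisy
outline that self-intersects is regenerated with halved noise, up to 10
attempts. Default-noise leaves pass the simple-polygon check at 100%.
Across the priors used for linked datasets (lobe count 0–7, elongation
1.4–4.0, petiole 0.15–0.30) measured circularity spans roughly 0.05–0.8 and
aspect ratio roughly 1.6–7, though AR can exceed the nominal upper end when
deep lobing narrows the effective width.

**Specimens.** Ids, lat/lon inside per-region bounding boxes, a member
state of the region (the packaged 8-region NOAA lookup excludes the West),
and collection dates uniform in the configured range.

**Weather.** Daily TAVG = `38 − 0.7·lat + 12·cos(2π(doy−200)/365)` °C plus
N(0, 3); each site draws a mean diurnal range ~ U(3, 8) °C, and TMAX/TMIN
sit that far (plus half-normal day noise) above/below TAVG, so
TMIN ≤ TAVG ≤ TMAX always. The per-site diurnal range matters: without it,
window means of TMAX and TMIN are exactly collinear with TAVG across sites
and multivariate temperature models are unidentifiable — real station
networks vary in continentality the same way. Precipitation is a Bernoulli
wet day (p = 0.3) times a Gamma(0.7, 0.4 in) amount. Series start 370 days
before the earliest collection so every YL window is covered. Optional
uniform missingness supports the coverage logic.

**Planted effect.** `lobe_depth = clip(0.75 − 0.02·AT_GS + N(0, σ), 0,
0.95)` per specimen, other parameters from documented priors, with a
ground-truth table returned for recovery tests. The defaults (baseline
depth 0.75, −0.02 per °C, σ = 0.05) place typical GS temperatures of
5–25 °C at depths 0.25–0.65 — lobing decreasing with warmth, on the scale
of variation the lamina model can express.

What the generator does **not** emulate: venation, serration, petiole
curvature, digitization jitter correlated along the trace, spatially
correlated weather between nearby sites, station dropout patterns, or
collection-date bias toward flowering season. Passing tests therefore
demonstrate the correctness of the pipeline's geometry and statistics under
controlled conditions, not field performance on herbarium material.

## Numerical choices and degenerate inputs

* Resampling is linear along the polygon; original vertices are generally
  not retained.
* Zero centroid size, coincident tip/base, zero-length sides, and
  fewer-than-3-vertex outlines raise typed errors
  (`GeometryError`/`ParameterError`/...); a self-intersecting *input*
  outline only warns, since hand traces occasionally self-touch.
* GPA convergence is measured as the Procrustes distance between
  successive means; 1e-6 is far below any biological signal at unit
  centroid size.
* Exact classification ties break to canonical archetype order, making
  results order-deterministic.
* All generators are pure functions of (parameters, seed); the pipeline
  derives stage seeds by fixed offsets from one master seed, and two runs
  with equal configuration produce byte-identical CSVs.

## Verification oracles

The test suite checks the implementation against independent routes:
closed-form descriptors (unit square, fine polygonal circle, rectangles),
a brute-force arc-length walk for resampling, a rotation-grid search for
pairwise superimposition, direct projection for PC scores, the closed-form
Gaussian log-likelihood for AIC, and constructed contingency tables for
Cramér's V. Planted-effect recovery uses 50 replicates of n = 300: the
"true" circularity slope per replicate is the OLS slope of the *expected*
circularity under depth noise (3-node Gauss–Hermite quadrature through the
noise-free generator) on GS temperature — the estimand the noisy regression
actually targets, since the depth→circularity map is nonlinear — and 95%
CIs must cover it in 85–99% of replicates. Model selection must pick a
GS-window model (ΔAIC = 0) in ≥ 90% of 50 simulations with the response
planted on AT_GS.

## Problem sizes

Defaults used by the test and acceptance suites: 200-leaf GPA at S = 50,
a 300-leaf single-mode morphospace family at S = 100, 50 model-selection
simulations at n = 120, and 50 planted-effect replicates at n = 300 — sizes
at which every stochastic criterion is stable under reseeding while the
full suite completes in a few minutes on one CPU.

## Known limitations

* Archetypes are synthetic stand-ins (see above); type-frequency outputs
  are not comparable to published type prevalences.
* The GS window uses calendar-month offsets and the YL window exactly 365
  days; leap-day handling follows pandas date arithmetic (clamping at
  month ends).
* The lamina model cannot produce compound (fully dissected) leaves,
  overlapping lobes, or asymmetric lobe *placement* — asymmetry enters
  only as half-width noise.
* No semilandmark sliding, tangent-space projection, or robust/weighted
  Procrustes variants.
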