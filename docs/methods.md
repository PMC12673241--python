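# Methods

This note documents the models, conventions and numerical choices behind
`thermoniche`, the assumptions of the synthetic study world, and what the
test suite does and does not establish about real data.

## 1. Ingestion protocol

**Fix filters.** On-ground fixes are those with null velocity; "null" is
`speed ≤ speed_tol` with `speed_tol = 0` by default (the tolerance is a
config knob because real tags report small nonzero jitter).  When no speed
column exists, step speed (displacement / time gap) is substituted with a
warning.  Daylight windows are fixed local-clock hours — floor-hour within
[6, 17] during breeding and [7, 20] during post-breeding — not solar
elevation, because the protocol is stated in clock hours.  Local time is
UTC + a configurable offset (default +1); no daylight-saving handling is
attempted.

**Seasons.** Breeding starts May 1 for every individual.  Departure is the
first date from which every observed daily centroid stays outside the
breeding area for ≥ 30 consecutive calendar days; days without fixes do not
break a run, and the earliest qualifying date wins.  The "breeding area"
for a candidate date is the 90% kernel contour of the individual's fixes
*before* that date, buffered by 1 km — using only prior fixes matters,
because an early migrant would otherwise drag its destination into its own
breeding polygon and mask its departure.  A candidate closer than 30 days
to the end of tracking cannot be confirmed; such individuals are flagged
indeterminate and excluded.  Birds with no qualifying date are residents
with the fixed post-breeding window Jul 15 – Sep 15.  Strict
consecutiveness (no tolerated returns) is a deliberate reading of the
30-day rule and is exposed as a sensitivity knob (`min_away_days`).

**Inclusion.** Captured before May 1; ≥ 7 distinct tracked days before
departure (residents referenced to Jul 15); for multi-year birds only the
most recent year with a valid season pair.  Every removed fix or individual
carries a named exclusion reason, and record counts are conserved across
filtering.

## 2. Microclimate variables

Buffer statistics are computed over every 30-m cell whose *centre* lies
within 500 m of the fix (cell-centre-in-circle membership is unambiguous
and oracle-checkable), at the hour nearest the fix timestamp (single
matched hour; pooling multiple hours per fix is available as an option).
The median uses midpoint interpolation and the SD the n−1 denominator.
Buffers partly outside the raster are evaluated over the available cells
when coverage is ≥ 50%, else flagged invalid.  The refugia metrics are

    refugia use          = T(fix cell) − median(buffer)
    refugia availability = min(buffer) − median(buffer)

both ≤ 0 by construction (availability exactly; use whenever the fix cell
is in its own buffer), with more negative values meaning more refugia use /
availability.  The NDVI covariate is the day-weighted mean of the 8-day
composites intersecting the 8 days before departure (residents: before
Jul 15), averaged spatially over the individual's breeding area (its 90%
kernel polygon); day-weighting resolves the ambiguity of an "8-day mean"
over a staggered composite calendar.

## 3. Niche space

The eight variables are z-scored globally — one mean/SD per variable over
all fixes of all individuals, seasons and years — and eigendecomposed
(full-rank PCA).  Global rather than season-wise standardization keeps all
niches in a single comparable space.  The retained dimensionality is the
smallest number of leading axes cumulatively explaining > 70% of variance;
in every world this package generates that is two, matching the regime the
analysis is designed for (a dominant temperature axis and a refugia axis).

**Axis orientation.** Signs are fixed so that PC1 increases with the five
temperature variables and PC2 increases with *refugia availability in the
ecological sense*: the availability statistic (≤ 0, more negative = more
refugia) loads negatively on PC2, equivalently buffer-temperature SD loads
positively.  High PC2 therefore means a refugia-rich microclimate.  This
orientation is what makes the distance model's PC2 coefficient negative
when refugia-rich breeders migrate shorter distances.

**Kernel niches.** The niche of a unit is the highest-density region (HDR)
enclosing 99.5% of a binned Gaussian KDE of its PC1–PC2 scores.  The
bandwidth is the bivariate normal reference rule, `h_j = sd_j · n^(−1/6)`
per axis (the d = 2 Scott rule, the same family conventional kernel
home-range tools use); the evaluation grid is 400 × 400 cells spanning the
scores ± 3 bandwidths; the HDR threshold is found by ranking grid cells by
density and accumulating mass — not by a density quantile of the points.
Because smoothing inflates the KDE's covariance by (1 + h_rel²) relative to
the data, a raw p-mass HDR systematically encloses more than p of the data
(≈ 90.5% at p = 0.90, n = 10⁵).  The threshold is therefore taken at the
analytically corrected mass p_eff = 1 − (1 − p)^(1/(1 + h_rel²)), which
restores nominal data coverage under the bivariate-normal reference model;
the uncorrected convention is available via `coverage_correction=False`.
Polygons (with holes) are extracted from the density surface with contourpy
and handled as shapely geometries; area and centroid come from the polygon.
Units with fewer than 30 scores (configurable) are skipped, not estimated.

**Overlap and dissimilarity.** Overlap is always
100 · area(subject ∩ reference) / area(reference) — the reference niche is
the denominator.  Species-level seasonal overlap is reported in both
directions, since the denominator convention for "post-breeding overlapped
with breeding" is genuinely ambiguous.  Individual niches are compared
against their own population's same-season, same-year niche.  Seasonal
dissimilarity is the Euclidean distance between an individual's breeding
and post-breeding niche centroids in PC units; individuals missing either
seasonal niche are dropped from the dissimilarity model with a logged
reason.

## 4. Movement

Daily utilization distributions use the same kernel engine in geographic
space at 90% mass (minimum 5 fixes per day).  The mean breeding centroid
averages the breeding daily centroids.  Consecutive post-breeding daily
centroids within a 5-km collapse radius are merged into "areas" (area
centroid = mean of members), and the total distance travelled is the chain
breeding centroid → area 1 → area 2 → …, summed in km.  A literal
every-daily-centroid sum would scale with tracking duration (a bird sitting
60 days at one site 36 km away would "travel" 2160 km) and contradict the
km-scale distances the statistic is meant to express; the literal rule is
kept behind `literal_daily=True` as a sensitivity option.  This collapse
radius and the 0.5-km floor inside `ln(distance)` (which keeps residents
finite) are the two interpretive constants of the movement stage; both are
config-exposed.

## 5. Mixed models

Both models are linear mixed-effects fits with a random intercept for
breeding population, REML by default, via statsmodels' MixedLM:

* distance model: `ln(km) ~ pc1_centroid + pc2_centroid + mean_ndvi_8d`;
* dissimilarity model:
  `dissimilarity ~ overlap_pop_breeding + pc1_centroid + pc2_centroid + ln_distance`.

All covariates are z-scored across the individuals entering each fit; the
(mean, SD) pairs are stored on the fit object so coefficients can be mapped
back to natural units exactly.  Fixed-effect p-values are Wald z — mixed
models have no exact small-sample df, and this choice is recorded rather
than hidden; at the ~30–50-individual scale it is mildly liberal, which the
null-world experiment quantifies (observed type-I ≈ 3–5% at nominal 5%).
Optimisation falls back through several optimisers (and to ML) until a
converged fit with finite standard errors is found; boundary (singular)
random-intercept estimates are flagged, not silently refit.  With a single
population the random intercept is unidentifiable and an OLS fit is used
with a warning.

**Subsampling robustness.** For each population with more than k = 5
individuals, the population seasonal niche is rebuilt from every subset of
5 individuals — all C(n, 5) subsets when ≤ 10,000, otherwise exactly 10,000
distinct seeded draws — and its overlap with the full seasonal reference
niche recorded.  Subset niches are evaluated on the reference niche's own
grid so the 10,000 overlaps are fast mask intersections; this is the one
place the polygon route is bypassed for throughput, and the full-data
reference value is computed by the same mask route for comparability.

## 6. The synthetic world

The generator emulates the study design: 5 breeding populations (~10 males
each) in a 30-km planar landscape, tracked from April capture to Sep 15 at
10–120-min cadence.

**Thermal landscape.** Temperature is separable:
`T(x, y, t) = a(t) + S(x, y)` with `a(t)` a diurnal sinusoid (peak 15:00,
half-amplitude 7 °C) plus a linear seasonal warming of 10 °C from May 1 to
Sep 15 on a 19 °C May-1 daily mean, and `S(x, y)` a south→north cooling
gradient (12 °C across the landscape — the compressed-geography analogue of
cooler northern post-breeding areas), a −4 °C offset inside refugia patches
(discs of radius 30–120 m, Poisson-placed at per-population densities of
0.5–6 km⁻² inside breeding zones and a northward-enriched background), and
static Gaussian-correlated noise (SD 0.5 °C, 90-m correlation length).
Separability makes the cube cheap (one 2-D surface + one hourly series) and
is exact for the phenomena modelled: no weather fronts, no advection, no
soil memory.  A dense (hour, y, x) backing is supported for arbitrary
rasters.

**Tracks.** Individuals hold a correlated random walk (discrete OU,
stationary SD 150 m, lag-1 correlation 0.7 — fix-level autocorrelation of
habitat choice is otherwise unconstrained, so it is a single tunable knob)
around a home centre; above 27 °C a fix relocates with probability 0.6 to
the coolest cell within 250 m, the behavioural refugia-seeking that makes
the hot post-breeding season differ from spring in *used* (not just
available) microclimate.  Ground fixes have speed 0; 2% of fixes and the
migration hop itself get flight speeds > 5 m/s so the velocity filter has
work to do.

**Built-in effects.** Migration distance is drawn as
`ln d = 4.0 + β_refugia · m + ε`, `ε ~ N(0, 0.6)`, where `m ≥ 0` is the
refugia-availability *magnitude* (median − min of the home buffer) and
β_refugia = −0.6 by default: refugia-rich breeders move less, and draws
under 2 km become residents.  Destination choice implements niche tracking:
with probability `1 − exp(−β_tracking · d / 10 km)` a migrant picks, among
candidate sites on its distance ring, the one whose season-adjusted
conditions (spatial median temperature + seasonal offset, and availability)
best match its breeding site; otherwise the site is random.  Short migrants
thus *cannot* offset the seasonal warming (the gradient reach is ~15 km)
while long migrants can — the physical mechanism behind the negative
dissimilarity–distance relationship.  A 20% share of longer migrants uses a
second post-breeding area.  Optional edge-case individuals (a second
tracked year, a post-May-1 capture, a 4-day pre-departure track) exercise
the inclusion rules.

**What the world does not have.** Real terrain and canopy physics, weather
variability, GPS position error, behavioural states beyond the single
heat-seeking rule, females/juveniles, multi-year site fidelity (the
two-year option re-draws rather than repeats behaviour).  Passing tests
therefore establish that the *pipeline* recovers known structure from data
with the assumed statistical shape — not that the assumed shape is a
complete model of field data.

## 7. Scaled experiment sizes

Replicate-world experiments (effect recovery, null calibration) use 5 × 6
individuals, 2-hourly fixes, environment joins thinned to 120
fixes/individual/season, 150-cell niche grids, and daily-mean centroids in
place of daily-UD centroids; buffer statistics and centroid estimates
stabilise well below these sizes, so the reductions change runtime, not
estimands.  The direction-reproduction world uses 5 × 9 individuals (a
~46-bird study analogue) with hourly fixes and strong tracking
(β_tracking = 6).  The "truth" for the recovered PC2 slope is the
projection of the generating linear predictor onto the fitted scaled
covariate, β_refugia · cov(m, PC2-centroid_scaled), computed per world from
the generator's ground-truth table.

## 8. Known limitations

* The availability distribution is bimodal at low patch density (a buffer
  either contains a patch or not), so the distance model's covariate is not
  Gaussian; the mixed models tolerate this but SEs are approximate.
* Wald-z inference is anti-conservative at very small n; with < 2
  populations the random effect is dropped entirely.
* Niche areas inherit ~1% discretisation error from the 400-cell grid;
  overlaps of near-tangent polygons inherit it too.
* The NDVI covariate is nearly collinear with departure date by
  construction in the synthetic world (both track the seasonal decline), so
  its null effect there is expected, not evidence about real food effects.
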