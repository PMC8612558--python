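# Methods

This note records the models, conventions and numerical choices behind
`aohmap`, and what the synthetic-data tests do and do not establish about
behaviour on real data.

## Coordinate model

All metric work — the alpha value, nearest-neighbour distances, pixel
areas — happens in a spherical Lambert cylindrical equal-area projection
(`x = R·λ`, `y = R·sin φ`) on the authalic radius `R = 6 371 007.1809 m`.
The projection preserves spherical area exactly, so a 1000 m grid pixel is
exactly 1 km² at any latitude and analytic area checks in the tests are
exact. Distances are projected Euclidean, not geodesic; east–west
distances are increasingly stretched away from the equator, which is
acceptable for the low-latitude study systems this tool targets but
should be kept in mind for high-latitude use. Rasters are stored as plain
TIFFs with an ESRI world file (`.tfw`, referencing the *centre* of the
upper-left pixel) and a one-line `.prj` sidecar carrying the project CRS
identifier (`cea` or `wgs84`) — all georeferencing stays in text form.

## Checklist qualification

A record qualifies if it is approved **and** complete **and** its protocol
is not historical/incidental **and**, for traveling protocols, distance
≤ 7 km and duration ≤ 180 min. Both thresholds are inclusive: what is
excluded is strictly *above* 7 km or *greater than* 3 hours. Two cases the
upstream data sources leave open are resolved conservatively:

* a traveling checklist with no recorded distance is excluded — the 7 km
  rule cannot be verified, and location confidence is the point of the
  rule;
* a missing duration on a non-traveling protocol is retained — stationary
  and other protocols are anchored to a point regardless of duration.

The approval flag is honoured as given; no re-review is attempted.

## Alpha hull

The hull input is the union of presence points and published-range
polygon vertices (exterior rings and holes alike, no densification). The
alpha value is the median of **all** pairwise presence–presence distances
— presences only, since it describes the spacing of actual observations;
range vertices shape the hull but not its concavity parameter. Distances
are projected, in km.

Construction is the planar alpha complex: the union of Delaunay triangles
whose circumradius is at most alpha. Input points are deduplicated and
lexicographically sorted first, so the result is invariant to input order.
Two boundary conventions:

* **Infinite-alpha limit.** When alpha is at least the diameter of the
  point set, an alpha disk can no longer pinch the boundary anywhere, and
  the hull is returned as the exact convex hull. This also sidesteps
  near-degenerate sliver triangles whose circumradii exceed any practical
  alpha and would otherwise leave hairline deficits at the convex limit.
* **Fallback.** With fewer than three non-collinear input points (or no
  usable alpha from fewer than two distinct presences) no alpha shape
  exists; the envelope falls back to the union of the published range and
  one-pixel buffers around each presence, flagged `fallback_used`.

Monotonicity (larger alpha never shrinks the hull) holds by construction:
the kept-triangle set grows with alpha, and the convex hull is the
supremum.

## Habitat refinement

* **Percentile convention.** All percentiles (elevation 1%/99%, cover
  25%) use linear interpolation between order statistics, fixed
  project-wide. The extreme-trim and upper-75% rules themselves guard
  against mislocated records (a convenient landmark rather than the
  observation point) and against zero-cover artefacts such as lodges or
  trailheads; zero covers are removed before the cover percentile.
* **Elevational envelope.** Final limits take the outer envelope of the
  observed percentiles and the documented limits; a documented limit
  missing on one side leaves that side purely observed (one-sided
  envelope).
* **Point extraction** reads the single containing 1 km cell — no
  interpolation — matching the cell-based semantics of the habitat data.
  Fine cover rasters are bilinearly resampled onto the 1 km analysis grid
  (values clipped to [0, 100]).
* **AOH rule.** A pixel is AOH iff its centre lies inside or on the hull,
  its elevation is within the final limits (inclusive), and — in forest
  mode — its cover meets the threshold. Open-habitat species (by
  metadata, or when every presence has zero cover) are mapped in
  elevation-only mode and flagged; their summaries are excluded from the
  category aggregates. Plantation/landcover confusion is out of scope:
  cover is taken at face value.
* Presences falling outside the AOH are retained for hull building and
  occupancy — an observed bird trumps a habitat model.

## Absences and occupancy

The absence grid (default 5 km cells, ≥ 25 checklists) is anchored at the
AOH raster origin; registration is configurable but not inferred. A cell
qualifies only on checklists located on AOH pixels (a visit to unsuitable
habitat says nothing about absence), yet any in-cell detection
disqualifies it, including detections at non-AOH pixels. Cell centroids
are geometric cell centres.

The occupancy partition is plain nearest neighbour from each AOH pixel
centre to the union of presences and absence centroids, by projected
Euclidean distance (k-d tree, verified in tests against an exhaustive
per-pixel oracle). Exact ties label *occupied* — the optimistic
convention. With no absence cells the whole AOH is occupied; with no
presences, unoccupied; with neither, the partition is undefined and an
error is raised. No detectability correction or effort weighting is
applied.

## Summaries

Areas are pixel counts × pixel area (raster path) or equal-area polygon
area (vector path); geographic-coordinate polygons are rejected rather
than silently mis-measured. The per-species ratio is AOH / published
range; category aggregates report the **mean of per-species ratios** and
the fraction of species per ratio bin (<50%, 50–150%, >150%, plus >100%),
with bin edges configurable. Species flagged `lt10_obs` (fewer than ten
qualifying observations) or `open_habitat` are mapped but excluded from
aggregates. Batch screening skips species whose published range is
125 000 km² or larger, the method's stated target set, when the range size
is known.

## Synthetic data generator

The `fixtures` module emulates the study's data conditions:

* **Landscape**: 1 km pixels directly in the equal-area CRS (a lon/lat
  mode exists for projection tests). Elevation is a west–east ramp or a
  Gaussian ridge, 0–3000 m, with 20% smooth noise. Tree cover is a
  smooth random field thresholded so that exactly the requested fraction
  of pixels is forested; forested values are rank-transformed to spread
  evenly over (0, 100], i.e. canopy percentages rather than raw field
  amplitudes.
* **Virtual species**: a rectangular true range covering a set fraction
  of the landscape, a true elevation band, a true minimum cover, and a
  per-visit detection probability (default 0.8). A species is *suitable*
  exactly on pixels satisfying all three truth criteria; detection is
  Bernoulli(detect_prob) there and impossible elsewhere. Red List
  categories default to a frequency table loosely matching a small-ranged
  Neotropical forest avifauna (CR 6%, EN 12%, VU 18%, NT 22%, LC 42%).
* **Checklist streams**: effort is uniform or clustered around eight
  hotspot centres with isotropic Gaussian scatter (σ = extent/20),
  mimicking birders' site fidelity. Dates are uniform over 2000–2020,
  with a flag to inject pre-2000 records for the extraction date floor.
  An exact count `round(n·violation_fraction)` of records violates the
  traveling effort rule; separate fractions control historical/incidental
  protocols and incomplete checklists. Everything is a pure function of
  (seed, parameters).

What the generator does **not** model: observer skill, distance-dependent
detectability, seasonal movement, spatial autocorrelation of detection,
or range shapes more complex than rectangles. Passing recovery tests
therefore demonstrate the pipeline's correctness given its own
assumptions — not that those assumptions hold in any particular field
dataset.

## Problem sizes and study conditions in the checks

The test suite and `scripts/acceptance.py` run the study at desk scale:
landscapes of 80×80 to 150×150 km, checklist streams of 200 to 16 000
records, 10–30 virtual species with 300–1000 presences each, and
nearest-neighbour oracle grids up to 200×200. Recovery-test species are
placed so their elevation band is genuinely occupied up to its edges (the
band is derived from inner quantiles of the elevations available inside
the range), since percentile estimators cannot see an edge that habitat
never reaches.

## Known limitations

* Projected (not geodesic) distances; see the coordinate model above.
* The alpha-from-presences-only reading of the median rule is a
  documented choice; the alternative (presences ∪ range vertices) would
  typically give larger alphas and smoother hulls.
* The absence date window is unbounded: all records passing the ingest
  filters count, regardless of age.
* HTML maps reference the Leaflet assets from a CDN; layers and popups
  are self-contained, but the basemap requires network access to render.
* The eBird/GBIF-style display-only overlays are accepted as pre-built
  point lists; no API retrieval is implemented.
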