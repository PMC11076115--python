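# Methods

This note documents the models and procedures implemented in
`tricksterbiogeo`, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the package's
known limitations.

## Grid model

The analysis grid is a discrete global grid system (DGGS). The default
backend is a **Fibonacci-lattice spherical-Voronoi grid**: resolution
*r* places `N(r) = 120·7^r + 2` generator points on the unit sphere by
the golden-angle spiral (near-uniform density), and a cell is the
Voronoi region of one generator. `N(r)` follows the cell cardinalities
of an aperture-7 hexagonal hierarchy — 122, 842, 5882, 41,162 cells at
r = 0–3 — so resolution 1 gives the familiar ~840-cell global hexagonal
tiling used in grid-based macroecology. The generator point doubles as
the cell centroid, which makes `point_to_cell(cell_centroid(c)) == c`
exact and the partition property structural rather than numerical.
Point lookup is nearest-generator on a KD-tree of unit vectors
(chordal and great-circle nearest neighbours coincide on the sphere).
Two further backends exist: a thin adapter over `h3`/h3-py when that
library is installed, and an equal-angle lat/lon grid for cheap
debugging (its cell counts do not follow the aperture-7 series).

Distances are centroid-to-centroid great-circle distances on a sphere
of radius **6371.0 km** (haversine). Any fixed radius preserves every
rank-based quantity in the analysis; the value only scales reported
kilometres. Between-cell distance is defined centroid-to-centroid
rather than boundary-to-boundary because the centroid is also the
convention for climate lookup; for near-uniform cells the two differ by
at most one cell diameter and cannot reorder medians materially.

Presence reduction is deliberate information destruction: a category is
present in a cell or absent, record multiplicity is discarded (kept only
in a diagnostic counter). This is the standard defence against
heterogeneous sampling effort in aggregated occurrence databases, where
per-category record counts span orders of magnitude.

## Cleaning

Presence databases carry systematic coordinate artefacts. The cleaner
removes (i) records at exactly (0, 0) — absolute tolerance 1e-9°, since
exact-zero detection is the intent; (ii) out-of-range coordinates;
(iii) records within a configurable radius of user-supplied exclusion
points. The exclusion list generalises the capital/centroid/institution
gazetteer tests of dedicated cleaning tools without bundling gazetteer
data: the analyst supplies the points that are artefact magnets in
their database. Cleaning is order-preserving and idempotent, and the
report's counts always reconcile (`n_output = n_input − removals`).

## Climate and biome classification

Cell climate is (MAT °C, MAP mm/yr) looked up nearest-node at the cell
centroid on a rectilinear climate surface. When the centroid is nodata
(ocean), the cell's climate is the arithmetic mean of the surface
values at the real-animal coordinates inside the cell — those
coordinates are on land by construction, so they sample the cell's
terrestrial climate. Cells where neither route yields both variables
are MISSING: excluded (and counted) in biome statistics, retained in
the distance and co-occurrence analyses, which need no climate.

Whittaker's scheme classifies (MAT, MAP) into nine biome classes; any
climate outside all nine polygons is an OUTLIER, giving exactly ten
labels. The packaged polygon file
(`data/whittaker_polygons_synthetic.csv`) is a **synthetic stylized
digitization** made for this package: nine simple polygons tiling
−15…30 °C × 0…450 cm/yr with the classic topology (cold → tundra/boreal,
dry → deserts and grasslands, warm-wet → tropical forests). Users who
need a specific published digitization can load their own CSV with the
same schema; classification near class borders depends on the
digitization chosen. Precipitation is converted mm → cm (÷10) inside
the classifier because the diagram's axis is cm. Boundary points count
as inside, and overlaps resolve by a fixed priority order, so
classification is total and deterministic.

## Statistics

**Biome fractions.** Each comparison is a 2×K Pearson chi-squared test
(no continuity correction) after dropping classes empty in both rows;
df = K′−1. The background ("null model") row is the biome census of the
union of all real-animal cells — the terrestrial area accessible to the
study taxa. An optional Monte-Carlo p-value (multinomial resampling
under the margins) is available for small expected counts, where the
asymptotic tail is unreliable; the default mirrors the plain test.
FDR is Benjamini–Hochberg, applied **within each comparison family**
(real-vs-background across categories; trickster-vs-background;
real-vs-trickster; permutation tests) — the most common convention for
per-column significance marks; a pooled mode is available in the
pipeline config.

**Conditional probability.** P(real | trickster) is a binomial
proportion over trickster cells; the interval is the **Wilson score**
interval (default 95%). Wilson was chosen over Wald because the
estimates of interest sit near 1, where Wald collapses and Wilson keeps
near-nominal coverage (verified by simulation in the test suite:
coverage within ±2% of 95% at n = 50).

**Permutation test.** The statistic is the median of all C(n, 2)
pairwise centroid distances among a category's trickster cells (even
counts: mean of the two central order statistics). The null re-places n
cells uniformly without replacement on the category's real-animal
cells. All trickster cells enter the observed statistic, including any
outside the real range, while the null samples only real cells — the
null hypothesis is literally "the motif occurs where the animal
occurs". Two p-values are reported: the empirical
(#{null ≤ obs}+1)/(B+1), exact and bounded below by 1/(B+1), used for
inference and FDR; and the lower tail of a normal fitted to the null
medians, a parametric extrapolation that can express tail probabilities
far below the empirical floor. The Gaussian tail is a documented
approximation, not ground truth — the null medians are not exactly
normal, so it should be read as an order-of-magnitude summary.

Randomness: every analysis draws from one top-level seed; per-category
streams are derived by hashing (seed, category name) into a
`SeedSequence`, so results are independent of the order in which
categories are processed and bit-reproducible.

## Synthetic worlds

The generator emulates the statistical structure of the real inputs,
not their geography:

- **Surface**: MAT(lat) = 30 − 0.6·|lat| °C + N(0, 1 °C) on a 2° grid;
  precipitation drawn per latitudinal band (2600 ± 500 mm in the inner
  tropics, 700 ± 250 mm in the subtropics, 1000 ± 250 mm in temperate
  latitudes, 400 ± 150 mm poleward of 55°) — values chosen to populate
  the major Whittaker classes along the gradient; 30% of nodes become
  ocean (nodata) in contiguous circular blobs, which also exercises the
  centroid-nodata fallback path.
- **Species**: points are sampled only from surface nodes whose climate
  lies in the species' declared (MAT, MAP) niche, with intensity
  decaying from a random hotspot as (1 + d/500 km)^−bias (default
  bias 2) to mimic spatially uneven database sampling; each point is
  jittered within its node. Default 600 points per species. The
  generator emits one random variate triple per point, so increasing
  `n_points` extends the point sequence instead of reshuffling it and
  presence sets are monotone in sampling effort by construction.
- **Tricksters** (one point per chosen cell centroid, since the
  statistics are presence-only at cell level): `SUBSET_RANDOM` draws
  n cells uniformly from the species' cells — the permutation null is
  true and P(real | trickster) = 1; `SUBSET_CLUSTERED` takes a seed
  cell plus its nearest range cells within `cluster_spread_km` — the
  power case; `DECOUPLED` draws from the whole global grid —
  P(real | trickster) has hypergeometric expectation
  |real cells| / |all cells|.
- **Default world**: 16 categories (the canonical category count for
  this analysis), six clustered, five random, five decoupled, 12
  trickster cells each, clustered spread 3000 km.

Problem sizes used by the acceptance checks — 200 null categories and
100 clustered categories at B = 999 replicates, a 16-category pipeline
at B = 999 — were chosen so that calibration (null rejection ≈ 5%,
KS-uniform p-values), power (≥ 0.8 after FDR at the frozen clustered
settings) and recovery are measured with useful precision while the
whole suite runs in well under a minute; production runs default to
B = 10,000.

What the generator does **not** emulate: real continental geometry,
spatial autocorrelation of folklore sampling beyond the hotspot bias,
cultural transmission dynamics, and the enormous record density of real
biodiversity databases. The last point matters for the resolution
robustness check: with only ~600 points per species, refining the grid
from resolution 1 to 2 fragments real presence, so conditional
probabilities for subset scenarios drop at resolution 2 even though the
clustering conclusions (which categories are flagged significant) are
identical at both resolutions. In data-rich real applications the
conditional probabilities are far less sensitive to resolution. Passing
tests therefore demonstrate the correctness and calibration of the
machinery, not the field behaviour of any particular dataset.

## Numerical and degenerate-input conventions

- Longitude is normalised to [−180, 180); lon = 180 maps to −180.
- KD-tree nearest-neighbour ties (measure-zero) resolve to the lowest
  generator index; boundary climate points resolve by biome priority
  order.
- The median-distance statistic is undefined below two cells; such
  categories are excluded from the permutation report with a logged
  reason. A category with more trickster cells than real cells has an
  undefined null and is likewise excluded and logged.
- Chi-squared requires ≥ 2 informative classes and positive row sums;
  violations raise rather than return a value. In the pipeline report
  such comparisons appear as NaN and are excluded from their FDR family.
- The Gaussian tail p degenerates to an indicator when the null medians
  have zero variance.

## Known limitations

- The biome polygon asset is a stylized partition; per-class counts near
  borders are digitization-dependent.
- The Gaussian tail p-value inherits a normality assumption the null
  distribution only approximately satisfies.
- No spatial-autocorrelation correction is applied to the chi-squared
  tests; presence cells are treated as exchangeable units.
- Presence-only logic cannot distinguish absence from non-detection;
  low conditional probabilities are evidence against constraint only
  insofar as the real-animal data are dense.
- GeoTIFF climate rasters are not read directly; convert to the
  long-format CSV (`lon, lat, mat, map_mm`) first.
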