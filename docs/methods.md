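# Methods

## Analysis model

The pipeline treats urban expansion as the only land-cover dynamic: the
baseline land-cover map is static and every change is a non-urban → urban
conversion taken from a scenario's urban-mask stack.  Conversion is
irreversible, so stacks must be monotone (each epoch's mask is a superset
of its predecessor); the pipeline validates this and refuses non-monotone
inputs.  All rasters must share one grid (same dimensions, cell size,
origin, CRS label); there is no silent resampling.  The working lattice
is row-major with row 0 at the north edge, 0-based indices, and cell
locations at cell centers.  Missing data propagates: a stage's output is
missing wherever any required input is missing.

### Habitat accounting

Land cover is reduced to seven aggregate classes — cropland, urban,
forest, shrubland, grassland, wetland, other — and natural habitat is
everything except cropland and urban.  Seven classes rather than six are
kept because wetland dynamics are reported separately throughout; the
class set is table-driven so a six-class reduction is a configuration,
not a code change.  Loss attribution always uses the baseline habitat
class (no dynamic cropland/forest transitions between epochs), and
cropland → urban conversion is tracked in a parallel ledger: it counts
toward total urbanized area but never toward natural-habitat loss.
Per-zone aggregation is exact integer cell counting times cell areas, so
partition zone systems (ecoregions, biomes, countries) sum to the global
ledger without tolerance.  A protected area counts as "affected" when at
least one urban cell intersects it; per-zone urban growth percentages are
undefined (flagged, excluded from summaries) for zones with no baseline
urban area.

### Hot-spot analysis

The hot-spot stage emulates the standard optimized workflow with
explicit, configurable pieces: (1) sum 1 km losses onto a coarser
fishnet (default factor 10, i.e. 10 km analysis cells); (2) select a
distance band by incremental spatial autocorrelation — evaluate the
z-score of global Moran's I (normality assumption, binary band weights
excluding self) at each candidate distance and take the first local
peak, falling back to the arg-max when no interior peak exists; (3)
compute Getis–Ord G*ᵢ z-scores with binary band weights including self
(row-standardized weights available); (4) convert to two-sided p-values
and classify signed bins ±1/±2/±3 at α = 0.10/0.05/0.01, applying
Benjamini–Hochberg FDR across all non-missing cells first (default on).
Edge cells use truncated neighborhoods; there is no toroidal wrap.  A
zero-variance field yields z = 0 and all-zero bins — no significance
claims without variance.  Under i.i.d. Gaussian null fields the FDR
classifier at q = 0.05 flags a nonzero bin in ≤ 5% of cells in at least
95% of replicates (verified by simulation in the test suite).

### Fragmentation

Patches are connected components of the habitat mask; connectivity
defaults to 8 (the common landscape-metrics convention) and is
configurable.  Definitions:

- MPS (ha) = total class area / patch count.
- ED (m/ha) = total length of sides shared between a class cell and a
  different-class cell inside the analysis extent, divided by the extent
  area.  The raster exterior and out-of-extent cells never contribute
  edge, which makes the metric independent of padding.
- ENN_MN (m) = mean over patches of the minimum cell-center distance
  from the patch's edge cells to the edge cells of the nearest other
  patch; defined only with ≥ 2 patches.

An edge cell is a class cell with at least one 4-neighbor of a different
class inside the extent.  Buffer-zone metrics use a fixed region: the
cells within the buffer radius (default 5 km) of final-epoch urban land
plus that urban footprint itself, so habitat–urban boundaries count as
edge and habitat not yet urbanized at earlier epochs stays in scope.
Zones whose region is empty are flagged and excluded from cross-zone
medians.

The proximity effect is measured per epoch as the mean, over urban edge
cells, of the Euclidean cell-center distance to the nearest natural-
habitat edge cell (computed with exact distance transforms; brute-force
oracles cross-check in tests).  The change between consecutive epochs is
reported as d_prev − d_curr, so a positive value means urban land moved
closer to habitat.  The sign convention follows the interpretation
"positive = increased proximity pressure"; units with no habitat of a
class yield flagged, undefined records.

### Biodiversity loss

Before conversion accounting, the land-systems map's urban layer is
replaced by the baseline urban mask: baseline-urban cells become the
urban system, cells coded urban in the input but not urban at baseline
become "unclassified" and are excluded from conversion accounting (the
fill class is otherwise unknowable, and exclusion cannot bias per-system
means).

Each land system is assigned one or more (land-use class, intensity)
pairs; its baseline loss is the unweighted mean of the assigned
coefficients.  The conversion change contrasts this with the urban
coefficient.  Two conventions are implemented because the phrasing "loss
difference" is ambiguous: the default ratio convention,
100·(V_u − V_s)/V_s with V = 1 + pct/100, expresses the change relative
to the source system's remaining biodiversity value; the difference
convention returns percentage points (urban − system).  Both agree when
the source is pristine (V_s = 1); a fully degraded source (V_s = 0) is
flagged undefined under the ratio convention.

Species loss per 10 km cell is the area-weighted mean conversion change
over the cell's converted 1 km cells times the cell's richness, clipped
at the richness (a cell cannot lose more species than it has).  The
default (`dilution="none"`) multiplies by the full cell richness even
when only part of the cell converts — faithful to the source estimator —
while `dilution="fractional"` additionally scales by the converted-area
fraction, because the default can assign large losses to barely-
converted cells.  Threatened and small-ranged layers reuse the same
relative-change map against their own richness grids (no separate
coefficients exist).  Abundance is reported as relative change only;
no absolute abundance surface is available to multiply against.

Priority zones are ranked by the sum of two within-zone descending ranks
(habitat-loss fraction, small-ranged species loss); the lowest rank sum
is the highest priority and ties break by zone id.  The exact published
criterion is not specified anywhere, so this deterministic rank-sum rule
is this package's documented choice.  Top-percentile selection keeps
cells at or above the (100−q)th percentile of the nonzero losses, ties
included.

## Synthetic worlds

The generator emulates the study's input stack with configurable
parameters and records ground truth for every product:

- **Land cover**: seeded region growing with largest-remainder exact
  class targets; default proportions 30% forest, 22% grassland, 22%
  cropland, 10% shrubland, 8% other, 5% wetland, 3% urban — a natural-
  habitat-dominated landscape with a small initial urban footprint.
  Mean patch diameter (`clustering`, default 6 cells) sets the seed
  density.
- **Urban expansion**: per epoch, candidate non-urban cells are drawn
  without replacement with weight = smooth development potential ×
  (1 + urban fraction in the 3×3 neighborhood) until the epoch's demand
  (in cells, to keep accounting exact) is met.  Weights never vanish, so
  leapfrog growth away from existing urban land can occur.  Default
  demand schedules give the five scenarios total 2015→2100 growth of
  54–111% of the baseline urban area, evenly spread over epochs —
  spanning the projected global range across the SSP narratives.
- **Land systems**: each cover class splits into 1–3 systems ("dense",
  "open", "mosaic" variants) along a smooth random field; the legend
  records the parent class.  Variants map to minimal/light/intense
  intensity in the default intensity mapping.
- **Richness**: smoothed Gaussian fields on the 10 km grid scaled to
  `richness_range` (default 50–400 species per cell) and rounded;
  threatened and small-ranged layers are fixed fractions (12% / 25%) of
  the total, so containment holds by construction.
- **Zones**: ecoregions and countries are Voronoi partitions of random
  seeds; biomes group ecoregions; protected areas are disjoint grown
  blobs hitting the target cover fraction (default 12%) exactly at cell
  resolution; a priority scheme marks a random third of the ecoregions.
- **Coefficients**: baseline row at 0; urban at −48% richness / −62%
  abundance (the high-loss conversions reported for vertebrate taxa);
  cropland markedly negative; natural classes mildly negative, scaling
  with intensity.

One global seed feeds fixed per-product substreams, so regenerating one
product never shifts another, and all outputs are bit-reproducible.

What the generator does *not* emulate: real spatial autocorrelation
structure of land cover (no coastlines, elevation or rivers), demand
feedbacks between scenarios and land markets, georeferenced projections
(the synthetic CRS is a flat equal-area plane; a cosine-latitude area
model exists for geographic grids), range-map geometry behind richness
fields, and PA gazetting practices.  Green tests therefore demonstrate
the correctness of the computational chain under known ground truth, not
the realism of any particular global projection.

## Numerical choices

- Cell areas: equal-area mode gives exactly (cell_size/1000)² km² per
  cell; cosine-latitude mode scales rows by cos(latitude).
- Distances are cell-center to cell-center, computed by exact Euclidean
  distance transforms; patch labeling uses standard connected-component
  labeling; both are verified against brute-force enumeration to 1e-9
  (exact for integer quantities) on grids up to 50×50.
- Gi* denominators ≤ 0 (complete neighborhoods on tiny fields) yield
  z = 0 rather than infinities; all-missing fields are a hard error.
- Aggregation ignores missing cells; an all-missing block is missing.
- CSV output uses a fixed float format so identical configurations
  reproduce byte-identical tables.

## Problem sizes

Tests run on worlds up to 300 × 300 cells (2 scenarios × 9 epochs, the
full-pipeline check) and fixtures ≤ 50 × 50 for oracle comparisons; the
reproduction script uses a 200 × 200 world with all five scenarios and
decadal epochs 2015–2100.  These sizes exercise every code path while
keeping a complete run in tens of seconds on one CPU; all stages scale
linearly in cell count except ENN_MN (near-linear via KD-trees) and the
synthetic allocator (linear with a small Python constant).

## Known limitations

- The distance-band "optimization" is a deterministic Moran's-I peak
  search over a candidate list, not a reimplementation of any
  proprietary tool; absolute hot-spot maps from such tools are not an
  equivalence surface.
- Fragmentation metrics cover MPS/ED/ENN_MN only (no core-area, shape,
  or dispersal-weighted connectivity metrics).
- The species-loss estimator inherits the source method's assumptions:
  static richness fields, coefficients independent of location, and no
  extinction-debt dynamics or species-level range tracking.
- Reprojection/warping and vector-polygon ingestion are out of scope;
  all inputs must arrive on one shared grid, with the 10 km richness
  grid nesting the 1 km grid by an integer factor.
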