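# Methods

## Data model and curation

A specimen record is a digitised voucher: id, sex, morph, morph group,
subspecies, country, verbatim locality, WGS84 coordinates and a geocode
error in km. Coordinates are either both present or both missing; a record
with only one coordinate is read as not geocoded (with a warning). Morphs
are female wing-pattern phenotypes in this system, so a morph on a male
record is a validation warning, not an error — century-old labels are
messy, and hard-failing on them would block whole datasets.

Only records with a geocode error **strictly below 40 km** enter spatial
analyses. The strict inequality matters at the boundary: a record at
exactly 40 km is excluded. The filter is idempotent and monotone in the
threshold, which the tests assert as properties.

The morph registry carries three lookup tables for *P. dardanus*: morph →
morph group, subspecies → recorded female morphs, and the set of
"imperfect" morphs (mixed or inaccurately mimetic forms: trimeni,
dorrippoides, dionysoides, proto-cenea, mixtoides, swynnertoni, carpenteri,
lamborni, plus the label `intermediate` for specimens spanning groups).
All keys are normalised (lower case, "f." prefix stripped). Group
membership for the common forms follows the classical similarity classes;
f. *leighi* sits in the *planemoides* group on breeding evidence, and the
rare Ethiopian tailed variants are filed with their tail-less
counterparts. Assignments for a handful of rare imperfect forms are not
fixed by any authoritative table and are plain registry data — override
the registry wholesale to use another taxonomy. One spelling in the
source material ("hippcoonides") is stored corrected as *hippocoonides*.

## Projection

All distances and areas are computed in an Albers equal-area conic plane.
The exact parameterisation of "Albers (Africa)" is a convention, not a
datum: central meridian 25° E, standard parallels 20° N and 23° S, latitude
of origin 0°, no false offsets — recorded in `crs_tag` and configurable.
The projection is evaluated on the authalic sphere (R = 6 371 007.181 m),
which makes it *exactly* area-preserving for spherical geometry; the tests
verify a 1°×1° cell's planar area against the spherical-excess formula to
0.5 %, and forward/inverse round-trips to 10⁻⁶ degree. Distances after
projection are planar Euclidean (the standard projected-GIS workflow), not
geodesic.

## Spatial statistics

**Weights.** Binary distance bands: w_ij = 1 iff 0 < d(i,j) ≤ band (closed
band). Moran's I uses w_ii = 0; Gi\* uses self-inclusive weights
(w_ii = 1). Coincident localities cannot arise (aggregation dedupes on
projected coordinates rounded to 1 m; the rounding only merges genuinely
identical geocodes), but coincident *points* are legal neighbours in the
weights builder.

**Moran's I** is computed with the analytical z-score under the
randomisation (permutation) assumption — the common GIS default — with the
normality variance available behind a flag:

- E[I] = −1/(n−1)
- Var_rand uses S₁ = ½ Σ(w_ij+w_ji)², S₂ = Σᵢ(Σⱼw_ij + Σⱼw_ji)², and the
  kurtosis term b₂ = n Σz⁴/(Σz²)².

The tests check the analytic z against a 999-shuffle permutation null
(agreement within 0.3) and the statistic itself against a naive double-loop
oracle to 10⁻¹⁰ relative error. All-equal values and empty weights are
errors ("zero variance", "empty weights"), not NaNs.

**Incremental band selection.** Moran's I is swept over ascending bands;
the best band maximises z (ties → smallest band). The default sweep runs
from the smallest band at which every locality has a neighbour (the
maximum nearest-neighbour distance) to half the maximum pairwise distance
in 10 equal steps; bands yielding no neighbour pairs are skipped with a
warning. The selected band is data-dependent output, never a constant.

**Gi\*.** For each locality, Gi\* compares the neighbourhood sum to its
expectation under exchangeability, normalised so the score is
standard-normal under the null. A locality whose neighbourhood is the
entire data set has a 0/0 score, reported as 0 with a warning. Labels are
a plain two-sided cut at ±2.5 sd; no multiple-testing correction is
applied (matching the classic GIS workflow), and an FDR-style correction
is deliberately not the default.

**Density and quantile classes.** Density is a circle count: the total
specimen count within 280 km of each locality (presence-only counting
behind a flag). Values are displayed in k = 7 equal-frequency classes by
rank, ties to the lower class, with each class's share of total density
reported.

**Pipeline composition and a calibration caveat.** The hot-spot pipeline
aggregates → sweeps Moran's I on per-locality specimen counts → builds the
density surface → scores it with Gi\* at the selected band. Feeding Gi\*
the *density layer* follows the classic sampling-effort workflow, but the
density field is spatially smoothed by construction, which violates the
exchangeability its null assumes: under complete spatial randomness the
labelled fraction is ~8–12 % rather than the nominal ≈0.6 %, at any band.
This is a property of the method, not of the implementation — Gi\* applied
to the raw per-site counts calibrates correctly (hot rate ≤ 3Φ(−2.5) over
500 CSR replicates in the acceptance suite), and the pipeline exposes
`gi_on="counts"` for null-faithful labelling. Hot-spot *detection* of real
clusters is unaffected: planted clusters are recovered with full
sensitivity and ≤5 % background hot rate under the default density mode.

## Range inference

Per taxon (morph group or subspecies) with ≥3 non-collinear localities:
convex hull (vertices counter-clockwise from the lowest-y, then lowest-x
vertex; degenerate taxa are skipped with a warning), then environmental
clipping. The class raster is block-downsampled to 20 km cells by majority
vote (ties → smallest class id; nodata ignored unless a block is all
nodata), the class under each occurrence is extracted with half-open cell
intervals ([x₀, x₀+cell) so a point on a shared edge belongs to the
greater cell), and the clipped range is the exact geometric intersection
of the hull with the union of occupied-class cells — no rasterised
approximation. Invariants: clipped ⊆ hull, every occurrence lies in the
clipped polygon, and clipping is idempotent. Subspecies labels must be
present in the input; inferring designations for unlabelled specimens from
nearby areas or characteristic forms is a curatorial act outside
algorithmic scope.

## Overlay

Containment is boundary-inclusive (a specimen on the range edge counts as
inside) — the conservative choice for a "collected within the extent"
claim. The union of the transitional subspecies' clipped ranges is formed
before testing, so a point in both ranges counts once. Specimens, not
unique localities, are the counting unit. The overlay itself reports
raw counts only; a label-shuffling permutation test is provided as a
clearly flagged extension beyond that.

## Synthetic data

The generator emulates exactly the features the analyses consume:

- **Clustered sampling effort.** Uniform background specimens (CSR) plus
  disc clusters of over-collecting. Cluster specimens are multinomially
  assigned to a smaller set of unique sites (~3 specimens per site on
  average), because the analysed attribute — specimens per locality — only
  varies if collectors revisit sites, as they did historically. Background
  specimens are singleton sites.
- **Regional morph compositions.** Each region (polygon + subspecies
  label) carries a morph frequency table; females draw a morph, males
  carry none (female fraction defaults to 0.464, the collection's ratio).
  Geocode errors are U[0, 60] km so the 40 km filter removes about a third.
- **The imperfect-mimic association.** A specimen whose drawn morph is
  imperfect targets the transitional polygon with probability 1 − ε and is
  relocated only when on the wrong side, making the planted
  inside-probability exactly 1 − ε (a clean binomial for the overlay
  check) while disturbing the clustered pattern minimally.
- **Class raster.** Each cell takes the class of the first listed class
  polygon covering its centre; nodata elsewhere.

All draws flow from one `numpy.random.Generator` seeded once — no global
state; identical seed+config reproduce records byte-for-byte through the
CLI.

**Reference scenario.** 7000×7000 km extent; three clusters of radius
150 km (planted clustering scale: 300 km diameter, the distance that first
captures all within-cluster pairs) with 400/350/300 specimens, separated
by 1600–3100 km inside a two-part transitional belt; 3500 background
specimens; five faunal regions (Western, Eastern, meseres, polytrophus,
island) with distinct morph tables; ε = 0.1 (echoing an observed ≈ 0.097
leakage); a five-class raster aligned with the regions. The geometry is
deliberate: cluster separation well above ~5× the cluster diameter keeps
incremental Moran's I from developing a competing z-peak at the
inter-cluster arrangement scale, and the background density places the
sweep's lowest band (the maximum nearest-neighbour distance, ~250–350 km)
near the planted scale so the sweep can resolve it. What passing tests on
this scenario do **not** show: real coastline geometry, gazetteer errors
beyond a scalar radius, non-uniform collecting along rivers/roads, or true
ecosystem class maps — the generator makes no attempt at those.

## Numerical and interface choices

- Locality deduplication rounds projected coordinates to 1 m.
- Quantile ties go to the lower class; block-majority ties to the smallest
  class id; hull vertex order is canonicalised — all for determinism.
- Raster I/O is the plain-text ESRI ASCII-grid dialect; polygons are
  emitted as WGS84 GeoJSON (densified before inverse projection so long
  edges stay faithful); tabulations and locality tables are CSV.
- CLI stages write a JSON manifest (config echo, versions, seed, in/out
  counts at each filter) sufficient to reproduce a run; reruns with the
  same seed and config are byte-identical, which the tests assert.
- Problem sizes in the shipped scenario (≈4.5k records, ≈2.6k localities)
  keep every analysis exact (no spatial indexing approximations) while the
  full suite runs in well under a minute.

## Known limitations

- The density-fed Gi\* label rate is anti-conservative under pure noise
  (see above); use `gi_on="counts"` when null calibration matters.
- Hulls are convex: ranges spanning concave coastlines over-cover before
  clipping, and clipping can only remove whole environmental classes.
- The projection is spherical-authalic; ellipsoidal-vs-spherical area
  differences (~0.1 %) are far below the 20 km raster granularity but
  would matter for precision cartography.
- Geocode error is treated as a scalar filter, not propagated into the
  statistics.
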