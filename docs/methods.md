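# Methods

## Scoring model

ToxPi scoring turns heterogeneous raw factors into dimensionless,
rank-preserving scores. For a model with slices $j=1..k$, each holding
components $c$, and records $i=1..n$:

1. **Component scaling.** Each raw column is min–max scaled across
   records: the minimum observed value maps to 0 and the maximum to 1.
   Inverted components are negated before scaling, so the raw minimum
   scores 1. Scores are therefore *relative to the observed cohort*:
   adding or removing records can change every score, and a record's
   score says nothing absolute about its raw value. Scaling is invariant
   under positive affine transforms of a raw column.
2. **Slice combination.** A slice score is the unweighted mean of its
   scaled components, min–max rescaled across records. The rescale makes
   every slice span $[0,1]$ regardless of how internally correlated its
   components are; the combiner is deliberately the simplest one that
   has this property.
3. **Overall score.** The slice-weighted sum, divided by its maximum.
   The arg-max record (all of them, under ties) scores exactly 1.

Degenerate-input policies, chosen to keep pipelines running on real,
messy tables and logged when they fire:

- a constant column (min = max) scores 0 everywhere — a factor with no
  variation carries no ranking information, and this avoids 0/0;
- a missing raw cell scores 0 after scaling ("no evidence of risk");
  an *entirely* missing column is an error naming the column;
- an all-zero weighted sum yields all-zero overall scores;
- with a single record, every column is constant, so all scores are 0.

Only linear and inverted-linear scaling are offered; log or custom
transforms should be applied upstream.

## Glyph geometry

Slices are laid out clockwise from north in model order, slice $j$
sweeping $2\pi w_j/\sum w$ radians (the last sweep absorbs float
rounding so the total is $2\pi$ exactly) and reaching radius
$R\,s_{ij}$ meters. The start-at-north, clockwise convention matches
the familiar desktop ToxPi rendering; it is a convention, not a
requirement of the method. Arcs are discretized on a global 5°-aligned
grid (so adjacent wedges share vertices and unions are clean); at 5°
steps polygon area is within 0.13 % of the exact circular sector, and
the step is configurable. Zero-score slices are kept as zero-area
degenerate polygons at the center so that every slice remains a
selectable feature with attributes. A full-circle sweep (single-slice
model) is drawn as a disk without the center vertex.

Metric drawing requires a projected CRS. Two projections are built in
with closed-form forward/inverse transforms: spherical Web Mercator
(EPSG:3857, the web-mapping default) and the CONUS Albers equal-area
conic on GRS80 (EPSG:5070, preferable for distance-band analysis because
it preserves area and keeps CONUS distances near-true; Mercator inflates
them by ~1/cos φ). Round-trip error is far below the 10⁻⁶-degree
contract. Input coordinates are geographic WGS84 unless a vector file
declares otherwise.

The default glyph radius is 2 % of the bounding-box diagonal of the
anchors (1 km fallback when all anchors coincide): large enough to read,
small enough that neighboring county-scale glyphs rarely swallow each
other. No automatic de-overlapping of neighboring glyphs is attempted.

## Layers and multi-scale output

The glyph layer carries a fixed attribute schema per wedge (id, label,
slice name/score/weight/color, overall score, dense rank, raw component
values as JSON) so map clients can configure popups without joins.
Boundary joins keep unmatched polygons with a null score (preserving the
basemap) and error only when *nothing* matches. Region aggregation takes
per-slice medians (even counts average the middle two), renormalizes the
weighted sums of the medians across regions, and anchors each region at
the mean of its member anchors; the median is robust to a few extreme
members, and renormalizing across regions keeps the coarse layer on the
same $[0,1]$ scale, though region overall scores are consequently *not*
comparable to the fine layer's. Coarse glyphs are drawn at 3×R. Since
open formats cannot encode scale-dependent rendering, fine and coarse
layers carry `zoom_min`/`zoom_max` scale-denominator hints
(0–2.5 M / 2.5 M–1 G) and the client decides what to show; choropleth
values are stored raw and unclassified for the same reason.

GeoJSON output is reprojected to WGS84 per RFC 7946 and round-trips
attributes exactly and vertices bit-for-bit (floats serialized with
repr); GeoPackage keeps the native projected CRS and holds several
layers per container; the Shapefile writer is a minimal polygon codec
that truncates attribute names to the format's 10-character limit with a
warning and is lossy on numeric precision by design.

## Hotspot analysis

Weights are binary within a Euclidean distance band in the projected
plane, with self-inclusion ($w_{ii}=1$, the defining feature of Gi\* as
opposed to Gi). The band is always explicit; 50 miles (80 467.2 m) is
the county-scale default. The z-score uses the randomization-consistent
variance, so under the null (values randomly permuted over locations) it
is approximately standard normal; a saturated neighborhood ($W_i=n$)
leaves the statistic undefined and is assigned z = 0 ("no local
deviation") rather than erroring, while a constant value field *is* an
error — spatial-randomness testing on a constant is meaningless.
Features whose only neighbor is themselves are flagged in the log.

p-values are two-sided normal; by default they are Benjamini–Hochberg
adjusted before binning (mirroring the behavior of "optimized" hotspot
tooling, whose exact internal corrections are not published — no claim
of equivalence is made; `use_fdr=False` gives the textbook statistic).
Bins: |bin| = 3, 2, 1 for effective p ≤ 0.01, 0.05, 0.10, sign from z.
Only Gi\* is implemented; Local Moran's I and kernel-weighted variants
are out of scope.

## Synthetic data

The generator emulates county-level composite-vulnerability inputs: a
10×10 lattice of half-degree cells (~44–56 km centroid spacing at CONUS
latitudes, so the 50-mile band yields queen-style neighborhoods of 9 for
interior cells — county-like spacing) anchored at (−105°, 33°); raw
components i.i.d. standard normal across records with a within-slice
latent factor giving pairwise correlation 0.5 (slices act as coherent
groups while columns stay distinguishable); optional planted clusters
add a mean shift in SD units to every component of chosen slices for a
block of cells, with the sign flipped for inverted components so the
cluster is always high-*risk* after scaling. The bundled 14-slice,
4-category model uses public pandemic-vulnerability slice vocabulary;
its weights (3 and 2 for the two infection-rate slices, 1 elsewhere) and
component lists are synthetic stand-ins, as the file itself notes.

What the generator does *not* emulate: real counties' irregular
geometry and area variation, spatially autocorrelated background fields,
heavy-tailed or ordinal components, and missingness patterns. Passing
tests therefore demonstrate correctness of the machinery and calibration
under idealized spatial nulls, not performance on any particular real
dataset. All randomness uses `numpy.random.default_rng` (PCG64);
identical seeds give byte-identical fixture files.

## Verification choices and problem sizes

The Gi\* implementation is checked elementwise (10⁻¹⁰) against an
independently written loop-based evaluation of the formula on 100+
random instances with n ≤ 30. Type-I calibration uses 500 permutation
replicates on the 100-cell lattice, asserting the |bin| ≥ 1 rate (FDR
off) within 3 binomial standard errors of the nominal 0.10; the normal
approximation at neighborhood size ~9 makes the empirical rate sit
slightly below nominal (~0.095). Cluster recovery runs the full
simulate→score→Gi\* pipeline for 100 seeds with a 3-SD 3×3 block and
requires bin +3 at the block interior (the one cell whose whole
neighborhood lies inside the block) in ≥ 90 % of runs. These sizes keep
the whole suite under ~10 s while leaving the stochastic assertions
well-powered.

## Known limitations

- Scores are cohort-relative; merging datasets changes scores.
- The projection registry is two CRSs; other EPSG codes are rejected
  rather than approximated.
- The Shapefile codec handles polygons only and is intentionally
  minimal; use GeoPackage or GeoJSON for lossless interchange.
- Normal-approximation p-values are anti-conservative for features with
  very few neighbors; widen the band or use FDR mode when neighborhoods
  are small.
- The pre-scored CSV dialect (`id,overall,<slices...>,lon,lat`) is this
  package's documented interchange format; other tools' exports may need
  a header rename.
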