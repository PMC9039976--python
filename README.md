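# toxpimap

Composite-index mapping without an ArcGIS license: **toxpimap** scores
multi-factor, location-tied data with the Toxicological Prioritization
Index (ToxPi), draws each record as an interactive-ready ToxPi profile —
a circular glyph of wedge-shaped slices — as plain GIS feature layers,
and classifies spatial clusters of high and low scores with the
Getis-Ord Gi\* hotspot statistic. It is aimed at environmental-health and
epidemiology groups who build county- or tract-level vulnerability
indices (a pandemic vulnerability index is the canonical example) and
want shareable, open-format map layers instead of proprietary toolboxes.

## The model

A **ToxPi model** declares ordered *slices*, each a named group of one or
more raw data *components* with an angular weight $w_j$ and a color.
Scoring compresses everything onto $[0,1]$:

- each component column is min–max scaled across records, so 0 is the
  minimum observed value and 1 the maximum; components flagged `invert`
  are negated first (for factors where *less* means *more* risk, e.g.
  hospital beds per capita);
- slice score $s_{ij}$ = the unweighted mean of record $i$'s scaled
  components in slice $j$, min–max rescaled across records so every slice
  spans $[0,1]$;
- overall score = $\sum_j w_j s_{ij}$, renormalized by its maximum, so the
  highest-scoring record is exactly 1.

Each record is drawn at its anchor coordinate (explicit lon/lat, or the
centroid of a joined boundary polygon) as one polygon per slice: slice
$j$ sweeps the angle $2\pi w_j/\sum w$ and extends to radius
$R\,s_{ij}$, so *longer slice means higher risk* and a more filled glyph
means higher overall vulnerability. Optional maximum-radius rings mark
the score-1 envelope.

For cluster detection, overall (or single-slice) scores feed the local
Gi\* statistic under binary distance-band weights $w_{ij}\in\{0,1\}$
(default band: 50 miles = 80 467.2 m, with self-inclusion):

$$z_i=\frac{\sum_j w_{ij}x_j-\bar X W_i}
{S\sqrt{\left[n W_i-W_i^2\right]/(n-1)}}$$

Two-sided normal p-values (Benjamini–Hochberg adjusted by default) place
every feature in one of **seven bins** `Gi_Bin` ∈ {−3…+3}: |bin| 3/2/1 at
the 99/95/90 % confidence levels, + for hotspots, − for coldspots, 0 not
significant.

## Worked example

Generate the bundled synthetic fixture — a 10×10 half-degree county-style
lattice scored with a 14-slice, 4-category model, with a 3×3 block of
cells shifted +3 SD — then draw layers and run hotspot analysis:

```sh
$ toxpimap synth --out-dir fixture --cluster 3x3 --shift 3
model: fixture/model.yaml
data: fixture/data.csv
lattice: fixture/lattice.geojson

$ toxpimap create --input fixture/data.csv --model fixture/model.yaml \
    --output map.gpkg --boundary fixture/lattice.geojson \
    --boundary-key key --boundary-label label --crs 5070 --rings \
    --scored-output scored.csv
glyph layer: 1400 features (100 records x 14 slices, R = 13751.5 m)
ring layer: 100 features
boundary layer: 100 features

$ toxpimap hotspot --input scored.csv --crs 5070 --output-csv hotspots.csv
100 features analysed; Gi_Bin counts -3:0 -2:0 -1:0 +0:91 +1:0 +2:3 +3:6
wrote hotspots.csv
```

The glyph layer holds one selectable wedge polygon per record and slice
(100 × 14 = 1400 features), each carrying its slice name, score, weight,
color, the record's overall score and rank, and the underlying raw
component values for popups; `R = 13751.5 m` is the adaptive glyph radius
(2 % of the anchor bounding-box diagonal). The hotspot run flags 9 cells
as significant hotspots (6 at the 99 % level, 3 at 95 %) — the planted
high-risk block and its edge — and no coldspots; per-feature z-scores,
p-values, and bins are in `hotspots.csv`.

A multi-scale bundle (fine glyphs + region-median coarse glyphs at 3×R +
matching choropleths, tagged with zoom hints) comes from
`toxpimap create-multiscale --region-field <column> ...`.

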