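"""Feature-layer assembly and vector output.

Turns a scored table into attributed GIS layers:

* ``glyph`` — one polygon per (record, slice) wedge, carrying the full
  popup attribute schema (id, label, slice name/score/weight/color, overall
  score, dense rank, and the slice's raw component values as JSON);
* ``ring`` — one maximum-radius circle per record (the score-1 envelope);
* ``boundary`` — joined boundary polygons labeled with overall scores;
* ``choropleth`` — boundary polygons shaded by an arbitrary per-key value;
* coarse variants (``glyph_coarse``, ``choropleth_coarse``) built from
  region-median aggregation for multi-scale maps, distinguished by
  ``zoom_min``/``zoom_max`` hint attributes (scale denominators; the map
  client decides which layer to display at a given zoom).

Layers write to GeoJSON (reprojected to WGS84 per RFC 7946), GeoPackage
(native projected CRS; several layers may share one container), or ESRI
Shapefile (field names truncated to 10 characters with a warning).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from . import _vecio, geometry
from .errors import DataIOError, ValidationError
from .model_io import BoundaryLayer, ScoredTable, ToxPiModel

logger = logging.getLogger(__name__)

ROLES = ("glyph", "ring", "boundary", "choropleth",
         "glyph_coarse", "choropleth_coarse")

#: Default zoom hints (map scale denominators) for fine vs coarse layers.
FINE_ZOOM = (0.0, 2.5e6)
COARSE_ZOOM = (2.5e6, 1.0e9)


@dataclass
class FeatureLayer:
    """Geometry + attributes with a layer role and CRS."""

    role: str
    features: list[tuple]  # (shapely geometry, attribute dict)
    crs: int
    zoom_hint: tuple[float, float] | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES and self.role != "generic":
            raise ValidationError(f"unknown layer role {self.role!r}")
        if self.name is None:
            self.name = self.role

    def __len__(self) -> int:
        return len(self.features)


def dense_ranks(overall: np.ndarray) -> np.ndarray:
    """Dense descending ranks: highest overall score gets rank 1; ties share."""
    uniq = np.unique(np.asarray(overall, dtype=float))[::-1]
    lookup = {v: i + 1 for i, v in enumerate(uniq)}
    return np.array([lookup[v] for v in overall], dtype=int)


def resolve_anchors(scored: ScoredTable, crs: int,
                    boundaries: BoundaryLayer | None = None) -> np.ndarray:
    """Projected (x, y) anchor per record.

    Explicit lon/lat wins; records with only a join key fall back to the
    centroid of the matching boundary polygon. Unresolvable records are an
    error listing the offending ids.
    """
    lon = np.array(scored.lon, dtype=float)
    lat = np.array(scored.lat, dtype=float)
    centroids = boundaries.centroid_lookup() if boundaries is not None else {}
    unresolved = []
    for i, rid in enumerate(scored.ids):
        if np.isnan(lon[i]) or np.isnan(lat[i]):
            key = scored.join_key[i]
            if key is not None and key in centroids:
                lon[i], lat[i] = centroids[key]
            else:
                unresolved.append(rid)
    if unresolved:
        raise ValidationError(
            f"records without resolvable anchor coordinates: {unresolved[:10]}"
            + (" ..." if len(unresolved) > 10 else ""))
    return geometry.project_points(np.column_stack([lon, lat]), crs)


def _labels(scored: ScoredTable, boundaries: BoundaryLayer | None) -> list[str]:
    if boundaries is None:
        return list(scored.ids)
    lab = dict(zip(boundaries.keys, boundaries.labels))
    return [lab.get(k, rid) if k is not None else rid
            for rid, k in zip(scored.ids, scored.join_key)]


def build_profile_layer(
    scored: ScoredTable,
    model: ToxPiModel,
    R: float | None = None,
    crs: int = 3857,
    arc_step: float = 5.0,
    boundaries: BoundaryLayer | None = None,
    zoom_hint: tuple[float, float] | None = None,
    role: str = "glyph",
) -> FeatureLayer:
    """One wedge polygon per (record, slice), fully attributed for popups.

    *R* defaults to 2% of the anchor bounding-box diagonal.
    """
    anchors = resolve_anchors(scored, crs, boundaries)
    if R is None:
        R = geometry.default_radius(anchors)
    ranks = dense_ranks(scored.overall)
    labels = _labels(scored, boundaries)
    features = []
    for i, rid in enumerate(scored.ids):
        wedges = geometry.profile_glyph(anchors[i], scored.slice_scores[i],
                                        scored.weights, R, arc_step)
        for j, (slc, wedge) in enumerate(zip(model.slices, wedges)):
            components = {}
            if scored.raw is not None:
                row = scored.raw.iloc[i]
                components = {c.column: (None if np.isnan(row[c.column])
                                         else float(row[c.column]))
                              for c in slc.components}
            attrs = {
                "id": rid,
                "label": labels[i],
                "slice_name": slc.name,
                "slice_score": float(scored.slice_scores[i, j]),
                "slice_weight": float(slc.weight),
                "slice_color": slc.color,
                "overall_score": float(scored.overall[i]),
                "rank": int(ranks[i]),
                "components": json.dumps(components),
            }
            if zoom_hint is not None:
                attrs["zoom_min"], attrs["zoom_max"] = zoom_hint
            features.append((wedge, attrs))
    return FeatureLayer(role=role, features=features, crs=crs,
                        zoom_hint=zoom_hint)


def build_rings_layer(
    scored: ScoredTable,
    R: float | None = None,
    crs: int = 3857,
    arc_step: float = 5.0,
    boundaries: BoundaryLayer | None = None,
) -> FeatureLayer:
    """One maximum-radius ring per record, marking the score-1 envelope."""
    anchors = resolve_anchors(scored, crs, boundaries)
    if R is None:
        R = geometry.default_radius(anchors)
    features = [
        (geometry.ring_polygon(anchors[i], R, arc_step),
         {"id": rid, "overall_score": float(scored.overall[i]),
          "radius_m": float(R)})
        for i, rid in enumerate(scored.ids)
    ]
    return FeatureLayer(role="ring", features=features, crs=crs)


def build_boundary_layer(boundaries: BoundaryLayer,
                         scored: ScoredTable,
                         crs: int | None = None) -> FeatureLayer:
    """Boundary polygons labeled and joined (by key) to overall scores.

    Unmatched boundaries are kept with a null score (logged) so the basemap
    stays continuous; zero matches is an error (likely a wrong key field).
    """
    by_key = {k: float(o) for k, o in zip(scored.join_key, scored.overall)
              if k is not None}
    by_key.update({rid: float(o) for rid, o in zip(scored.ids, scored.overall)
                   if rid not in by_key})
    out_crs = crs if crs is not None else boundaries.crs
    features, matched = [], 0
    for key, label, geom in zip(boundaries.keys, boundaries.labels,
                                boundaries.geometries):
        score = by_key.get(key)
        matched += score is not None
        if score is None:
            logger.warning("boundary %r has no scored record; score null", key)
        features.append((
            geometry.transform_geometry(geom, boundaries.crs, out_crs),
            {"join_key": key, "label": label, "overall_score": score}))
    if matched == 0:
        raise ValidationError(
            "no boundary keys match any scored record; check the key field")
    return FeatureLayer(role="boundary", features=features, crs=out_crs)


def make_choropleth(
    boundaries: BoundaryLayer,
    values: dict[str, float],
    value_name: str,
    crs: int | None = None,
    zoom_hint: tuple[float, float] | None = None,
    role: str = "choropleth",
) -> FeatureLayer:
    """Boundary polygons attributed with a per-key value (raw, unclassified).

    Classification/symbolization is the map client's job; the raw value is
    stored under *value_name*.
    """
    if not values:
        raise ValidationError("empty values map for choropleth")
    out_crs = crs if crs is not None else boundaries.crs
    features, matched = [], 0
    for key, label, geom in zip(boundaries.keys, boundaries.labels,
                                boundaries.geometries):
        val = values.get(key)
        matched += val is not None
        attrs = {"join_key": key, "label": label,
                 value_name: None if val is None else float(val)}
        if zoom_hint is not None:
            attrs["zoom_min"], attrs["zoom_max"] = zoom_hint
        features.append((
            geometry.transform_geometry(geom, boundaries.crs, out_crs), attrs))
    if matched == 0:
        raise ValidationError(
            f"no boundary keys match the {value_name!r} values map")
    return FeatureLayer(role=role, features=features, crs=out_crs,
                        zoom_hint=zoom_hint)


def aggregate_regions(scored: ScoredTable,
                      region_of: dict[str, str]) -> ScoredTable:
    """Collapse records into one record per region by slice-score medians.

    Per region and slice the median of member slice scores is taken (even
    counts average the middle two); region overall scores are the weighted
    sums of the medians renormalized across regions; the region anchor is
    the centroid (mean) of member anchors.
    """
    from .scoring import overall_scores

    if not region_of:
        raise ValidationError("empty region mapping")
    missing = [rid for rid in scored.ids if rid not in region_of]
    if missing:
        raise ValidationError(f"records without a region: {missing[:10]}")
    regions = list(dict.fromkeys(region_of[rid] for rid in scored.ids))
    idx = {r: [] for r in regions}
    for i, rid in enumerate(scored.ids):
        idx[region_of[rid]].append(i)
    med = np.vstack([np.median(scored.slice_scores[idx[r]], axis=0)
                     for r in regions])
    lon = np.array([np.nanmean(scored.lon[idx[r]]) for r in regions])
    lat = np.array([np.nanmean(scored.lat[idx[r]]) for r in regions])
    return ScoredTable(
        ids=regions,
        slice_names=list(scored.slice_names),
        slice_scores=med,
        overall=overall_scores(med, scored.weights),
        weights=scored.weights.copy(),
        lon=lon,
        lat=lat,
        join_key=list(regions),
    )


def dissolve_boundaries(boundaries: BoundaryLayer,
                        region_of: dict[str, str]) -> BoundaryLayer:
    """Union member polygons into one polygon per region."""
    import shapely

    groups: dict[str, list] = {}
    for key, geom in zip(boundaries.keys, boundaries.geometries):
        region = region_of.get(key)
        if region is not None:
            groups.setdefault(region, []).append(geom)
    if not groups:
        raise ValidationError("region mapping matches no boundary keys")
    keys = list(groups)
    return BoundaryLayer(
        keys=keys,
        labels=keys,
        geometries=[shapely.union_all(groups[k]) for k in keys],
        crs=boundaries.crs,
    )


# ---------------------------------------------------------------------------
# Vector output
# ---------------------------------------------------------------------------


def write_layer(layer: FeatureLayer, path: str | os.PathLike,
                fmt: str | None = None, layer_name: str | None = None) -> None:
    """Write a layer to GeoJSON, GeoPackage, or Shapefile.

    GeoJSON output is reprojected to WGS84 (RFC 7946); GeoPackage keeps the
    native projected CRS and supports multiple layers per container file.
    """
    fmt = fmt or _vecio.infer_format(path)
    name = layer_name or layer.name or layer.role
    if fmt == "GeoJSON":
        feats = [(geometry.transform_geometry(g, layer.crs, 4326), a)
                 for g, a in layer.features]
        _vecio.write_geojson(feats, path, crs=4326,
                             extra_top={"name": name})
    elif fmt == "GeoPackage":
        _vecio.write_gpkg(layer.features, path, name, layer.crs)
    elif fmt == "Shapefile":
        _vecio.write_shapefile(layer.features, path, layer.crs)
    else:
        raise ValidationError(f"unsupported output format {fmt!r}")
    logger.info("wrote %d %s feature(s) to %s", len(layer), layer.role, path)


def read_layer(path: str | os.PathLike, layer_name: str | None = None,
               role: str = "generic") -> FeatureLayer:
    """Read any supported vector file back into a FeatureLayer."""
    features, crs = _vecio.read_vector(path, layer_name)
    if not features:
        raise DataIOError(f"no features in {path}")
    return FeatureLayer(role=role, features=features, crs=crs,
                        name=layer_name)


def build_multiscale(
    scored: ScoredTable,
    model: ToxPiModel,
    region_of: dict[str, str],
    boundaries: BoundaryLayer | None = None,
    R: float | None = None,
    crs: int = 3857,
    arc_step: float = 5.0,
) -> list[FeatureLayer]:
    """The multi-scale bundle: fine glyphs + region-median coarse glyphs,
    plus fine/coarse choropleths when boundary polygons are available.

    Coarse glyphs are drawn at 3x the fine radius and tagged with coarse
    zoom hints so a map client can switch layers by zoom extent.
    """
    anchors = resolve_anchors(scored, crs, boundaries)
    if R is None:
        R = geometry.default_radius(anchors)
    regional = aggregate_regions(scored, region_of)
    out = [
        build_profile_layer(scored, model, R, crs, arc_step, boundaries,
                            zoom_hint=FINE_ZOOM, role="glyph"),
        build_profile_layer(regional, model, 3 * R, crs, arc_step,
                            zoom_hint=COARSE_ZOOM, role="glyph_coarse"),
    ]
    if boundaries is not None:
        fine_vals = {k: float(o) for k, o in zip(scored.join_key, scored.overall)
                     if k is not None}
        if not fine_vals:
            fine_vals = dict(zip(scored.ids, map(float, scored.overall)))
        out.append(make_choropleth(boundaries, fine_vals, "overall_score",
                                   crs=crs, zoom_hint=FINE_ZOOM))
        coarse = dissolve_boundaries(boundaries, region_of_keys(
            region_of, scored))
        coarse_vals = dict(zip(regional.ids, map(float, regional.overall)))
        out.append(make_choropleth(coarse, coarse_vals, "overall_score",
                                   crs=crs, zoom_hint=COARSE_ZOOM,
                                   role="choropleth_coarse"))
    return out


def region_of_keys(region_of: dict[str, str],
                   scored: ScoredTable) -> dict[str, str]:
    """Remap an id->region mapping onto boundary join keys."""
    out = {}
    for rid, key in zip(scored.ids, scored.join_key):
        if key is not None and rid in region_of:
            out[key] = region_of[rid]
    return out or dict(region_of)
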