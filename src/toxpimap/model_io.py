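"""Shared data model and file parsers.

This module defines the in-memory containers used throughout the package —
the declarative ToxPi model (slices of weighted, optionally inverted
components), raw per-location source tables, pre-scored result tables, and
boundary polygon layers — together with the readers and writers for their
on-disk dialects.

Model configurations are YAML::

    name: My model
    slices:
      - name: Infection Rate
        weight: 2.0
        color: "#8b0000"
        category: Infection     # optional color-family grouping
        components:
          - column: cases_per_capita
          - column: pct_vaccinated
            invert: true

Data tables are delimited text (comma or tab, sniffed) with a header row.
Each record needs a unique ``id`` and either explicit ``lon``/``lat``
coordinates (geographic WGS84) or a ``join_key`` into a boundary polygon
layer. Empty cells and the sentinels ``NA``/``NaN`` (case-insensitive) are
treated as missing.

The scored-table dialect is a CSV with header
``id,overall,<slice names...>,lon,lat``; every score lies in [0, 1].
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from shapely.geometry.base import BaseGeometry

from .errors import DataIOError, ValidationError

_MISSING_SENTINELS = {"", "na", "nan"}

# ---------------------------------------------------------------------------
# Model types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Component:
    """One raw data column feeding a slice.

    ``invert=True`` flips the scaling direction so that low raw values map
    to high scores — used for factors where less is riskier (e.g. hospital
    beds per capita).
    """

    column: str
    invert: bool = False

    def __post_init__(self) -> None:
        if not self.column:
            raise ValidationError("component column name must be non-empty")


@dataclass(frozen=True)
class Slice:
    """A named group of components with an angular weight and a color."""

    name: str
    weight: float
    color: str
    components: tuple[Component, ...]
    category: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("slice name must be non-empty")
        if not (isinstance(self.weight, (int, float)) and math.isfinite(self.weight)
                and self.weight > 0):
            raise ValidationError(f"slice {self.name!r}: weight must be > 0, got {self.weight!r}")
        if len(self.components) == 0:
            raise ValidationError(f"slice {self.name!r}: needs at least one component")
        cols = [c.column for c in self.components]
        if len(set(cols)) != len(cols):
            raise ValidationError(f"slice {self.name!r}: duplicate component columns")


@dataclass(frozen=True)
class ToxPiModel:
    """Ordered collection of slices; the declarative scoring model."""

    name: str
    slices: tuple[Slice, ...]

    def __post_init__(self) -> None:
        if len(self.slices) == 0:
            raise ValidationError("model must declare at least one slice")
        names = [s.name for s in self.slices]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValidationError(f"duplicate slice names: {sorted(dupes)}")

    @property
    def slice_names(self) -> list[str]:
        return [s.name for s in self.slices]

    @property
    def weights(self) -> np.ndarray:
        return np.array([s.weight for s in self.slices], dtype=float)

    @property
    def categories(self) -> list[str]:
        """Distinct slice categories (color families), in first-seen order."""
        seen: list[str] = []
        for s in self.slices:
            cat = s.category if s.category is not None else s.name
            if cat not in seen:
                seen.append(cat)
        return seen

    @property
    def component_columns(self) -> list[str]:
        out: list[str] = []
        for s in self.slices:
            out.extend(c.column for c in s.components)
        return out


@dataclass
class SourceTable:
    """Raw per-location records keyed by a unique id.

    ``raw`` holds the numeric component columns (NaN = missing); ``extras``
    keeps any additional non-component columns (e.g. a region field) so
    downstream steps can use them.
    """

    ids: list[str]
    lon: np.ndarray
    lat: np.ndarray
    join_key: list[str | None]
    raw: pd.DataFrame
    extras: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        n = len(self.ids)
        if len(set(self.ids)) != n:
            seen, dupes = set(), set()
            for i in self.ids:
                (dupes if i in seen else seen).add(i)
            raise ValidationError(f"duplicate record ids: {sorted(dupes)}")
        if not (len(self.lon) == len(self.lat) == len(self.join_key) == len(self.raw) == n):
            raise ValidationError("SourceTable fields have inconsistent lengths")
        has_coord = ~(np.isnan(self.lon) | np.isnan(self.lat))
        has_key = np.array([k is not None for k in self.join_key])
        bad = ~(has_coord | has_key)
        if bad.any():
            missing = [self.ids[i] for i in np.flatnonzero(bad)]
            raise ValidationError(
                f"records without lon/lat or join_key: {missing[:10]}")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class ScoredTable:
    """Per-record slice scores and overall score, all in [0, 1].

    ``raw`` optionally carries the source component columns so that map
    layers can expose underlying values in feature popups.
    """

    ids: list[str]
    slice_names: list[str]
    slice_scores: np.ndarray  # n_records x n_slices
    overall: np.ndarray
    weights: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    join_key: list[str | None] = field(default_factory=list)
    raw: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.slice_scores = np.asarray(self.slice_scores, dtype=float)
        self.overall = np.asarray(self.overall, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not self.join_key:
            self.join_key = [None] * len(self.ids)
        n, k = self.slice_scores.shape
        if n != len(self.ids) or k != len(self.slice_names):
            raise ValidationError("slice_scores shape does not match ids/slice_names")
        for name, arr in (("slice", self.slice_scores), ("overall", self.overall)):
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
                raise ValidationError(f"{name} scores outside [0, 1]")

    def __len__(self) -> int:
        return len(self.ids)

    def slice_column(self, name: str) -> np.ndarray:
        try:
            j = self.slice_names.index(name)
        except ValueError:
            raise ValidationError(
                f"unknown slice {name!r}; known: {self.slice_names}") from None
        return self.slice_scores[:, j]


@dataclass
class BoundaryLayer:
    """Polygon features keyed for joining to data records."""

    keys: list[str]
    labels: list[str]
    geometries: list[BaseGeometry]
    crs: int = 4326  # EPSG code of the stored coordinates

    def __post_init__(self) -> None:
        if len(set(self.keys)) != len(self.keys):
            raise ValidationError("duplicate boundary join keys")
        for k, g in zip(self.keys, self.geometries):
            if g.geom_type not in ("Polygon", "MultiPolygon"):
                raise ValidationError(f"boundary {k!r}: geometry is {g.geom_type}, "
                                      "expected Polygon/MultiPolygon")
            if not g.is_valid:
                raise ValidationError(f"boundary {k!r}: invalid polygon geometry")

    def __len__(self) -> int:
        return len(self.keys)

    def centroid_lookup(self) -> dict[str, tuple[float, float]]:
        return {k: (g.centroid.x, g.centroid.y)
                for k, g in zip(self.keys, self.geometries)}


# ---------------------------------------------------------------------------
# Model config I/O
# ---------------------------------------------------------------------------


def parse_model_config(path: str | os.PathLike) -> ToxPiModel:
    """Read a YAML model configuration into a validated :class:`ToxPiModel`.

    Slice order is preserved as written. Raises :class:`ValidationError`
    naming the offending slice for duplicate names, non-positive weights, or
    empty component lists; :class:`DataIOError` for a missing file.
    """
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    except OSError as exc:
        raise DataIOError(f"cannot read model config {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise ValidationError(f"malformed model config {path}: {exc}") from exc
    if not isinstance(doc, dict) or "slices" not in doc:
        raise ValidationError(f"model config {path} must map 'name' and 'slices'")
    slices = []
    for i, raw in enumerate(doc["slices"]):
        if not isinstance(raw, dict):
            raise ValidationError(f"slice #{i + 1}: expected a mapping")
        name = str(raw.get("name", "")).strip()
        if not name:
            raise ValidationError(f"slice #{i + 1}: missing name")
        try:
            weight = float(raw.get("weight", 1.0))
        except (TypeError, ValueError):
            raise ValidationError(f"slice {name!r}: non-numeric weight") from None
        comps = tuple(
            Component(column=str(c["column"]), invert=bool(c.get("invert", False)))
            for c in raw.get("components", []) or []
        )
        slices.append(Slice(
            name=name,
            weight=weight,
            color=str(raw.get("color", "#808080")),
            components=comps,
            category=raw.get("category"),
        ))
    return ToxPiModel(name=str(doc.get("name", "unnamed")), slices=tuple(slices))


def write_model_config(model: ToxPiModel, path: str | os.PathLike) -> None:
    """Serialize a model back to the YAML dialect read by parse_model_config."""
    doc = {
        "name": model.name,
        "slices": [
            {
                "name": s.name,
                "weight": float(s.weight),
                "color": s.color,
                **({"category": s.category} if s.category is not None else {}),
                "components": [
                    {"column": c.column, **({"invert": True} if c.invert else {})}
                    for c in s.components
                ],
            }
            for s in model.slices
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


# ---------------------------------------------------------------------------
# Data table I/O
# ---------------------------------------------------------------------------


def _read_delimited(path: str | os.PathLike) -> pd.DataFrame:
    if not os.path.exists(path):
        raise DataIOError(f"input file not found: {path}")
    try:
        return pd.read_csv(path, sep=None, engine="python", dtype=str,
                           keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error variety
        raise DataIOError(f"cannot parse delimited file {path}: {exc}") from exc


def _numeric(series: pd.Series, column: str) -> np.ndarray:
    """Parse a string column to float; sentinels -> NaN; junk -> error."""
    stripped = series.str.strip()
    sentinel = stripped.str.lower().isin(_MISSING_SENTINELS)
    # python float() rather than pandas' fast parser: exact round-trip of
    # %.17g output is part of the dialect contract
    out = np.full(len(stripped), np.nan)
    bad = []
    for i, (cell, is_na) in enumerate(zip(stripped, sentinel)):
        if is_na:
            continue
        try:
            out[i] = float(cell)
        except ValueError:
            bad.append(cell)
    if bad:
        raise ValidationError(
            f"column {column!r}: non-numeric values {bad[:3]} "
            "(use empty/NA/NaN for missing)")
    return out


def parse_data_table(
    path: str | os.PathLike,
    model: ToxPiModel,
    *,
    id_field: str = "id",
    lon_field: str = "lon",
    lat_field: str = "lat",
    join_field: str = "join_key",
) -> SourceTable:
    """Read a raw delimited data table and validate it against *model*.

    Every component column of the model must be present; missing values are
    kept as NaN (the scoring step maps them to 0 and logs the count). No row
    is ever silently dropped.
    """
    df = _read_delimited(path)
    if id_field not in df.columns:
        raise ValidationError(f"missing required id column {id_field!r}")
    missing = [c for c in model.component_columns if c not in df.columns]
    if missing:
        raise ValidationError(f"data table missing model columns: {missing}")

    ids = df[id_field].str.strip().tolist()
    n = len(ids)
    lon = (_numeric(df[lon_field], lon_field) if lon_field in df.columns
           else np.full(n, np.nan))
    lat = (_numeric(df[lat_field], lat_field) if lat_field in df.columns
           else np.full(n, np.nan))
    if join_field in df.columns:
        jk = [k.strip() or None for k in df[join_field]]
    else:
        jk = [None] * n

    comp_cols = list(dict.fromkeys(model.component_columns))
    raw = pd.DataFrame({c: _numeric(df[c], c) for c in comp_cols}, index=ids)
    reserved = set(comp_cols) | {id_field, lon_field, lat_field, join_field}
    extras = df[[c for c in df.columns if c not in reserved]].copy()
    extras.index = pd.Index(ids)
    return SourceTable(ids=ids, lon=lon, lat=lat, join_key=jk, raw=raw,
                       extras=extras)


# ---------------------------------------------------------------------------
# Scored table dialect
# ---------------------------------------------------------------------------

_SCORED_FIXED = ("id", "overall", "lon", "lat")


def parse_scored_table(path: str | os.PathLike) -> ScoredTable:
    """Read the scored-table CSV dialect (id, overall, slices..., lon, lat).

    Column matching is by header name, order-free; any column that is not
    ``id``/``overall``/``lon``/``lat`` is taken to be a slice score. Scores
    outside [0, 1] are rejected.
    """
    df = _read_delimited(path)
    missing = [c for c in ("id", "overall") if c not in df.columns]
    if missing:
        raise ValidationError(f"scored table missing columns: {missing}")
    slice_names = [c for c in df.columns if c not in _SCORED_FIXED]
    if not slice_names:
        raise ValidationError("scored table has no slice-score columns")

    ids = df["id"].str.strip().tolist()
    overall = _numeric(df["overall"], "overall")
    scores = np.column_stack([_numeric(df[c], c) for c in slice_names])
    for label, arr in (("overall", overall), ("slice score", scores)):
        if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
            raise ValidationError(f"{label} outside [0, 1] in {path}")
    n = len(ids)
    lon = _numeric(df["lon"], "lon") if "lon" in df.columns else np.full(n, np.nan)
    lat = _numeric(df["lat"], "lat") if "lat" in df.columns else np.full(n, np.nan)
    return ScoredTable(ids=ids, slice_names=slice_names, slice_scores=scores,
                       overall=overall, weights=np.ones(len(slice_names)),
                       lon=lon, lat=lat)


def write_scored_table(scored: ScoredTable, path: str | os.PathLike) -> None:
    """Write the scored-table CSV dialect: ``id,overall,<slices...>,lon,lat``."""
    df = pd.DataFrame({"id": scored.ids, "overall": scored.overall})
    for j, name in enumerate(scored.slice_names):
        df[name] = scored.slice_scores[:, j]
    df["lon"] = scored.lon
    df["lat"] = scored.lat
    # %.17g round-trips IEEE doubles exactly, so parse(write(x)) == x
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Boundary layers
# ---------------------------------------------------------------------------


def read_boundaries(
    path: str | os.PathLike,
    key_field: str,
    label_field: str | None = None,
) -> BoundaryLayer:
    """Read a polygon vector file (GeoJSON/GeoPackage/Shapefile) as boundaries.

    *key_field* must be a unique attribute; *label_field* defaults to the key.
    Slightly invalid polygons are repaired with a zero-width buffer; anything
    unrepairable is rejected.
    """
    from ._vecio import read_vector  # deferred: avoids import cycle

    features, crs = read_vector(path)
    if not features:
        raise DataIOError(f"no features found in {path}")
    keys, labels, geoms = [], [], []
    for geom, attrs in features:
        if key_field not in attrs:
            raise ValidationError(
                f"key field {key_field!r} absent from {path} attributes "
                f"(available: {sorted(attrs)})")
        if not geom.is_valid:
            geom = geom.buffer(0)
        keys.append(str(attrs[key_field]))
        labels.append(str(attrs.get(label_field, attrs[key_field]))
                      if label_field else str(attrs[key_field]))
        geoms.append(geom)
    return BoundaryLayer(keys=keys, labels=labels, geometries=geoms,
                         crs=crs or 4326)
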