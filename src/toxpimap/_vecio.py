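"""Lightweight vector-file backend: GeoJSON, GeoPackage, ESRI Shapefile.

Features are ``(shapely geometry, attribute dict)`` pairs. GeoJSON goes
through ``json`` + ``shapely``; GeoPackage is written/read directly with
``sqlite3`` following the OGC table layout and geometry-blob header;
Shapefile support is a minimal polygon codec (.shp/.shx/.dbf/.prj) with the
format's 10-character field-name limit enforced by truncation + warning.

Attribute fidelity: GeoJSON and GeoPackage round-trip attribute values
exactly (strings, ints, floats, None); Shapefile stringifies per dBASE
rules and is therefore lossy by design.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
import os
import sqlite3
import struct
import warnings

import numpy as np
import shapely
import shapely.wkb
from shapely.geometry import mapping, shape
from shapely.geometry.polygon import orient

from .errors import DataIOError, ValidationError

Feature = tuple  # (geometry, dict)

_WKT = {
    4326: 'GEOGCS["WGS 84",DATUM["WGS_1984",SPHEROID["WGS 84",6378137,298.257223563]],'
          'PRIMEM["Greenwich",0],UNIT["degree",0.0174532925199433],'
          'AUTHORITY["EPSG","4326"]]',
    3857: 'PROJCS["WGS 84 / Pseudo-Mercator",GEOGCS["WGS 84",DATUM["WGS_1984",'
          'SPHEROID["WGS 84",6378137,298.257223563]],PRIMEM["Greenwich",0],'
          'UNIT["degree",0.0174532925199433]],PROJECTION["Mercator_1SP"],'
          'PARAMETER["central_meridian",0],PARAMETER["scale_factor",1],'
          'PARAMETER["false_easting",0],PARAMETER["false_northing",0],'
          'UNIT["metre",1],AUTHORITY["EPSG","3857"]]',
    5070: 'PROJCS["NAD83 / Conus Albers",GEOGCS["NAD83",DATUM["North_American_Datum_1983",'
          'SPHEROID["GRS 1980",6378137,298.257222101]],PRIMEM["Greenwich",0],'
          'UNIT["degree",0.0174532925199433]],PROJECTION["Albers_Conic_Equal_Area"],'
          'PARAMETER["latitude_of_center",23],PARAMETER["longitude_of_center",-96],'
          'PARAMETER["standard_parallel_1",29.5],PARAMETER["standard_parallel_2",45.5],'
          'PARAMETER["false_easting",0],PARAMETER["false_northing",0],'
          'UNIT["metre",1],AUTHORITY["EPSG","5070"]]',
}


def _pyval(v):
    """Coerce numpy scalars to plain python for serialization."""
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.bool_):
        return bool(v)
    return v


def infer_format(path: str | os.PathLike) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    table = {".geojson": "GeoJSON", ".json": "GeoJSON",
             ".gpkg": "GeoPackage", ".shp": "Shapefile"}
    if ext not in table:
        raise ValidationError(
            f"cannot infer vector format from extension {ext!r} "
            "(use .geojson/.json, .gpkg, or .shp)")
    return table[ext]


# ---------------------------------------------------------------------------
# GeoJSON
# ---------------------------------------------------------------------------


def write_geojson(features: list[Feature], path, crs: int = 4326,
                  extra_top: dict | None = None) -> None:
    """Write a FeatureCollection. Per RFC 7946 coordinates should be WGS84;
    callers reproject before handing features here."""
    doc = {
        "type": "FeatureCollection",
        **(extra_top or {}),
        "features": [
            {"type": "Feature", "geometry": mapping(geom),
             "properties": {k: _pyval(v) for k, v in attrs.items()}}
            for geom, attrs in features
        ],
    }
    if crs != 4326:  # non-standard but preserves information
        doc["crs"] = {"type": "name",
                      "properties": {"name": f"urn:ogc:def:crs:EPSG::{crs}"}}
    try:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)
    except OSError as exc:
        raise DataIOError(f"cannot write {path}: {exc}") from exc


def read_geojson(path) -> tuple[list[Feature], int]:
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except OSError as exc:
        raise DataIOError(f"cannot read {path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise DataIOError(f"{path} is not valid GeoJSON: {exc}") from exc
    crs = 4326
    if isinstance(doc.get("crs"), dict):
        name = doc["crs"].get("properties", {}).get("name", "")
        digits = "".join(ch for ch in name.rsplit(":", 1)[-1] if ch.isdigit())
        if digits:
            crs = int(digits)
    feats = doc.get("features", [])
    return [(shape(f["geometry"]), dict(f.get("properties") or {}))
            for f in feats], crs


# ---------------------------------------------------------------------------
# GeoPackage (sqlite3)
# ---------------------------------------------------------------------------

_GPKG_BASE = """
CREATE TABLE IF NOT EXISTS gpkg_spatial_ref_sys (
  srs_name TEXT NOT NULL, srs_id INTEGER PRIMARY KEY,
  organization TEXT NOT NULL, organization_coordsys_id INTEGER NOT NULL,
  definition TEXT NOT NULL, description TEXT);
CREATE TABLE IF NOT EXISTS gpkg_contents (
  table_name TEXT PRIMARY KEY, data_type TEXT NOT NULL,
  identifier TEXT UNIQUE, description TEXT DEFAULT '',
  last_change DATETIME, min_x DOUBLE, min_y DOUBLE,
  max_x DOUBLE, max_y DOUBLE, srs_id INTEGER);
CREATE TABLE IF NOT EXISTS gpkg_geometry_columns (
  table_name TEXT UNIQUE NOT NULL, column_name TEXT NOT NULL,
  geometry_type_name TEXT NOT NULL, srs_id INTEGER NOT NULL,
  z TINYINT NOT NULL, m TINYINT NOT NULL,
  PRIMARY KEY (table_name, column_name));
"""


def _gpkg_blob(geom, srs_id: int) -> bytes:
    minx, miny, maxx, maxy = geom.bounds
    header = (b"GP" + bytes([0, 0b00000011])  # version 0, little endian, XY env
              + struct.pack("<i", srs_id)
              + struct.pack("<4d", minx, maxx, miny, maxy))
    return header + shapely.wkb.dumps(geom, byte_order=1)


def _gpkg_parse_blob(blob: bytes):
    if blob is None:
        return None
    if blob[:2] != b"GP":
        raise DataIOError("not a GeoPackage geometry blob")
    flags = blob[3]
    env = (flags >> 1) & 0x07
    env_len = {0: 0, 1: 32, 2: 48, 3: 48, 4: 64}.get(env)
    if env_len is None:
        raise DataIOError(f"invalid GeoPackage envelope indicator {env}")
    return shapely.wkb.loads(blob[8 + env_len:])


def _sql_ident(name: str) -> str:
    safe = "".join(ch if ch.isalnum() or ch == "_" else "_" for ch in name)
    return safe or "layer"


def _ensure_gpkg(con: sqlite3.Connection) -> None:
    con.execute("PRAGMA application_id = 1196444487")  # 'GPKG'
    con.execute("PRAGMA user_version = 10200")
    con.executescript(_GPKG_BASE)
    rows = [(-1, "Undefined cartesian SRS", "NONE", -1, "undefined"),
            (0, "Undefined geographic SRS", "NONE", 0, "undefined")]
    rows += [(code, f"EPSG:{code}", "EPSG", code, _WKT[code]) for code in _WKT]
    con.executemany(
        "INSERT OR IGNORE INTO gpkg_spatial_ref_sys "
        "(srs_id, srs_name, organization, organization_coordsys_id, definition)"
        " VALUES (?,?,?,?,?)", rows)


def write_gpkg(features: list[Feature], path, layer_name: str,
               crs: int) -> None:
    """Write (or append) one feature table into a GeoPackage container."""
    table = _sql_ident(layer_name)
    attrs0 = features[0][1] if features else {}
    cols, coltypes = [], []
    for key, val in attrs0.items():
        val = _pyval(val)
        sqltype = ("INTEGER" if isinstance(val, bool) or isinstance(val, int)
                   else "REAL" if isinstance(val, float) else "TEXT")
        cols.append(key)
        coltypes.append(sqltype)
    try:
        con = sqlite3.connect(path)
    except sqlite3.Error as exc:
        raise DataIOError(f"cannot open GeoPackage {path}: {exc}") from exc
    try:
        with con:
            _ensure_gpkg(con)
            con.execute(f'DROP TABLE IF EXISTS "{table}"')
            coldefs = "".join(f', "{_sql_ident(c)}" {t}'
                              for c, t in zip(cols, coltypes))
            con.execute(f'CREATE TABLE "{table}" '
                        f"(fid INTEGER PRIMARY KEY AUTOINCREMENT, "
                        f"geom BLOB{coldefs})")
            geom_type = (features[0][0].geom_type.upper() if features
                         else "GEOMETRY")
            placeholders = ",".join("?" * (1 + len(cols)))
            con.executemany(
                f'INSERT INTO "{table}" (geom'
                + "".join(f', "{_sql_ident(c)}"' for c in cols)
                + f") VALUES ({placeholders})",
                [( _gpkg_blob(geom, crs),
                   *[_pyval(attrs.get(c)) for c in cols])
                 for geom, attrs in features])
            bounds = shapely.total_bounds(
                [g for g, _ in features]) if features else (None,) * 4
            now = _dt.datetime.now(_dt.timezone.utc).strftime(
                "%Y-%m-%dT%H:%M:%SZ")
            con.execute("INSERT OR REPLACE INTO gpkg_contents "
                        "(table_name, data_type, identifier, last_change, "
                        " min_x, min_y, max_x, max_y, srs_id) "
                        "VALUES (?,?,?,?,?,?,?,?,?)",
                        (table, "features", table, now, *map(_pyval, bounds),
                         crs))
            con.execute("INSERT OR REPLACE INTO gpkg_geometry_columns "
                        "VALUES (?,?,?,?,0,0)",
                        (table, "geom", geom_type, crs))
    finally:
        con.close()


def list_gpkg_layers(path) -> list[str]:
    con = sqlite3.connect(path)
    try:
        rows = con.execute(
            "SELECT table_name FROM gpkg_contents "
            "WHERE data_type = 'features'").fetchall()
    except sqlite3.Error as exc:
        raise DataIOError(f"{path} is not a GeoPackage: {exc}") from exc
    finally:
        con.close()
    return [r[0] for r in rows]


def read_gpkg(path, layer_name: str | None = None) -> tuple[list[Feature], int]:
    if not os.path.exists(path):
        raise DataIOError(f"file not found: {path}")
    layers = list_gpkg_layers(path)
    if not layers:
        raise DataIOError(f"no feature layers in {path}")
    if layer_name is None:
        layer_name = layers[0]
    if layer_name not in layers:
        raise DataIOError(f"layer {layer_name!r} not in {path}; has {layers}")
    con = sqlite3.connect(path)
    con.row_factory = sqlite3.Row
    try:
        srs = con.execute("SELECT srs_id FROM gpkg_contents WHERE table_name=?",
                          (layer_name,)).fetchone()[0]
        feats = []
        for row in con.execute(f'SELECT * FROM "{layer_name}"'):
            attrs = {k: row[k] for k in row.keys() if k not in ("fid", "geom")}
            feats.append((_gpkg_parse_blob(row["geom"]), attrs))
    finally:
        con.close()
    return feats, int(srs)


# ---------------------------------------------------------------------------
# ESRI Shapefile (minimal polygon codec)
# ---------------------------------------------------------------------------


def _shp_rings(geom) -> list[list[tuple[float, float]]]:
    """Rings in shapefile convention: exterior clockwise, holes CCW."""
    polys = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
    rings = []
    for poly in polys:
        poly = orient(poly, sign=-1.0)  # CW exterior, CCW holes
        rings.append(list(poly.exterior.coords))
        rings.extend(list(r.coords) for r in poly.interiors)
    return rings


def write_shapefile(features: list[Feature], path, crs: int) -> None:
    """Write polygon features as .shp/.shx/.dbf (+ .prj when CRS is known).

    Attribute names longer than 10 characters are truncated with a warning
    (dBASE limit); values are written as text (C) or numeric (N) fields.
    """
    if not features:
        raise ValidationError("cannot write an empty shapefile")
    base, _ = os.path.splitext(str(path))
    attrs0 = {k: _pyval(v) for k, v in features[0][1].items()}

    fields = []  # (orig, name10, type, length, decimals)
    used = set()
    for key, val in attrs0.items():
        name = key[:10]
        if len(key) > 10:
            warnings.warn(
                f"shapefile field name {key!r} truncated to {name!r} "
                "(dBASE 10-character limit)", UserWarning, stacklevel=2)
        while name in used:  # disambiguate collisions after truncation
            name = (name[:9] + str(len(used) % 10))
        used.add(name)
        if isinstance(val, bool) or isinstance(val, int):
            fields.append((key, name, "N", 18, 0))
        elif isinstance(val, float):
            fields.append((key, name, "N", 24, 10))
        else:
            fields.append((key, name, "C", 100, 0))

    # --- geometry records
    records = []
    for geom, _ in features:
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise ValidationError(
                f"shapefile writer supports polygons only, got {geom.geom_type}")
        rings = _shp_rings(geom)
        pts = [pt for ring in rings for pt in ring]
        parts, offset = [], 0
        for ring in rings:
            parts.append(offset)
            offset += len(ring)
        xs = [p[0] for p in pts]
        ys = [p[1] for p in pts]
        content = struct.pack("<i4d", 5, min(xs), min(ys), max(xs), max(ys))
        content += struct.pack("<2i", len(parts), len(pts))
        content += struct.pack(f"<{len(parts)}i", *parts)
        content += b"".join(struct.pack("<2d", x, y) for x, y in pts)
        records.append(content)

    all_bounds = shapely.total_bounds([g for g, _ in features])
    header_bbox = struct.pack("<4d", *all_bounds) + struct.pack("<4d", 0, 0, 0, 0)

    shp_len = 100 + sum(8 + len(c) for c in records)
    with open(base + ".shp", "wb") as fh:
        fh.write(struct.pack(">7i", 9994, 0, 0, 0, 0, 0, shp_len // 2))
        fh.write(struct.pack("<2i", 1000, 5))
        fh.write(header_bbox)
        for i, content in enumerate(records, start=1):
            fh.write(struct.pack(">2i", i, len(content) // 2))
            fh.write(content)

    with open(base + ".shx", "wb") as fh:
        shx_len = 100 + 8 * len(records)
        fh.write(struct.pack(">7i", 9994, 0, 0, 0, 0, 0, shx_len // 2))
        fh.write(struct.pack("<2i", 1000, 5))
        fh.write(header_bbox)
        offset = 100
        for content in records:
            fh.write(struct.pack(">2i", offset // 2, len(content) // 2))
            offset += 8 + len(content)

    rec_size = 1 + sum(f[3] for f in fields)
    with open(base + ".dbf", "wb") as fh:
        today = _dt.date.today()
        header_size = 32 + 32 * len(fields) + 1
        fh.write(struct.pack("<4B i 2H 20x", 3, today.year - 1900, today.month,
                             today.day, len(features), header_size, rec_size))
        for _, name, ftype, length, dec in fields:
            fh.write(struct.pack("<11s c 4x BB 14x", name.encode("ascii"),
                                 ftype.encode("ascii"), length, dec))
        fh.write(b"\x0d")
        for _, attrs in features:
            fh.write(b" ")
            for key, _, ftype, length, dec in fields:
                val = _pyval(attrs.get(key))
                if ftype == "N":
                    if val is None or (isinstance(val, float) and math.isnan(val)):
                        text = " " * length
                    elif dec:
                        text = f"{float(val):{length}.{dec}f}"[:length].rjust(length)
                    else:
                        text = str(int(val)).rjust(length)
                else:
                    text = ("" if val is None else str(val))[:length].ljust(length)
                fh.write(text.encode("utf-8", "replace")[:length].ljust(length))
        fh.write(b"\x1a")

    if crs in _WKT:
        with open(base + ".prj", "w", encoding="ascii") as fh:
            fh.write(_WKT[crs])


def _read_dbf(path) -> list[dict]:
    with open(path, "rb") as fh:
        buf = fh.read()
    n_rec, header_size, rec_size = struct.unpack_from("<i 2H", buf, 4)
    fields = []
    pos = 32
    while buf[pos] != 0x0D:
        name = buf[pos:pos + 11].split(b"\x00")[0].decode("ascii")
        ftype = chr(buf[pos + 11])
        length = buf[pos + 16]
        dec = buf[pos + 17]
        fields.append((name, ftype, length, dec))
        pos += 32
    out = []
    pos = header_size
    for _ in range(n_rec):
        rec = buf[pos:pos + rec_size]
        pos += rec_size
        attrs, off = {}, 1
        for name, ftype, length, dec in fields:
            cell = rec[off:off + length].decode("utf-8", "replace").strip()
            off += length
            if ftype == "N":
                attrs[name] = (None if not cell
                               else float(cell) if dec or "." in cell
                               else int(cell))
            else:
                attrs[name] = cell
        out.append(attrs)
    return out


def read_shapefile(path) -> tuple[list[Feature], int]:
    base, _ = os.path.splitext(str(path))
    if not os.path.exists(base + ".shp"):
        raise DataIOError(f"file not found: {base}.shp")
    with open(base + ".shp", "rb") as fh:
        buf = fh.read()
    if struct.unpack_from(">i", buf, 0)[0] != 9994:
        raise DataIOError(f"{path} is not a shapefile")
    geoms = []
    pos = 100
    while pos < len(buf):
        (_, words) = struct.unpack_from(">2i", buf, pos)
        pos += 8
        shape_type = struct.unpack_from("<i", buf, pos)[0]
        if shape_type == 5:
            n_parts, n_pts = struct.unpack_from("<2i", buf, pos + 36)
            parts = list(struct.unpack_from(f"<{n_parts}i", buf, pos + 44))
            coords_off = pos + 44 + 4 * n_parts
            flat = struct.unpack_from(f"<{2 * n_pts}d", buf, coords_off)
            pts = list(zip(flat[0::2], flat[1::2]))
            rings = [pts[a:b] for a, b in zip(parts, parts[1:] + [n_pts])]
            geoms.append(_assemble_polygon(rings))
        elif shape_type == 0:
            geoms.append(None)
        else:
            raise DataIOError(
                f"shapefile reader supports polygon type 5 only, got {shape_type}")
        pos += 2 * words
    attrs = _read_dbf(base + ".dbf") if os.path.exists(base + ".dbf") else [{}] * len(geoms)
    crs = 4326
    if os.path.exists(base + ".prj"):
        with open(base + ".prj", "r", encoding="ascii", errors="replace") as fh:
            wkt = fh.read()
        for code, canned in _WKT.items():
            if f'"{code}"' in wkt or wkt.strip() == canned:
                crs = code
    return list(zip(geoms, attrs)), crs


def _assemble_polygon(rings):
    from shapely.geometry import MultiPolygon, Polygon

    def signed_area(ring):
        x = np.array([p[0] for p in ring])
        y = np.array([p[1] for p in ring])
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    shells = [r for r in rings if signed_area(r) <= 0]  # CW = exterior
    holes = [r for r in rings if signed_area(r) > 0]
    if not shells:  # degenerate; treat every ring as a shell
        shells, holes = rings, []
    polys = []
    for shell in shells:
        shell_poly = Polygon(shell)
        mine = [h for h in holes
                if shell_poly.contains(Polygon(h).representative_point())]
        polys.append(Polygon(shell, mine))
    return polys[0] if len(polys) == 1 else MultiPolygon(polys)


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------


def read_vector(path, layer_name: str | None = None) -> tuple[list[Feature], int]:
    """Read any supported vector file; returns (features, EPSG code)."""
    fmt = infer_format(path)
    if not os.path.exists(str(path)):
        raise DataIOError(f"file not found: {path}")
    if fmt == "GeoJSON":
        return read_geojson(path)
    if fmt == "GeoPackage":
        return read_gpkg(path, layer_name)
    return read_shapefile(path)
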