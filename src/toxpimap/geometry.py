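"""Glyph geometry: map projections, angular layout, wedge and ring polygons.

A ToxPi profile is drawn at a record's anchor coordinate as a fan of wedge
("slice") polygons. Slice *j* spans the angle ``2*pi*w_j / sum(w)`` (its
weight share of the circle) and extends to radius ``R * s_j`` where ``s_j``
is the slice score in [0, 1] and ``R`` the glyph radius in meters. Slices
start at north (12 o'clock) and proceed clockwise in model order. Arcs are
discretized at ``arc_step`` degrees (default 5, keeping polygon areas within
0.2% of the exact circular sector).

Metric geometry requires a projected CRS; a small built-in registry provides
spherical Web Mercator (EPSG:3857, the default) and the CONUS Albers
equal-area conic on GRS80 (EPSG:5070), both with closed-form forward and
inverse transforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon

from .errors import ValidationError

TAU = 2.0 * math.pi

# ---------------------------------------------------------------------------
# Projections
# ---------------------------------------------------------------------------

_A_WGS84 = 6378137.0  # semi-major axis shared by WGS84 and GRS80 (meters)


def _merc_fwd(lon: np.ndarray, lat: np.ndarray):
    x = _A_WGS84 * np.radians(lon)
    y = _A_WGS84 * np.log(np.tan(np.pi / 4 + np.radians(lat) / 2))
    return x, y


def _merc_inv(x: np.ndarray, y: np.ndarray):
    lon = np.degrees(x / _A_WGS84)
    lat = np.degrees(2 * np.arctan(np.exp(y / _A_WGS84)) - np.pi / 2)
    return lon, lat


class _Albers:
    """Ellipsoidal Albers equal-area conic (Snyder's closed forms)."""

    def __init__(self, lat1: float, lat2: float, lat0: float, lon0: float,
                 a: float = _A_WGS84, inv_f: float = 298.257222101):
        f = 1.0 / inv_f
        self.a = a
        self.e2 = f * (2 - f)
        self.e = math.sqrt(self.e2)
        self.lon0 = math.radians(lon0)
        p1, p2, p0 = (math.radians(v) for v in (lat1, lat2, lat0))
        m1, m2 = self._m(p1), self._m(p2)
        q1, q2 = self._q(np.array(p1)), self._q(np.array(p2))
        self.n = (m1 ** 2 - m2 ** 2) / (q2 - q1)
        self.C = m1 ** 2 + self.n * q1
        self.rho0 = self._rho(self._q(np.array(p0)))

    def _m(self, phi: float) -> float:
        s = math.sin(phi)
        return math.cos(phi) / math.sqrt(1 - self.e2 * s * s)

    def _q(self, phi: np.ndarray) -> np.ndarray:
        s = np.sin(phi)
        e = self.e
        return (1 - self.e2) * (s / (1 - self.e2 * s * s)
                                - np.log((1 - e * s) / (1 + e * s)) / (2 * e))

    def _rho(self, q: np.ndarray) -> np.ndarray:
        return self.a * np.sqrt(self.C - self.n * q) / self.n

    def fwd(self, lon: np.ndarray, lat: np.ndarray):
        lam = np.radians(lon)
        rho = self._rho(self._q(np.radians(lat)))
        theta = self.n * (lam - self.lon0)
        return rho * np.sin(theta), self.rho0 - rho * np.cos(theta)

    def inv(self, x: np.ndarray, y: np.ndarray):
        dy = self.rho0 - np.asarray(y, dtype=float)
        rho = np.hypot(x, dy)
        theta = np.arctan2(np.asarray(x, dtype=float) * np.sign(self.n),
                           dy * np.sign(self.n))
        q = (self.C - (rho * self.n / self.a) ** 2) / self.n
        lam = self.lon0 + theta / self.n
        phi = np.arcsin(np.clip(q / 2, -1, 1))
        for _ in range(8):  # Newton-type fixed point; converges in ~3 steps
            s = np.sin(phi)
            one = 1 - self.e2 * s * s
            corr = (one ** 2 / (2 * np.cos(phi))) * (
                q / (1 - self.e2) - s / one
                + np.log((1 - self.e * s) / (1 + self.e * s)) / (2 * self.e))
            phi = phi + corr
        return np.degrees(lam), np.degrees(phi)


_CONUS_ALBERS = _Albers(lat1=29.5, lat2=45.5, lat0=23.0, lon0=-96.0)

#: EPSG code -> (forward, inverse) lon/lat <-> x/y transforms (meter units).
PROJECTIONS = {
    3857: (_merc_fwd, _merc_inv),
    5070: (_CONUS_ALBERS.fwd, _CONUS_ALBERS.inv),
}


def project_points(lonlat, crs: int = 3857) -> np.ndarray:
    """Project geographic (lon, lat) degree pairs to plane coordinates.

    *crs* is an EPSG code from the built-in registry (3857 Web Mercator,
    5070 CONUS Albers). Returns an (n, 2) float array of meters.
    """
    if crs not in PROJECTIONS:
        raise ValidationError(
            f"unknown projected CRS EPSG:{crs}; supported: "
            f"{sorted(PROJECTIONS)}")
    arr = np.atleast_2d(np.asarray(lonlat, dtype=float))
    lon, lat = arr[:, 0], arr[:, 1]
    if not np.isfinite(arr).all():
        raise ValidationError("non-finite lon/lat passed to project_points")
    if (np.abs(lat) >= 89.9999).any() and crs == 3857:
        raise ValidationError("latitude out of Web Mercator domain")
    x, y = PROJECTIONS[crs][0](lon, lat)
    return np.column_stack([x, y])


def unproject_points(xy, crs: int = 3857) -> np.ndarray:
    """Inverse of :func:`project_points`: plane meters back to (lon, lat)."""
    if crs not in PROJECTIONS:
        raise ValidationError(f"unknown projected CRS EPSG:{crs}")
    arr = np.atleast_2d(np.asarray(xy, dtype=float))
    lon, lat = PROJECTIONS[crs][1](arr[:, 0], arr[:, 1])
    return np.column_stack([lon, lat])


def transform_geometry(geom, crs_from: int, crs_to: int):
    """Reproject a shapely geometry between registry CRSs (4326 = geographic)."""
    if crs_from == crs_to:
        return geom

    def _shift(coords: np.ndarray) -> np.ndarray:
        pts = coords if crs_from == 4326 else unproject_points(coords, crs_from)
        return pts if crs_to == 4326 else project_points(pts, crs_to)

    return shapely.transform(geom, _shift)


# ---------------------------------------------------------------------------
# Angular layout
# ---------------------------------------------------------------------------


def layout_angles(weights) -> list[tuple[float, float]]:
    """Partition the circle among slices proportionally to their weights.

    Returns ``(start_angle, sweep)`` radian pairs, measured clockwise from
    north, laid out consecutively in input order. The final sweep absorbs
    floating-point rounding so the sweeps sum to exactly ``2*pi``.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValidationError("layout_angles: empty weight vector")
    if not np.isfinite(w).all() or (w <= 0).any():
        raise ValidationError("layout_angles: weights must be positive finite")
    sweeps = TAU * w / w.sum()
    sweeps[-1] = TAU - sweeps[:-1].sum()
    starts = np.concatenate([[0.0], np.cumsum(sweeps)[:-1]])
    return list(zip(starts.tolist(), sweeps.tolist()))


@dataclass(frozen=True)
class WedgeSpec:
    """One slice wedge: center (projected meters), angles (radians), radius."""

    center: tuple[float, float]
    start_angle: float
    sweep: float
    radius: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in self.center):
            raise ValidationError("wedge center must be finite")
        if not 0 < self.sweep <= TAU + 1e-12:
            raise ValidationError(f"sweep must be in (0, 2*pi], got {self.sweep}")
        if self.radius < 0:
            raise ValidationError("wedge radius must be >= 0")


def _dir(angle: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # clockwise-from-north: 0 -> +y (north), pi/2 -> +x (east)
    return np.sin(angle), np.cos(angle)


def _arc_angles(start: float, end: float, step_rad: float) -> np.ndarray:
    """Angles from start to end on the global step grid, endpoints included."""
    eps = 1e-9 * step_rad
    k0 = math.floor(start / step_rad) + 1
    k1 = math.ceil(end / step_rad) - 1
    grid = [k * step_rad for k in range(k0, k1 + 1)
            if start + eps < k * step_rad < end - eps]
    return np.array([start, *grid, end])


def wedge_polygon(spec: WedgeSpec, arc_step: float = 5.0) -> Polygon:
    """Build the closed polygon for one wedge.

    The shell runs center -> arc (at <= *arc_step* degree increments, grid
    aligned so adjacent wedges share vertices) -> back to center. A radius
    of zero yields a degenerate zero-area polygon at the center, kept so
    every slice remains a selectable feature. A full ``2*pi`` sweep yields
    a disk without the center vertex.
    """
    if arc_step <= 0:
        raise ValidationError("arc_step must be > 0 degrees")
    step = math.radians(arc_step)
    cx, cy = spec.center
    if spec.radius == 0:
        return Polygon([(cx, cy)] * 4)
    if spec.sweep >= TAU - 1e-12:
        return ring_polygon(spec.center, spec.radius, arc_step)
    ang = _arc_angles(spec.start_angle, spec.start_angle + spec.sweep, step)
    dx, dy = _dir(ang)
    xs = np.concatenate([[cx], cx + spec.radius * dx, [cx]])
    ys = np.concatenate([[cy], cy + spec.radius * dy, [cy]])
    return Polygon(zip(xs, ys))


def ring_polygon(center, R: float, arc_step: float = 5.0) -> Polygon:
    """Circle of radius *R* marking the score = 1 envelope of a glyph."""
    if R <= 0:
        raise ValidationError("ring radius must be > 0")
    if arc_step <= 0:
        raise ValidationError("arc_step must be > 0 degrees")
    step = math.radians(arc_step)
    ang = np.arange(0.0, TAU - 1e-9 * step, step)
    dx, dy = _dir(ang)
    cx, cy = center
    return Polygon(zip(cx + R * dx, cy + R * dy))


def profile_glyph(center, slice_scores, weights, R: float,
                  arc_step: float = 5.0) -> list[Polygon]:
    """All wedge polygons for one record's ToxPi profile.

    Wedge *j* gets radius ``R * slice_scores[j]`` and the angular span given
    by :func:`layout_angles`. Wedges only touch along shared edges — their
    interiors never overlap — so each is independently selectable on a map.
    """
    s = np.asarray(slice_scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if s.shape != w.shape:
        raise ValidationError(
            f"scores ({s.shape}) and weights ({w.shape}) differ in length")
    if np.nanmin(s) < -1e-12 or np.nanmax(s) > 1 + 1e-12:
        raise ValidationError("slice scores must lie in [0, 1]")
    if R <= 0:
        raise ValidationError("glyph radius R must be > 0")
    return [
        wedge_polygon(WedgeSpec(tuple(center), start, sweep, R * float(si)),
                      arc_step)
        for (start, sweep), si in zip(layout_angles(w), np.nan_to_num(s))
    ]


def default_radius(anchors_xy) -> float:
    """Adaptive glyph radius: 2% of the anchor bounding-box diagonal.

    Keeps unattended runs legible across data extents; falls back to 1 km
    when all anchors coincide (zero diagonal).
    """
    xy = np.atleast_2d(np.asarray(anchors_xy, dtype=float))
    span = xy.max(axis=0) - xy.min(axis=0)
    diag = float(np.hypot(*span))
    return 0.02 * diag if diag > 0 else 1000.0
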