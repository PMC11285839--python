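"""Spherical geodesy for strait-scale trajectory analysis.

All coordinates are WGS84 decimal degrees, west longitudes negative.
Distances use a spherical earth of radius 6 371 000 m; over the < 50 km
scales of a sea strait the spherical error is below 0.5 %, far smaller
than any quantity the analysis depends on.

Nearest-point searches against a coastline polyline run in an azimuthal
equidistant tangent plane centred on the query point: radial distances from
the query point are exact great-circle distances, and in-plane segment
interpolation is sub-metre at these scales.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import shape
from shapely.geometry.base import BaseGeometry

from .errors import InputError, UndefinedBearingError

EARTH_RADIUS_M = 6_371_000.0


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 position: longitude (degrees east), latitude (degrees north)."""

    lon: float
    lat: float

    def __post_init__(self):
        if not (math.isfinite(self.lon) and math.isfinite(self.lat)):
            raise InputError(f"non-finite coordinate: ({self.lon}, {self.lat})")
        if not (-180.0 <= self.lon <= 180.0 and -90.0 <= self.lat <= 90.0):
            raise InputError(f"coordinate out of range: ({self.lon}, {self.lat})")


@dataclass
class Coastline:
    """An ordered, open polyline of shore vertices.

    Offshore islands are excluded by construction: callers supply
    island-free polylines.
    """

    name: str
    lons: np.ndarray
    lats: np.ndarray

    def __post_init__(self):
        self.lons = np.asarray(self.lons, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        if self.lons.shape != self.lats.shape or self.lons.ndim != 1:
            raise InputError("coastline lons/lats must be equal-length 1-d arrays")
        if self.lons.size < 2:
            raise InputError(f"coastline {self.name!r} needs >= 2 vertices")
        same = (np.diff(self.lons) == 0) & (np.diff(self.lats) == 0)
        if same.any():
            raise InputError(f"coastline {self.name!r} has repeated consecutive vertices")

    @property
    def vertices(self) -> list[GeoPoint]:
        return [GeoPoint(lo, la) for lo, la in zip(self.lons, self.lats)]

    @classmethod
    def from_points(cls, name: str, points) -> "Coastline":
        pts = list(points)
        return cls(name, np.array([p.lon for p in pts]), np.array([p.lat for p in pts]))


# ---------------------------------------------------------------------------
# great-circle primitives
# ---------------------------------------------------------------------------

def _check_finite(*vals):
    for v in vals:
        if not np.all(np.isfinite(v)):
            raise InputError("non-finite coordinate")


def haversine_distance(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance in metres between two points."""
    return float(haversine_arrays(a.lon, a.lat, b.lon, b.lat))


def haversine_arrays(lon1, lat1, lon2, lat2):
    """Vectorised haversine distance (metres); inputs in degrees."""
    _check_finite(lon1, lat1, lon2, lat2)
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def initial_bearing(a: GeoPoint, b: GeoPoint) -> float:
    """Initial great-circle bearing a→b, degrees clockwise from true north in [0, 360)."""
    if a.lon == b.lon and a.lat == b.lat:
        raise UndefinedBearingError("bearing between coincident points is undefined")
    return float(bearing_arrays(a.lon, a.lat, b.lon, b.lat))


def bearing_arrays(lon1, lat1, lon2, lat2):
    """Vectorised initial bearing (degrees in [0, 360)); coincident pairs give nan."""
    _check_finite(lon1, lat1, lon2, lat2)
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    brg = np.degrees(np.arctan2(y, x)) % 360.0
    same = (y == 0) & (x == 0)
    return np.where(same, np.nan, brg)


def destination_point(p: GeoPoint, bearing_deg: float, distance_m: float) -> GeoPoint:
    """Point reached travelling `distance_m` along the great circle at `bearing_deg`."""
    if distance_m == 0.0:
        return p
    lat1 = math.radians(p.lat)
    lon1 = math.radians(p.lon)
    brg = math.radians(bearing_deg)
    delta = distance_m / EARTH_RADIUS_M
    lat2 = math.asin(math.sin(lat1) * math.cos(delta) + math.cos(lat1) * math.sin(delta) * math.cos(brg))
    lon2 = lon1 + math.atan2(
        math.sin(brg) * math.sin(delta) * math.cos(lat1),
        math.cos(delta) - math.sin(lat1) * math.sin(lat2),
    )
    lon2 = (math.degrees(lon2) + 540.0) % 360.0 - 180.0
    return GeoPoint(lon2, math.degrees(lat2))


# ---------------------------------------------------------------------------
# nearest point on a coastline
# ---------------------------------------------------------------------------

def nearest_points_batch(lons, lats, coast: Coastline):
    """Nearest point on `coast` for many query points at once.

    For each query point, project every coastline vertex into the azimuthal
    equidistant plane centred on that point, find the closest point over all
    polyline segments, and return (bearing to it, distance to it) arrays.
    """
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    # distances/bearings from each query point to each vertex: (M, V)
    d = haversine_arrays(lons[:, None], lats[:, None], coast.lons[None, :], coast.lats[None, :])
    th = np.radians(
        bearing_arrays(lons[:, None], lats[:, None], coast.lons[None, :], coast.lats[None, :])
    )
    th = np.where(np.isnan(th), 0.0, th)  # coincident vertex: direction irrelevant at d=0
    x = d * np.sin(th)
    y = d * np.cos(th)
    ax, ay = x[:, :-1], y[:, :-1]
    sx, sy = np.diff(x, axis=1), np.diff(y, axis=1)
    seg2 = sx * sx + sy * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.clip(-(ax * sx + ay * sy) / seg2, 0.0, 1.0)
    t = np.where(seg2 > 0, t, 0.0)
    qx = ax + t * sx
    qy = ay + t * sy
    dist = np.hypot(qx, qy)
    best = np.argmin(dist, axis=1)
    rows = np.arange(lons.size)
    bx, by = qx[rows, best], qy[rows, best]
    best_dist = dist[rows, best]
    brg = np.degrees(np.arctan2(bx, by)) % 360.0
    brg = np.where(best_dist > 0, brg, np.nan)
    return brg, best_dist


def nearest_point_on_coastline(p: GeoPoint, c: Coastline) -> tuple[GeoPoint, float]:
    """The point on the coastline polyline closest to `p`, and its distance in metres."""
    brg, dist = nearest_points_batch([p.lon], [p.lat], c)
    d = float(dist[0])
    if d == 0.0:
        return p, 0.0
    return destination_point(p, float(brg[0]), d), d


def within_buffer(p: GeoPoint, c: Coastline, radius_m: float) -> bool:
    """True iff `p` lies strictly closer than `radius_m` to the coastline."""
    if radius_m <= 0:
        raise InputError("buffer radius must be positive")
    _, d = nearest_point_on_coastline(p, c)
    return d < radius_m


# ---------------------------------------------------------------------------
# GeoJSON I/O
# ---------------------------------------------------------------------------

def read_coastlines_geojson(path) -> dict[str, Coastline]:
    """Read LineString features into Coastlines keyed by their "name" property."""
    with open(path) as fh:
        doc = json.load(fh)
    out: dict[str, Coastline] = {}
    for feat in doc.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") != "LineString":
            continue
        name = feat.get("properties", {}).get("name", f"coastline_{len(out)}")
        coords = np.asarray(geom["coordinates"], dtype=float)
        out[name] = Coastline(name, coords[:, 0], coords[:, 1])
    if not out:
        raise InputError(f"no LineString features found in {path}")
    return out


def read_geofence_geojson(path) -> BaseGeometry:
    """Read the first Polygon feature as a shapely geometry (lon/lat coordinates)."""
    with open(path) as fh:
        doc = json.load(fh)
    for feat in doc.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") in ("Polygon", "MultiPolygon"):
            return shape(geom)
    raise InputError(f"no Polygon feature found in {path}")


def bbox_polygon(lon_min: float, lon_max: float, lat_min: float, lat_max: float) -> BaseGeometry:
    """Axis-aligned geofence rectangle in lon/lat."""
    from shapely.geometry import box

    return box(lon_min, lat_min, lon_max, lat_max)


def coastlines_to_geojson(coastlines, geofence: BaseGeometry | None = None) -> dict:
    """Serialise Coastlines (and optionally the geofence polygon) to a FeatureCollection."""
    feats = []
    for c in coastlines:
        feats.append(
            {
                "type": "Feature",
                "properties": {"name": c.name},
                "geometry": {
                    "type": "LineString",
                    "coordinates": [[float(lo), float(la)] for lo, la in zip(c.lons, c.lats)],
                },
            }
        )
    if geofence is not None:
        feats.append(
            {
                "type": "Feature",
                "properties": {"name": "geofence"},
                "geometry": geofence.__geo_interface__,
            }
        )
    return {"type": "FeatureCollection", "features": feats}
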