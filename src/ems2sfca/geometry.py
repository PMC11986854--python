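"""Coordinate handling, pairwise distances and point-pattern statistics.

Points live either in geographic WGS84 coordinates (longitude/latitude in
decimal degrees, distances by great circle) or in a planar frame whose units
are kilometers (distances Euclidean).  No reprojection is performed:
coordinates are used as given, and the caller declares which frame they are
in.  Synthetic scenarios use the planar frame so that every distance has an
exact closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from shapely.geometry import MultiPoint

#: Mean Earth radius (IUGG), kilometers.
EARTH_RADIUS_KM = 6371.0088

CrsMode = Literal["geographic", "planar"]
Metric = Literal["haversine", "euclidean"]


@dataclass(frozen=True)
class GeoPoint:
    """A point with an identifier, either geographic (lon/lat) or planar (km)."""

    id: str
    x: float
    y: float
    crs_mode: CrsMode = "geographic"

    def __post_init__(self) -> None:
        if self.crs_mode not in ("geographic", "planar"):
            raise ValueError(f"unknown crs_mode {self.crs_mode!r}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"point {self.id!r}: non-finite coordinates")
        if self.crs_mode == "geographic":
            if not (-180.0 <= self.x <= 180.0):
                raise ValueError(f"point {self.id!r}: longitude {self.x} out of range")
            if not (-90.0 <= self.y <= 90.0):
                raise ValueError(f"point {self.id!r}: latitude {self.y} out of range")


@dataclass
class DistanceMatrix:
    """Pairwise demand-by-station distances in kilometers.

    ``values[i, j]`` is the distance from ``demand_ids[i]`` to
    ``station_ids[j]``.  For planar inputs the "kilometers" are whatever unit
    the planar coordinates carry; synthetic scenarios use km throughout.
    """

    demand_ids: list[str]
    station_ids: list[str]
    values: np.ndarray
    metric: Metric = "euclidean"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.demand_ids), len(self.station_ids)):
            raise ValueError(
                f"distance matrix shape {self.values.shape} does not match "
                f"{len(self.demand_ids)} demand x {len(self.station_ids)} station ids"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("distances must be finite and nonnegative")


@dataclass
class NNResult:
    """Average nearest-neighbor statistic for a point pattern.

    ``ratio`` < 1 indicates clustering relative to complete spatial
    randomness over the given area, > 1 indicates dispersion.  ``z_score``
    uses the classical standard error 0.26136 / sqrt(n^2 / A).
    """

    observed_mean: float
    expected_mean: float
    ratio: float
    z_score: float
    n_points: int
    area: float
    area_source: str = field(default="supplied")


def _check_pair(a: GeoPoint, b: GeoPoint) -> None:
    if a.crs_mode != b.crs_mode:
        raise ValueError(
            f"mixed crs_mode: {a.id!r} is {a.crs_mode}, {b.id!r} is {b.crs_mode}"
        )


def haversine_distance(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance in km between two geographic points."""
    _check_pair(a, b)
    if a.crs_mode != "geographic":
        raise ValueError("haversine_distance requires geographic points")
    lon1, lat1, lon2, lat2 = map(math.radians, (a.x, a.y, b.x, b.y))
    s = (
        math.sin((lat2 - lat1) / 2.0) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(s)))


def _coords(points: Sequence[GeoPoint]) -> np.ndarray:
    return np.array([(p.x, p.y) for p in points], dtype=float)


def _pairwise(a_xy: np.ndarray, b_xy: np.ndarray, metric: Metric) -> np.ndarray:
    if metric == "euclidean":
        diff = a_xy[:, None, :] - b_xy[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))
    if metric == "haversine":
        a = np.radians(a_xy)
        b = np.radians(b_xy)
        dlat = a[:, None, 1] - b[None, :, 1]
        dlon = a[:, None, 0] - b[None, :, 0]
        s = (
            np.sin(dlat / 2.0) ** 2
            + np.cos(a[:, None, 1]) * np.cos(b[None, :, 1]) * np.sin(dlon / 2.0) ** 2
        )
        return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(s)))
    raise ValueError(f"unknown metric {metric!r}")


def _validate_metric(points: Sequence[GeoPoint], metric: Metric) -> None:
    modes = {p.crs_mode for p in points}
    if len(modes) > 1:
        raise ValueError("mixed crs_mode within point set")
    mode = modes.pop()
    if metric == "haversine" and mode != "geographic":
        raise ValueError("haversine metric requires geographic points")
    if metric == "euclidean" and mode != "planar":
        raise ValueError("euclidean metric requires planar points")


def distance_matrix(
    demand: Sequence[GeoPoint],
    stations: Sequence[GeoPoint],
    metric: Metric | None = None,
) -> DistanceMatrix:
    """Pairwise distances, demand points as rows and stations as columns.

    ``metric`` defaults to the natural one for the points' frame:
    haversine for geographic coordinates, Euclidean for planar.
    """
    if len(demand) == 0:
        raise ValueError("demand point list is empty")
    if len(stations) == 0:
        raise ValueError("station list is empty")
    all_points = list(demand) + list(stations)
    if metric is None:
        metric = "haversine" if all_points[0].crs_mode == "geographic" else "euclidean"
    _validate_metric(all_points, metric)
    ids = [p.id for p in demand]
    sids = [p.id for p in stations]
    for name, id_list in (("demand", ids), ("station", sids)):
        if len(set(id_list)) != len(id_list):
            raise ValueError(f"duplicate ids in {name} point set")
    values = _pairwise(_coords(demand), _coords(stations), metric)
    return DistanceMatrix(demand_ids=ids, station_ids=sids, values=values, metric=metric)


def _local_planar_km(xy: np.ndarray) -> np.ndarray:
    """Project lon/lat degrees to a local equirectangular km frame."""
    lat0 = np.radians(xy[:, 1].mean())
    kx = np.radians(1.0) * EARTH_RADIUS_KM * np.cos(lat0)
    ky = np.radians(1.0) * EARTH_RADIUS_KM
    out = np.empty_like(xy)
    out[:, 0] = xy[:, 0] * kx
    out[:, 1] = xy[:, 1] * ky
    return out


def convex_hull_area_km2(points: Sequence[GeoPoint]) -> float:
    """Convex-hull area of a point set, km² (planar km or local projection)."""
    xy = _coords(points)
    if points[0].crs_mode == "geographic":
        xy = _local_planar_km(xy)
    return float(MultiPoint(xy).convex_hull.area)


def nearest_neighbor_index(
    points: Sequence[GeoPoint],
    area: float | None = None,
    metric: Metric | None = None,
) -> NNResult:
    """Average nearest-neighbor index of a point pattern.

    The observed mean nearest-neighbor distance is compared with the
    expectation under complete spatial randomness over ``area`` km²,
    ``0.5 / sqrt(n / area)``.  When ``area`` is omitted the convex-hull
    area of the points is used, and the result records which was used.
    Coincident points are allowed and contribute zero distance.
    """
    if len(points) < 2:
        raise ValueError("nearest-neighbor index needs at least 2 points")
    if metric is None:
        metric = "haversine" if points[0].crs_mode == "geographic" else "euclidean"
    _validate_metric(points, metric)

    area_source = "supplied"
    if area is None:
        area = convex_hull_area_km2(points)
        area_source = "convex_hull"
    if not area > 0:
        raise ValueError("area must be positive")

    xy = _coords(points)
    d = _pairwise(xy, xy, metric)
    np.fill_diagonal(d, np.inf)
    observed = float(d.min(axis=1).mean())

    n = len(points)
    expected = 0.5 / math.sqrt(n / area)
    se = 0.26136 / math.sqrt(n**2 / area)
    return NNResult(
        observed_mean=observed,
        expected_mean=expected,
        ratio=observed / expected,
        z_score=(observed - expected) / se,
        n_points=n,
        area=float(area),
        area_source=area_source,
    )
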