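"""Settlement-intensity quantification from site extents.

Occupation intensity per historical period is proxied by the area (in
hectares) of the convex hull drawn around that period's settlement
geometries, classified on an ordinal scale: low (< 0.5 ha), medium
(0.5–1.0 ha, bounds inclusive), high (> 1.0 ha); periods with no mapped
sites are "no occupation".  Coordinates must be in a projected metric CRS;
geographic (degree) coordinates are refused rather than silently
mis-measured.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPoint

__all__ = ["SiteGeometry", "Intensity", "PeriodOccupation", "convex_hull",
           "hull_area_ha", "classify_intensity", "tabulate_periods",
           "load_sites_geojson"]


class Intensity(str, enum.Enum):
    no_occupation = "no_occupation"
    low = "low"
    medium = "medium"
    high = "high"


@dataclass(frozen=True)
class SiteGeometry:
    period: str
    site_id: str
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 1:
            raise ValueError(f"site {self.site_id!r}: needs >= 1 vertex")
        arr = np.asarray(self.vertices, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"site {self.site_id!r}: non-finite coordinates")


@dataclass(frozen=True)
class PeriodOccupation:
    period: str
    age_bp_lower: float | None
    age_bp_upper: float | None
    area_ha: float
    intensity: Intensity
    n_sites: int = 0


def _check_metric(points: np.ndarray) -> None:
    if np.all(np.abs(points[:, 0]) <= 180.0) and np.all(np.abs(points[:, 1]) <= 90.0):
        raise ValueError(
            "coordinates look geographic (degrees); supply a projected metric CRS"
        )


def convex_hull(points) -> list[tuple[float, float]]:
    """Convex hull of 2-D points, counter-clockwise, collinear points dropped.

    Inputs of 1–2 distinct points (or collinear sets) return degenerate
    hulls with zero area.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.size == 0:
        raise ValueError("convex hull of empty point set")
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (x, y) pairs")
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if hull.geom_type == "Point":
        return [(hull.x, hull.y)]
    if hull.geom_type == "LineString":
        return [tuple(c) for c in hull.coords]
    coords = list(hull.exterior.coords)[:-1]  # drop closing duplicate
    ring = np.asarray(coords)
    # shoelace signed area; shapely may emit either orientation
    x, y = ring[:, 0], ring[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if signed < 0:
        coords = coords[::-1]
    return [tuple(c) for c in coords]


def hull_area_ha(hull) -> float:
    """Area of an ordered hull in hectares (coordinates in meters).

    Shoelace area divided by 10,000; degenerate hulls (points, segments)
    have area 0.
    """
    ring = np.asarray(list(hull), dtype=float)
    if ring.ndim != 2 or len(ring) < 3:
        return 0.0
    x, y = ring[:, 0], ring[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return abs(float(signed)) / 10_000.0


def classify_intensity(area_ha: float, occupied: bool = True) -> Intensity:
    """Ordinal settlement-intensity class from hull area in hectares."""
    if area_ha < 0:
        raise ValueError("area_ha must be >= 0")
    if not occupied:
        return Intensity.no_occupation
    if area_ha < 0.5:
        return Intensity.low
    if area_ha <= 1.0:
        return Intensity.medium
    return Intensity.high


def tabulate_periods(geometries: list[SiteGeometry], period_defs,
                     per_site: bool = False) -> list[PeriodOccupation]:
    """Period table of hull areas and intensity classes.

    ``period_defs`` is a sequence of (period, age_bp_lower, age_bp_upper).
    By default one hull is drawn over the union of a period's site vertices;
    ``per_site=True`` instead sums per-site hull areas.  Periods without
    geometry are "no occupation" with area 0; geometries naming a period
    absent from ``period_defs`` are an error.
    """
    defs = [(str(p), lo, up) for p, lo, up in period_defs]
    known = {p for p, _, _ in defs}
    by_period: dict[str, list[SiteGeometry]] = {}
    for g in geometries:
        if g.period not in known:
            raise ValueError(f"unknown period {g.period!r} in site {g.site_id!r}")
        by_period.setdefault(g.period, []).append(g)
    rows = []
    for period, lo, up in defs:
        sites = by_period.get(period, [])
        if not sites:
            rows.append(PeriodOccupation(period=period, age_bp_lower=lo,
                                         age_bp_upper=up, area_ha=0.0,
                                         intensity=Intensity.no_occupation))
            continue
        all_pts = np.asarray([v for g in sites for v in g.vertices], dtype=float)
        _check_metric(all_pts)
        if per_site:
            area = sum(hull_area_ha(convex_hull(g.vertices)) for g in sites)
        else:
            area = hull_area_ha(convex_hull(all_pts))
        rows.append(PeriodOccupation(period=period, age_bp_lower=lo,
                                     age_bp_upper=up, area_ha=area,
                                     intensity=classify_intensity(area, True),
                                     n_sites=len(sites)))
    return rows


def load_sites_geojson(path) -> list[SiteGeometry]:
    """Load site geometries from a GeoJSON FeatureCollection.

    Each feature needs ``period`` and ``site_id`` properties and a Point or
    Polygon geometry (exterior ring only) in a projected metric CRS.
    """
    with open(path) as fh:
        fc = json.load(fh)
    sites = []
    for feat in fc.get("features", []):
        props = feat.get("properties", {})
        geom = feat.get("geometry", {})
        gtype = geom.get("type")
        if gtype == "Point":
            verts = [tuple(geom["coordinates"])]
        elif gtype == "Polygon":
            ring = geom["coordinates"][0]
            verts = [tuple(c) for c in ring]
            if len(verts) > 1 and verts[0] == verts[-1]:
                verts = verts[:-1]
        else:
            raise ValueError(f"unsupported geometry type {gtype!r}")
        sites.append(SiteGeometry(period=str(props["period"]),
                                  site_id=str(props["site_id"]),
                                  vertices=tuple(verts)))
    return sites
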