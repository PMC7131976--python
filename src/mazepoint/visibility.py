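"""2.5-D visibility: sightlines over hedges, pointing-pair classes, isovists.

The maze is flat ground with vertical walls of finite height. A sightline
between two eye points is clear when, at every wall segment its planar
projection crosses, the linearly interpolated sight height strictly exceeds
the wall height. An endpoint lying exactly on a wall counts as blocked.

The isovist of a viewpoint is the planar region it can see, computed by an
angular ray sweep against the walls tall enough to block at that eye height,
clipped to the layout bounds. Its area relative to the bounds area is the
``scale_ratio`` -- the geographic-scale measure: the fraction of the
environment visually accessible from one position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .geometry import MazeLayout

__all__ = [
    "Isovist",
    "classify_pointing_pairs",
    "isovist",
    "line_of_sight",
    "visible_landmarks",
]

_EPS = 1e-9


def _crossings(p: np.ndarray, q: np.ndarray,
               walls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Parameters t along p->q and wall heights for every wall crossed.

    Intersection is inclusive at segment endpoints, so a sightline that only
    grazes a wall end still counts as crossing it.
    """
    if walls.size == 0:
        return np.empty(0), np.empty(0)
    d = q - p                                   # sightline direction
    a = walls[:, 0:2]
    e = walls[:, 2:4] - a                       # wall directions
    denom = d[0] * e[:, 1] - d[1] * e[:, 0]
    ap = a - p
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ap[:, 0] * e[:, 1] - ap[:, 1] * e[:, 0]) / denom
        u = (ap[:, 0] * d[1] - ap[:, 1] * d[0]) / denom
    hit = (np.abs(denom) > _EPS) & (t >= -_EPS) & (t <= 1 + _EPS) \
        & (u >= -_EPS) & (u <= 1 + _EPS)
    return t[hit], walls[hit, 4]


def line_of_sight(layout: MazeLayout,
                  frm: tuple[float, float, float],
                  to: tuple[float, float, float]) -> bool:
    """True when the straight sightline between two eye points clears every
    wall it crosses.

    ``frm`` and ``to`` are ``(x, y, eye height)`` triples. Coincident planar
    points are trivially intervisible.
    """
    p = np.asarray(frm[:2], dtype=float)
    q = np.asarray(to[:2], dtype=float)
    h1, h2 = float(frm[2]), float(to[2])
    if np.hypot(*(q - p)) < _EPS:
        return True
    t, wall_h = _crossings(p, q, layout.walls)
    if t.size == 0:
        return True
    sight_h = h1 + t * (h2 - h1)
    return bool(np.all(sight_h > wall_h + _EPS))


def classify_pointing_pairs(layout: MazeLayout,
                            eye_height: float) -> pd.DataFrame:
    """Visible / non-visible classification of every ordered location pair.

    Both endpoints are evaluated at the same eye height, the convention used
    for the ground-perspective pointing task. Returns an ``n*(n-1)``-row
    frame with columns ``origin``, ``target``, ``visible``; visibility is
    symmetric in origin and target at equal eye heights.
    """
    ids = layout.location_ids
    if len(ids) < 2:
        raise ValueError("layout needs at least two locations")
    rows = []
    vis_cache: dict[tuple[int, int], bool] = {}
    for o in ids:
        for tgt in ids:
            if o == tgt:
                continue
            key = (min(o, tgt), max(o, tgt))
            if key not in vis_cache:
                vis_cache[key] = line_of_sight(
                    layout,
                    (*layout.coords[key[0]], eye_height),
                    (*layout.coords[key[1]], eye_height),
                )
            rows.append((o, tgt, vis_cache[key]))
    return pd.DataFrame(rows, columns=["origin", "target", "visible"])


@dataclass(frozen=True)
class Isovist:
    """Visible region of a single viewpoint."""

    viewpoint: tuple[float, float, float]  # x, y, eye height
    polygon: Polygon
    area: float
    scale_ratio: float          # area / bounds area, in (0, 1]
    angular_resolution: float   # degrees between sweep rays

    def to_geojson(self) -> dict:
        x, y, h = self.viewpoint
        return {
            "type": "Feature",
            "geometry": {
                "type": "Polygon",
                "coordinates": [list(map(list, self.polygon.exterior.coords))],
            },
            "properties": {
                "kind": "isovist", "x": x, "y": y, "eye_height_m": h,
                "area_m2": self.area, "scale_ratio": self.scale_ratio,
            },
        }


def _bounds_walls(bounds: tuple[float, float, float, float]) -> np.ndarray:
    minx, miny, maxx, maxy = bounds
    inf = np.inf
    return np.array([
        (minx, miny, maxx, miny, inf),
        (maxx, miny, maxx, maxy, inf),
        (maxx, maxy, minx, maxy, inf),
        (minx, maxy, minx, miny, inf),
    ])


def isovist(layout: MazeLayout, location: int, eye_height: float,
            angular_resolution: float = 0.25) -> Isovist:
    """Angular-sweep isovist from a route location.

    Rays are cast every ``angular_resolution`` degrees against the walls at
    least as tall as the eye height (shorter walls are overlooked) and the
    bounding rectangle; the visible region is the polygon of nearest hits.
    The sweep converges to the exact visibility polygon as the resolution
    shrinks; a rasterized line-of-sight oracle bounds its error in tests.
    """
    if not (0 < angular_resolution <= 1.0):
        raise ValueError("angular_resolution must be in (0, 1] degrees")
    if location not in layout.coords:
        raise KeyError(f"unknown location {location}")
    v = np.asarray(layout.coords[location], dtype=float)
    minx, miny, maxx, maxy = layout.bounds
    if not (minx <= v[0] <= maxx and miny <= v[1] <= maxy):
        raise ValueError("viewpoint lies outside the layout bounds")

    blocking = layout.walls[layout.walls[:, 4] >= eye_height - _EPS]
    segs = np.vstack([blocking[:, :4], _bounds_walls(layout.bounds)[:, :4]]) \
        if blocking.size else _bounds_walls(layout.bounds)[:, :4]

    az = np.radians(np.arange(0.0, 360.0, angular_resolution))
    d = np.stack([np.sin(az), np.cos(az)], axis=1)        # (R, 2), cw from north
    a = segs[:, 0:2]
    e = segs[:, 2:4] - a                                  # (W, 2)
    ap = a - v                                            # (W, 2)
    denom = d[:, 0:1] * e[:, 1] - d[:, 1:2] * e[:, 0]     # (R, W)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ap[:, 0] * e[:, 1] - ap[:, 1] * e[:, 0]) / denom      # cross(ap, e)
        u = (ap[None, :, 0] * d[:, 1:2]
             - ap[None, :, 1] * d[:, 0:1]) / denom                  # cross(ap, d)
    hit = (np.abs(denom) > _EPS) & (u >= -_EPS) & (u <= 1 + _EPS) & (t > _EPS)
    t = np.where(hit, t, np.inf)
    reach = t.min(axis=1)                                 # (R,)
    reach = np.where(np.isfinite(reach), reach, 0.0)
    ring = v + reach[:, None] * d
    poly = Polygon(ring)
    if not poly.is_valid:
        poly = poly.buffer(0)
    poly = poly.intersection(Polygon.from_bounds(*layout.bounds))
    area = float(poly.area)
    return Isovist(viewpoint=(v[0], v[1], eye_height), polygon=poly,
                   area=area, scale_ratio=area / layout.bounds_area,
                   angular_resolution=angular_resolution)


def visible_landmarks(layout: MazeLayout, location: int,
                      eye_height: float) -> set[str]:
    """Names of landmarks whose top is visible from a location's eye point.

    A landmark is visible when an unblocked 2.5-D sightline connects the
    eye point to the top of its column; the landmark at the viewpoint itself
    is always included.
    """
    if location not in layout.coords:
        raise KeyError(f"unknown location {location}")
    v = layout.coords[location]
    out = set()
    for loc_id, lm in layout.landmarks.items():
        if loc_id == location or line_of_sight(
                layout, (v[0], v[1], eye_height), (lm.x, lm.y, lm.height)):
            out.add(lm.name)
    return out
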