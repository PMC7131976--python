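"""Maze route geometry: intrinsic route specs, planar realization, azimuths.

A maze is described intrinsically -- an ordered chain of locations joined by
straight legs, with a signed turn angle at each interior location -- and
realized deterministically as planar coordinates (location 1 at the origin,
initial heading due north). Hedge walls are offset curves of the route
centerline; landmarks are vertical columns at the location coordinates.

Azimuths are degrees in [0, 360), measured clockwise from north, the usual
map convention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import LineString

__all__ = [
    "GROUND_EYE_HEIGHT",
    "ELEVATED_EYE_HEIGHT",
    "DEFAULT_CORRIDOR_WIDTH",
    "DEFAULT_HEDGE_HEIGHT",
    "Landmark",
    "Leg",
    "MazeLayout",
    "RouteSpec",
    "SelfIntersectingRouteError",
    "angular_error",
    "azimuth_of_vector",
    "normalize_azimuth",
    "signed_angle_difference",
    "realize_layout",
    "reference_route",
    "reference_layout",
    "true_direction",
]

#: Eye height (m) of an observer standing on the ground.
GROUND_EYE_HEIGHT = 1.4
#: Eye height (m) of the elevated (pseudo-aerial) viewpoint.
ELEVATED_EYE_HEIGHT = 5.3
#: Default corridor width (m) between the two hedge rows of a leg.
DEFAULT_CORRIDOR_WIDTH = 3.0
#: Default hedge height (m): above ground eye height, below the elevated one.
DEFAULT_HEDGE_HEIGHT = 2.5


# ---------------------------------------------------------------------------
# Azimuth arithmetic
# ---------------------------------------------------------------------------

def normalize_azimuth(degrees: float) -> float:
    """Map an angle in degrees onto [0, 360). Idempotent."""
    r = float(np.asarray(degrees) % 360.0)
    return 0.0 if r >= 360.0 else r   # -eps % 360 rounds to 360.0


def azimuth_of_vector(dx: float, dy: float) -> float:
    """Azimuth of the planar vector (dx east, dy north), clockwise from north."""
    if dx == 0.0 and dy == 0.0:
        raise ValueError("azimuth of the zero vector is undefined")
    return normalize_azimuth(math.degrees(math.atan2(dx, dy)))


def angular_error(judged: float, truth: float) -> float:
    """Absolute angular difference between two azimuths, in [0, 180].

    This is the pointing-error metric: the shorter arc between the judged
    and the actual target direction, irrespective of sign.
    """
    d = abs(judged - truth) % 360.0
    return float(min(d, 360.0 - d))


def signed_angle_difference(a: float, b: float) -> float:
    """Signed difference a - b mapped to (-180, 180]."""
    d = (a - b) % 360.0
    return float(d - 360.0) if d > 180.0 else float(d)


# ---------------------------------------------------------------------------
# Route specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Leg:
    """A straight route segment from one location to the next."""

    from_id: int
    to_id: int
    length: float  # meters; 0.0 marks a leg removed by an edit (fused ends)


@dataclass(frozen=True)
class RouteSpec:
    """Intrinsic route description: locations, legs and interior turn angles.

    ``turns[loc]`` is the signed heading change (degrees, + = clockwise) the
    route makes at interior location ``loc``. Locations are identified by
    consecutive integers ``1..n`` along the route.
    """

    location_names: tuple[str, ...]
    legs: tuple[Leg, ...]
    turns: dict[int, float] = field(default_factory=dict)

    @property
    def n_locations(self) -> int:
        return len(self.location_names)

    @property
    def location_ids(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_locations + 1))

    def leg(self, from_id: int, to_id: int) -> Leg:
        for leg in self.legs:
            if (leg.from_id, leg.to_id) == (from_id, to_id):
                return leg
        raise KeyError(f"no leg ({from_id}, {to_id}) in route")

    def validate(self, allow_zero_legs: bool = False) -> None:
        n = self.n_locations
        if n < 2:
            raise ValueError("a route needs at least two locations")
        if len(self.legs) != n - 1:
            raise ValueError(f"expected {n - 1} legs for {n} locations")
        for i, leg in enumerate(self.legs, start=1):
            if (leg.from_id, leg.to_id) != (i, i + 1):
                raise ValueError(
                    f"legs must form the simple path 1..{n}; "
                    f"leg {i} is ({leg.from_id}, {leg.to_id})"
                )
            if leg.length < 0 or (leg.length == 0 and not allow_zero_legs):
                raise ValueError(f"leg ({leg.from_id}, {leg.to_id}) has "
                                 f"non-positive length {leg.length}")
        interior = set(range(2, n))
        unknown = set(self.turns) - interior
        if unknown:
            raise ValueError(f"turn at non-interior location(s) {sorted(unknown)}")

    # -- realization -------------------------------------------------------

    def headings(self) -> list[float]:
        """Azimuth of each leg, location 1 heading due north, turns applied
        at interior locations in route order."""
        heading = 0.0
        out = []
        for leg in self.legs:
            if leg.from_id != 1:
                heading = normalize_azimuth(heading + self.turns.get(leg.from_id, 0.0))
            out.append(heading)
        return out

    def coordinates(self) -> dict[int, np.ndarray]:
        """Planar (x east, y north) coordinates of every location, derived
        deterministically from leg lengths and turns."""
        coords = {1: np.zeros(2)}
        pos = np.zeros(2)
        for leg, heading in zip(self.legs, self.headings()):
            rad = math.radians(heading)
            pos = pos + leg.length * np.array([math.sin(rad), math.cos(rad)])
            coords[leg.to_id] = pos
        return coords

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "locations": [
                {"id": i, "name": name}
                for i, name in zip(self.location_ids, self.location_names)
            ],
            "legs": [
                {"from": leg.from_id, "to": leg.to_id, "length_m": leg.length}
                for leg in self.legs
            ],
            "turns": [
                {"at": loc, "angle_deg": ang} for loc, ang in sorted(self.turns.items())
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RouteSpec":
        locations = sorted(d["locations"], key=lambda x: x["id"])
        spec = cls(
            location_names=tuple(loc["name"] for loc in locations),
            legs=tuple(
                Leg(leg["from"], leg["to"], float(leg["length_m"]))
                for leg in d["legs"]
            ),
            turns={t["at"]: float(t["angle_deg"]) for t in d.get("turns", [])},
        )
        spec.validate(allow_zero_legs=True)
        return spec


# ---------------------------------------------------------------------------
# Realized layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Landmark:
    """A columnar landmark standing at a route location."""

    x: float
    y: float
    height: float
    name: str


class SelfIntersectingRouteError(ValueError):
    """Raised when corridors of non-adjacent legs would overlap."""


@dataclass(frozen=True)
class MazeLayout:
    """Realized 2.5-D maze: coordinates, hedge walls, landmarks, bounds.

    ``walls`` is an (m, 5) float array of segments ``(x1, y1, x2, y2, height)``.
    ``bounds`` is the enclosing rectangle ``(minx, miny, maxx, maxy)``.
    """

    coords: dict[int, np.ndarray]
    walls: np.ndarray
    landmarks: dict[int, Landmark]
    bounds: tuple[float, float, float, float]
    corridor_width: float
    hedge_height: float
    route: RouteSpec | None = None

    @property
    def location_ids(self) -> tuple[int, ...]:
        return tuple(sorted(self.coords))

    @property
    def bounds_area(self) -> float:
        minx, miny, maxx, maxy = self.bounds
        return (maxx - minx) * (maxy - miny)

    def to_geojson(self) -> dict:
        """Walls, locations and landmarks as a planar GeoJSON FeatureCollection
        (coordinates in meters)."""
        features = []
        for x1, y1, x2, y2, h in self.walls:
            features.append({
                "type": "Feature",
                "geometry": {"type": "LineString",
                             "coordinates": [[x1, y1], [x2, y2]]},
                "properties": {"kind": "wall", "height_m": h},
            })
        for loc_id in self.location_ids:
            x, y = self.coords[loc_id]
            features.append({
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [x, y]},
                "properties": {"kind": "location", "id": int(loc_id)},
            })
        for loc_id, lm in self.landmarks.items():
            features.append({
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [lm.x, lm.y]},
                "properties": {"kind": "landmark", "location": int(loc_id),
                               "name": lm.name, "height_m": lm.height},
            })
        return {"type": "FeatureCollection", "features": features}


def _check_no_corridor_collision(spec: RouteSpec, coords: dict[int, np.ndarray],
                                 width: float) -> None:
    """Non-adjacent legs must keep at least one corridor width of clearance."""
    segs = []
    for leg in spec.legs:
        if leg.length == 0:
            continue
        segs.append((leg, LineString([coords[leg.from_id], coords[leg.to_id]])))
    for i in range(len(segs)):
        for j in range(i + 2, len(segs)):
            leg_i, line_i = segs[i]
            leg_j, line_j = segs[j]
            # consecutive non-zero legs share a vertex; anything beyond that
            # must stay a full corridor width apart
            if line_i.distance(line_j) < width - 1e-9:
                raise SelfIntersectingRouteError(
                    f"corridors of legs ({leg_i.from_id},{leg_i.to_id}) and "
                    f"({leg_j.from_id},{leg_j.to_id}) collide"
                )


def _wall_segments(centerline: LineString, width: float,
                   hedge_height: float) -> np.ndarray:
    """Two mitre-joined offset polylines plus end caps, as segment rows."""
    rows: list[tuple[float, float, float, float, float]] = []
    sides = []
    for signed in (width / 2.0, -width / 2.0):
        off = centerline.offset_curve(signed, join_style="mitre", mitre_limit=10.0)
        if off.geom_type != "LineString" or off.is_empty:
            raise SelfIntersectingRouteError(
                "corridor offset degenerated; route folds onto itself")
        pts = np.asarray(off.coords)
        sides.append(pts)
        for p, q in zip(pts[:-1], pts[1:]):
            rows.append((p[0], p[1], q[0], q[1], hedge_height))
    left, right = sides
    # end caps close the corridor behind the start and end locations
    # (offset_curve preserves the centerline direction on both sides)
    for a, b in ((left[0], right[0]), (left[-1], right[-1])):
        rows.append((a[0], a[1], b[0], b[1], hedge_height))
    return np.array(rows, dtype=float)


def realize_layout(
    spec: RouteSpec,
    corridor_width: float = DEFAULT_CORRIDOR_WIDTH,
    hedge_height: float = DEFAULT_HEDGE_HEIGHT,
    landmark_heights: dict[int, float] | None = None,
    bounds_margin: float | None = None,
) -> MazeLayout:
    """Realize an intrinsic route as planar coordinates with hedge corridors.

    Location 1 sits at the origin with the route initially heading north.
    Each leg is flanked by two parallel hedge walls ``corridor_width/2``
    either side of its centerline, joined with mitred corners at turns; the
    corridor is capped just beyond the first and last location. Landmarks
    are placed at location coordinates with the given column heights
    (default: hedge height minus 0.3 m).

    Raises :class:`SelfIntersectingRouteError` when non-adjacent corridors
    would overlap, naming the colliding legs.
    """
    if corridor_width <= 0:
        raise ValueError("corridor_width must be positive")
    spec.validate(allow_zero_legs=True)
    coords = spec.coordinates()
    _check_no_corridor_collision(spec, coords, corridor_width)

    # extend the centerline half a corridor width beyond both route ends so
    # the end locations sit strictly inside the walled corridor
    pts = [coords[i] for i in spec.location_ids]
    path = [p for i, p in enumerate(pts)
            if i == 0 or not np.allclose(p, pts[i - 1])]
    ext = corridor_width / 2.0
    d0 = path[0] - path[1]
    d1 = path[-1] - path[-2]
    path = ([path[0] + ext * d0 / np.linalg.norm(d0)] + path
            + [path[-1] + ext * d1 / np.linalg.norm(d1)])
    centerline = LineString(path)
    if not centerline.is_simple:
        raise SelfIntersectingRouteError("route centerline self-intersects")
    walls = _wall_segments(centerline, corridor_width, hedge_height)

    heights = landmark_heights or {}
    default_h = hedge_height - 0.3
    landmarks = {
        i: Landmark(coords[i][0], coords[i][1],
                    heights.get(i, default_h), spec.location_names[i - 1])
        for i in spec.location_ids
    }

    margin = corridor_width if bounds_margin is None else bounds_margin
    xs = np.concatenate([walls[:, [0, 2]].ravel(), [c[0] for c in coords.values()]])
    ys = np.concatenate([walls[:, [1, 3]].ravel(), [c[1] for c in coords.values()]])
    bounds = (float(xs.min() - margin), float(ys.min() - margin),
              float(xs.max() + margin), float(ys.max() + margin))
    return MazeLayout(coords=coords, walls=walls, landmarks=landmarks,
                      bounds=bounds, corridor_width=corridor_width,
                      hedge_height=hedge_height, route=spec)


def true_direction(layout: MazeLayout, origin: int, target: int) -> float:
    """Azimuth of the straight line from one location to another."""
    if origin == target:
        raise ValueError("origin and target must differ")
    d = layout.coords[target] - layout.coords[origin]
    if np.hypot(d[0], d[1]) < 1e-12:
        raise ValueError(
            f"locations {origin} and {target} are coincident; "
            "direction undefined")
    return azimuth_of_vector(d[0], d[1])


# ---------------------------------------------------------------------------
# Packaged reconstruction of the study maze
# ---------------------------------------------------------------------------

#: Landmark names in route order (start to end).
LANDMARK_NAMES = (
    "Lighthouse", "Traffic Light", "Blue Flag", "Big Ben", "Chimney",
    "Street Lamp", "Statue of Liberty", "Payphone", "Eiffel Tower",
)

# Leg lengths (m) of the packaged reconstruction. The published planar figure
# carries no numeric coordinates, so these are repository constants chosen to
# satisfy every stated constraint: nine locations, seven right-angle turns,
# the two legs between locations 5 and 7 strictly longest, leg 6-7 unequal to
# leg 8-9, and a non-self-intersecting orthogonal course.
_REFERENCE_LEG_LENGTHS = (10.0, 12.0, 9.0, 11.0, 22.0, 18.0, 10.0, 8.0)
_REFERENCE_TURNS = {2: 90.0, 3: 90.0, 4: -90.0, 5: -90.0,
                    6: 90.0, 7: 90.0, 8: -90.0}

# Column heights (m). Two landmarks overtop the hedges so that exactly one
# extra landmark becomes visible from the elevated viewpoint at each of
# locations 2, 4, 6 and 8; the rest stay low enough that even a descending
# elevated sightline is below hedge top by its last wall crossing.
_REFERENCE_LANDMARK_HEIGHTS = {i: 1.0 for i in range(1, 10)}
_REFERENCE_LANDMARK_HEIGHTS[3] = 9.0   # Blue Flag
_REFERENCE_LANDMARK_HEIGHTS[7] = 9.0   # Statue of Liberty


def reference_route() -> RouteSpec:
    """The packaged nine-location route reconstruction (see module docs)."""
    spec = RouteSpec(
        location_names=LANDMARK_NAMES,
        legs=tuple(Leg(i, i + 1, ln)
                   for i, ln in enumerate(_REFERENCE_LEG_LENGTHS, start=1)),
        turns=dict(_REFERENCE_TURNS),
    )
    spec.validate()
    return spec


def reference_layout(corridor_width: float = DEFAULT_CORRIDOR_WIDTH,
                     hedge_height: float = DEFAULT_HEDGE_HEIGHT) -> MazeLayout:
    """Realized reference maze with the packaged landmark heights."""
    return realize_layout(reference_route(), corridor_width, hedge_height,
                          landmark_heights=dict(_REFERENCE_LANDMARK_HEIGHTS))


# ---------------------------------------------------------------------------
# Layout JSON document
# ---------------------------------------------------------------------------

def layout_to_json(spec: RouteSpec, corridor_width: float,
                   hedge_height: float,
                   landmark_heights: dict[int, float] | None = None) -> str:
    doc = spec.to_dict()
    doc["corridor_width_m"] = corridor_width
    doc["hedge_height_m"] = hedge_height
    if landmark_heights:
        doc["landmark_heights_m"] = {str(k): v for k, v in landmark_heights.items()}
    return json.dumps(doc, indent=2)


def layout_from_json(text: str) -> MazeLayout:
    doc = json.loads(text)
    spec = RouteSpec.from_dict(doc)
    heights = {int(k): float(v)
               for k, v in doc.get("landmark_heights_m", {}).items()}
    return realize_layout(
        spec,
        corridor_width=float(doc.get("corridor_width_m", DEFAULT_CORRIDOR_WIDTH)),
        hedge_height=float(doc.get("hedge_height_m", DEFAULT_HEDGE_HEIGHT)),
        landmark_heights=heights or None,
    )


def mirror_route(spec: RouteSpec) -> RouteSpec:
    """Reverse the sign of every turn: the mirror-image maze."""
    return replace(spec, turns={k: -v for k, v in spec.turns.items()})
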