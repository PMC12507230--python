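"""Region geometry for the flume: plume polygon, target circle, station
rectangle, trajectory crossings and perimeter-density expected ratios.

Coordinates are arena-frame centimeters.  The arena origin sits at the
downstream end: x increases upstream, y across-stream, and the mean flow
direction is (-1, 0) — water runs toward -x, so an animal moving "against
flow" moves toward +x.

The three-station apparatus is a rectangle of three equal squares laid
across the stream.  Its external perimeter is partitioned into labeled
segments (the downstream-facing long edge is crossed by against-flow
approaches, the upstream-facing one by with-flow approaches, plus the two
short side edges).  Under the null model that crossings are uniform per
unit boundary length, the expected share of approaches through a segment
is its length fraction — e.g. 3/8 for either long edge of the 3x1
rectangle, and 1/3 for the baited square conditional on entry through one
long edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from shapely.geometry import LineString, Point, Polygon
from skimage.measure import label as cc_label
from skimage.measure import regionprops

logger = logging.getLogger(__name__)

#: flume working-section dimensions, cm (length along flow x width)
ARENA_LENGTH_CM = 185.0
ARENA_WIDTH_CM = 116.0
#: reach radius of the virtual target circle, cm
TARGET_RADIUS_CM = 14.0
DEFAULT_FLOW = (-1.0, 0.0)


@dataclass
class PlumePolygon:
    """Extent of the chemosensory plume as a simple polygon in cm."""

    vertices: np.ndarray
    source: tuple[float, float]
    provenance: str = "manual_file"

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 3:
            raise ValueError("polygon needs >= 3 vertices")
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise ValueError("polygon is self-intersecting or degenerate")
        if not poly.covers(Point(self.source)):
            raise ValueError("plume source must lie inside the polygon")

    @property
    def shapely(self) -> Polygon:
        return Polygon(self.vertices)

    def to_dict(self) -> dict:
        return {
            "vertices": self.vertices.tolist(),
            "source": list(self.source),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlumePolygon":
        return cls(
            vertices=np.asarray(d["vertices"], dtype=float),
            source=tuple(d["source"]),
            provenance=d.get("provenance", "manual_file"),
        )


@dataclass
class TargetCircle:
    """Virtual target circle around a baited station."""

    center: tuple[float, float]
    radius: float = TARGET_RADIUS_CM

    def contains(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        d = np.linalg.norm(p - np.asarray(self.center), axis=1)
        return d <= self.radius

    @property
    def circumference(self) -> float:
        return 2.0 * np.pi * self.radius


@dataclass
class BoundarySegment:
    """One labeled piece of a region's external perimeter.

    ``start``/``end`` are ordered counter-clockwise around the region; by the
    half-open ownership convention a segment owns its counter-clockwise
    (``end``) corner, so partition corners are classified unambiguously.
    """

    start: np.ndarray
    end: np.ndarray
    side: str  # with_flow | against_flow | side
    station: int | None = None
    bait: bool | None = None

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.asarray(self.end) - np.asarray(self.start)))

    def contains_point(self, p, tol: float = 1e-6) -> bool:
        """Point-on-segment test honoring the half-open corner rule."""
        a, b = np.asarray(self.start, float), np.asarray(self.end, float)
        ab, ap = b - a, np.asarray(p, float) - a
        L = np.linalg.norm(ab)
        t = float(np.dot(ap, ab) / (L * L))
        perp = abs(ab[0] * ap[1] - ab[1] * ap[0]) / L
        if perp > tol:
            return False
        # owns its CCW (end) corner, not its start corner
        return tol / L < t <= 1.0 + tol / L


@dataclass
class StationRectangle:
    """Three-station rectangle: three equal squares laid across-stream.

    The rectangle's long axis runs along y (across the flow); ``bait_index``
    selects which of the three squares (ordered by increasing y) holds the
    baited station.
    """

    center: tuple[float, float]
    square_size: float
    bait_index: int
    flow_direction: tuple[float, float] = DEFAULT_FLOW

    def __post_init__(self):
        if self.bait_index not in (0, 1, 2):
            raise ValueError("bait_index must be 0, 1 or 2")
        f = np.asarray(self.flow_direction, float)
        self.flow_direction = tuple(f / np.linalg.norm(f))

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        cx, cy = self.center
        s = self.square_size
        return (cx - s / 2, cy - 1.5 * s, cx + s / 2, cy + 1.5 * s)

    @property
    def polygon(self) -> Polygon:
        x0, y0, x1, y1 = self.bounds
        return Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])

    def contains(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        x0, y0, x1, y1 = self.bounds
        return (
            (p[:, 0] >= x0) & (p[:, 0] <= x1) & (p[:, 1] >= y0) & (p[:, 1] <= y1)
        )

    def external_segments(self) -> list[BoundarySegment]:
        """CCW-ordered labeled external perimeter (internal edges excluded)."""
        x0, y0, x1, y1 = self.bounds
        s = self.square_size
        fx = self.flow_direction[0]
        # the downstream-facing long edge has outward normal opposite to +x
        # when flow is (-1, 0): animals travelling upstream cross it
        low_x_side = "against_flow" if fx < 0 else "with_flow"
        high_x_side = "with_flow" if fx < 0 else "against_flow"
        ys = [y0, y0 + s, y0 + 2 * s, y1]
        segs: list[BoundarySegment] = []
        # CCW walk: low-y short edge, high-x long edge, high-y short edge,
        # low-x long edge
        segs.append(BoundarySegment(np.array([x0, y0]), np.array([x1, y0]), "side"))
        for i in range(3):
            segs.append(
                BoundarySegment(
                    np.array([x1, ys[i]]),
                    np.array([x1, ys[i + 1]]),
                    high_x_side,
                    station=i,
                    bait=(i == self.bait_index),
                )
            )
        segs.append(BoundarySegment(np.array([x1, y1]), np.array([x0, y1]), "side"))
        for i in (2, 1, 0):
            segs.append(
                BoundarySegment(
                    np.array([x0, ys[i + 1]]),
                    np.array([x0, ys[i]]),
                    low_x_side,
                    station=i,
                    bait=(i == self.bait_index),
                )
            )
        return segs


@dataclass
class RegionSet:
    """All regions a run needs, with the flow direction that orients them."""

    target_circle: TargetCircle | None = None
    station_rect: StationRectangle | None = None
    plume: PlumePolygon | None = None
    flow_direction: tuple[float, float] = DEFAULT_FLOW
    arena_size_cm: tuple[float, float] = (ARENA_LENGTH_CM, ARENA_WIDTH_CM)


@dataclass
class CrossingEvent:
    """First entry of one approach into a region."""

    frame: int
    point: tuple[float, float]
    region_id: str
    label: str | None = None
    started_inside: bool = False
    backcast_start_frame: int = 0
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# plume polygon from a plume-visualization video


def variance_projection(frames) -> np.ndarray:
    """Per-pixel temporal (population) variance of a video stack.

    Pixels washed by the intermittent plume fluctuate strongly and light up
    in the variance image; static background does not.
    """
    stack = np.asarray(frames, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a stack of >= 2 frames")
    return stack.var(axis=0)


def threshold_to_polygon(
    variance_image: np.ndarray,
    px_per_cm: float,
    source_cm: tuple[float, float],
    percentile: float = 99.0,
) -> PlumePolygon:
    """Percentile-threshold a variance image into a plume polygon.

    The mask keeps pixels above the given intensity percentile; the polygon
    is the convex hull of the largest connected component, converted to cm.
    """
    img = np.asarray(variance_image, dtype=float)
    if img.max() == img.min():
        raise ValueError("constant variance image; cannot threshold")
    mask = img > np.percentile(img, percentile)
    if not mask.any():
        raise ValueError("empty mask after thresholding")
    labels = cc_label(mask)
    props = regionprops(labels)
    if len(props) > 1:
        logger.info("threshold_to_polygon: %d components, keeping largest", len(props))
    biggest = max(props, key=lambda p: p.area)
    coords = biggest.coords  # (row, col)
    pts = np.stack([coords[:, 1], coords[:, 0]], axis=1).astype(float)  # (x, y) px
    if len(np.unique(pts, axis=0)) < 3:
        raise ValueError("largest component is degenerate")
    verts_cm = pts[ConvexHull(pts).vertices] / px_per_cm
    poly = Polygon(verts_cm)
    if not poly.covers(Point(source_cm)):
        # grow the hull minimally to include the declared source
        verts_cm = np.vstack([verts_cm, np.asarray(source_cm, float)])
        verts_cm = verts_cm[ConvexHull(verts_cm).vertices]
        logger.warning("plume source outside hull; hull extended to include it")
    return PlumePolygon(vertices=verts_cm, source=tuple(source_cm), provenance="variance_projection")


def point_in_polygon(point, polygon) -> bool:
    """Even-odd containment with boundary points counting as inside."""
    poly = polygon.shapely if isinstance(polygon, PlumePolygon) else Polygon(polygon)
    return bool(poly.covers(Point(point)))


# ---------------------------------------------------------------------------
# crossing events


def _interp_circle_crossing(p0, p1, circle: TargetCircle) -> np.ndarray:
    """Exact entry point of segment p0->p1 into a circle (p0 out, p1 in)."""
    c = np.asarray(circle.center, float)
    d = p1 - p0
    f = p0 - c
    a = float(np.dot(d, d))
    b = 2.0 * float(np.dot(f, d))
    cc = float(np.dot(f, f)) - circle.radius**2
    disc = b * b - 4 * a * cc
    disc = max(disc, 0.0)
    t = (-b - np.sqrt(disc)) / (2 * a)  # first intersection along the segment
    t = float(np.clip(t, 0.0, 1.0))
    return p0 + t * d


def _interp_polygon_crossing(p0, p1, poly: Polygon) -> np.ndarray:
    seg = LineString([tuple(p0), tuple(p1)])
    inter = seg.intersection(poly.exterior)
    if inter.is_empty:
        return np.asarray(p1, float)
    if inter.geom_type == "Point":
        return np.array([inter.x, inter.y])
    pts = [g for g in getattr(inter, "geoms", [inter]) if g.geom_type == "Point"]
    if not pts:
        return np.asarray(p1, float)
    # earliest intersection along the travel direction
    best = min(pts, key=lambda g: Point(p0).distance(g))
    return np.array([best.x, best.y])


def first_crossing(
    track: pd.DataFrame,
    region,
    region_id: str,
    frame_rate_hz: float = 10.0,
    reset_s: float = 30.0,
    backcast_s: float = 600.0,
) -> list[CrossingEvent]:
    """First-passage events of the body center into a region.

    One event is emitted per approach.  After an event, a new approach only
    begins once the track has remained outside the region for at least
    ``reset_s`` seconds.  Crossing points are linearly interpolated on the
    boundary-straddling segment (exactly, for the circle).  A track that
    starts inside the region yields an event at its first frame flagged
    ``started_inside``.
    """
    pts = track[["center_x_cm", "center_y_cm"]].to_numpy(dtype=float)
    frames = track["frame"].to_numpy()
    if isinstance(region, TargetCircle):
        inside = region.contains(pts)
    elif isinstance(region, StationRectangle):
        inside = region.contains(pts)
    elif isinstance(region, PlumePolygon):
        poly = region.shapely
        inside = np.array([poly.covers(Point(p)) for p in pts])
    else:
        raise TypeError(f"unsupported region type: {type(region)!r}")

    reset_frames = int(round(reset_s * frame_rate_hz))
    backcast_frames = int(round(backcast_s * frame_rate_hz))
    events: list[CrossingEvent] = []
    armed = True  # ready to record the next entry
    run_outside = 0
    for i in range(len(pts)):
        if inside[i]:
            if armed:
                if i == 0:
                    events.append(
                        CrossingEvent(
                            frame=int(frames[0]),
                            point=tuple(pts[0]),
                            region_id=region_id,
                            started_inside=True,
                            backcast_start_frame=int(frames[0]),
                        )
                    )
                else:
                    if isinstance(region, TargetCircle):
                        cp = _interp_circle_crossing(pts[i - 1], pts[i], region)
                    elif isinstance(region, StationRectangle):
                        cp = _interp_polygon_crossing(pts[i - 1], pts[i], region.polygon)
                    else:
                        cp = _interp_polygon_crossing(pts[i - 1], pts[i], region.shapely)
                    events.append(
                        CrossingEvent(
                            frame=int(frames[i]),
                            point=tuple(cp),
                            region_id=region_id,
                            backcast_start_frame=int(max(frames[0], frames[i] - backcast_frames)),
                        )
                    )
                armed = False
            run_outside = 0
        else:
            run_outside += 1
            if run_outside >= reset_frames:
                armed = True
    return events


def classify_approach(event: CrossingEvent, regions: RegionSet) -> str:
    """Label a crossing event by where it entered.

    Station-rectangle crossings get ``<side>`` or ``<side>:bait`` /
    ``<side>:control`` labels; target-circle crossings get ``inside_plume``
    or ``outside_plume`` by whether the crossing point lies in the plume
    polygon.
    """
    p = np.asarray(event.point, float)
    if event.region_id == "station_rect":
        rect = regions.station_rect
        if rect is None:
            raise ValueError("RegionSet has no station rectangle")
        for seg in rect.external_segments():
            if seg.contains_point(p, tol=1e-6):
                if seg.side == "side":
                    label = "side"
                else:
                    label = f"{seg.side}:{'bait' if seg.bait else 'control'}"
                event.label = label
                event.extras["station"] = seg.station
                return label
        # fall back to the nearest segment if interpolation left the point
        # marginally off the boundary
        segs = rect.external_segments()
        seg = min(segs, key=lambda s: LineString([tuple(s.start), tuple(s.end)]).distance(Point(p)))
        label = "side" if seg.side == "side" else f"{seg.side}:{'bait' if seg.bait else 'control'}"
        event.label = label
        event.extras["station"] = seg.station
        return label
    if event.region_id == "target_circle":
        if regions.plume is None:
            raise ValueError("RegionSet has no plume polygon")
        label = "inside_plume" if point_in_polygon(p, regions.plume) else "outside_plume"
        event.label = label
        return label
    raise ValueError(f"unknown region id: {event.region_id!r}")


# ---------------------------------------------------------------------------
# expected ratios under the perimeter-density null


def expected_ratios(regions: RegionSet, hypothesis: str) -> dict[str, float]:
    """Geometric expected ratios under uniform-per-length crossing density.

    Hypotheses
    ----------
    ``side_partition``
        {against_flow, with_flow, side} shares of the station rectangle's
        external perimeter (3/8, 3/8, 2/8 for the 3x1 rectangle).
    ``stations_given_against_flow`` / ``stations_given_with_flow``
        per-station shares conditional on entry through that long edge
        (1/3 each).
    ``plume_arc``
        {inside_plume, outside_plume} shares of the target-circle
        circumference by overlap with the plume polygon.
    """
    if hypothesis in ("side_partition", "stations_given_against_flow", "stations_given_with_flow"):
        rect = regions.station_rect
        if rect is None:
            raise ValueError("RegionSet has no station rectangle")
        segs = rect.external_segments()
        total = sum(s.length for s in segs)
        if total == 0:
            raise ValueError("zero total perimeter")
        if hypothesis == "side_partition":
            out: dict[str, float] = {}
            for s in segs:
                out[s.side] = out.get(s.side, 0.0) + s.length / total
            return out
        side = "against_flow" if hypothesis.endswith("against_flow") else "with_flow"
        subset = [s for s in segs if s.side == side]
        sub_total = sum(s.length for s in subset)
        if sub_total == 0:
            raise ValueError(f"no {side} segments")
        out = {}
        for s in subset:
            key = "bait" if s.bait else f"control_{s.station}"
            out[key] = out.get(key, 0.0) + s.length / sub_total
        return out
    if hypothesis == "plume_arc":
        circle = regions.target_circle
        if circle is None or regions.plume is None:
            raise ValueError("need target circle and plume polygon")
        ring = Point(circle.center).buffer(circle.radius, quad_segs=720).exterior
        inside_len = ring.intersection(regions.plume.shapely).length
        frac = inside_len / ring.length
        return {"inside_plume": frac, "outside_plume": 1.0 - frac}
    raise ValueError(f"unknown hypothesis: {hypothesis!r}")


# ---------------------------------------------------------------------------
# occupancy


def occupancy_stats(
    track: pd.DataFrame,
    regions: RegionSet,
    active: np.ndarray,
    wall_band_cm: float = 15.0,
    start_hour: float = 0.0,
) -> dict:
    """Region occupancy and hourly activity.

    ``active`` is a per-frame boolean annotation.  Occupancy fractions are
    computed over active frames only; the hourly profile is the fraction of
    frames flagged active within each clock hour (clock = ``start_hour`` +
    elapsed time).
    """
    active = np.asarray(active, dtype=bool)
    if len(active) != len(track):
        raise ValueError("activity flags must align with the track")
    if not active.any():
        raise ValueError("no active frames")
    pts = track[["center_x_cm", "center_y_cm"]].to_numpy(dtype=float)
    L, W = regions.arena_size_cm
    near_wall = (
        (pts[:, 0] <= wall_band_cm)
        | (pts[:, 0] >= L - wall_band_cm)
        | (pts[:, 1] <= wall_band_cm)
        | (pts[:, 1] >= W - wall_band_cm)
    )
    out: dict = {"wall_fraction": float(near_wall[active].mean())}
    if regions.plume is not None:
        poly = regions.plume.shapely
        in_plume = np.array([poly.covers(Point(p)) for p in pts[active]])
        out["plume_fraction"] = float(in_plume.mean())
    hours = (start_hour + track["time_s"].to_numpy(dtype=float) / 3600.0) % 24
    hourly = {}
    for h in np.unique(np.floor(hours).astype(int)):
        sel = np.floor(hours).astype(int) == h
        hourly[int(h)] = float(active[sel].mean())
    out["hourly_activity"] = hourly
    return out
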