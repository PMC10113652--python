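"""Space-time prism (STP) volumes from trip diaries.

A travel prism is the area of the minimum bounding 2-D activity space of a
trip's shortest network route (taken as the convex hull of the route
vertices) times the recorded travel time.  An activity prism is a disc
footprint at the activity location times the dwell duration.  Summing a
person's travel and activity prisms over the survey day gives their total
daily mobility in km²·h; people in the top quarter of totals are the
"large STP" (highly mobile) group.

Degenerate, collinear routes would have a zero-area hull, so they fall back
to a thin ε-buffer around the polyline (ε = 0.01 km by default) — a straight
out-and-back trip still sweeps some corridor of space.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from shapely.geometry import LineString, MultiPoint, Point

from .data_model import (
    PipelineConfig,
    RoadNetwork,
    RoutingError,
    TripRecord,
    ValidationError,
)
from .quantiles import top_fraction_threshold


@dataclass
class DailySTP:
    """Per-person daily space-time prism volumes (km²·h)."""

    person_id: str
    travel_volume: float
    activity_volume: float
    expansion_factor: float
    large_stp: bool = False

    @property
    def total_volume(self) -> float:
        return self.travel_volume + self.activity_volume


def shortest_route(network: RoadNetwork, origin: Sequence[float],
                   destination: Sequence[float]) -> np.ndarray:
    """Shortest network route between two planar points, as a polyline.

    Origin and destination are snapped to their nearest network nodes; the
    straight snap segments are prepended/appended to the minimum-length node
    path.  Returns an (n, 2) array; a degenerate single-point polyline when
    origin equals destination.
    """
    origin = np.asarray(origin, dtype=float)
    destination = np.asarray(destination, dtype=float)
    if np.allclose(origin, destination):
        return origin.reshape(1, 2)
    a = network.snap(origin)
    b = network.snap(destination)
    path, _ = network.shortest_path_nodes(a, b)
    coords = [tuple(origin)] + [network.node_position(n) for n in path] + [tuple(destination)]
    deduped = [coords[0]]
    for c in coords[1:]:
        if not (abs(c[0] - deduped[-1][0]) < 1e-12 and abs(c[1] - deduped[-1][1]) < 1e-12):
            deduped.append(c)
    return np.asarray(deduped, dtype=float)


def route_bounding_area(route: np.ndarray, epsilon: float = 0.01) -> float:
    """Area (km²) of the minimum bounding 2-D space of a route.

    Convex hull of the route vertices; collinear or single-point routes use
    the ε-buffer area of the polyline instead so they are not exactly zero.
    """
    route = np.asarray(route, dtype=float)
    if route.ndim != 2 or route.shape[1] != 2:
        raise ValidationError("route must be an (n, 2) coordinate array")
    hull_area = MultiPoint(route).convex_hull.area if len(route) >= 3 else 0.0
    if hull_area >= math.pi * epsilon**2:
        return float(hull_area)
    geom = Point(route[0]) if len(route) == 1 else LineString(route)
    return float(geom.buffer(epsilon, quad_segs=256).area)


def travel_prism_volume(route: np.ndarray, travel_time: float,
                        epsilon: float = 0.01) -> float:
    """Travel prism volume: bounding area of the route × travel time (km²·h)."""
    if travel_time < 0:
        raise ValidationError(f"travel time must be nonnegative, got {travel_time}")
    if travel_time == 0.0:
        return 0.0
    return route_bounding_area(route, epsilon) * travel_time


def activity_prism_volume(duration: float, footprint_radius: float = 0.1) -> float:
    """Activity prism volume: disc footprint πr² × dwell duration (km²·h)."""
    if duration < 0:
        raise ValidationError(f"duration must be nonnegative, got {duration}")
    if footprint_radius <= 0:
        raise ValidationError("footprint radius must be positive")
    return math.pi * footprint_radius**2 * duration


def daily_stp(trips_of_person: Sequence[TripRecord], network: RoadNetwork,
              cfg: PipelineConfig) -> DailySTP:
    """Sum one person's travel and activity prisms over the survey day.

    Travel time comes straight from the diary (arrive − depart).  Activity
    durations are the inter-trip dwells at each destination; the last dwell
    is closed at 24:00 unless the final destination is home — dwells at home
    contribute nothing, only out-of-home activity counts.
    """
    trips = list(trips_of_person)
    if not trips:
        return DailySTP(person_id="", travel_volume=0.0, activity_volume=0.0,
                        expansion_factor=1.0)
    indices = [t.trip_index for t in trips]
    if indices != sorted(indices):
        raise ValidationError(
            f"person {trips[0].person_id}: trips not sorted by trip_index")
    for prev, nxt in zip(trips[:-1], trips[1:]):
        if nxt.depart_time < prev.arrive_time - 1e-9:
            raise ValidationError(
                f"person {trips[0].person_id}: trips {prev.trip_index} and "
                f"{nxt.trip_index} overlap in time")
    travel = 0.0
    activity = 0.0
    for i, trip in enumerate(trips):
        trip.validate()
        try:
            route = shortest_route(network, trip.origin, trip.destination)
        except RoutingError as err:
            raise RoutingError(
                f"person {trip.person_id}, trip {trip.trip_index}: {err}") from err
        travel += travel_prism_volume(route, trip.arrive_time - trip.depart_time,
                                      cfg.route_buffer_epsilon)
        if trip.purpose == "home":
            continue
        if i + 1 < len(trips):
            dwell = trips[i + 1].depart_time - trip.arrive_time
        else:
            dwell = 24.0 - trip.arrive_time
        activity += activity_prism_volume(max(dwell, 0.0),
                                          cfg.activity_footprint_radius)
    return DailySTP(person_id=trips[0].person_id, travel_volume=travel,
                    activity_volume=activity,
                    expansion_factor=trips[0].expansion_factor)


def compute_daily_stps(trips: Sequence[TripRecord], network: RoadNetwork,
                       cfg: PipelineConfig) -> list[DailySTP]:
    """Daily STP for every person appearing in the trip table."""
    by_person: dict[str, list[TripRecord]] = {}
    for t in trips:
        by_person.setdefault(t.person_id, []).append(t)
    out = []
    for pid in sorted(by_person):
        person_trips = sorted(by_person[pid], key=lambda t: t.trip_index)
        out.append(daily_stp(person_trips, network, cfg))
    return out


def flag_large_stp(population: Sequence[DailySTP],
                   mobility_quantile: float = 0.25) -> list[DailySTP]:
    """Flag the expansion-weighted top fraction of daily totals as large-STP.

    The threshold is the weighted (1−q) quantile of total volumes with
    expansion factors as frequency weights; everyone at or above the
    threshold is flagged (ties are included).
    """
    if not population:
        raise ValidationError("cannot flag an empty population")
    if not 0.0 < mobility_quantile < 1.0:
        raise ValidationError("mobility_quantile must be in (0, 1)")
    totals = [s.total_volume for s in population]
    weights = [s.expansion_factor for s in population]
    threshold = top_fraction_threshold(totals, mobility_quantile, weights)
    return [dataclasses.replace(s, large_stp=s.total_volume >= threshold)
            for s in population]


def write_stp_table(stps: Sequence[DailySTP], path) -> None:
    import pandas as pd

    pd.DataFrame([
        {"person_id": s.person_id, "travel_volume": s.travel_volume,
         "activity_volume": s.activity_volume, "total_volume": s.total_volume,
         "expansion_factor": s.expansion_factor, "large_stp": s.large_stp}
        for s in stps
    ]).to_csv(path, index=False)
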