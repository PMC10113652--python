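"""Domain types, configuration and file formats shared by all pipeline stages.

All geometry is planar and expressed in kilometres in a single projected
system, so that space-time volumes come out directly in km²·h.  Readers
refuse coordinates that look like raw longitude/latitude unless the file
carries an explicit projection directive (``"crs_units": "km"``), because
every downstream quantity assumes planar km.

Times are decimal hours within a single survey day; overnight trips are
clipped at 24 h with a logged warning (diaries cover one day).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon, mapping, shape
from shapely.strtree import STRtree

log = logging.getLogger(__name__)

#: The six facility types analysed throughout.
FACILITY_TYPES = ("bar", "cinema", "gym", "worship", "library", "mall")

#: Fixed trip-purpose → facility-type map used for visitor matching.
PURPOSE_TO_TYPE = {
    "eat_drink": "bar",
    "leisure": "cinema",
    "exercise": "gym",
    "worship": "worship",
    "study": "library",
    "shop": "mall",
}
TYPE_TO_PURPOSE = {v: k for k, v in PURPOSE_TO_TYPE.items()}

#: Closed vocabulary of trip purposes.
PURPOSES = tuple(PURPOSE_TO_TYPE) + ("work", "home")

TRIP_COLUMNS = (
    "person_id",
    "trip_index",
    "ox",
    "oy",
    "dx",
    "dy",
    "depart",
    "arrive",
    "purpose",
    "mode",
    "expansion_factor",
)


class SeRiskError(Exception):
    """Base class for package errors."""


class FormatError(SeRiskError):
    """An input file does not conform to the expected format."""


class ValidationError(SeRiskError):
    """A value violates a domain invariant."""


class RoutingError(SeRiskError):
    """No route could be found on the road network."""


class StageError(SeRiskError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TripRecord:
    """One origin-destination diary row of one person.

    Coordinates are planar km; times are decimal hours of the survey day.
    ``expansion_factor`` is the survey weight scaling the respondent to the
    population they represent.
    """

    person_id: str
    trip_index: int
    origin: tuple[float, float]
    destination: tuple[float, float]
    depart_time: float
    arrive_time: float
    purpose: str
    mode: str = ""
    expansion_factor: float = 1.0
    outside_boundary: bool = False

    def validate(self) -> "TripRecord":
        if self.arrive_time < self.depart_time:
            raise ValidationError(
                f"trip {self.person_id}/{self.trip_index}: arrive before depart"
            )
        if not self.expansion_factor > 0:
            raise ValidationError(
                f"trip {self.person_id}/{self.trip_index}: expansion_factor must be > 0"
            )
        if self.purpose not in PURPOSES:
            raise ValidationError(
                f"trip {self.person_id}/{self.trip_index}: unknown purpose "
                f"{self.purpose!r} (allowed: {', '.join(PURPOSES)})"
            )
        return self


@dataclass
class PoIRecord:
    """A facility point with one of the six facility types."""

    poi_id: str
    facility_type: str
    location: tuple[float, float]
    census_unit_id: str | None = None

    def validate(self) -> "PoIRecord":
        if self.facility_type not in FACILITY_TYPES:
            raise ValidationError(
                f"PoI {self.poi_id}: facility_type {self.facility_type!r} "
                f"not one of {FACILITY_TYPES}"
            )
        return self


@dataclass
class CensusUnit:
    """A census polygon with resident population; density is derived."""

    unit_id: str
    polygon: Polygon
    population: float

    @property
    def density(self) -> float:
        """Population per km²."""
        return self.population / self.polygon.area


class RoadNetwork:
    """Planar road network: nodes with km positions, edges with lengths.

    Routing is restricted to the largest connected component.  Shortest
    paths are served from a cached all-pairs predecessor matrix
    (scipy.sparse.csgraph), which is far cheaper than per-query searches at
    travel-diary volumes.
    """

    def __init__(self, graph: nx.Graph):
        if graph.number_of_nodes() == 0:
            raise ValidationError("road network has no nodes")
        components = list(nx.connected_components(graph))
        largest = max(components, key=len)
        if len(components) > 1:
            log.warning(
                "road network has %d components; routing restricted to the "
                "largest (%d of %d nodes)",
                len(components), len(largest), graph.number_of_nodes(),
            )
        self.graph = graph
        # canonical spatial ordering: route tie-breaking must not depend on
        # how nodes happen to be labelled (grid indices vs file order)
        self._nodes = sorted(largest, key=lambda n: tuple(graph.nodes[n]["pos"]))
        self._index = {n: i for i, n in enumerate(self._nodes)}
        self._coords = np.array(
            [graph.nodes[n]["pos"] for n in self._nodes], dtype=float
        )
        for u, v, data in graph.edges(data=True):
            d = math.dist(graph.nodes[u]["pos"], graph.nodes[v]["pos"])
            if data["length"] < d - 1e-9:
                raise ValidationError(
                    f"edge {u}-{v}: length {data['length']} shorter than "
                    f"straight-line distance {d}"
                )
        self._kdtree: cKDTree | None = None
        self._dist: np.ndarray | None = None
        self._pred: np.ndarray | None = None

    @property
    def nodes(self) -> list:
        return list(self._nodes)

    @property
    def coords(self) -> np.ndarray:
        return self._coords

    def node_position(self, node) -> tuple[float, float]:
        return tuple(self.graph.nodes[node]["pos"])

    def snap(self, point: Sequence[float]):
        """Nearest routable node to a planar point."""
        if self._kdtree is None:
            self._kdtree = cKDTree(self._coords)
        _, i = self._kdtree.query(np.asarray(point, dtype=float))
        return self._nodes[int(i)]

    def _ensure_paths(self) -> None:
        if self._dist is not None:
            return
        n = len(self._nodes)
        rows, cols, vals = [], [], []
        for u, v, data in self.graph.edges(data=True):
            if u not in self._index or v not in self._index:
                continue
            i, j = self._index[u], self._index[v]
            rows += [i, j]
            cols += [j, i]
            vals += [data["length"], data["length"]]
        adj = csr_matrix((vals, (rows, cols)), shape=(n, n))
        self._dist, self._pred = shortest_path(
            adj, method="D", directed=False, return_predecessors=True
        )

    def shortest_path_nodes(self, source, target) -> tuple[list, float]:
        """Minimum-length node path and its length (km)."""
        if source not in self._index or target not in self._index:
            raise RoutingError(f"node off the routable component: {source} or {target}")
        self._ensure_paths()
        i, j = self._index[source], self._index[target]
        if i == j:
            return [source], 0.0
        if not np.isfinite(self._dist[i, j]):
            raise RoutingError(f"no path between {source} and {target}")
        path = [j]
        while path[-1] != i:
            path.append(int(self._pred[i, path[-1]]))
        return [self._nodes[k] for k in reversed(path)], float(self._dist[i, j])


@dataclass
class CityBundle:
    """Everything one city analysis needs, in one projected km system."""

    trips: list[TripRecord]
    pois: list[PoIRecord]
    units: list[CensusUnit]
    network: RoadNetwork
    boundary: Polygon


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def _default_psr_weights() -> dict[int, float]:
    return {1: 1000.0, 2: 100.0, 3: 10.0, 4: 1.0}


def _default_activity_weights() -> dict[str, float]:
    return {"bar": 5.0, "cinema": 5.0, "gym": 5.0, "worship": 4.0, "mall": 3.0, "library": 2.0}


@dataclass
class PipelineConfig:
    """Tunable parameters of the whole pipeline.

    Quantiles are top-fractions: ``agglomeration_quantile=0.25`` flags the
    quarter of each facility type with the smallest Thiessen cells;
    0.125 is the stricter robustness alternative.  PSR classes are weighted
    exponentially (Class 1 → 1000 … Class 4 → 1) and facility types by
    activity riskiness (bars/cinemas/gyms 5, worship 4, malls 3, libraries 2).
    """

    agglomeration_quantile: float = 0.25
    mobility_quantile: float = 0.25
    density_quantile: float = 0.25
    alpha: float = 0.05
    psr_weights: dict[int, float] = field(default_factory=_default_psr_weights)
    activity_weights: dict[str, float] = field(default_factory=_default_activity_weights)
    kde_bandwidth: float = 1.0  # km
    kde_cell_size: float = 0.1  # km
    activity_footprint_radius: float = 0.1  # km
    route_buffer_epsilon: float = 0.01  # km, degenerate-route fallback
    pooled_variance: bool = False
    bonferroni: bool = False
    density_weighted_kde: bool = False
    random_seed: int = 0


def validate_config(cfg: PipelineConfig | Mapping | None = None) -> PipelineConfig:
    """Fill defaults and enforce the config invariants."""
    if cfg is None:
        cfg = PipelineConfig()
    elif isinstance(cfg, Mapping):
        unknown = set(cfg) - {f.name for f in dataclasses.fields(PipelineConfig)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = PipelineConfig(**cfg)
    for name in ("agglomeration_quantile", "mobility_quantile", "density_quantile", "alpha"):
        v = getattr(cfg, name)
        if not (0.0 < v < 1.0):
            raise ValidationError(f"{name} must be in (0, 1), got {v}")
    cfg.psr_weights = {int(k): float(v) for k, v in cfg.psr_weights.items()}
    cfg.activity_weights = {k: float(v) for k, v in cfg.activity_weights.items()}
    for k, v in {**cfg.psr_weights, **cfg.activity_weights}.items():
        if not v > 0:
            raise ValidationError(f"weight for {k!r} must be positive, got {v}")
    for name in ("kde_bandwidth", "kde_cell_size", "activity_footprint_radius",
                 "route_buffer_epsilon"):
        if not getattr(cfg, name) > 0:
            raise ValidationError(f"{name} must be positive")
    return cfg


def read_config(path: str | Path) -> PipelineConfig:
    """Read a key:value (YAML) config file and validate it."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise FormatError(f"{path}: expected a key:value mapping")
    return validate_config(data)


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# point-in-unit assignment
# ---------------------------------------------------------------------------


class UnitIndex:
    """Spatial index over census units with a deterministic tie rule.

    A point on a shared unit boundary is assigned to the unit whose
    ``unit_id`` sorts first, so assignment does not depend on the geometry
    backend's edge conventions.
    """

    def __init__(self, units: Sequence[CensusUnit]):
        self.units = list(units)
        self._tree = STRtree([u.polygon for u in self.units])

    def locate(self, point: Sequence[float]) -> CensusUnit | None:
        p = Point(point)
        hits = [
            self.units[i]
            for i in self._tree.query(p, predicate="intersects")
            if self.units[i].polygon.covers(p)
        ]
        if not hits:
            return None
        return min(hits, key=lambda u: u.unit_id)


def check_partition(units: Sequence[CensusUnit], boundary: Polygon,
                    tol_overlap: float = 1e-6, tol_union: float = 1e-6) -> None:
    """Reject unit sets that overlap or fail to cover the boundary."""
    tree = STRtree([u.polygon for u in units])
    for i, u in enumerate(units):
        for j in tree.query(u.polygon, predicate="intersects"):
            if j <= i:
                continue
            inter = u.polygon.intersection(units[j].polygon).area
            if inter > tol_overlap:
                raise ValidationError(
                    f"census units {u.unit_id} and {units[j].unit_id} overlap "
                    f"by {inter:g} km²"
                )
    total = sum(u.polygon.area for u in units)
    if abs(total - boundary.area) > tol_union * max(boundary.area, 1.0):
        raise ValidationError(
            f"census units cover {total:g} km² but the boundary is "
            f"{boundary.area:g} km²"
        )


def assign_census_units(pois: Sequence[PoIRecord],
                        units: Sequence[CensusUnit]) -> list[PoIRecord]:
    """Attach ``census_unit_id`` to every PoI (deterministic tie rule)."""
    index = UnitIndex(units)
    out = []
    for poi in pois:
        unit = index.locate(poi.location)
        out.append(dataclasses.replace(
            poi, census_unit_id=None if unit is None else unit.unit_id))
    return out


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_KM_DIRECTIVE = "crs_units"


def _coords_look_geographic(coords: np.ndarray) -> bool:
    if coords.size == 0:
        return False
    x, y = coords[:, 0], coords[:, 1]
    return bool((np.abs(x) <= 180).all() and (np.abs(y) <= 90).all())


def _check_projected(obj: Mapping, coords: np.ndarray, path) -> None:
    if obj.get(_KM_DIRECTIVE) == "km":
        return
    if _coords_look_geographic(coords):
        raise FormatError(
            f"{path}: coordinates look like raw lon/lat and the file carries "
            f'no projection directive; supply planar km coordinates with '
            f'"{_KM_DIRECTIVE}": "km" at the top level'
        )


def _all_coords(geojson: Mapping) -> np.ndarray:
    pts: list[Sequence[float]] = []

    def walk(c):
        if isinstance(c, (list, tuple)):
            if c and isinstance(c[0], (int, float)):
                pts.append(c[:2])
            else:
                for sub in c:
                    walk(sub)

    for feat in geojson.get("features", []):
        walk(feat.get("geometry", {}).get("coordinates", []))
    return np.array(pts, dtype=float) if pts else np.empty((0, 2))


def _load_geojson(path: str | Path) -> Mapping:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    _check_projected(gj, _all_coords(gj), path)
    return gj


def read_trips(path: str | Path) -> list[TripRecord]:
    """Read a trips CSV (one row per origin-destination record)."""
    df = pd.read_csv(path, dtype={"person_id": str, "mode": str},
                     float_precision="round_trip")
    required = [c for c in TRIP_COLUMNS if c != "mode"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if "mode" not in df.columns:
        df["mode"] = ""
    trips = []
    clipped = 0
    for row in df.itertuples(index=False):
        depart, arrive = float(row.depart), float(row.arrive)
        if arrive > 24.0 or depart > 24.0:
            clipped += 1
            depart, arrive = min(depart, 24.0), min(arrive, 24.0)
        trips.append(TripRecord(
            person_id=str(row.person_id),
            trip_index=int(row.trip_index),
            origin=(float(row.ox), float(row.oy)),
            destination=(float(row.dx), float(row.dy)),
            depart_time=depart,
            arrive_time=arrive,
            purpose=str(row.purpose),
            mode="" if pd.isna(row.mode) else str(row.mode),
            expansion_factor=float(row.expansion_factor),
        ).validate())
    if clipped:
        log.warning("%s: clipped %d overnight trip(s) at 24 h", path, clipped)
    return trips


def write_trips(trips: Iterable[TripRecord], path: str | Path) -> None:
    rows = [
        {
            "person_id": t.person_id, "trip_index": t.trip_index,
            "ox": t.origin[0], "oy": t.origin[1],
            "dx": t.destination[0], "dy": t.destination[1],
            "depart": t.depart_time, "arrive": t.arrive_time,
            "purpose": t.purpose, "mode": t.mode,
            "expansion_factor": t.expansion_factor,
        }
        for t in trips
    ]
    # %.17g round-trips float64 exactly: a written bundle reruns identically
    pd.DataFrame(rows, columns=list(TRIP_COLUMNS)).to_csv(
        path, index=False, float_format="%.17g")


def read_pois(path: str | Path) -> list[PoIRecord]:
    gj = _load_geojson(path)
    pois = []
    for feat in gj["features"]:
        geom = shape(feat["geometry"])
        props = feat.get("properties", {})
        for key in ("poi_id", "facility_type"):
            if key not in props:
                raise FormatError(f"{path}: PoI feature missing property {key!r}")
        pois.append(PoIRecord(
            poi_id=str(props["poi_id"]),
            facility_type=str(props["facility_type"]),
            location=(geom.x, geom.y),
            census_unit_id=(str(props["census_unit_id"])
                            if props.get("census_unit_id") is not None else None),
        ).validate())
    return pois


def write_pois(pois: Iterable[PoIRecord], path: str | Path,
               extra: Mapping[str, Mapping] | None = None) -> None:
    """Write PoIs as GeoJSON; ``extra`` maps poi_id → extra properties."""
    features = []
    for p in pois:
        props = {"poi_id": p.poi_id, "facility_type": p.facility_type,
                 "census_unit_id": p.census_unit_id}
        if extra and p.poi_id in extra:
            props.update(extra[p.poi_id])
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": list(p.location)},
            "properties": props,
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", _KM_DIRECTIVE: "km",
                   "features": features}, fh)


def read_census_units(path: str | Path) -> list[CensusUnit]:
    gj = _load_geojson(path)
    units = []
    for feat in gj["features"]:
        props = feat.get("properties", {})
        for key in ("unit_id", "population"):
            if key not in props:
                raise FormatError(f"{path}: census feature missing property {key!r}")
        poly = shape(feat["geometry"])
        if poly.geom_type not in ("Polygon", "MultiPolygon"):
            raise FormatError(f"{path}: census geometry must be polygonal")
        pop = float(props["population"])
        if pop < 0:
            raise ValidationError(f"unit {props['unit_id']}: negative population")
        units.append(CensusUnit(unit_id=str(props["unit_id"]), polygon=poly,
                                population=pop))
    return units


def write_census_units(units: Iterable[CensusUnit], path: str | Path) -> None:
    features = [{
        "type": "Feature",
        "geometry": mapping(u.polygon),
        "properties": {"unit_id": u.unit_id, "population": u.population},
    } for u in units]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", _KM_DIRECTIVE: "km",
                   "features": features}, fh)


def read_boundary(path: str | Path) -> Polygon:
    gj = _load_geojson(path)
    for feat in gj["features"]:
        geom = shape(feat["geometry"])
        if geom.geom_type in ("Polygon", "MultiPolygon"):
            return geom
    raise FormatError(f"{path}: no polygon feature found")


def write_boundary(boundary: Polygon, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", _KM_DIRECTIVE: "km",
                   "features": [{"type": "Feature", "geometry": mapping(boundary),
                                 "properties": {}}]}, fh)


def read_network(path: str | Path, nodes_path: str | Path | None = None) -> RoadNetwork:
    """Read a road network from GeoJSON LineStrings or a CSV edge list.

    The CSV form (node_a,node_b,length_km[,time_h]) needs a companion nodes
    table (node_id,x,y) giving planar km positions.
    """
    path = Path(path)
    graph = nx.Graph()
    if path.suffix.lower() in (".geojson", ".json"):
        gj = _load_geojson(path)
        for feat in gj["features"]:
            geom = shape(feat["geometry"])
            if geom.geom_type != "LineString":
                continue
            coords = list(geom.coords)
            props = feat.get("properties", {})
            for a, b in zip(coords[:-1], coords[1:]):
                na, nb = (round(a[0], 9), round(a[1], 9)), (round(b[0], 9), round(b[1], 9))
                graph.add_node(na, pos=na)
                graph.add_node(nb, pos=nb)
                graph.add_edge(na, nb, length=math.dist(na, nb),
                               time=props.get("time_h"))
    else:
        if nodes_path is None:
            raise FormatError(
                f"{path}: a CSV edge list needs a nodes table (node_id,x,y) "
                "for planar km positions"
            )
        nodes = pd.read_csv(nodes_path, dtype={"node_id": str})
        for col in ("node_id", "x", "y"):
            if col not in nodes.columns:
                raise FormatError(f"{nodes_path}: missing required column(s) ['{col}']")
        edges = pd.read_csv(path, dtype={"node_a": str, "node_b": str})
        for col in ("node_a", "node_b", "length_km"):
            if col not in edges.columns:
                raise FormatError(f"{path}: missing required column(s) ['{col}']")
        for row in nodes.itertuples(index=False):
            graph.add_node(str(row.node_id), pos=(float(row.x), float(row.y)))
        for row in edges.itertuples(index=False):
            graph.add_edge(str(row.node_a), str(row.node_b),
                           length=float(row.length_km),
                           time=float(row.time_h) if hasattr(row, "time_h") else None)
    return RoadNetwork(graph)


def write_network(network: RoadNetwork, path: str | Path) -> None:
    features = []
    for u, v, data in network.graph.edges(data=True):
        pu = network.graph.nodes[u]["pos"]
        pv = network.graph.nodes[v]["pos"]
        features.append({
            "type": "Feature",
            "geometry": {"type": "LineString", "coordinates": [list(pu), list(pv)]},
            "properties": {"length_km": data["length"], "time_h": data.get("time")},
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", _KM_DIRECTIVE: "km",
                   "features": features}, fh)


def read_city_bundle(trips_path, pois_path, units_path, network_path,
                     boundary_path, network_nodes_path=None) -> CityBundle:
    """Load and cross-link a full city bundle.

    Every PoI gets the census unit containing it; trips whose endpoints fall
    outside the boundary are flagged (``outside_boundary``), not dropped.
    """
    trips = read_trips(trips_path)
    pois = read_pois(pois_path)
    units = read_census_units(units_path)
    network = read_network(network_path, network_nodes_path)
    boundary = read_boundary(boundary_path)
    check_partition(units, boundary)
    pois = assign_census_units(pois, units)
    flagged = 0
    for t in trips:
        if not (boundary.covers(Point(t.origin)) and boundary.covers(Point(t.destination))):
            t.outside_boundary = True
            flagged += 1
    if flagged:
        log.warning("%d trip(s) have endpoints outside the boundary", flagged)
    return CityBundle(trips=trips, pois=pois, units=units, network=network,
                      boundary=boundary)
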