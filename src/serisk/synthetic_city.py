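"""Synthetic city generator with plantable ground truth.

The real inputs of this kind — municipal travel-diary surveys — are
license-restricted, so the generator builds a complete stand-in city bundle
with the same trip-based structure: a grid road network, Voronoi census
units with log-normal populations, six facility types placed clustered
(bars) or dispersed (the rest), and one-day person diaries whose trip rows
carry purposes, times and expansion factors.

Ground truth is planted on the *person mobility scale*, not on STP
directly: persons whose anchor facility is in the "risky" agglomeration
state for its type (high agglomeration for bars, low for the others) get a
d·σ boost to their log mobility scale.  Recovering the planted Group A/B
pattern therefore exercises the full prism engine, not just the test.

Seeding is hierarchical: one root seed spawns an independent child stream
per sub-generator, so changing, say, PoI counts does not perturb the
diaries.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from shapely.geometry import MultiPoint, Point, Polygon, box
from shapely.ops import voronoi_diagram

from . import agglomeration
from .data_model import (
    FACILITY_TYPES,
    TYPE_TO_PURPOSE,
    CensusUnit,
    CityBundle,
    PipelineConfig,
    PoIRecord,
    RoadNetwork,
    TripRecord,
    ValidationError,
)


def _default_poi_counts() -> dict[str, int]:
    return {"bar": 48, "worship": 36, "gym": 30, "cinema": 16, "library": 16,
            "mall": 12}


def _default_clustering() -> dict[str, str]:
    return {"bar": "mixed", "cinema": "dispersed", "gym": "dispersed",
            "worship": "dispersed", "library": "dispersed", "mall": "dispersed"}


@dataclass
class ScenarioConfig:
    """Study conditions of the default synthetic city.

    A 14×14 km city with a 0.5 km street grid and 140 census units; homes
    and facilities occupy the built-up interior (the outer 2.5–3.5 km band
    is the fringe).  3,000 surveyed persons is in the range of real
    travel-diary samples.  Bars are "mixed" — a quarter in tight districts
    (Matérn clusters, 0.3 km offsets), the rest standalone — which gives
    the type two genuinely distinct agglomeration states; the other five
    types are dispersed by inhibition.  Person mobility scales are
    winsorized log-normal (median ≈ 1.1 km, σ = 0.35 on the log scale,
    capped at +2σ), giving daily STP distributions with the heavy right
    tail survey data show, and the planted agglomeration–mobility effect
    is d = 1 log-σ.
    """

    extent_km: tuple[float, float] = (14.0, 14.0)
    spacing_km: float = 0.5
    n_units: int = 140
    home_margin_km: float = 3.5
    pop_lognormal: tuple[float, float] = (8.0, 0.6)
    poi_counts: dict[str, int] = field(default_factory=_default_poi_counts)
    clustering: dict[str, str] = field(default_factory=_default_clustering)
    cluster_sd_km: float = 0.3
    cluster_fraction: float = 0.25
    poi_margin_km: float = 2.5
    n_persons: int = 3000
    effect_size: float = 1.0
    mobility_lognormal: tuple[float, float] = (math.log(1.1), 0.35)
    attraction_range_km: float = 1.0
    trip_speed_kmh: float = 15.0
    seed: int = 0


@dataclass
class ScenarioTruth:
    """What the generator planted, for recovery scoring downstream."""

    expected_group: dict[str, str]
    planted_class1_pois: frozenset[str]
    risky_poi_ids: frozenset[str]
    effect_size: float
    n_persons: int
    seed: int
    top_density_units: frozenset[str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "expected_group": self.expected_group,
                "planted_class1_pois": sorted(self.planted_class1_pois),
                "risky_poi_ids": sorted(self.risky_poi_ids),
                "effect_size": self.effect_size,
                "n_persons": self.n_persons,
                "seed": self.seed,
                "top_density_units": sorted(self.top_density_units),
            }, fh, indent=1)


# ---------------------------------------------------------------------------
# sub-generators
# ---------------------------------------------------------------------------


def generate_network(extent_km: tuple[float, float], spacing_km: float,
                     seed: int = 0) -> RoadNetwork:
    """Planar grid street network; every edge is one ``spacing_km`` segment."""
    if spacing_km <= 0:
        raise ValidationError("spacing must be positive")
    wx, wy = extent_km
    nx_cells = wx / spacing_km
    ny_cells = wy / spacing_km
    if abs(nx_cells - round(nx_cells)) > 1e-9 or abs(ny_cells - round(ny_cells)) > 1e-9:
        raise ValidationError("spacing must divide both extents")
    g = nx.grid_2d_graph(int(round(nx_cells)) + 1, int(round(ny_cells)) + 1)
    out = nx.Graph()
    for (i, j) in g.nodes:
        out.add_node((i, j), pos=(i * spacing_km, j * spacing_km))
    for u, v in g.edges:
        out.add_edge(u, v, length=spacing_km)
    return RoadNetwork(out)


def _uniform_in(boundary: Polygon, rng: np.random.Generator,
                n: int) -> np.ndarray:
    minx, miny, maxx, maxy = boundary.bounds
    pts = []
    while len(pts) < n:
        cand = rng.uniform((minx, miny), (maxx, maxy), size=(max(n, 16), 2))
        import shapely
        keep = shapely.intersects_xy(boundary, cand[:, 0], cand[:, 1])
        pts.extend(map(tuple, cand[keep]))
    return np.array(pts[:n])


def generate_census_units(boundary: Polygon, n_units: int,
                          pop_lognormal: tuple[float, float],
                          seed: int = 0) -> list[CensusUnit]:
    """Voronoi partition of seeded centers with log-normal populations."""
    if n_units < 1:
        raise ValidationError("need at least one census unit")
    rng = np.random.default_rng(seed)
    mu, sigma = pop_lognormal
    if n_units == 1:
        pop = float(np.round(rng.lognormal(mu, sigma))) if sigma > 0 else math.exp(mu)
        return [CensusUnit("u0000", boundary, pop)]
    centers = _uniform_in(boundary, rng, n_units)
    span = max(boundary.bounds[2] - boundary.bounds[0],
               boundary.bounds[3] - boundary.bounds[1])
    cells = voronoi_diagram(MultiPoint(centers.tolist()),
                            envelope=boundary.buffer(2 * span).envelope)
    pops = np.exp(rng.normal(mu, sigma, size=n_units)) if sigma > 0 \
        else np.full(n_units, math.exp(mu))
    units = []
    remaining = list(cells.geoms)
    for i, c in enumerate(centers):
        pt = Point(c)
        hit = next((j for j, cell in enumerate(remaining) if cell.covers(pt)),
                   None)
        if hit is None:
            hit = min(range(len(remaining)),
                      key=lambda j: remaining[j].distance(pt))
        poly = remaining.pop(hit).intersection(boundary)
        units.append(CensusUnit(unit_id=f"u{i:04d}", polygon=poly,
                                population=float(pops[i])))
    total = sum(u.polygon.area for u in units)
    if not math.isclose(total, boundary.area, rel_tol=1e-6):
        raise ValidationError("census units do not partition the boundary")
    return units


def place_pois(boundary: Polygon, counts: Mapping[str, int],
               clustering: Mapping[str, str], cluster_sd_km: float = 0.3,
               cluster_fraction: float = 0.25, seed: int = 0) -> list[PoIRecord]:
    """Place PoIs of each type by its spatial regime.

    ``clustered``: all points from a Matérn-style cluster process (parent
    centers plus Gaussian offsets).  ``dispersed``: sequential inhibition
    (minimum-distance thinning).  ``mixed``: a ``cluster_fraction`` of the
    points in tight clusters — the city's facility districts — and the rest
    dispersed, which is what gives a type two genuinely distinct
    agglomeration states.
    """
    rng = np.random.default_rng(seed)
    pois = []
    for ftype in sorted(counts):
        n = counts[ftype]
        if n < 1:
            raise ValidationError(f"count for {ftype!r} must be positive")
        mode = clustering.get(ftype, "dispersed")
        if mode == "clustered" and n > 1:
            pts = _matern_cluster(boundary, n, cluster_sd_km, rng)
        elif mode == "mixed" and n > 3:
            n_clustered = math.ceil(cluster_fraction * n)
            clustered = _matern_cluster(boundary, n_clustered, cluster_sd_km,
                                        rng, n_parents=max(1, n_clustered // 6))
            dispersed = _inhibition(boundary, n - n_clustered, rng)
            pts = np.vstack([clustered, dispersed])
        else:
            pts = _inhibition(boundary, n, rng)
        for k, (x, y) in enumerate(pts):
            pois.append(PoIRecord(poi_id=f"{ftype}{k:04d}", facility_type=ftype,
                                  location=(float(x), float(y))).validate())
    return pois


def _matern_cluster(boundary: Polygon, n: int, sd: float,
                    rng: np.random.Generator,
                    n_parents: int | None = None) -> np.ndarray:
    import shapely
    if n_parents is None:
        n_parents = max(1, n // 8)
    parents = _uniform_in(boundary, rng, n_parents)
    pts = []
    while len(pts) < n:
        parent = parents[rng.integers(n_parents)]
        cand = parent + rng.normal(scale=sd, size=2)
        if shapely.intersects_xy(boundary, cand[0], cand[1]):
            pts.append(cand)
    return np.array(pts)


def _inhibition(boundary: Polygon, n: int, rng: np.random.Generator,
                max_tries_per_point: int = 200,
                d_min: float | None = None) -> np.ndarray:
    """Sequential inhibition: uniform candidates thinned by a minimum distance."""
    if d_min is None:
        d_min = 0.7 * math.sqrt(boundary.area / n)
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        cand = _uniform_in(boundary, rng, 1)[0]
        if all(np.hypot(*(cand - p)) >= d_min for p in pts):
            pts.append(cand)
            tries = 0
        else:
            tries += 1
            if tries > max_tries_per_point:
                raise ValidationError(
                    f"inhibition distance {d_min:g} km infeasible for {n} points")
    return np.array(pts)


def generate_travel_diaries(pois: Sequence[PoIRecord],
                            units: Sequence[CensusUnit],
                            network: RoadNetwork,
                            n_persons: int,
                            boundary: Polygon,
                            risky_poi_ids: frozenset[str] = frozenset(),
                            effect_size: float = 0.0,
                            mobility_lognormal: tuple[float, float] = (math.log(1.1), 0.35),
                            attraction_range_km: float = 1.0,
                            home_margin_km: float = 3.5,
                            trip_speed_kmh: float = 15.0,
                            seed: int = 0) -> list[TripRecord]:
    """One-day diaries: home → work stops → one facility visit → home.

    Each person anchors on one PoI: a facility type drawn uniformly, then a
    PoI of that type by a gravity rule (probability ∝ exp(−d/range), so
    nearby facilities — and agglomerations of them — attract more visitors),
    reporting the matching trip purpose there.  Work-excursion distances
    scale with the person's log-normal mobility scale; anchoring on a
    risky-state PoI adds ``effect_size`` log-σ to that scale.  The facility
    choice itself never depends on the mobility scale, so the planted effect
    is a clean difference between visitor cohorts.
    """
    if n_persons < 1:
        raise ValidationError("need at least one person")
    rng = np.random.default_rng(seed)
    mu_s, sigma_s = mobility_lognormal
    by_type: dict[str, list[PoIRecord]] = {}
    for p in pois:
        by_type.setdefault(p.facility_type, []).append(p)
    types = sorted(by_type)
    if not types:
        raise ValidationError("no PoIs to visit")
    type_locs = {t: np.array([p.location for p in by_type[t]]) for t in types}
    minx, miny, maxx, maxy = boundary.bounds
    import shapely

    # homes come from an inner residential belt so daily excursions are not
    # systematically clipped by the city edge
    residential = boundary.buffer(-home_margin_km)
    if residential.is_empty or residential.area < 1e-6:
        residential = boundary

    trips: list[TripRecord] = []
    for k in range(n_persons):
        pid = f"p{k:05d}"
        home = _uniform_in(residential, rng, 1)[0]
        ftype = types[rng.integers(len(types))]
        dists = np.hypot(*(type_locs[ftype] - home).T)
        attract = np.exp(-dists / attraction_range_km)
        attract /= attract.sum()
        target = by_type[ftype][int(rng.choice(len(attract), p=attract))]
        boost = sigma_s * effect_size if target.poi_id in risky_poi_ids else 0.0
        # winsorized log-normal draw: the cap sits at +2σ in z-space for
        # everyone, so the planted boost survives in the upper tail
        z = float(np.clip(rng.normal(), -3.0, 2.0))
        s = math.exp(mu_s + sigma_s * z + boost)
        ef = float(np.exp(rng.normal(0.4, 0.3)))
        stops: list[tuple[np.ndarray, str]] = []
        for mult in (1.5, 2.0, 2.5):  # three work excursions per day
            # excursion distance rides on the person's mobility scale; the
            # direction avoids the axes so the route's bounding space cannot
            # degenerate; excursions pointing off the map are shortened, not
            # redrawn, so the scale→distance link survives near the boundary
            ang = (math.pi / 2) * rng.integers(4) + rng.uniform(0.35, 1.22)
            dist = s * mult
            direction = np.array([math.cos(ang), math.sin(ang)])
            cand = home + dist * direction
            while dist > 0.1 and not shapely.intersects_xy(boundary, cand[0], cand[1]):
                dist *= 0.8
                cand = home + dist * direction
            if not shapely.intersects_xy(boundary, cand[0], cand[1]):
                cand = np.clip(home + 0.1 * direction, (minx, miny), (maxx, maxy))
            stops.append((cand, "work"))
        stops.append((np.asarray(target.location), TYPE_TO_PURPOSE[ftype]))
        stops.append((home, "home"))
        t = rng.uniform(7.0, 9.0)
        origin = home
        for idx, (dest, purpose) in enumerate(stops):
            dist = float(np.hypot(*(dest - origin))) * 1.3
            dt = max(dist / trip_speed_kmh, 0.05)
            depart = min(t, 24.0)
            arrive = min(t + dt, 24.0)
            trips.append(TripRecord(
                person_id=pid, trip_index=idx,
                origin=(float(origin[0]), float(origin[1])),
                destination=(float(dest[0]), float(dest[1])),
                depart_time=depart, arrive_time=arrive, purpose=purpose,
                mode="road", expansion_factor=ef).validate())
            dwell = float(rng.uniform(0.75, 2.5)) if purpose != "home" else 0.0
            t = arrive + dwell
            origin = dest
    return trips


# ---------------------------------------------------------------------------
# scenario composition
# ---------------------------------------------------------------------------


def generate_scenario(scfg: ScenarioConfig | None = None,
                      cfg: PipelineConfig | None = None,
                      seed: int | None = None
                      ) -> tuple[CityBundle, ScenarioTruth]:
    """Compose the four sub-generators into a bundle plus planted truth."""
    from .data_model import assign_census_units, validate_config
    from .quantiles import top_fraction_threshold

    scfg = scfg or ScenarioConfig()
    cfg = validate_config(cfg)
    root = scfg.seed if seed is None else seed
    children = np.random.SeedSequence(root).spawn(5)
    child_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]

    wx, wy = scfg.extent_km
    boundary = box(0.0, 0.0, wx, wy)
    network = generate_network(scfg.extent_km, scfg.spacing_km, child_seeds[0])
    units = generate_census_units(boundary, scfg.n_units, scfg.pop_lognormal,
                                  child_seeds[1])
    # facilities sit in the built-up interior, like homes; the outermost
    # band is the city fringe
    built_up = boundary.buffer(-scfg.poi_margin_km)
    if built_up.is_empty or built_up.area < 1e-6:
        built_up = boundary
    pois = place_pois(built_up, scfg.poi_counts, scfg.clustering,
                      scfg.cluster_sd_km, scfg.cluster_fraction,
                      child_seeds[2])
    pois = assign_census_units(pois, units)

    # the risky agglomeration state per type: high for bars, low otherwise
    cells = agglomeration.agglomerate(pois, boundary,
                                      cfg.agglomeration_quantile,
                                      seed=child_seeds[3])
    risky = set()
    for p in pois:
        high = cells[p.poi_id].high_agglomeration
        if (p.facility_type == "bar" and high) or \
           (p.facility_type != "bar" and not high):
            risky.add(p.poi_id)

    if scfg.effect_size > 0:
        expected = {t: ("A" if t == "bar" else "B")
                    for t in sorted(scfg.poi_counts)}
        planted = frozenset(risky)
    else:
        expected = {t: "C" for t in sorted(scfg.poi_counts)}
        planted = frozenset()

    trips = generate_travel_diaries(
        pois, units, network, scfg.n_persons, boundary,
        risky_poi_ids=frozenset(risky), effect_size=scfg.effect_size,
        mobility_lognormal=scfg.mobility_lognormal,
        attraction_range_km=scfg.attraction_range_km,
        home_margin_km=scfg.home_margin_km,
        trip_speed_kmh=scfg.trip_speed_kmh, seed=child_seeds[4])

    dens = [u.density for u in units]
    thr = top_fraction_threshold(dens, cfg.density_quantile)
    top_density = frozenset(u.unit_id for u in units if u.density >= thr)

    truth = ScenarioTruth(expected_group=expected,
                          planted_class1_pois=planted,
                          risky_poi_ids=frozenset(risky),
                          effect_size=scfg.effect_size,
                          n_persons=scfg.n_persons, seed=root,
                          top_density_units=top_density)
    bundle = CityBundle(trips=trips, pois=pois, units=units, network=network,
                        boundary=boundary)
    return bundle, truth


def write_bundle(bundle: CityBundle, truth: ScenarioTruth, out_dir) -> None:
    """Write the bundle in the same formats the readers consume."""
    from pathlib import Path

    from .data_model import (write_boundary, write_census_units, write_network,
                             write_pois, write_trips)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_trips(bundle.trips, out / "trips.csv")
    write_pois(bundle.pois, out / "pois.geojson")
    write_census_units(bundle.units, out / "census_units.geojson")
    write_network(bundle.network, out / "network.geojson")
    write_boundary(bundle.boundary, out / "boundary.geojson")
    truth.to_json(out / "truth.json")
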