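"""Facility agglomeration via Thiessen (Voronoi) polygons.

For each facility type separately, the city is partitioned into Thiessen
cells of that type's PoIs, clipped to the city boundary.  A small cell means
locally dense facilities; per type, the quarter of PoIs with the smallest
cells (12.5% under the stricter robustness setting) is flagged as "high
agglomeration".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import voronoi_diagram

from .data_model import PoIRecord, ValidationError

log = logging.getLogger(__name__)


@dataclass
class ThiessenCell:
    poi_id: str
    facility_type: str
    area: float  # km²
    high_agglomeration: bool = False


def _jitter_duplicates(points: np.ndarray, seed: int) -> np.ndarray:
    """Perturb coincident generators by ~1e-6 km (Voronoi needs distinct points)."""
    rng = np.random.default_rng(seed)
    pts = points.copy()
    for _ in range(100):
        _, inverse, counts = np.unique(
            np.round(pts, 12), axis=0, return_inverse=True, return_counts=True)
        dup = counts[inverse] > 1
        if not dup.any():
            return pts
        pts[dup] += rng.normal(scale=1e-6, size=(int(dup.sum()), 2))
    raise ValidationError("could not separate coincident PoI coordinates")


def thiessen_areas(pois_of_one_type: Sequence[PoIRecord], boundary: Polygon,
                   seed: int = 0) -> list[ThiessenCell]:
    """Thiessen cell area of each PoI of one type, clipped to the boundary."""
    pois = list(pois_of_one_type)
    if not pois:
        raise ValidationError("need at least one PoI")
    types = {p.facility_type for p in pois}
    if len(types) > 1:
        raise ValidationError(f"mixed facility types in one tessellation: {types}")
    if len(pois) == 1:
        return [ThiessenCell(pois[0].poi_id, pois[0].facility_type, boundary.area)]
    points = np.array([p.location for p in pois], dtype=float)
    if len(np.unique(np.round(points, 12), axis=0)) < len(points):
        log.warning("coincident PoI coordinates jittered by ~1e-6 km")
        points = _jitter_duplicates(points, seed)
    span = max(boundary.bounds[2] - boundary.bounds[0],
               boundary.bounds[3] - boundary.bounds[1])
    envelope = boundary.buffer(2.0 * span).envelope
    cells = voronoi_diagram(MultiPoint(points.tolist()), envelope=envelope)
    out: list[ThiessenCell] = [None] * len(pois)  # type: ignore[list-item]
    remaining = list(cells.geoms)
    for i, poi in enumerate(pois):
        pt = Point(points[i])
        hit = None
        for j, cell in enumerate(remaining):
            if cell.covers(pt):
                hit = j
                break
        if hit is None:  # numerical edge case: take the nearest cell
            hit = min(range(len(remaining)),
                      key=lambda j: remaining[j].distance(pt))
        clipped = remaining.pop(hit).intersection(boundary)
        out[i] = ThiessenCell(poi.poi_id, poi.facility_type, float(clipped.area))
    total = sum(c.area for c in out)
    if not math.isclose(total, boundary.area, rel_tol=1e-6):
        raise ValidationError(
            f"Thiessen areas sum to {total:g}, boundary is {boundary.area:g}")
    return out


def flag_high_agglomeration(cells: Sequence[ThiessenCell],
                            q: float) -> list[ThiessenCell]:
    """Flag the ⌈q·n⌉ smallest cells as high agglomeration.

    Ties at the cutoff break by smaller area first, then lexicographic
    poi_id, so the flag set is deterministic across geometry backends and
    nested across thresholds (the 12.5% set is a subset of the 25% set).
    """
    if not cells:
        raise ValidationError("no cells to flag")
    if not 0.0 < q < 1.0:
        raise ValidationError(f"agglomeration quantile must be in (0, 1), got {q}")
    order = sorted(cells, key=lambda c: (c.area, c.poi_id))
    k = math.ceil(q * len(order))
    flagged_ids = {c.poi_id for c in order[:k]}
    return [replace(c, high_agglomeration=c.poi_id in flagged_ids) for c in cells]


def agglomerate(pois: Sequence[PoIRecord], boundary: Polygon, q: float,
                seed: int = 0) -> dict[str, ThiessenCell]:
    """Per-type tessellation and flagging for a whole city; keyed by poi_id."""
    out: dict[str, ThiessenCell] = {}
    by_type: dict[str, list[PoIRecord]] = {}
    for p in pois:
        by_type.setdefault(p.facility_type, []).append(p)
    for ftype in sorted(by_type):
        cells = flag_high_agglomeration(
            thiessen_areas(by_type[ftype], boundary, seed=seed), q)
        for c in cells:
            out[c.poi_id] = c
    return out


def write_cell_table(cells: Sequence[ThiessenCell], path) -> None:
    import pandas as pd

    pd.DataFrame([
        {"poi_id": c.poi_id, "facility_type": c.facility_type,
         "area_km2": c.area, "high_agglomeration": c.high_agglomeration}
        for c in cells
    ]).to_csv(path, index=False)
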