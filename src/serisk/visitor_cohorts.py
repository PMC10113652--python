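"""Matching survey persons to PoIs and per-PoI visitor-mobility flags.

A person counts as visiting a PoI when some trip of theirs ends in the
census unit containing the PoI *and* the trip purpose maps to the PoI's
facility type (shopping trips match malls, eat/drink trips match bars, and
so on).  Each person is counted once per PoI however many qualifying trips
they made.

Per-PoI visitor mobility is the expansion-weighted mean daily STP of the
PoI's matched visitors, compared against PoIs of the same facility type at
the same top-quarter threshold used elsewhere in the pipeline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .data_model import (
    PURPOSE_TO_TYPE,
    PURPOSES,
    CensusUnit,
    PoIRecord,
    TripRecord,
    UnitIndex,
    ValidationError,
)
from .quantiles import top_fraction_threshold
from .stp_engine import DailySTP

log = logging.getLogger(__name__)


@dataclass
class VisitorMatch:
    poi_id: str
    facility_type: str
    person_ids: frozenset[str] = frozenset()
    expanded_population: float = 0.0  # Σ expansion factors of matched persons
    mean_visitor_stp: float = math.nan  # km²·h, expansion-weighted
    high_visitor_mobility: bool = False

    @property
    def n_samples(self) -> int:
        return len(self.person_ids)


def match_visitors(trips: Sequence[TripRecord], pois: Sequence[PoIRecord],
                   units: Sequence[CensusUnit]) -> list[VisitorMatch]:
    """Match every person to every PoI they visited (unit + purpose rule)."""
    for p in pois:
        if p.census_unit_id is None:
            raise ValidationError(f"PoI {p.poi_id} has no census unit assigned")
    by_unit_type: dict[tuple[str, str], list[PoIRecord]] = {}
    for p in pois:
        by_unit_type.setdefault((p.census_unit_id, p.facility_type), []).append(p)
    index = UnitIndex(units)
    visitors: dict[str, set[str]] = {p.poi_id: set() for p in pois}
    weights: dict[str, float] = {}
    unit_cache: dict[tuple[float, float], str | None] = {}
    for trip in trips:
        if trip.purpose not in PURPOSES:
            raise ValidationError(
                f"purpose {trip.purpose!r} outside the closed vocabulary "
                f"{PURPOSES}")
        ftype = PURPOSE_TO_TYPE.get(trip.purpose)
        if ftype is None:  # work/home trips visit no facility
            continue
        weights.setdefault(trip.person_id, trip.expansion_factor)
        key = trip.destination
        if key not in unit_cache:
            unit = index.locate(trip.destination)
            unit_cache[key] = None if unit is None else unit.unit_id
        unit_id = unit_cache[key]
        if unit_id is None:
            continue
        for poi in by_unit_type.get((unit_id, ftype), []):
            visitors[poi.poi_id].add(trip.person_id)
    out = []
    for p in sorted(pois, key=lambda p: p.poi_id):
        ids = frozenset(visitors[p.poi_id])
        out.append(VisitorMatch(
            poi_id=p.poi_id, facility_type=p.facility_type, person_ids=ids,
            expanded_population=sum(weights[i] for i in ids)))
    return out


def flag_visitor_mobility(matches: Sequence[VisitorMatch],
                          stps: Sequence[DailySTP],
                          mobility_quantile: float = 0.25) -> list[VisitorMatch]:
    """Fill mean visitor STP and the per-type high-visitor-mobility flag.

    The flag is true when a PoI's expansion-weighted mean visitor STP is at
    or above the (1−q) quantile of means across same-type PoIs with at
    least one visitor; visitor-less PoIs are flagged false and excluded
    from the quantile pool.
    """
    stp_by_person: Mapping[str, DailySTP] = {s.person_id: s for s in stps}
    filled: list[VisitorMatch] = []
    for m in matches:
        if not m.person_ids:
            filled.append(replace(m, mean_visitor_stp=math.nan,
                                  high_visitor_mobility=False))
            continue
        missing = [pid for pid in m.person_ids if pid not in stp_by_person]
        if missing:
            raise ValidationError(
                f"PoI {m.poi_id}: matched person(s) without a daily STP: "
                f"{sorted(missing)[:5]}")
        num = sum(stp_by_person[i].expansion_factor *
                  stp_by_person[i].total_volume for i in m.person_ids)
        den = sum(stp_by_person[i].expansion_factor for i in m.person_ids)
        filled.append(replace(m, mean_visitor_stp=num / den))
    by_type: dict[str, list[VisitorMatch]] = {}
    for m in filled:
        if m.person_ids:
            by_type.setdefault(m.facility_type, []).append(m)
    thresholds = {
        ftype: top_fraction_threshold([m.mean_visitor_stp for m in pool],
                                      mobility_quantile)
        for ftype, pool in by_type.items()
    }
    out = []
    n_empty = 0
    for m in filled:
        if not m.person_ids:
            n_empty += 1
            out.append(m)
            continue
        thr = thresholds[m.facility_type]
        out.append(replace(m, high_visitor_mobility=m.mean_visitor_stp >= thr))
    if n_empty:
        log.info("%d PoI(s) had no matched visitors; flagged low mobility", n_empty)
    return out


def write_match_table(matches: Sequence[VisitorMatch], path) -> None:
    import pandas as pd

    rows = [{"poi_id": m.poi_id, "person_id": pid}
            for m in matches for pid in sorted(m.person_ids)]
    pd.DataFrame(rows, columns=["poi_id", "person_id"]).to_csv(path, index=False)


def write_poi_summary(matches: Sequence[VisitorMatch], path) -> None:
    import pandas as pd

    pd.DataFrame([
        {"poi_id": m.poi_id, "facility_type": m.facility_type,
         "n_samples": m.n_samples, "expanded_population": m.expanded_population,
         "mean_visitor_stp": m.mean_visitor_stp,
         "high_visitor_mobility": m.high_visitor_mobility}
        for m in matches
    ]).to_csv(path, index=False)
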