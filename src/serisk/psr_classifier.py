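"""Potential-spatial-risk (PSR) classes 1–4 for individual PoIs.

Each PoI is classified from four inputs: its facility type's A/B/C group,
its own high/low agglomeration flag, its visitors' high/low mobility flag,
and whether it sits in a top-quarter population-density census unit.  The
decision table, evaluated in order:

  1. group A and high agglomeration            → Class 1
  2. group B and low agglomeration             → Class 1
  3. low agglomeration, low mobility, high pop. density → Class 2
  4. low agglomeration, low mobility, low pop. density  → Class 4
  5. anything else                             → Class 3

Group-B PoIs with low agglomeration stay Class 1 regardless of mobility
(rule 2 fires first): lack of agglomeration is itself the risk factor for
those types.  Group-C types never reach Class 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .data_model import CensusUnit, PoIRecord, ValidationError
from .quantiles import top_fraction_threshold


@dataclass
class PSRLabel:
    poi_id: str
    facility_type: str
    psr_class: int
    group: str
    high_agglomeration: bool
    high_visitor_mobility: bool
    high_pop_density: bool


def flag_high_density(pois: Sequence[PoIRecord], units: Sequence[CensusUnit],
                      density_quantile: float = 0.25) -> dict[str, bool]:
    """True for PoIs in census units of top-quarter population density.

    The threshold is the (1−q) quantile of unit densities, unweighted across
    all units in the city; units at the threshold count as high (ties in).
    """
    if not 0.0 < density_quantile < 1.0:
        raise ValidationError("density_quantile must be in (0, 1)")
    densities = [u.density for u in units]
    threshold = top_fraction_threshold(densities, density_quantile)
    unit_flag = {u.unit_id: u.density >= threshold for u in units}
    out = {}
    for p in pois:
        if p.census_unit_id is None:
            raise ValidationError(f"PoI {p.poi_id} has no census unit")
        out[p.poi_id] = unit_flag[p.census_unit_id]
    return out


def classify_poi(group: str, high_agglom: bool, high_mobility: bool,
                 high_density: bool) -> int:
    """PSR class from the four flags; total over all 24 combinations."""
    if group not in ("A", "B", "C"):
        raise ValidationError(f"group must be A, B or C, got {group!r}")
    if group == "A" and high_agglom:
        return 1
    if group == "B" and not high_agglom:
        return 1
    if not high_agglom and not high_mobility and high_density:
        return 2
    if not high_agglom and not high_mobility and not high_density:
        return 4
    return 3


def classify_all(pois: Sequence[PoIRecord],
                 groups: Mapping[str, str],
                 agglom_flags: Mapping[str, bool],
                 mobility_flags: Mapping[str, bool],
                 density_flags: Mapping[str, bool]) -> list[PSRLabel]:
    """PSR label for every PoI.

    ``groups`` maps facility_type → A/B/C; the flag mappings are keyed by
    poi_id.
    """
    labels = []
    for p in sorted(pois, key=lambda p: p.poi_id):
        g = groups[p.facility_type]
        ha = agglom_flags[p.poi_id]
        hm = mobility_flags[p.poi_id]
        hd = density_flags[p.poi_id]
        labels.append(PSRLabel(
            poi_id=p.poi_id, facility_type=p.facility_type,
            psr_class=classify_poi(g, ha, hm, hd), group=g,
            high_agglomeration=ha, high_visitor_mobility=hm,
            high_pop_density=hd))
    return labels


def write_psr_table(labels: Sequence[PSRLabel], path) -> None:
    import pandas as pd

    pd.DataFrame([
        {"poi_id": l.poi_id, "facility_type": l.facility_type,
         "psr_class": l.psr_class, "group": l.group,
         "high_agglomeration": l.high_agglomeration,
         "high_visitor_mobility": l.high_visitor_mobility,
         "high_pop_density": l.high_pop_density}
        for l in labels
    ]).to_csv(path, index=False)
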