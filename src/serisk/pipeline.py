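"""End-to-end orchestration: STP → matching → agglomeration → association →
PSR classes → risk surfaces, plus the descriptive city summary and the
12.5%-threshold robustness rerun."""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import agglomeration as agg
from . import association, psr_classifier, risk_surface, stp_engine, visitor_cohorts
from .association import GroupAssignment, _weighted_moments
from .data_model import (
    FACILITY_TYPES,
    CityBundle,
    PipelineConfig,
    StageError,
    ValidationError,
    validate_config,
)
from .psr_classifier import PSRLabel
from .risk_surface import RiskSurface, jaccard
from .stp_engine import DailySTP
from .visitor_cohorts import VisitorMatch

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    stps: list[DailySTP]
    matches: list[VisitorMatch]
    cells: dict[str, agg.ThiessenCell]
    groups: list[GroupAssignment]
    labels: list[PSRLabel]
    surface: RiskSurface
    density_only: RiskSurface
    summary: pd.DataFrame


def _stage(name):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as err:
            raise StageError(name, str(err)) from err
        log.info("stage %-12s done in %.2fs", name, time.perf_counter() - t0)
        return out
    return wrap


def group_tests(matches: Sequence[VisitorMatch],
                stps: Sequence[DailySTP],
                cells: dict[str, agg.ThiessenCell],
                cfg: PipelineConfig) -> list[GroupAssignment]:
    """Per-type weighted t-test of visitor STP between agglomeration strata.

    The unit of analysis is the person-visit: a person matched to PoIs in
    both strata contributes to both.  A type with fewer than two visitors in
    either stratum cannot be tested and falls to Group C (logged).
    """
    stp_by_person = {s.person_id: s for s in stps}
    alpha = cfg.alpha
    types = sorted({m.facility_type for m in matches})
    if cfg.bonferroni:
        alpha = alpha / len(types)
    out = []
    for ftype in types:
        high_persons: set[str] = set()
        low_persons: set[str] = set()
        for m in matches:
            if m.facility_type != ftype:
                continue
            target = high_persons if cells[m.poi_id].high_agglomeration else low_persons
            target.update(m.person_ids)
        strata = []
        for persons in (high_persons, low_persons):
            vals = np.array([stp_by_person[p].total_volume for p in sorted(persons)])
            ws = np.array([stp_by_person[p].expansion_factor for p in sorted(persons)])
            strata.append((vals, ws))
        (xh, wh), (xl, wl) = strata
        if len(xh) < 2 or len(xl) < 2:
            log.warning("type %s: a stratum has <2 visitors; assigning Group C",
                        ftype)
            mh = float((wh * xh).sum() / wh.sum()) if len(xh) else float("nan")
            ml = float((wl * xl).sum() / wl.sum()) if len(xl) else float("nan")
            out.append(GroupAssignment(
                facility_type=ftype, mean_high=mh, mean_low=ml,
                t_stat=float("nan"), dof=float("nan"), p_value=float("nan"),
                group="C", normalized_pair=(100.0, 100.0)))
            continue
        out.append(association.compare_strata(
            xh, xl, wh, wl, alpha=alpha, facility_type=ftype,
            pooled=cfg.pooled_variance))
    return out


def summarize_city(matches: Sequence[VisitorMatch],
                   stps: Sequence[DailySTP]) -> pd.DataFrame:
    """Descriptive per-type block plus a totals row.

    Per facility type: number of PoIs with visitors, expansion-weighted mean
    and std of visitor daily STP (persons counted once per type), distinct
    visitor count, and summed expansion factors.  The totals row pools
    distinct persons over all types.
    """
    stp_by_person = {s.person_id: s for s in stps}

    def block(person_ids: set[str], n_pois: int) -> dict:
        if not person_ids:
            return {"n_pois": n_pois, "mean_stp": float("nan"),
                    "std_stp": float("nan"), "n_samples": 0,
                    "expanded_population": 0.0}
        vals = np.array([stp_by_person[p].total_volume for p in sorted(person_ids)])
        ws = np.array([stp_by_person[p].expansion_factor for p in sorted(person_ids)])
        mean, var, n_eff = _weighted_moments(vals, ws)
        return {"n_pois": n_pois, "mean_stp": mean,
                "std_stp": float(np.sqrt(var)), "n_samples": len(person_ids),
                "expanded_population": float(ws.sum())}

    rows = {}
    all_persons: set[str] = set()
    all_pois = 0
    for ftype in FACILITY_TYPES:
        persons: set[str] = set()
        n_pois = 0
        for m in matches:
            if m.facility_type == ftype and m.person_ids:
                persons.update(m.person_ids)
                n_pois += 1
        rows[ftype] = block(persons, n_pois)
        all_persons.update(persons)
        all_pois += n_pois
    rows["total"] = block(all_persons, all_pois)
    return pd.DataFrame.from_dict(rows, orient="index")


def run_pipeline(bundle: CityBundle, cfg: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run all stages in order and optionally write every intermediate."""
    cfg = validate_config(cfg)
    stps = _stage("stp")(stp_engine.compute_daily_stps, bundle.trips,
                         bundle.network, cfg)
    stps = _stage("stp_flag")(stp_engine.flag_large_stp, stps,
                              cfg.mobility_quantile)
    matches = _stage("matching")(visitor_cohorts.match_visitors, bundle.trips,
                                 bundle.pois, bundle.units)
    matches = _stage("mobility")(visitor_cohorts.flag_visitor_mobility, matches,
                                 stps, cfg.mobility_quantile)
    cells = _stage("agglomeration")(agg.agglomerate, bundle.pois,
                                    bundle.boundary, cfg.agglomeration_quantile,
                                    cfg.random_seed)
    groups = _stage("association")(group_tests, matches, stps, cells, cfg)
    group_map = {g.facility_type: g.group for g in groups}
    density_flags = _stage("density")(psr_classifier.flag_high_density,
                                      bundle.pois, bundle.units,
                                      cfg.density_quantile)
    mobility_flags = {m.poi_id: m.high_visitor_mobility for m in matches}
    agglom_flags = {pid: c.high_agglomeration for pid, c in cells.items()}
    labels = _stage("psr")(psr_classifier.classify_all, bundle.pois, group_map,
                           agglom_flags, mobility_flags, density_flags)
    scale = None
    if cfg.density_weighted_kde:
        scale = risk_surface.density_scale_factors(bundle.pois, bundle.units)
    surface = _stage("surface")(risk_surface.risk_surface_from_labels,
                                bundle.pois, labels, bundle.boundary, cfg, scale)
    density_only = _stage("surface_ref")(risk_surface.density_only_surface,
                                         bundle.pois, bundle.boundary, cfg)
    summary = _stage("summary")(summarize_city, matches, stps)
    result = PipelineResult(stps=stps, matches=matches, cells=cells,
                            groups=groups, labels=labels, surface=surface,
                            density_only=density_only, summary=summary)
    if out_dir is not None:
        write_outputs(result, Path(out_dir))
    return result


def write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    stp_engine.write_stp_table(result.stps, out / "01_stp.csv")
    visitor_cohorts.write_match_table(result.matches, out / "02_matches.csv")
    visitor_cohorts.write_poi_summary(result.matches, out / "02_poi_summary.csv")
    agg.write_cell_table(sorted(result.cells.values(), key=lambda c: c.poi_id),
                         out / "03_thiessen.csv")
    association.write_group_table(result.groups, out / "04_groups.csv")
    psr_classifier.write_psr_table(result.labels, out / "05_psr.csv")
    risk_surface.write_ascii_grid(result.surface, out / "06_density.asc",
                                  "density")
    risk_surface.write_ascii_grid(result.surface, out / "06_octile.asc",
                                  "octile")
    risk_surface.high_risk_geojson(result.surface, out / "06_high_risk.geojson")
    risk_surface.write_ascii_grid(result.density_only,
                                  out / "06_density_only.asc", "density")
    result.summary.to_csv(out / "07_summary.csv")
    risk_surface.render_map(result.surface, out / "06_surface.png")


@dataclass
class RobustnessReport:
    """Paired outputs at the 25% and 12.5% agglomeration thresholds."""

    result_default: PipelineResult
    result_strict: PipelineResult
    q_default: float
    q_strict: float
    high_risk_jaccard: float


def robustness_rerun(bundle: CityBundle, cfg: PipelineConfig | None = None,
                     q_strict: float = 0.125) -> RobustnessReport:
    """Rerun with the stricter agglomeration threshold and compare masks.

    Only the agglomeration quantile changes between the runs; the report
    carries the Jaccard overlap of the two high-risk masks.  Overlap below
    0.5 is flagged for review (the expectation is that tightening the
    threshold leaves the broad spatial pattern intact).
    """
    cfg = validate_config(cfg)
    res_default = run_pipeline(bundle, cfg)
    cfg_strict = dataclasses.replace(cfg, agglomeration_quantile=q_strict)
    res_strict = run_pipeline(bundle, cfg_strict)
    overlap = jaccard(res_default.surface.high_risk, res_strict.surface.high_risk)
    if overlap < 0.5:
        log.warning("high-risk masks at q=%.3g vs %.3g overlap only %.2f — "
                    "flagged for review", cfg.agglomeration_quantile, q_strict,
                    overlap)
    return RobustnessReport(result_default=res_default, result_strict=res_strict,
                            q_default=cfg.agglomeration_quantile,
                            q_strict=q_strict, high_risk_jaccard=overlap)
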