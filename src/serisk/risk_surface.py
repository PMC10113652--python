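"""Weighted kernel-density risk surface, octile classes and high-risk mask.

Each PoI contributes a quartic (biweight) kernel of radius one bandwidth,
scaled by the product of its PSR-class weight (1000/100/10/1 for classes
1–4) and its facility type's activity weight (bars/cinemas/gyms 5, worship
4, malls 3, libraries 2).  Densities over in-boundary cells are displayed in
eight equal-count quantile classes; cells at or above the 75th percentile
form the "high-risk" mask.  A density-only surface (all weights equal)
serves as the traditional comparison map.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon, box, mapping
from shapely.ops import unary_union

from .data_model import PipelineConfig, PoIRecord, ValidationError
from .psr_classifier import PSRLabel


@dataclass
class RiskSurface:
    """Regular raster over the city boundary (cell centres, km)."""

    x0: float  # west edge of the grid
    y0: float  # south edge
    cell: float  # cell size, km
    density: np.ndarray  # (ny, nx), row 0 = southmost
    in_boundary: np.ndarray  # bool mask
    octile: np.ndarray | None = None  # 1–8 in-boundary, 0 outside
    high_risk: np.ndarray | None = None
    threshold: float = math.nan  # 75th-percentile density

    @property
    def shape(self) -> tuple[int, int]:
        return self.density.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.density.shape
        xs = self.x0 + (np.arange(nx) + 0.5) * self.cell
        ys = self.y0 + (np.arange(ny) + 0.5) * self.cell
        return np.meshgrid(xs, ys)


def poi_weight(psr_class: int, facility_type: str, cfg: PipelineConfig) -> float:
    """Kernel weight of one PoI: PSR-class weight × activity weight."""
    if psr_class not in cfg.psr_weights:
        raise ValidationError(f"unknown PSR class {psr_class!r}")
    if facility_type not in cfg.activity_weights:
        raise ValidationError(f"unknown facility type {facility_type!r}")
    return cfg.psr_weights[psr_class] * cfg.activity_weights[facility_type]


def quartic_kernel(u: np.ndarray) -> np.ndarray:
    """Quartic (biweight) kernel 3/π (1−u²)² on u < 1, normalized in 2-D."""
    u = np.asarray(u, dtype=float)
    out = np.zeros_like(u)
    inside = u < 1.0
    out[inside] = (3.0 / math.pi) * (1.0 - u[inside] ** 2) ** 2
    return out


def kernel_density(points: np.ndarray, weights: np.ndarray, boundary: Polygon,
                   bandwidth: float, cell: float) -> RiskSurface:
    """Weighted quartic KDE on a regular grid covering the boundary.

    density(c) = Σᵢ wᵢ K(|c − pᵢ|/h) / h², kernel truncated at h; cells
    outside the boundary are masked.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    weights = np.asarray(weights, dtype=float)
    if points.size == 0:
        raise ValidationError("kernel density needs at least one PoI")
    if bandwidth <= 0 or cell <= 0:
        raise ValidationError("bandwidth and cell size must be positive")
    minx, miny, maxx, maxy = boundary.bounds
    if maxx <= minx or maxy <= miny:
        raise ValidationError("boundary has empty extent")
    nx = max(1, math.ceil((maxx - minx) / cell))
    ny = max(1, math.ceil((maxy - miny) / cell))
    xs = minx + (np.arange(nx) + 0.5) * cell
    ys = miny + (np.arange(ny) + 0.5) * cell
    density = np.zeros((ny, nx))
    h = bandwidth
    for (px, py), w in zip(points, weights):
        i0 = max(0, int(np.searchsorted(xs, px - h)))
        i1 = min(nx, int(np.searchsorted(xs, px + h)) + 1)
        j0 = max(0, int(np.searchsorted(ys, py - h)))
        j1 = min(ny, int(np.searchsorted(ys, py + h)) + 1)
        if i0 >= i1 or j0 >= j1:
            continue
        dx = xs[i0:i1] - px
        dy = ys[j0:j1] - py
        u = np.sqrt(dx[None, :] ** 2 + dy[:, None] ** 2) / h
        density[j0:j1, i0:i1] += w * quartic_kernel(u) / h**2
    gx, gy = np.meshgrid(xs, ys)
    mask = shapely.intersects_xy(boundary, gx.ravel(), gy.ravel()).reshape(ny, nx)
    if not mask.any():
        raise ValidationError("no grid cell falls inside the boundary")
    return RiskSurface(x0=minx, y0=miny, cell=cell, density=density,
                       in_boundary=mask)


def classify_octiles(surface: RiskSurface) -> RiskSurface:
    """Fill octile classes (equal cell counts, ties to the lower octile) and
    the ≥ 75th-percentile high-risk mask over in-boundary cells."""
    vals = surface.density[surface.in_boundary]
    n = vals.size
    sorted_vals = np.sort(vals)
    # first-occurrence rank of each value → tied values share the lower octile
    first_pos = np.searchsorted(sorted_vals, surface.density.ravel(), side="left")
    octs = (first_pos * 8) // n + 1
    octile = np.zeros(surface.density.shape, dtype=int)
    octile.flat[:] = np.clip(octs, 1, 8)
    octile[~surface.in_boundary] = 0
    threshold = float(np.percentile(vals, 75))
    high = (surface.density >= threshold) & surface.in_boundary
    surface.octile = octile
    surface.high_risk = high
    surface.threshold = threshold
    return surface


def risk_surface_from_labels(pois: Sequence[PoIRecord],
                             labels: Sequence[PSRLabel],
                             boundary: Polygon, cfg: PipelineConfig,
                             density_scale: Mapping[str, float] | None = None
                             ) -> RiskSurface:
    """Weighted surface from classified PoIs (octiles and mask filled).

    ``density_scale`` optionally multiplies each PoI's weight by a factor
    derived from its census unit's population density (see config
    ``density_weighted_kde``).
    """
    by_id = {l.poi_id: l for l in labels}
    pts, ws = [], []
    for p in pois:
        lab = by_id[p.poi_id]
        w = poi_weight(lab.psr_class, p.facility_type, cfg)
        if density_scale is not None:
            w *= density_scale.get(p.poi_id, 1.0)
        pts.append(p.location)
        ws.append(w)
    surface = kernel_density(np.array(pts), np.array(ws), boundary,
                             cfg.kde_bandwidth, cfg.kde_cell_size)
    return classify_octiles(surface)


def density_only_surface(pois: Sequence[PoIRecord], boundary: Polygon,
                         cfg: PipelineConfig) -> RiskSurface:
    """Comparison surface using PoI locations only (all weights = 1)."""
    pts = np.array([p.location for p in pois])
    surface = kernel_density(pts, np.ones(len(pts)), boundary,
                             cfg.kde_bandwidth, cfg.kde_cell_size)
    return classify_octiles(surface)


def density_scale_factors(pois: Sequence[PoIRecord],
                          units, lo: float = 1.0, hi: float = 2.0
                          ) -> dict[str, float]:
    """Min-max-normalized unit density rescaled to [lo, hi], per PoI."""
    dens = {u.unit_id: u.density for u in units}
    values = np.array(list(dens.values()))
    vmin, vmax = values.min(), values.max()
    span = vmax - vmin
    out = {}
    for p in pois:
        d = dens[p.census_unit_id]
        norm = 0.0 if span == 0 else (d - vmin) / span
        out[p.poi_id] = lo + (hi - lo) * norm
    return out


# ---------------------------------------------------------------------------
# output formats
# ---------------------------------------------------------------------------


def write_ascii_grid(surface: RiskSurface, path, band: str = "density") -> None:
    """Write one band as an ESRI ASCII grid (plain-text raster)."""
    arr = getattr(surface, band)
    if arr is None:
        raise ValidationError(f"band {band!r} not filled")
    ny, nx = arr.shape
    data = np.where(surface.in_boundary, arr, -9999)
    with open(path, "w") as fh:
        fh.write(f"ncols {nx}\nnrows {ny}\n")
        fh.write(f"xllcorner {surface.x0}\nyllcorner {surface.y0}\n")
        fh.write(f"cellsize {surface.cell}\nNODATA_value -9999\n")
        for row in data[::-1]:  # ASCII grids run north → south
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def high_risk_geojson(surface: RiskSurface, path) -> None:
    """Dissolved high-risk cells as a GeoJSON polygon layer."""
    if surface.high_risk is None:
        raise ValidationError("octiles/high-risk not computed yet")
    ny, nx = surface.shape
    cells = []
    js, is_ = np.nonzero(surface.high_risk)
    for j, i in zip(js, is_):
        x = surface.x0 + i * surface.cell
        y = surface.y0 + j * surface.cell
        cells.append(box(x, y, x + surface.cell, y + surface.cell))
    geom = unary_union(cells) if cells else Polygon()
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "crs_units": "km",
                   "features": [{"type": "Feature", "geometry": mapping(geom),
                                 "properties": {"threshold": surface.threshold}}]},
                  fh)


def render_map(surface: RiskSurface, path, title: str = "SE-risk surface") -> None:
    """Octile map rendered to an image file (matplotlib, headless)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ny, nx = surface.shape
    extent = (surface.x0, surface.x0 + nx * surface.cell,
              surface.y0, surface.y0 + ny * surface.cell)
    shown = np.where(surface.in_boundary, surface.octile, np.nan)
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(shown, origin="lower", extent=extent, cmap="YlOrRd",
                   vmin=1, vmax=8)
    fig.colorbar(im, ax=ax, label="risk octile")
    ax.set_xlabel("x (km)")
    ax.set_ylabel("y (km)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Jaccard overlap of two boolean masks (1.0 when both are empty)."""
    union = np.logical_or(mask_a, mask_b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(mask_a, mask_b).sum() / union)
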