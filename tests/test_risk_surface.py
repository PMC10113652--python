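import math

import numpy as np
import pytest
from shapely.geometry import box

from serisk.data_model import ValidationError, validate_config
from serisk.risk_surface import (
    RiskSurface,
    classify_octiles,
    jaccard,
    kernel_density,
    poi_weight,
    quartic_kernel,
)


class TestPoIWeight:
    @pytest.mark.parametrize("cls,ftype,expected", [
        (1, "bar", 5000.0),
        (4, "library", 2.0),
        (2, "worship", 400.0),
        (3, "mall", 30.0),
    ])
    def test_products(self, cls, ftype, expected):
        assert poi_weight(cls, ftype, validate_config(None)) == expected

    def test_unknown_inputs_rejected(self):
        cfg = validate_config(None)
        with pytest.raises(ValidationError):
            poi_weight(5, "bar", cfg)
        with pytest.raises(ValidationError):
            poi_weight(1, "arcade", cfg)


class TestKernelDensity:
    def test_peak_value_at_source_cell(self):
        # point at an exact cell centre: density there is w·K(0)/h² = 3w/(πh²)
        boundary = box(0, 0, 1, 1)
        surf = kernel_density(np.array([[0.55, 0.55]]), np.array([2.0]),
                              boundary, bandwidth=0.3, cell=0.1)
        j, i = 5, 5  # cell centred at (0.55, 0.55)
        assert surf.density[j, i] == pytest.approx(3 * 2.0 / (math.pi * 0.09))

    def test_zero_beyond_bandwidth(self):
        boundary = box(0, 0, 2, 2)
        surf = kernel_density(np.array([[0.25, 0.25]]), np.array([1.0]),
                              boundary, bandwidth=0.2, cell=0.1)
        gx, gy = surf.cell_centers()
        far = np.hypot(gx - 0.25, gy - 0.25) > 0.2
        assert (surf.density[far] == 0).all()

    def test_mass_conservation_on_open_plane(self):
        # all mass well inside a large boundary, cell = h/10
        boundary = box(0, 0, 8, 8)
        pts = np.array([[4.0, 4.0], [3.0, 5.0]])
        ws = np.array([2.0, 5.0])
        surf = kernel_density(pts, ws, boundary, bandwidth=1.0, cell=0.1)
        mass = surf.density.sum() * 0.1**2
        assert mass == pytest.approx(ws.sum(), rel=0.01)

    def test_mirror_symmetry(self):
        boundary = box(0, 0, 2, 1)
        surf = kernel_density(np.array([[0.7, 0.5], [1.3, 0.5]]),
                              np.array([1.0, 1.0]), boundary,
                              bandwidth=0.5, cell=0.1)
        assert surf.density == pytest.approx(surf.density[:, ::-1])

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        boundary = box(0, 0, 3, 3)
        pts = rng.uniform(0, 3, size=(15, 2))
        ws = rng.uniform(1, 100, size=15)
        h, cell = 0.8, 0.15
        surf = kernel_density(pts, ws, boundary, h, cell)
        gx, gy = surf.cell_centers()
        for _ in range(20):
            j = rng.integers(surf.shape[0])
            i = rng.integers(surf.shape[1])
            u = np.hypot(gx[j, i] - pts[:, 0], gy[j, i] - pts[:, 1]) / h
            expected = float((ws * quartic_kernel(u)).sum() / h**2)
            assert surf.density[j, i] == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_raising_a_weight_never_decreases_density(self):
        boundary = box(0, 0, 2, 2)
        pts = np.array([[0.5, 0.5], [1.5, 1.5]])
        lo = kernel_density(pts, np.array([1.0, 1.0]), boundary, 0.8, 0.1)
        hi = kernel_density(pts, np.array([1.0, 3.0]), boundary, 0.8, 0.1)
        assert (hi.density >= lo.density - 1e-15).all()

    def test_no_pois_rejected(self):
        with pytest.raises(ValidationError):
            kernel_density(np.empty((0, 2)), np.empty(0), box(0, 0, 1, 1), 1, 0.1)


def surface_from(values: np.ndarray) -> RiskSurface:
    values = np.asarray(values, dtype=float)
    return RiskSurface(x0=0.0, y0=0.0, cell=1.0, density=values,
                       in_boundary=np.ones_like(values, dtype=bool))


class TestOctiles:
    def test_distinct_values_fill_octiles_equally(self):
        rng = np.random.default_rng(0)
        vals = rng.permutation(800).reshape(40, 20).astype(float)
        surf = classify_octiles(surface_from(vals))
        counts = np.bincount(surf.octile.ravel(), minlength=9)[1:]
        assert (counts == 100).all()
        assert surf.high_risk.sum() == 200

    def test_constant_surface_degenerate_ties(self):
        surf = classify_octiles(surface_from(np.full((10, 10), 7.0)))
        assert (surf.octile == 1).all()
        assert surf.high_risk.all()

    def test_high_risk_is_exactly_the_75th_percentile_set(self):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(0, 1, (30, 30))
        surf = classify_octiles(surface_from(vals))
        thr = np.percentile(vals, 75)
        assert (surf.high_risk == (vals >= thr)).all()

    def test_rank_statistics_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        vals = rng.lognormal(0, 1, (25, 25))
        a = classify_octiles(surface_from(vals))
        b = classify_octiles(surface_from(np.exp(vals / vals.max() * 3)))
        assert (a.octile == b.octile).all()
        assert (a.high_risk == b.high_risk).all()

    def test_out_of_boundary_cells_excluded(self):
        vals = np.arange(16, dtype=float).reshape(4, 4)
        surf = surface_from(vals)
        surf.in_boundary[0, :] = False
        surf = classify_octiles(surf)
        assert (surf.octile[0, :] == 0).all()
        assert not surf.high_risk[0, :].any()


class TestSurfacesOnScenario:
    def test_proportional_weights_give_identical_octiles(self, small_scenario):
        _, bundle, _ = small_scenario
        cfg = validate_config(None)
        pts = np.array([p.location for p in bundle.pois])
        a = classify_octiles(kernel_density(
            pts, np.ones(len(pts)), bundle.boundary,
            cfg.kde_bandwidth, cfg.kde_cell_size))
        b = classify_octiles(kernel_density(
            pts, np.full(len(pts), 7.0), bundle.boundary,
            cfg.kde_bandwidth, cfg.kde_cell_size))
        assert (a.octile == b.octile).all()
        assert (a.high_risk == b.high_risk).all()

    def test_weighted_and_density_only_masks_differ(self, default_run):
        _, _, result = default_run
        sym_diff = result.surface.high_risk ^ result.density_only.high_risk
        assert sym_diff.sum() > 0


class TestJaccard:
    def test_identical_masks(self):
        m = np.array([[True, False], [True, True]])
        assert jaccard(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.array([True, False])
        b = np.array([False, True])
        assert jaccard(a, b) == 0.0

    def test_both_empty(self):
        z = np.zeros(4, dtype=bool)
        assert jaccard(z, z) == 1.0
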