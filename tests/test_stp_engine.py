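import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from serisk.data_model import TripRecord, ValidationError, validate_config
from serisk.quantiles import weighted_quantile
from serisk.stp_engine import (
    DailySTP,
    activity_prism_volume,
    daily_stp,
    flag_large_stp,
    route_bounding_area,
    shortest_route,
    travel_prism_volume,
)
from serisk.synthetic_city import generate_network

from oracles import brute_force_hull_area


def polyline_length(route: np.ndarray) -> float:
    return float(np.hypot(*np.diff(route, axis=0).T).sum())


class TestShortestRoute:
    def test_identical_endpoints_degenerate(self):
        net = generate_network((2, 2), 1.0)
        route = shortest_route(net, (0.3, 0.3), (0.3, 0.3))
        assert route.shape == (1, 2)
        assert polyline_length(route) == 0.0

    def test_opposite_corners_of_grid(self):
        net = generate_network((2, 2), 1.0)
        route = shortest_route(net, (0.0, 0.0), (2.0, 2.0))
        assert polyline_length(route) == pytest.approx(4.0)

    def test_matches_networkx_on_random_pairs(self):
        """Dual route: the cached csgraph paths against networkx Dijkstra."""
        net = generate_network((5, 5), 1.0)
        rng = np.random.default_rng(42)
        for _ in range(25):
            a, b = rng.uniform(0, 5, 2), rng.uniform(0, 5, 2)
            route = shortest_route(net, a, b)
            na, nb = net.snap(a), net.snap(b)
            expected = nx.shortest_path_length(net.graph, na, nb, weight="length")
            snap_len = math.dist(a, net.node_position(na)) + \
                math.dist(b, net.node_position(nb))
            assert polyline_length(route) == pytest.approx(expected + snap_len)


class TestPrismVolumes:
    def test_unit_square_route(self):
        route = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert travel_prism_volume(route, 0.5) == pytest.approx(0.5)

    def test_straight_segment_uses_buffer(self):
        route = np.array([[0, 0], [2, 0]], dtype=float)
        # corridor: L·2ε + πε² at ε = 0.01
        expected = 2 * 0.02 + math.pi * 1e-4
        assert travel_prism_volume(route, 1.0) == pytest.approx(expected, rel=1e-4)

    def test_hull_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            pts = rng.uniform(0, 3, size=(rng.integers(3, 26), 2))
            assert route_bounding_area(pts) == pytest.approx(
                brute_force_hull_area(pts), rel=1e-9, abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            travel_prism_volume(np.zeros((1, 2)), -1.0)

    def test_activity_zero_duration(self):
        assert activity_prism_volume(0.0, 0.1) == 0.0

    def test_activity_closed_form(self):
        assert activity_prism_volume(2.0, 0.1) == pytest.approx(
            math.pi * 0.01 * 2.0)

    def test_doubling_radius_quadruples_volume(self):
        v1 = activity_prism_volume(1.5, 0.1)
        v2 = activity_prism_volume(1.5, 0.2)
        assert v2 == pytest.approx(4 * v1)


class TestDailySTP:
    def _net(self):
        return generate_network((2, 2), 1.0)

    def test_empty_day_is_zero(self):
        out = daily_stp([], self._net(), validate_config(None))
        assert out.total_volume == 0.0

    def test_travel_plus_activity_additivity(self):
        """One diagonal trip plus a 2 h dwell: the two closed forms add."""
        cfg = validate_config(None)
        net = self._net()
        trips = [
            TripRecord("p1", 0, (0.0, 0.0), (2.0, 2.0), 8.0, 8.5, "shop",
                       expansion_factor=2.0),
            TripRecord("p1", 1, (2.0, 2.0), (0.0, 0.0), 10.5, 11.0, "home",
                       expansion_factor=2.0),
        ]
        route = shortest_route(net, (0.0, 0.0), (2.0, 2.0))
        expected_travel = 2 * travel_prism_volume(route, 0.5)
        expected_activity = activity_prism_volume(2.0, cfg.activity_footprint_radius)
        out = daily_stp(trips, net, cfg)
        assert out.travel_volume == pytest.approx(expected_travel)
        assert out.activity_volume == pytest.approx(expected_activity)
        assert out.total_volume == pytest.approx(expected_travel + expected_activity)

    def test_home_dwell_contributes_nothing(self):
        cfg = validate_config(None)
        trips = [TripRecord("p1", 0, (0.0, 0.0), (1.0, 1.0), 8.0, 8.2, "home")]
        out = daily_stp(trips, self._net(), cfg)
        assert out.activity_volume == 0.0

    def test_final_nonhome_dwell_closes_at_midnight(self):
        cfg = validate_config(None)
        trips = [TripRecord("p1", 0, (0.0, 0.0), (1.0, 1.0), 8.0, 9.0, "shop")]
        out = daily_stp(trips, self._net(), cfg)
        assert out.activity_volume == pytest.approx(
            activity_prism_volume(15.0, cfg.activity_footprint_radius))

    def test_unsorted_trips_rejected(self):
        cfg = validate_config(None)
        trips = [TripRecord("p1", 1, (0, 0), (1, 1), 8.0, 8.5, "shop"),
                 TripRecord("p1", 0, (1, 1), (0, 0), 9.0, 9.5, "home")]
        with pytest.raises(ValidationError, match="sorted"):
            daily_stp(trips, self._net(), cfg)

    def test_overlapping_trips_rejected(self):
        cfg = validate_config(None)
        trips = [TripRecord("p1", 0, (0, 0), (1, 1), 8.0, 9.0, "shop"),
                 TripRecord("p1", 1, (1, 1), (0, 0), 8.5, 9.5, "home")]
        with pytest.raises(ValidationError, match="overlap"):
            daily_stp(trips, self._net(), cfg)

    def test_adding_a_trip_never_decreases_total(self):
        cfg = validate_config(None)
        net = self._net()
        base = [TripRecord("p1", 0, (0, 0), (2, 2), 8.0, 8.5, "shop")]
        extended = base + [TripRecord("p1", 1, (2, 2), (0, 2), 11.0, 11.3, "work")]
        assert daily_stp(extended, net, cfg).total_volume >= \
            daily_stp(base, net, cfg).total_volume


class TestLargeSTPFlag:
    def _pop(self, totals, weights=None):
        weights = weights or [1.0] * len(totals)
        return [DailySTP(f"p{i}", t, 0.0, w)
                for i, (t, w) in enumerate(zip(totals, weights))]

    def test_known_threshold(self):
        """Totals 1..8 with unit weights: the 75 % quantile interpolates to
        6.25, so exactly {7, 8} are flagged."""
        out = flag_large_stp(self._pop(list(range(1, 9))), 0.25)
        assert {s.person_id for s in out if s.large_stp} == {"p6", "p7"}

    def test_all_equal_all_flagged(self):
        out = flag_large_stp(self._pop([3.0] * 5), 0.25)
        assert all(s.large_stp for s in out)

    def test_weight_rescaling_leaves_flags_unchanged(self):
        totals = [1.0, 5.0, 2.0, 9.0, 4.0]
        weights = [1.0, 2.0, 0.5, 1.5, 3.0]
        a = flag_large_stp(self._pop(totals, weights), 0.25)
        b = flag_large_stp(self._pop(totals, [2 * w for w in weights]), 0.25)
        assert [s.large_stp for s in a] == [s.large_stp for s in b]

    def test_empty_population_rejected(self):
        with pytest.raises(ValidationError):
            flag_large_stp([], 0.25)


class TestWeightedQuantile:
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=40),
           st.floats(0, 1))
    @settings(max_examples=80, deadline=None)
    def test_equal_weights_reduce_to_numpy_linear(self, values, q):
        ours = weighted_quantile(values, q)
        assert ours == pytest.approx(float(np.quantile(values, q)), abs=1e-9)

    def test_weight_scale_invariance(self):
        v = [3.0, 1.0, 4.0, 1.5, 9.0]
        w = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert weighted_quantile(v, 0.4, w) == pytest.approx(
            weighted_quantile(v, 0.4, [10 * x for x in w]))

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=20),
           st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_level(self, values, q1, q2):
        lo, hi = sorted([q1, q2])
        w = [1.0 + (i % 3) for i in range(len(values))]
        assert weighted_quantile(values, lo, w) <= \
            weighted_quantile(values, hi, w) + 1e-12
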