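import json
import math

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from serisk.data_model import (
    CensusUnit,
    FormatError,
    PipelineConfig,
    PoIRecord,
    TripRecord,
    UnitIndex,
    ValidationError,
    assign_census_units,
    check_partition,
    read_city_bundle,
    read_network,
    read_pois,
    read_trips,
    validate_config,
    write_boundary,
    write_census_units,
    write_network,
    write_pois,
    write_trips,
)
from serisk.synthetic_city import generate_network


def make_trip(**kw):
    base = dict(person_id="p1", trip_index=0, origin=(0.0, 0.0),
                destination=(1.0, 1.0), depart_time=8.0, arrive_time=8.5,
                purpose="shop", expansion_factor=1.0)
    base.update(kw)
    return TripRecord(**base)


class TestConfig:
    def test_defaults(self):
        cfg = validate_config(None)
        assert cfg.agglomeration_quantile == 0.25
        assert cfg.psr_weights == {1: 1000.0, 2: 100.0, 3: 10.0, 4: 1.0}
        assert cfg.activity_weights["bar"] == 5.0
        assert cfg.activity_weights["library"] == 2.0

    def test_stricter_agglomeration_threshold_accepted(self):
        cfg = validate_config({"agglomeration_quantile": 0.125})
        assert cfg.agglomeration_quantile == 0.125

    @pytest.mark.parametrize("bad", [
        {"agglomeration_quantile": 1.5},
        {"mobility_quantile": 0.0},
        {"alpha": -0.1},
        {"psr_weights": {1: -5.0, 2: 100.0, 3: 10.0, 4: 1.0}},
        {"kde_bandwidth": 0.0},
    ])
    def test_invalid_values_rejected(self, bad):
        with pytest.raises(ValidationError):
            validate_config(bad)

    def test_unknown_key_rejected(self):
        with pytest.raises(ValidationError):
            validate_config({"not_a_setting": 1})


class TestTripValidation:
    def test_arrive_before_depart_rejected(self):
        with pytest.raises(ValidationError):
            make_trip(depart_time=9.0, arrive_time=8.0).validate()

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValidationError):
            make_trip(expansion_factor=0.0).validate()

    def test_unknown_purpose_rejected(self):
        with pytest.raises(ValidationError, match="bowling"):
            make_trip(purpose="bowling").validate()


class TestRoundTrip:
    def test_trips_round_trip_exact(self, tmp_path):
        trips = [make_trip(person_id=f"p{i}", origin=(i * 0.1234567891, 2.0),
                           destination=(3.0, i + 0.987654321))
                 for i in range(5)]
        path = tmp_path / "trips.csv"
        write_trips(trips, path)
        back = read_trips(path)
        for a, b in zip(trips, back):
            assert a.person_id == b.person_id
            assert a.trip_index == b.trip_index
            assert a.origin == pytest.approx(b.origin, abs=1e-9)
            assert a.destination == pytest.approx(b.destination, abs=1e-9)

    def test_missing_expansion_factor_named(self, tmp_path):
        path = tmp_path / "trips.csv"
        path.write_text("person_id,trip_index,ox,oy,dx,dy,depart,arrive,purpose\n"
                        "p1,0,0,0,1,1,8,9,shop\n")
        with pytest.raises(FormatError, match="expansion_factor"):
            read_trips(path)

    def test_overnight_trip_clipped(self, tmp_path):
        path = tmp_path / "trips.csv"
        write_trips([make_trip(depart_time=23.5, arrive_time=25.0)], path)
        back = read_trips(path)
        assert back[0].arrive_time == 24.0

    def test_lonlat_without_directive_refused(self, tmp_path):
        gj = {"type": "FeatureCollection", "features": [{
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [-0.12, 51.5]},
            "properties": {"poi_id": "x", "facility_type": "bar"}}]}
        path = tmp_path / "pois.geojson"
        path.write_text(json.dumps(gj))
        with pytest.raises(FormatError, match="lon/lat"):
            read_pois(path)


class TestUnitAssignment:
    def test_boundary_point_goes_to_first_sorting_unit(self):
        left = CensusUnit("b_unit", box(0, 0, 1, 1), 10)
        right = CensusUnit("a_unit", box(1, 0, 2, 1), 10)
        pois = [PoIRecord("p1", "bar", (1.0, 0.5))]  # exactly on the shared edge
        out = assign_census_units(pois, [left, right])
        assert out[0].census_unit_id == "a_unit"

    def test_point_outside_all_units_unassigned(self):
        units = [CensusUnit("u1", box(0, 0, 1, 1), 10)]
        out = assign_census_units([PoIRecord("p1", "bar", (5.0, 5.0))], units)
        assert out[0].census_unit_id is None

    def test_overlapping_partition_rejected(self, unit_square):
        units = [CensusUnit("u1", box(0, 0, 0.7, 1), 5),
                 CensusUnit("u2", box(0.5, 0, 1, 1), 5)]
        with pytest.raises(ValidationError, match="overlap"):
            check_partition(units, unit_square)


class TestBundleIO:
    def _write_minimal(self, tmp_path):
        write_trips([make_trip(destination=(0.5, 0.5)),
                     make_trip(person_id="p2", destination=(9.0, 9.0))],
                    tmp_path / "trips.csv")
        write_pois([PoIRecord("m1", "mall", (0.5, 0.5))],
                   tmp_path / "pois.geojson")
        write_census_units([CensusUnit("u1", box(0, 0, 2, 2), 100)],
                           tmp_path / "units.geojson")
        write_network(generate_network((2, 2), 1.0), tmp_path / "net.geojson")
        write_boundary(box(0, 0, 2, 2), tmp_path / "boundary.geojson")

    def test_minimal_bundle_loads_and_links(self, tmp_path):
        self._write_minimal(tmp_path)
        bundle = read_city_bundle(
            tmp_path / "trips.csv", tmp_path / "pois.geojson",
            tmp_path / "units.geojson", tmp_path / "net.geojson",
            tmp_path / "boundary.geojson")
        assert bundle.pois[0].census_unit_id == "u1"
        flags = {t.person_id: t.outside_boundary for t in bundle.trips}
        assert flags == {"p1": False, "p2": True}  # flagged, not dropped

    def test_network_round_trip(self, tmp_path):
        net = generate_network((2, 2), 1.0)
        write_network(net, tmp_path / "net.geojson")
        back = read_network(tmp_path / "net.geojson")
        assert len(back.nodes) == 9
        assert back.graph.number_of_edges() == 12

    def test_csv_edge_list_needs_nodes_table(self, tmp_path):
        path = tmp_path / "edges.csv"
        path.write_text("node_a,node_b,length_km\na,b,1.0\n")
        with pytest.raises(FormatError, match="nodes"):
            read_network(path)

    def test_edge_shorter_than_euclidean_rejected(self, tmp_path):
        (tmp_path / "nodes.csv").write_text("node_id,x,y\na,0,0\nb,3,4\n")
        (tmp_path / "edges.csv").write_text("node_a,node_b,length_km\na,b,1.0\n")
        with pytest.raises(ValidationError, match="straight-line"):
            read_network(tmp_path / "edges.csv", tmp_path / "nodes.csv")
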