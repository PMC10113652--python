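import dataclasses

import pytest
from shapely.geometry import box

from serisk import run_pipeline, validate_config
from serisk.synthetic_city import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def unit_square():
    return box(0.0, 0.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def small_scenario():
    """A scaled-down city: quick enough for per-module tests."""
    scfg = dataclasses.replace(
        ScenarioConfig(),
        extent_km=(10.0, 10.0), n_units=60, home_margin_km=2.0,
        poi_margin_km=1.5, n_persons=400,
        poi_counts={"bar": 24, "worship": 18, "gym": 15, "cinema": 8,
                    "library": 8, "mall": 6},
    )
    bundle, truth = generate_scenario(scfg, seed=7)
    return scfg, bundle, truth


@pytest.fixture(scope="session")
def default_run():
    """The default planted scenario and its full pipeline result."""
    bundle, truth = generate_scenario(seed=0)
    result = run_pipeline(bundle, validate_config(None))
    return bundle, truth, result
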