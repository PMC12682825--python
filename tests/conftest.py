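import numpy as np
import pytest

from stopsignal import engine
from stopsignal.phenotypes import Phenotype
from stopsignal.scenarios import ScenarioConfig
from stopsignal.soils import SoilLayer, build_profile, derive_hydraulics


@pytest.fixture(scope="session")
def run_cache():
    """Session-wide cache of finished simulation runs keyed by cell identity."""
    return {}


@pytest.fixture(scope="session")
def get_run(run_cache):
    def _get(soil, management, water, a_axial, a_lateral, co2=270.0, replicate=1):
        key = (soil, management, water, a_axial, a_lateral, co2, replicate)
        if key not in run_cache:
            cfg = ScenarioConfig(
                soil, management, water, co2, Phenotype(a_axial, a_lateral), replicate
            )
            run_cache[key] = engine.run(cfg)
        return run_cache[key]

    return _get


@pytest.fixture()
def sandy_loam_layer():
    return SoilLayer(0.0, 20.0, "sandy loam", bulk_density=1.45, organic_matter=2.0)


@pytest.fixture()
def toy_profile(sandy_loam_layer):
    """Single-layer 20 cm sandy loam column on the default 2 cm grid."""
    return build_profile([sandy_loam_layer], grid_dz=2.0)


@pytest.fixture()
def sandy_hydraulics(sandy_loam_layer):
    return derive_hydraulics(sandy_loam_layer)
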