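import numpy as np
import pytest

from aneuflow.geometry import AneurysmParams, build_geometry
from aneuflow.pipeline import RunConfig, run_experiment


@pytest.fixture(scope="session")
def type1_params():
    return AneurysmParams(model_type="type1", DA=10.0, CC=7.0, DP=10.0, CP=0.0, LA=0.0)


@pytest.fixture(scope="session")
def type2_params():
    return AneurysmParams(model_type="type2", DA=10.0, CC=7.0, DP=10.0, CP=0.02, LA=60.0)


@pytest.fixture(scope="session")
def type1_geometry(type1_params):
    return build_geometry(type1_params)


@pytest.fixture(scope="session")
def type2_geometry(type2_params):
    return build_geometry(type2_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def micro_config():
    """Small end-to-end configuration: 20 models, ~500 query points, 40 epochs."""
    return RunConfig.preset("ci", interior_density=0.03, surface_density=0.03,
                            max_epochs=40, max_epochs_pressure=40, patience=40,
                            split_ratio=0.8, max_query_points=500)


@pytest.fixture(scope="session")
def micro_velocity_runs():
    """Five seeded micro-scale velocity experiments (type ordering statistics).

    Deeper training than the smoke preset (120 epochs) so per-type error
    medians reflect task difficulty rather than early-training noise.
    """
    cfg = RunConfig.preset("ci", interior_density=0.03, surface_density=0.03,
                           max_epochs=120, max_epochs_pressure=120, patience=120,
                           split_ratio=0.8, max_query_points=500)
    return [run_experiment(cfg, seed=100 + i, variants=[("preop", "velocity")])
            for i in range(5)]
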