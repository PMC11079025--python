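import numpy as np
import pytest

from landmdi.grid import Grid, GridTransform
from landmdi.pipeline import prepare_classification_inputs
from landmdi.synthetic import ScenarioConfig, gen_process_inputs


@pytest.fixture
def transform():
    return GridTransform(0.0, 32 * 500.0, 500.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_grid(values, cell_size=500.0, nodata=None, crs_id=3035):
    values = np.asarray(values)
    tr = GridTransform(0.0, values.shape[0] * cell_size, cell_size)
    return Grid(values, tr, crs_id, nodata=nodata)


@pytest.fixture(scope="session")
def small_scenario():
    """One fully generated 48x48 scenario shared across read-only tests."""
    cfg = ScenarioConfig(shape=(48, 48), seed=7)
    land, zones, inputs, truth = gen_process_inputs(cfg)
    return cfg, land, zones, inputs, truth


@pytest.fixture(scope="session")
def classified_scenario(small_scenario):
    from landmdi.criticality import build_critical_stack

    cfg, land, zones, inputs, truth = small_scenario
    classify_inputs, raw = prepare_classification_inputs(inputs)
    masks, missing = build_critical_stack(classify_inputs)
    return cfg, land, zones, masks, raw, truth
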