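import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from wingbeam import comparative_inference as ci
from wingbeam import phylo_model as pm
from wingbeam import synthetic_data as sd

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def three_tip_tree() -> pm.Chronogram:
    return pm.read_tree("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset (seed 1) with three burst mystery taxa."""
    spec = sd.DatasetSpec(seed=1)
    table, tree, truth = sd.make_dataset(spec, seed=1)
    mystery = sd.make_mystery(spec, "burst", 3, seed=10_001)
    table = ci.TraitTable(pd.concat([table.data, mystery]))
    return spec, table, tree, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
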