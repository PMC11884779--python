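import numpy as np
import pandas as pd
import pytest

from aasub.matrix_io import to_rate_table
from aasub.modeling import ModelSpec
from aasub.properties import builtin_properties, pairwise_differences
from aasub.synth import (
    SynthScenario,
    generate_exchange_model,
    generate_feature_skeleton,
)


@pytest.fixture(scope="session")
def props():
    return builtin_properties()


@pytest.fixture(scope="session")
def diffs(props):
    return pairwise_differences(props)


def make_synth_data(scenario: SynthScenario) -> pd.DataFrame:
    """Feature table + simulated log rates for one scenario draw."""
    rng = np.random.default_rng(scenario.seed)
    feats = generate_feature_skeleton(scenario, rng=rng)
    model = generate_exchange_model(scenario, features=feats, rng=rng)
    rates = to_rate_table(model, mode=scenario.mode)
    keys = ["aa_from", "aa_to"] if scenario.mode == "directed" else ["aa1", "aa2"]
    return feats.merge(rates[keys + ["log_rate"]], on=keys, validate="one_to_one")


@pytest.fixture(scope="session")
def synth_data():
    return make_synth_data(SynthScenario(seed=11))


@pytest.fixture(scope="session")
def raw_spec():
    """Fit spec on the generator's own scale: z-scored predictors, raw response."""
    return ModelSpec(zscore_response=False)
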