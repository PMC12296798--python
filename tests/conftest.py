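import numpy as np
import pytest

import survweight as sw


@pytest.fixture
def tiny_dataset():
    """Four subjects, scalar covariate, all events, unit weights."""
    return sw.SurvivalDataset([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1],
                              [[1.0], [0.0], [1.0], [0.0]])


@pytest.fixture
def ph_cohort():
    """Moderate simulated proportional-hazards cohort (no tied times)."""
    spec = sw.DGPSpec("ph", [0.7], baseline=("constant", 1.0),
                      covariate_law=[("bernoulli", 0.5)],
                      censoring=("uniform", 4.0), n=400, seed=3)
    return sw.simulate(spec)


@pytest.fixture
def ah_cohort():
    spec = sw.DGPSpec("ah", [0.5], baseline=("constant", 1.0),
                      covariate_law=[("bernoulli", 0.5)],
                      censoring=("uniform", 2.0), n=400, seed=11)
    return sw.simulate(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)
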