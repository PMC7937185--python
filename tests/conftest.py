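import numpy as np
import pandas as pd
import pytest

from antvar import SimulationConfig, generate_study, transform_and_standardize


@pytest.fixture(scope="session")
def study_config():
    """Study-scale design: 12 + 11 colonies, 12 workers, 3 repeats."""
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def study(study_config):
    return generate_study(study_config)


@pytest.fixture(scope="session")
def trials_z(study):
    return transform_and_standardize(study.trials)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_grouped(rng, n_groups, n_per, s2b, s2w):
    """One-way grouped Gaussian data with known variance components."""
    g = np.repeat(np.arange(n_groups), n_per)
    y = rng.normal(0, np.sqrt(s2b), n_groups)[g] + rng.normal(0, np.sqrt(s2w), len(g))
    return pd.DataFrame({"g": g, "y": y})
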