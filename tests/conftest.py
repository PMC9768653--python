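import numpy as np
import pandas as pd
import pytest

from cogbattery.simulate import (
    SyntheticConfig,
    simulate_roster,
    simulate_trials,
    simulate_breeding,
)
from cogbattery.scoring import build_score_matrix
from cogbattery.gcp import extract_gcp


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def roster(default_config):
    return simulate_roster(default_config)


@pytest.fixture(scope="session")
def sequences(roster, default_config):
    return simulate_trials(roster, default_config)


@pytest.fixture(scope="session")
def scores(sequences):
    return build_score_matrix(sequences)


@pytest.fixture(scope="session")
def gcp_result(scores):
    return extract_gcp(scores)


@pytest.fixture(scope="session")
def breeding(roster, gcp_result, default_config):
    return simulate_breeding(roster, gcp_result.gcp, default_config)


@pytest.fixture(scope="session")
def large_cohort():
    """A 200-individual cohort with its scored battery (one expensive draw)."""
    cfg = SyntheticConfig(n_individuals=200, n_groups=50, seed=11)
    r = simulate_roster(cfg)
    sc = build_score_matrix(simulate_trials(r, cfg))
    return cfg, r, sc
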