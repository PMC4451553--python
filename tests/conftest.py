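import numpy as np
import pandas as pd
import pytest

from stratperm import PermutationConfig, SiteTable, StratificationPlan


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


def make_table(response, stressor, suitability, **extra) -> SiteTable:
    n = len(response)
    df = pd.DataFrame(
        {
            "site_id": [f"s{i:04d}" for i in range(n)],
            "response": response,
            "stressor": stressor,
            "suitability": suitability,
            **extra,
        }
    )
    return SiteTable(df)


def random_table(rng, n, p_resp=0.3, p_stress=0.3, continuous=False) -> SiteTable:
    stress = rng.binomial(1, p_stress, n).astype(float)
    if continuous:
        stress *= rng.lognormal(1.0, 1.0, n)
    return make_table(
        rng.binomial(1, p_resp, n),
        stress,
        rng.uniform(0.01, 0.99, n),
    )


@pytest.fixture
def toy_table():
    """One-stratum worked example: two stressor-positive unoccupied sites,
    two stressor-free occupied sites."""
    return make_table([0, 0, 1, 1], [1, 1, 0, 0], [0.5] * 4)


@pytest.fixture
def toy_plan():
    return StratificationPlan(1, [], [0, 0, 0, 0])


@pytest.fixture
def default_config():
    return PermutationConfig(n_permutations=10_000, seed=42)
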