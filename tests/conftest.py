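import numpy as np
import pytest

from eegraph import PipelineConfig, SyntheticCohortConfig, generate_cohort


def random_weighted_graph(
    rng: np.random.Generator,
    n: int,
    density: float = 1.0,
    low: float = 0.05,
    high: float = 1.0,
) -> np.ndarray:
    """Random symmetric zero-diagonal weight matrix, optionally sparsified."""
    W = rng.uniform(low, high, size=(n, n))
    W = (W + W.T) / 2.0
    if density < 1.0:
        mask = rng.random((n, n)) < density
        mask = np.triu(mask, 1)
        mask = mask | mask.T
        W = W * mask
    np.fill_diagonal(W, 0.0)
    return W


@pytest.fixture(scope="session")
def fast_config() -> PipelineConfig:
    """Pipeline config with reduced stochastic-measure settings for speed."""
    return PipelineConfig(
        louvain_restarts=3, sw_nulls=2, sw_rewires_per_edge=1, n_permutations=500
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-group cohort with a planted beta-band effect (shared
    across tests that only need *some* realistic cohort)."""
    config = SyntheticCohortConfig(n_per_group=6, group_effect={"beta": 0.15}, seed=42)
    subjects, covariates = generate_cohort(config)
    return config, subjects, covariates
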