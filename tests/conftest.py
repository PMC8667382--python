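import numpy as np
import pytest

from zibayes import (
    AggregateCounts,
    BinaryOutcomeData,
    SamplerConfig,
    UniformPriorPair,
)


@pytest.fixture(scope="session")
def paper_counts() -> AggregateCounts:
    """Aggregate data of the worked occupational-health example:
    430 presenteeism events among 1564 workers."""
    return AggregateCounts(m=430, n=1564)


@pytest.fixture(scope="session")
def default_priors() -> UniformPriorPair:
    return UniformPriorPair()


@pytest.fixture(scope="session")
def paper_outcomes() -> BinaryOutcomeData:
    """Per-observation 0/1 vector with the same sufficient statistics."""
    y = np.zeros(1564, dtype=int)
    y[:430] = 1
    return BinaryOutcomeData(y=y)


@pytest.fixture(scope="session")
def fast_config() -> SamplerConfig:
    """Reduced sampler settings for desk-scale tests."""
    return SamplerConfig(
        chains=2,
        iterations_per_chain=1000,
        target_accept=0.9,
        max_tree_depth=10,
        seed=20260927,
    )


def grid_posterior_weights(m: int, n: int, priors: UniformPriorPair, grid: int = 400):
    """Brute-force midpoint-grid oracle of the joint no-covariate posterior.

    Computes (omega*p)^m (1 - omega*p)^(n-m) directly from the model
    definition, independently of the package's closed-form marginals.
    Returns midpoint coordinates and unnormalized cell weights.
    """
    w_edges = np.linspace(priors.omega_lo, priors.omega_hi, grid + 1)
    p_edges = np.linspace(priors.p_lo, priors.p_hi, grid + 1)
    wc = (w_edges[:-1] + w_edges[1:]) / 2
    pc = (p_edges[:-1] + p_edges[1:]) / 2
    W, P = np.meshgrid(wc, pc, indexing="ij")
    t = W * P
    with np.errstate(divide="ignore", invalid="ignore"):
        logw = np.where(t > 0, m * np.log(t), 0.0 if m == 0 else -np.inf)
        logw = logw + (n - m) * np.log1p(-t)
    logw -= logw.max()
    return wc, pc, np.exp(logw)
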