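"""Synthetic ZIB data generators mirroring the simulation-study design.

Regression datasets draw four independent standard-normal covariates;
the exposure layer uses x1, x2 through logit(P(exposed)) = theta0 +
theta1*x1 + theta2*x2 and the occurrence layer uses x3, x4 through
logit(P(event | exposed)) = beta0 + beta1*x3 + beta2*x4.  The observed
outcome is the product of the two latent Bernoulli draws; the latent
exposure labels ride along for test oracles (a real survey never sees
them).

Each dataset owns one seeded generator with fixed-order sub-streams for
covariates, exposure and occurrence, so extending the design never
reshuffles earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .zib_core import BinaryOutcomeData, invlogit

__all__ = [
    "SimulationScenario",
    "simulate_regression_dataset",
    "simulate_nocov_dataset",
]


@dataclass(frozen=True)
class SimulationScenario:
    """One cell of the simulation design: true coefficient vectors for
    both parts, the sample size and the seed."""

    beta: tuple[float, float, float] = (0.5, 2.0, 3.0)
    theta: tuple[float, float, float] = (-0.5, -2.0, -3.0)
    n: int = 1500
    seed: int = 0
    shared_covariates: bool = False  # reuse x1, x2 in the occurrence part

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("sample size must be positive")
        if len(self.beta) != 3 or len(self.theta) != 3:
            raise ValueError("beta and theta must each have 3 entries")


def _substreams(seed: int, k: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(k)]


def simulate_regression_dataset(scenario: SimulationScenario) -> BinaryOutcomeData:
    """Draw one dataset from the scenario; the returned object carries the
    latent exposure labels in ``.exposure``."""
    rng_cov, rng_exp, rng_occ = _substreams(scenario.seed, 3)
    n = scenario.n
    x = rng_cov.standard_normal((n, 4))
    X = x[:, :2]
    Z = x[:, :2] if scenario.shared_covariates else x[:, 2:]

    t0, t1, t2 = scenario.theta
    b0, b1, b2 = scenario.beta
    p_exposed = invlogit(t0 + t1 * X[:, 0] + t2 * X[:, 1])
    p_event = invlogit(b0 + b1 * Z[:, 0] + b2 * Z[:, 1])

    exposure = (rng_exp.random(n) < p_exposed).astype(np.int8)
    occurrence = (rng_occ.random(n) < p_event).astype(np.int8)
    y = exposure * occurrence
    return BinaryOutcomeData(y=y, X=X, Z=Z, exposure=exposure)


def simulate_nocov_dataset(
    omega: float, p: float, n: int, seed: int
) -> BinaryOutcomeData:
    """Two-layer Bernoulli draw without covariates: exposure ~
    Bernoulli(omega), outcome = exposure * Bernoulli(p); the marginal
    outcome is Bernoulli(omega * p)."""
    if not (0.0 <= omega <= 1.0 and 0.0 <= p <= 1.0):
        raise ValueError(f"omega and p must lie in [0, 1]; got {omega}, {p}")
    if n <= 0:
        raise ValueError("sample size must be positive")
    rng_exp, rng_occ = _substreams(seed, 2)
    exposure = (rng_exp.random(n) < omega).astype(np.int8)
    occurrence = (rng_occ.random(n) < p).astype(np.int8)
    y = exposure * occurrence
    return BinaryOutcomeData(y=y, exposure=exposure)
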