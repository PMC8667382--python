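"""Core probability model for zero-inflated Bernoulli (ZIB) outcomes.

A ZIB observation arises from two latent Bernoulli layers: an exposure
indicator with success probability ``omega`` (a unit is "at risk") and,
among exposed units only, an event indicator with success probability
``p``.  Marginally the outcome is Bernoulli(omega * p); a zero can be
*structural* (never exposed, probability ``1 - omega``) or a *sample*
zero (exposed but no event, probability ``omega * (1 - p)``).  The two
factorizations of a given product omega*p are indistinguishable from the
likelihood alone, which is exactly why the Bayesian modules of this
package put informative priors on the two parameters.

Both model parts take logit links when covariates enter:

    logit(omega_i) = theta' [1, x_i],   logit(p_i) = beta' [1, z_i].

This module is pure computation (densities and log-likelihoods); it is
consumed by the analytic-posterior, MCMC, simulation and baseline layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit as _logit

__all__ = [
    "ZIBParameters",
    "AggregateCounts",
    "RegressionParameters",
    "BinaryOutcomeData",
    "invlogit",
    "logit",
    "zib_pmf",
    "zib_loglik_aggregate",
    "zib_loglik_regression",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ZIBParameters:
    """The pair (omega, p): exposure and occurrence-among-exposed probabilities."""

    omega: float
    p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.omega <= 1.0) or not (0.0 <= self.p <= 1.0):
            raise ValueError(
                f"omega and p must lie in [0, 1]; got omega={self.omega}, p={self.p}"
            )

    @property
    def structural_zero_prob(self) -> float:
        return 1.0 - self.omega

    @property
    def sample_zero_prob(self) -> float:
        return self.omega * (1.0 - self.p)

    @property
    def event_prob(self) -> float:
        return self.omega * self.p


@dataclass(frozen=True)
class AggregateCounts:
    """Sufficient statistics of the no-covariate model: m events out of n."""

    m: int
    n: int

    def __post_init__(self) -> None:
        if self.n < 0 or self.m < 0 or self.m > self.n:
            raise ValueError(f"need 0 <= m <= n; got m={self.m}, n={self.n}")


@dataclass(frozen=True)
class RegressionParameters:
    """Coefficients for the two logit-linked parts with their prior scales.

    ``theta`` governs the structural (exposure) part, ``beta`` the
    occurrence part; each vector includes its intercept as entry 0.
    ``sigma_theta`` / ``sigma_beta`` are the normal-prior standard
    deviations of the non-degenerate coefficient priors.
    """

    theta: np.ndarray
    beta: np.ndarray
    sigma_theta: float = 10.0
    sigma_beta: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", np.atleast_1d(np.asarray(self.theta, float)))
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, float)))
        if self.sigma_theta <= 0 or self.sigma_beta <= 0:
            raise ValueError("prior scales must be positive")


@dataclass
class BinaryOutcomeData:
    """Binary outcomes with (possibly empty) covariate blocks for each part.

    ``X`` holds structural-part covariates, ``Z`` occurrence-part
    covariates; neither contains an intercept column (one is prepended
    internally everywhere).  ``exposure`` optionally carries the latent
    at-risk labels when the data come from the simulator.
    """

    y: np.ndarray
    X: np.ndarray | None = None
    Z: np.ndarray | None = None
    exposure: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if self.y.ndim != 1:
            raise ValueError("y must be one-dimensional")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("outcome values must be exactly 0 or 1")
        self.y = self.y.astype(np.int8)
        n = self.y.shape[0]
        for name in ("X", "Z"):
            mat = getattr(self, name)
            if mat is None:
                setattr(self, name, np.empty((n, 0)))
                continue
            mat = np.asarray(mat, float)
            if mat.ndim == 1:
                mat = mat[:, None]
            if mat.shape[0] != n:
                raise ValueError(f"{name} has {mat.shape[0]} rows but y has {n}")
            if not np.isfinite(mat).all():
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, mat)

    @property
    def n(self) -> int:
        return int(self.y.shape[0])

    @property
    def counts(self) -> AggregateCounts:
        return AggregateCounts(m=int(self.y.sum()), n=self.n)


# ---------------------------------------------------------------------------
# links
# ---------------------------------------------------------------------------


def invlogit(x):
    """Numerically stable inverse logit 1 / (1 + exp(-x)), elementwise."""
    return expit(x)


def logit(q):
    """Log-odds log(q / (1 - q)), elementwise."""
    return _logit(q)


def _log_invlogit(x: np.ndarray) -> np.ndarray:
    # log sigmoid(x) = -softplus(-x), computed without overflow
    return -np.logaddexp(0.0, -x)


def _log1mexp(logx: np.ndarray) -> np.ndarray:
    """log(1 - exp(logx)) for logx <= 0, stable near both ends."""
    logx = np.asarray(logx, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            logx < -np.log(2.0),
            np.log1p(-np.exp(logx)),
            np.log(-np.expm1(np.minimum(logx, 0.0))),
        )
    return np.where(logx >= 0.0, -np.inf, out)


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------


def zib_pmf(params: ZIBParameters, y: int) -> float:
    """Probability of outcome ``y`` under the ZIB model.

    P(Y=1) = omega * p;  P(Y=0) = (1 - omega) + omega * (1 - p).
    """
    if y not in (0, 1):
        raise ValueError(f"outcome must be 0 or 1; got {y!r}")
    t = params.omega * params.p
    return t if y == 1 else 1.0 - t


def zib_loglik_aggregate(params: ZIBParameters, counts: AggregateCounts) -> float:
    """Aggregate log-likelihood m*log(omega*p) + (n-m)*log(1 - omega*p).

    Depends on (omega, p) only through the product omega*p — the
    frequentist non-identifiability that motivates the Bayesian
    treatment.  Returns -inf (never raises) when the data demand a
    probability that the parameters set to zero.
    """
    t = params.omega * params.p
    m, n = counts.m, counts.n
    with np.errstate(divide="ignore"):
        term1 = 0.0 if m == 0 else m * np.log(t)
        term0 = 0.0 if n == m else (n - m) * np.log1p(-t)
    return float(term1 + term0)


def _linear_predictors(
    params: RegressionParameters, data: BinaryOutcomeData
) -> tuple[np.ndarray, np.ndarray]:
    n = data.n
    if params.theta.shape[0] != data.X.shape[1] + 1:
        raise ValueError(
            f"theta has length {params.theta.shape[0]} but X implies "
            f"{data.X.shape[1] + 1} (intercept prepended internally)"
        )
    if params.beta.shape[0] != data.Z.shape[1] + 1:
        raise ValueError(
            f"beta has length {params.beta.shape[0]} but Z implies "
            f"{data.Z.shape[1] + 1} (intercept prepended internally)"
        )
    a = params.theta[0] + data.X @ params.theta[1:] if data.X.shape[1] else np.full(n, params.theta[0])
    b = params.beta[0] + data.Z @ params.beta[1:] if data.Z.shape[1] else np.full(n, params.beta[0])
    return a, b


def zib_loglik_regression(params: RegressionParameters, data: BinaryOutcomeData) -> float:
    """Per-observation ZIB log-likelihood with logit links on both parts.

    Computed in the log domain throughout: log P(Y=1) is a sum of two
    log-sigmoids, and log P(Y=0) = log(1 - exp(log omega + log p)) goes
    through a stable log1mexp, never by exponentiating logits first.
    """
    a, b = _linear_predictors(params, data)
    log_t = _log_invlogit(a) + _log_invlogit(b)  # log(omega_i * p_i)
    ones = data.y == 1
    ll = log_t[ones].sum() + _log1mexp(log_t[~ones]).sum()
    return float(ll)
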