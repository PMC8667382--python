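"""Exact posterior inference for the no-covariate ZIB model.

With aggregate data (m events out of n) and independent uniform priors
omega ~ U[a_w, b_w], p ~ U[a_p, b_p], the joint posterior is the
truncated Bernoulli(omega*p) likelihood

    f(p, omega)  ∝  (p*omega)^m (1 - p*omega)^(n-m)

on the prior box.  Integrating one parameter out gives closed-form
unnormalized marginals in terms of the beta distribution function
F(.; m+1, n-m+1) (the regularized incomplete beta):

    f(omega) ∝ [F(b_p * omega) - F(a_p * omega)] / omega
    f(p)     ∝ [F(b_w * p)     - F(a_w * p)]     / p

which at the default supports U[0, 1/2] x U[1/2, 1] reduce to
[F(omega) - F(omega/2)] / omega and F(p/2) / p.  Normalization uses
adaptive quadrature, quantiles root-finding on the quadrature CDF.
The apparent singularity at 0 is removable: the bracket vanishes like
x^(m+1), so the density tends to 0 for m >= 1 and to a finite limit
(b - a) * (n + 1) (unnormalized) for m = 0; both branches are evaluated
analytically.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import beta as beta_dist

from .zib_core import AggregateCounts, ZIBParameters, zib_loglik_aggregate

__all__ = [
    "UniformPriorPair",
    "MarginalPosterior",
    "ExactSummary",
    "joint_log_posterior",
    "marginal_density_omega",
    "marginal_density_p",
    "posterior_quantile",
    "summarize_exact",
]

_QUAD_KW = dict(epsabs=1e-10, epsrel=1e-10, limit=200)
_QUANTILE_XTOL = 1e-8


@dataclass(frozen=True)
class UniformPriorPair:
    """Supports of the independent uniform priors on omega and p.

    The defaults U[0, 0.5] for omega and U[0.5, 1] for p encode the
    assumption that structural zeros are the majority zero source
    (1 - omega > 0.5) while exposed units experience the event more
    often than not (p > 0.5); it is this asymmetry that renders the
    two parameters identifiable.
    """

    omega_lo: float = 0.0
    omega_hi: float = 0.5
    p_lo: float = 0.5
    p_hi: float = 1.0

    def __post_init__(self) -> None:
        ok = (
            0.0 <= self.omega_lo < self.omega_hi <= 1.0
            and 0.0 <= self.p_lo < self.p_hi <= 1.0
        )
        if not ok:
            raise ValueError(f"invalid prior supports: {self}")

    def support(self, target: str) -> tuple[float, float]:
        if target == "omega":
            return self.omega_lo, self.omega_hi
        if target == "p":
            return self.p_lo, self.p_hi
        raise ValueError(f"target must be 'omega' or 'p', got {target!r}")


def joint_log_posterior(
    params: ZIBParameters, counts: AggregateCounts, priors: UniformPriorPair
) -> float:
    """Unnormalized joint log posterior: the aggregate log-likelihood on the
    prior box, -inf outside it."""
    inside = (
        priors.omega_lo <= params.omega <= priors.omega_hi
        and priors.p_lo <= params.p <= priors.p_hi
    )
    if not inside:
        return -np.inf
    return zib_loglik_aggregate(params, counts)


class MarginalPosterior:
    """Normalized marginal posterior of one parameter (omega or p).

    Evaluates the closed-form unnormalized density, its normalizing
    constant (adaptive quadrature), CDF, and quantiles (Brent root
    finding on the CDF).
    """

    def __init__(
        self,
        target: str,
        counts: AggregateCounts,
        priors: UniformPriorPair = UniformPriorPair(),
    ) -> None:
        self.target = target
        self.counts = counts
        self.priors = priors
        self.lo, self.hi = priors.support(target)
        # the *other* parameter's support scales the beta-CDF arguments
        self._a, self._b = priors.support("p" if target == "omega" else "omega")
        self._F = beta_dist(counts.m + 1, counts.n - counts.m + 1).cdf

    # -- unnormalized density ------------------------------------------------

    def _unnormalized(self, x):
        x = np.asarray(x, float)
        m, n = self.counts.m, self.counts.n
        with np.errstate(divide="ignore", invalid="ignore"):
            val = (self._F(self._b * x) - self._F(self._a * x)) / x
        # removable singularity at 0: bracket ~ x^(m+1)
        limit0 = 0.0 if m >= 1 else (self._b - self._a) * (n + 1)
        val = np.where(x == 0.0, limit0, val)
        return np.where((x >= self.lo) & (x <= self.hi), val, 0.0)

    @cached_property
    def normalizing_constant(self) -> float:
        z = quad(lambda x: float(self._unnormalized(x)), self.lo, self.hi, **_QUAD_KW)[0]
        if not z > 0:
            raise ValueError(f"degenerate posterior: normalizing constant {z}")
        return z

    # -- normalized density / CDF / quantiles --------------------------------

    def pdf(self, x):
        return self._unnormalized(x) / self.normalizing_constant

    def cdf(self, x: float) -> float:
        x = float(np.clip(x, self.lo, self.hi))
        if x == self.lo:
            return 0.0
        val = quad(lambda t: float(self._unnormalized(t)), self.lo, x, **_QUAD_KW)[0]
        return min(val / self.normalizing_constant, 1.0)

    def quantile(self, q: float) -> float:
        if not 0.0 < q < 1.0:
            raise ValueError(f"quantile level must be in (0, 1); got {q}")
        return brentq(
            lambda x: self.cdf(x) - q, self.lo, self.hi, xtol=_QUANTILE_XTOL
        )

    def credible_interval(self, level: float = 0.95) -> tuple[float, float]:
        alpha = (1.0 - level) / 2.0
        return self.quantile(alpha), self.quantile(1.0 - alpha)


def marginal_density_omega(
    omega, counts: AggregateCounts, priors: UniformPriorPair = UniformPriorPair()
):
    """Normalized marginal posterior density of omega at the given point(s)."""
    return MarginalPosterior("omega", counts, priors).pdf(omega)


def marginal_density_p(
    p, counts: AggregateCounts, priors: UniformPriorPair = UniformPriorPair()
):
    """Normalized marginal posterior density of p at the given point(s)."""
    return MarginalPosterior("p", counts, priors).pdf(p)


def posterior_quantile(
    target: str,
    q: float,
    counts: AggregateCounts,
    priors: UniformPriorPair = UniformPriorPair(),
) -> float:
    """Quantile of the normalized marginal posterior of ``target``."""
    return MarginalPosterior(target, counts, priors).quantile(q)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExactSummary:
    """Medians and central 95% intervals of omega, p and the event
    probability omega*p."""

    counts: AggregateCounts
    priors: UniformPriorPair
    omega: tuple[float, float, float]  # (median, lower 2.5%, upper 97.5%)
    p: tuple[float, float, float]
    event_prob: tuple[float, float, float]
    normalizing_constant_omega: float
    normalizing_constant_p: float

    def rounded(self, ndigits: int = 2) -> dict:
        rnd = lambda t: tuple(round(v, ndigits) for v in t)
        return {
            "omega": rnd(self.omega),
            "p": rnd(self.p),
            "event_prob": rnd(self.event_prob),
        }


def _product_quantiles(
    counts: AggregateCounts,
    priors: UniformPriorPair,
    qs: tuple[float, ...],
    grid: int = 400,
) -> tuple[float, ...]:
    """Quantiles of omega*p under the joint posterior, via a midpoint grid
    over the prior box (the product has no one-dimensional closed form)."""
    w = np.linspace(priors.omega_lo, priors.omega_hi, grid + 1)
    pp = np.linspace(priors.p_lo, priors.p_hi, grid + 1)
    wc, pc = (w[:-1] + w[1:]) / 2.0, (pp[:-1] + pp[1:]) / 2.0
    W, P = np.meshgrid(wc, pc, indexing="ij")
    t = W * P
    m, n = counts.m, counts.n
    with np.errstate(divide="ignore"):
        logw = m * np.log(t, where=t > 0, out=np.full_like(t, -np.inf)) + (
            n - m
        ) * np.log1p(-t)
    logw -= logw.max()
    weight = np.exp(logw).ravel()
    weight /= weight.sum()
    order = np.argsort(t.ravel())
    tv, cw = t.ravel()[order], np.cumsum(weight[order])
    return tuple(float(tv[np.searchsorted(cw, q)]) for q in qs)


def summarize_exact(
    counts: AggregateCounts, priors: UniformPriorPair = UniformPriorPair()
) -> ExactSummary:
    """Exact-posterior summary: quadrature medians and 95% intervals for
    omega and p, grid-based summary for the event probability omega*p."""
    mw = MarginalPosterior("omega", counts, priors)
    mp = MarginalPosterior("p", counts, priors)
    qs = (0.5, 0.025, 0.975)
    return ExactSummary(
        counts=counts,
        priors=priors,
        omega=tuple(mw.quantile(q) for q in qs),
        p=tuple(mp.quantile(q) for q in qs),
        event_prob=_product_quantiles(counts, priors, qs),
        normalizing_constant_omega=mw.normalizing_constant,
        normalizing_constant_p=mp.normalizing_constant,
    )
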