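import numpy as np
import pytest
from scipy.integrate import quad

from zibayes import (
    AggregateCounts,
    MarginalPosterior,
    UniformPriorPair,
    ZIBParameters,
    joint_log_posterior,
    marginal_density_omega,
    marginal_density_p,
    posterior_quantile,
    summarize_exact,
)

from conftest import grid_posterior_weights


class TestJointPosterior:
    def test_truncation_outside_prior_box(self, paper_counts, default_priors):
        assert joint_log_posterior(
            ZIBParameters(0.6, 0.7), paper_counts, default_priors
        ) == -np.inf

    def test_flat_with_no_data(self, default_priors):
        assert joint_log_posterior(
            ZIBParameters(0.3, 0.8), AggregateCounts(0, 0), default_priors
        ) == 0.0

    def test_grid_integral_matches_normalizing_constant(
        self, paper_counts, default_priors
    ):
        # integrate the joint posterior over the box by 400x400 midpoint rule;
        # the closed-form marginal divides the likelihood by B(m+1, n-m+1)
        # (the beta-function prefactor of the regularized incomplete beta),
        # so the grid mass rescaled by that factor must match the marginal's
        # normalizing constant
        from scipy.special import betaln

        m, n = paper_counts.m, paper_counts.n
        wc, pc, weights = grid_posterior_weights(m, n, default_priors)
        dw, dp = wc[1] - wc[0], pc[1] - pc[0]
        W, P = np.meshgrid(wc, pc, indexing="ij")
        t = W * P
        logmax = (m * np.log(t) + (n - m) * np.log1p(-t)).max()
        grid_mass = weights.sum() * dw * dp * np.exp(logmax - betaln(m + 1, n - m + 1))
        z = MarginalPosterior("omega", paper_counts, default_priors).normalizing_constant
        assert grid_mass == pytest.approx(z, rel=1e-3)


class TestMarginalDensities:
    @pytest.mark.parametrize(
        "m,n",
        [(m, n) for m in range(0, 6) for n in range(max(m, 1), 11)] + [(430, 1564)],
    )
    def test_marginals_integrate_to_one(self, m, n, default_priors):
        counts = AggregateCounts(m, n)
        for target in ("omega", "p"):
            marg = MarginalPosterior(target, counts, default_priors)
            total = quad(lambda x: float(marg.pdf(x)), marg.lo, marg.hi, limit=200)[0]
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_m0_n1_closed_form(self, default_priors):
        # symbolically, f(omega) ∝ 1 - 3*omega/4 on [0, 1/2]; normalized
        # value at 0 is 32/13
        counts = AggregateCounts(0, 1)
        dens = marginal_density_omega(np.array([0.0]), counts, default_priors)
        assert dens[0] == pytest.approx(32 / 13, rel=1e-9)
        # shape check against the symbolic form at interior points
        marg = MarginalPosterior("omega", counts, default_priors)
        x = np.array([0.1, 0.3, 0.45])
        ratio = marg.pdf(x) / (1 - 3 * x / 4)
        assert np.allclose(ratio, ratio[0], rtol=1e-9)

    def test_no_data_posterior_equals_prior(self, default_priors):
        counts = AggregateCounts(0, 0)
        assert marginal_density_p(0.7, counts, default_priors) == pytest.approx(2.0)
        assert marginal_density_omega(0.3, counts, default_priors) == pytest.approx(2.0)

    def test_outside_support_is_zero(self, paper_counts, default_priors):
        assert marginal_density_omega(0.7, paper_counts, default_priors) == 0.0
        assert marginal_density_p(0.3, paper_counts, default_priors) == 0.0

    @pytest.mark.parametrize("m,n", [(430, 1564), (3, 10), (0, 5)])
    def test_closed_form_matches_grid_oracle(self, m, n, default_priors):
        # marginalize the brute-force 2-D grid and compare pointwise
        counts = AggregateCounts(m, n)
        wc, pc, weights = grid_posterior_weights(m, n, default_priors)
        dw, dp = wc[1] - wc[0], pc[1] - pc[0]

        omega_grid = weights.sum(axis=1) * dp
        omega_grid /= omega_grid.sum() * dw
        got = marginal_density_omega(wc, counts, default_priors)
        assert np.max(np.abs(got - omega_grid)) <= 1e-3 * max(1, omega_grid.max())

        p_grid = weights.sum(axis=0) * dw
        p_grid /= p_grid.sum() * dp
        got_p = marginal_density_p(pc, counts, default_priors)
        assert np.max(np.abs(got_p - p_grid)) <= 1e-3 * max(1, p_grid.max())

    def test_general_priors_reduce_to_default_form(self, paper_counts):
        wide = UniformPriorPair(0.0, 0.5, 0.5, 1.0)
        x = np.linspace(0.05, 0.45, 7)
        assert np.allclose(
            marginal_density_omega(x, paper_counts, wide),
            marginal_density_omega(x, paper_counts),
        )
        # a genuinely different box still integrates to 1
        other = UniformPriorPair(0.1, 0.6, 0.4, 0.9)
        marg = MarginalPosterior("omega", paper_counts, other)
        total = quad(lambda t: float(marg.pdf(t)), marg.lo, marg.hi, limit=200)[0]
        assert total == pytest.approx(1.0, abs=1e-6)


class TestQuantiles:
    def test_paper_point_estimates(self, paper_counts, default_priors):
        assert round(
            posterior_quantile("omega", 0.5, paper_counts, default_priors), 2
        ) == 0.37
        assert round(
            posterior_quantile("p", 0.5, paper_counts, default_priors), 2
        ) == 0.74

    def test_paper_credible_intervals(self, paper_counts, default_priors):
        lo = posterior_quantile("p", 0.025, paper_counts, default_priors)
        hi = posterior_quantile("p", 0.975, paper_counts, default_priors)
        assert (round(lo, 2), round(hi, 2)) == (0.55, 0.99)

    def test_monotone_and_inverse_of_cdf(self, paper_counts, default_priors):
        marg = MarginalPosterior("omega", paper_counts, default_priors)
        qs = [0.1, 0.25, 0.5, 0.75, 0.9]
        xs = [marg.quantile(q) for q in qs]
        assert all(a < b for a, b in zip(xs, xs[1:]))
        for x in xs:
            assert marg.quantile(marg.cdf(x)) == pytest.approx(x, abs=1e-6)

    def test_support_confinement(self, default_priors):
        for counts in (AggregateCounts(0, 3), AggregateCounts(5, 9)):
            for q in (0.01, 0.5, 0.99):
                x = posterior_quantile("omega", q, counts, default_priors)
                assert 0.0 <= x <= 0.5

    def test_invalid_quantile_level(self, paper_counts, default_priors):
        with pytest.raises(ValueError):
            posterior_quantile("omega", 1.5, paper_counts, default_priors)


class TestSummaries:
    def test_paper_summary(self, paper_counts):
        summ = summarize_exact(paper_counts)
        rounded = summ.rounded()
        assert rounded["omega"] == (0.37, 0.27, 0.49)
        assert rounded["p"] == (0.74, 0.55, 0.99)

    def test_product_median_near_sample_proportion(self, paper_counts):
        summ = summarize_exact(paper_counts)
        assert summ.event_prob[0] == pytest.approx(430 / 1564, abs=0.01)

    def test_no_data_medians_equal_prior_medians(self):
        summ = summarize_exact(AggregateCounts(0, 0))
        assert summ.omega[0] == pytest.approx(0.25, abs=1e-6)
        assert summ.p[0] == pytest.approx(0.75, abs=1e-6)

    def test_product_interval_concentrates_with_n(self):
        # fixed event proportion ~0.275, growing n
        widths = []
        for m, n in ((27, 100), (430, 1564), (2750, 10000)):
            s = summarize_exact(AggregateCounts(m, n))
            widths.append(s.event_prob[2] - s.event_prob[1])
        assert widths[0] > widths[1] > widths[2]

    def test_invalid_prior_box(self):
        with pytest.raises(ValueError):
            UniformPriorPair(0.5, 0.2, 0.5, 1.0)
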