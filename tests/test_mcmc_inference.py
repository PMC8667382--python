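import numpy as np
import pytest

from zibayes import (
    BinaryOutcomeData,
    CoefficientPrior,
    PosteriorDraws,
    SamplerConfig,
    UniformPriorPair,
    check_convergence,
    fit_zib_mcmc,
    summarize_draws,
    summarize_exact,
)
from zibayes.synthetic_data import SimulationScenario, simulate_regression_dataset


def _draws_from_array(arr: np.ndarray, names) -> PosteriorDraws:
    return PosteriorDraws(
        draws=arr, names=list(names), config=SamplerConfig(chains=arr.shape[0])
    )


class TestNoCovariateFits:
    def test_seeded_determinism(self, paper_outcomes, fast_config):
        small = SamplerConfig(
            chains=2, iterations_per_chain=300, target_accept=0.8,
            max_tree_depth=8, seed=7,
        )
        a = fit_zib_mcmc(paper_outcomes, UniformPriorPair(), small)
        b = fit_zib_mcmc(paper_outcomes, UniformPriorPair(), small)
        assert np.array_equal(a.draws, b.draws)

    def test_matches_exact_posterior(self, paper_outcomes, paper_counts, fast_config):
        draws = fit_zib_mcmc(paper_outcomes, UniformPriorPair(), fast_config)
        summ = summarize_draws(draws).table
        exact = summarize_exact(paper_counts)
        for name, (med, lo, hi) in (("omega", exact.omega), ("p", exact.p)):
            assert summ.loc[name, "median"] == pytest.approx(med, abs=0.02)
            assert summ.loc[name, "lower"] == pytest.approx(lo, abs=0.03)
            assert summ.loc[name, "upper"] == pytest.approx(hi, abs=0.03)

    def test_prior_recovery_without_data(self, fast_config):
        data = BinaryOutcomeData(y=np.empty(0, dtype=int))
        draws = fit_zib_mcmc(data, UniformPriorPair(), fast_config)
        summ = summarize_draws(draws).table
        assert summ.loc["omega", "median"] == pytest.approx(0.25, abs=0.02)
        assert summ.loc["p", "median"] == pytest.approx(0.75, abs=0.02)

    def test_all_ones_piles_at_upper_bounds(self, fast_config):
        data = BinaryOutcomeData(y=np.ones(200, dtype=int))
        draws = fit_zib_mcmc(data, UniformPriorPair(), fast_config)
        summ = summarize_draws(draws).table
        assert summ.loc["omega", "median"] > 0.45
        assert summ.loc["p", "median"] > 0.9

    def test_overlapping_priors_warn_about_identifiability(self, fast_config):
        data = BinaryOutcomeData(y=np.array([0, 1] * 50))
        priors = UniformPriorPair(0.0, 0.8, 0.2, 1.0)
        draws = fit_zib_mcmc(data, priors, fast_config)
        assert any("identifiable" in w for w in draws.warnings)

    def test_metropolis_fallback_agrees_on_medians(self, paper_outcomes, paper_counts):
        config = SamplerConfig(
            chains=2, iterations_per_chain=8000, seed=3, method="metropolis"
        )
        draws = fit_zib_mcmc(paper_outcomes, UniformPriorPair(), config)
        summ = summarize_draws(draws).table
        exact = summarize_exact(paper_counts)
        assert summ.loc["omega", "median"] == pytest.approx(exact.omega[0], abs=0.04)
        assert summ.loc["p", "median"] == pytest.approx(exact.p[0], abs=0.06)


class TestRegressionFits:
    def test_recovers_generating_coefficients(self, fast_config):
        data = simulate_regression_dataset(SimulationScenario(n=1500, seed=7))
        draws = fit_zib_mcmc(data, config=fast_config)
        summ = summarize_draws(draws).table
        truth = {
            "theta0": -0.5, "theta1": -2.0, "theta2": -3.0,
            "beta0": 0.5, "beta1": 2.0, "beta2": 3.0,
        }
        for name, value in truth.items():
            assert summ.loc[name, "lower"] - 0.2 < value < summ.loc[name, "upper"] + 0.2

    def test_hyperprior_mode_samples_scales(self, fast_config):
        data = simulate_regression_dataset(SimulationScenario(n=400, seed=2))
        draws = fit_zib_mcmc(data, CoefficientPrior(hyper=True), fast_config)
        assert "sigma_theta" in draws.names and "sigma_beta" in draws.names
        assert (draws.pooled("sigma_theta") > 0).all()

    def test_rejects_non_binary_outcome(self):
        with pytest.raises(ValueError):
            BinaryOutcomeData(y=np.array([0, 1, 2]))


class TestSummaries:
    def test_degenerate_draws_flagged(self):
        arr = np.full((2, 100, 1), 3.14)
        draws = _draws_from_array(arr, ["c"])
        summ = summarize_draws(draws).table
        assert summ.loc["c", "median"] == summ.loc["c", "lower"] == 3.14
        assert np.isnan(summ.loc["c", "rhat"])

    def test_standard_normal_draws_quantiles(self):
        rng = np.random.default_rng(0)
        arr = rng.standard_normal((4, 2500, 1))
        summ = summarize_draws(_draws_from_array(arr, ["z"])).table
        assert summ.loc["z", "median"] == pytest.approx(0.0, abs=0.05)
        assert summ.loc["z", "lower"] == pytest.approx(-1.96, abs=0.1)
        assert summ.loc["z", "upper"] == pytest.approx(1.96, abs=0.1)

    def test_formatted_table_row_convention(self):
        rng = np.random.default_rng(1)
        arr = 1.43 + 0.4 * rng.standard_normal((2, 500, 1))
        text = summarize_draws(_draws_from_array(arr, ["bad"])).formatted()
        # "estimate (lower, upper)" layout
        assert text.startswith("bad: 1.4")
        assert "(" in text and "," in text and text.endswith(")")

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            summarize_draws(_draws_from_array(np.zeros((1, 10, 1)), ["a"]))


class TestConvergenceChecks:
    def test_well_mixed_chains_pass(self, paper_outcomes, fast_config):
        draws = fit_zib_mcmc(paper_outcomes, UniformPriorPair(), fast_config)
        report = check_convergence(draws, rhat_threshold=1.05, ess_threshold=50)
        assert report.all_pass

    def test_disjoint_constant_chains_fail(self):
        arr = np.concatenate(
            [np.zeros((1, 200, 1)), np.ones((1, 200, 1))], axis=0
        )
        # add jitter so within-chain variance is finite but tiny
        rng = np.random.default_rng(0)
        arr = arr + 1e-6 * rng.standard_normal(arr.shape)
        report = check_convergence(_draws_from_array(arr, ["x"]))
        assert not report.all_pass
        # rank-normalized split R-hat saturates below the classical statistic
        # but still far exceeds any sane threshold
        assert report.table.loc["x", "rhat"] > 1.5

    def test_short_chain_fails_ess(self):
        rng = np.random.default_rng(2)
        arr = rng.standard_normal((2, 25, 1))
        report = check_convergence(_draws_from_array(arr, ["x"]), ess_threshold=400)
        assert not report.all_pass

    def test_single_chain_degrades_to_ess_only(self):
        rng = np.random.default_rng(3)
        arr = rng.standard_normal((1, 500, 1))
        report = check_convergence(_draws_from_array(arr, ["x"]), ess_threshold=100)
        assert any("single chain" in n for n in report.notes)
        assert np.isnan(report.table.loc["x", "rhat"])
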