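import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import olfthresh as ot
from olfthresh.irt import fit_per_subject


def brute_force_loglik(table, beta, mu, sigma, span=12.0, npts=100_001):
    """Trapezoid integration of the marginal likelihood over the ability."""
    total = 0.0
    a = np.linspace(mu - span * sigma, mu + span * sigma, npts)
    dens = np.exp(-0.5 * ((a - mu) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
    for _, g in table.groupby("subject_id"):
        p = 1 / 3 + 2 / 3 * expit(a[:, None] - beta * g["dilution_step"].to_numpy())
        lik = np.prod(np.where(g["response"].to_numpy() == 1, p, 1 - p), axis=1)
        total += math.log(np.trapezoid(lik * dens, a))
    return total


class TestQuadrature:
    def test_matches_brute_force_on_small_instance(self, nshap_gamma):
        rng = np.random.default_rng(3)
        t = nshap_gamma.sample_thresholds(5, rng)
        table = ot.simulate_constant_stimuli(
            t, nshap_gamma.beta, ot.ConstantStimuliProtocol(ot.NSHAP_STEPS), rng)
        model = ot.ThresholdIRT.from_dataframe(table, n_quadrature=61)
        for params in [(0.76, 1.8, 2.2), (1.5, -1.0, 0.7), (0.3, 4.0, 5.0)]:
            got = model.loglike(params)
            want = brute_force_loglik(table, *params)
            assert got == pytest.approx(want, rel=1e-6, abs=1e-6)

    def test_node_count_stability(self, small_table):
        table, _ = small_table
        fits = [ot.ThresholdIRT.from_dataframe(table, n_quadrature=k).fit()
                for k in (15, 61)]
        assert abs(fits[0].beta - fits[1].beta) < 1e-3

    def test_gradient_matches_finite_differences(self, small_table):
        table, _ = small_table
        model = ot.ThresholdIRT.from_dataframe(table)
        theta = np.array([math.log(1.0), 9.0, math.log(3.5)])
        _, grad = model._negll_and_grad(theta)
        from scipy.optimize import approx_fprime

        num = approx_fprime(theta, model._negll, 1e-6)
        np.testing.assert_allclose(grad, num, rtol=5e-4, atol=5e-4)


class TestFit:
    def test_parameter_recovery(self, normosmic, proto16):
        rng = np.random.default_rng(1)
        t = normosmic.sample_thresholds(1000, rng)
        table = ot.simulate_constant_stimuli(t, normosmic.beta, proto16, rng)
        res = ot.ThresholdIRT.from_dataframe(table).fit()
        assert res.converged
        assert abs(res.beta - 1.12) < 3 * res.bse["beta"]
        assert abs(res.mu_alpha - 10.5) < 3 * res.bse["mu_alpha"]
        assert abs(res.var_alpha - 16.6) < 3 * res.bse["var_alpha"]

    def test_zero_variance_population(self, proto16):
        # all subjects share alpha = 6: mu recovered, variance pushed to ~0
        rng = np.random.default_rng(4)
        table = ot.simulate_constant_stimuli(
            np.full(400, 6.0 / 1.12), 1.12, proto16, rng)
        res = ot.ThresholdIRT.from_dataframe(table).fit()
        assert res.params["var_alpha"] < 0.2
        assert abs(res.mu_alpha - 6.0) < 0.3

    def test_requires_binary_responses(self):
        df = pd.DataFrame({"subject_id": [0, 0, 1, 1],
                           "presentation_index": [0, 1, 0, 1],
                           "dilution_step": [1.0, 2.0, 1.0, 2.0],
                           "response": [1, 2, 0, 1]})
        with pytest.raises(ValueError, match="impute"):
            ot.ThresholdIRT.from_dataframe(df)

    def test_pattern_collapsing_matches_full_likelihood(self, nshap_gamma):
        rng = np.random.default_rng(9)
        t = nshap_gamma.sample_thresholds(300, rng)
        table = ot.simulate_constant_stimuli(
            t, nshap_gamma.beta, ot.ConstantStimuliProtocol(ot.NSHAP_STEPS), rng)
        collapsed = ot.ThresholdIRT.from_dataframe(table)
        assert collapsed.n_groups < collapsed.n_subjects
        # defeat collapsing with an infinitesimal design perturbation
        jittered = table.copy()
        jittered.loc[0, "dilution_step"] += 1e-9
        full = ot.ThresholdIRT.from_dataframe(jittered)
        assert full.n_groups == full.n_subjects
        params = (0.8, 1.5, 2.0)
        assert collapsed.loglike(params) == pytest.approx(full.loglike(params),
                                                          rel=1e-6)


@pytest.fixture(scope="module")
def nshap_fit(nshap_gamma):
    rng = np.random.default_rng(14)
    truths = nshap_gamma.sample_thresholds(2000, rng)
    table = ot.simulate_constant_stimuli(
        truths, nshap_gamma.beta, ot.ConstantStimuliProtocol(ot.NSHAP_STEPS), rng)
    res = ot.ThresholdIRT.from_dataframe(table).fit()
    return res, truths


class TestEmpiricalBayes:
    def test_shrinkage(self, nshap_fit):
        res, truths = nshap_fit
        eb = res.empirical_bayes()
        assert eb["threshold_eb"].var() < np.var(truths)
        # posterior SD never exceeds the prior SD
        assert (eb["alpha_eb_sd"] <= res.sigma_alpha + 1e-9).all()

    def test_unconditionally_unbiased(self, nshap_fit):
        res, truths = nshap_fit
        eb = res.empirical_bayes()
        se = np.std(truths) / math.sqrt(len(truths))
        assert abs(eb["threshold_eb"].mean() - truths.mean()) < 4 * se

    def test_estimates_depend_only_on_response_pattern(self):
        # two subjects with identical patterns, one pair differing by one item
        df = pd.DataFrame({
            "subject_id": np.repeat([0, 1, 2], 6),
            "presentation_index": np.tile(np.arange(6), 3),
            "dilution_step": np.tile([6, 5, 4, 2, 1, 0], 3),
            "response": [1, 1, 0, 1, 1, 1,
                         1, 1, 0, 1, 1, 1,
                         0, 0, 0, 1, 1, 1],
        })
        res = ot.ThresholdIRT.from_dataframe(df, n_quadrature=31).fit()
        eb = res.empirical_bayes().set_index("subject_id")
        assert eb.loc[0, "alpha_eb"] == pytest.approx(eb.loc[1, "alpha_eb"],
                                                      abs=1e-12)
        assert eb.loc[2, "alpha_eb"] < eb.loc[0, "alpha_eb"]

    def test_all_correct_pattern_has_maximal_threshold(self, nshap_gamma):
        rng = np.random.default_rng(15)
        truths = nshap_gamma.sample_thresholds(1500, rng)
        table = ot.simulate_constant_stimuli(
            truths, nshap_gamma.beta, ot.ConstantStimuliProtocol(ot.NSHAP_STEPS), rng)
        res = ot.ThresholdIRT.from_dataframe(table).fit()
        eb = res.empirical_bayes()
        score = table.groupby("subject_id")["response"].sum()
        top = eb["threshold_eb"].max()
        winners = eb.loc[eb["threshold_eb"] == top, "subject_id"]
        assert (score.loc[winners] == 6).all()

    def test_eb_monotone_in_number_correct(self):
        # identical designs; strictly nested response patterns
        patterns = [[0, 0, 0, 0, 0, 0], [1, 0, 0, 0, 0, 0], [1, 1, 0, 0, 0, 0],
                    [1, 1, 1, 0, 0, 0], [1, 1, 1, 1, 0, 0], [1, 1, 1, 1, 1, 0],
                    [1, 1, 1, 1, 1, 1]]
        df = pd.DataFrame({
            "subject_id": np.repeat(np.arange(len(patterns)), 6),
            "presentation_index": np.tile(np.arange(6), len(patterns)),
            "dilution_step": np.tile([0, 1, 2, 4, 5, 6], len(patterns)),
            "response": np.concatenate(patterns),
        })
        res = ot.ThresholdIRT.from_dataframe(df, n_quadrature=31).fit()
        eb = res.empirical_bayes().sort_values("subject_id")
        assert np.all(np.diff(eb["alpha_eb"].to_numpy()) > 0)


class TestPerSubjectFit:
    def test_separation_flagged(self):
        fit = fit_per_subject([1] * 16, list(range(1, 17)), beta=1.12)
        assert not fit.estimable
        assert math.isnan(fit.threshold)

    def test_recovery_with_many_items(self):
        rng = np.random.default_rng(6)
        alpha, beta = 9.0, 1.12
        steps = np.tile(np.arange(1, 17), 25)  # 400 presentations
        p = 1 / 3 + 2 / 3 * expit(alpha - beta * steps)
        y = (rng.random(steps.size) < p).astype(int)
        fit = fit_per_subject(y, steps, beta=beta)
        assert fit.estimable
        assert fit.threshold == pytest.approx(alpha / beta, abs=0.6)

    def test_joint_slope_fit(self):
        rng = np.random.default_rng(7)
        alpha, beta = 7.0, 1.0
        steps = np.tile(np.arange(1, 17), 40)
        p = 1 / 3 + 2 / 3 * expit(alpha - beta * steps)
        y = (rng.random(steps.size) < p).astype(int)
        fit = fit_per_subject(y, steps)
        assert fit.estimable
        assert fit.beta == pytest.approx(beta, abs=0.35)
        # by construction the estimated threshold sits at the 2/3 point
        assert ot.p_correct(fit.alpha, fit.threshold, fit.beta) == pytest.approx(
            2 / 3, abs=1e-9)
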