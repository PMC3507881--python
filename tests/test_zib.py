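"""Presence/detection model: likelihood pieces, sampler, diagnostics."""

import datetime as dt
from types import SimpleNamespace

import numpy as np
import pytest
from scipy.stats import binom, kstest

from mycophen.io import DetectionMatrix
from mycophen.zib import (LatentConditional, ZIBConfig, ZIBModel, ZIBResults,
                          gelman_rubin, latent_conditional, marginal_loglik,
                          presence_prob, summarize_posterior)


def _matrix(D, N, groups=None):
    D = np.atleast_2d(np.asarray(D))
    n, J = D.shape
    groups = groups or [f"g{j}" for j in range(J)]
    dates = [dt.date(1990 + i // 12, 1 + i % 12, 15) for i in range(n)]
    return DetectionMatrix(D=D, N=np.asarray(N), groups=groups,
                           dates=dates, survey_ids=list(range(1, n + 1)))


class TestPresenceProb:
    @pytest.mark.parametrize("alpha,beta,x,expected", [
        (0.0, (0.0, 0.0, 0.0, 0.0), (1.0, 2.0, 3.0, 4.0), 0.5),
        (0.0, (1.0, 0.0, 0.0, 0.0), (np.log(3), 0.0, 0.0, 0.0), 0.75),
    ])
    def test_logistic_values(self, alpha, beta, x, expected):
        assert presence_prob(alpha, np.array(beta),
                             np.array(x)) == pytest.approx(expected)

    def test_deep_saturation_neither_underflows_nor_nans(self):
        p = presence_prob(-50.0, np.zeros(4), np.ones(4))
        assert 0.0 < p <= 1e-20

    def test_monotone_in_covariate_with_positive_coefficient(self):
        beta = np.array([1.0, 0.0, 0.0, 0.0])
        xs = [presence_prob(0.3, beta, np.array([v, 0, 0, 0]))
              for v in (-2.0, 0.0, 2.0)]
        assert xs[0] < xs[1] < xs[2]


class TestMarginalLoglik:
    def test_perfect_detection_reduces_to_plain_binomial(self):
        for D, N, p in [(0, 5, 0.3), (3, 5, 0.3), (5, 5, 0.9)]:
            assert marginal_loglik(D, N, p, 1.0) == pytest.approx(
                binom.logpmf(D, N, p))

    def test_enumeration_example(self):
        # N=3, D=1, p=d=0.5: summing Bin(X;3,.5)*Bin(1;X,.5) over X gives
        # C(3,1) * 0.25 * 0.75^2 = 0.421875
        assert marginal_loglik(1, 3, 0.5, 0.5) == pytest.approx(
            np.log(0.421875))

    def test_certain_event_has_zero_loglik(self):
        assert marginal_loglik(4, 4, 1.0, 1.0) == pytest.approx(0.0)

    def test_impossible_count_raises(self):
        with pytest.raises(ValueError):
            marginal_loglik(5, 3, 0.5, 0.5)

    def test_matches_explicit_latent_sum_on_spot_grid(self):
        for N in (1, 4, 9):
            for p in (0.15, 0.6):
                for d in (0.25, 0.8):
                    for D in range(N + 1):
                        x = np.arange(D, N + 1)
                        brute = np.sum(binom.pmf(x, N, p) *
                                       binom.pmf(D, x, d))
                        assert marginal_loglik(D, N, p, d) == pytest.approx(
                            np.log(brute), abs=1e-10)


class TestLatentConditional:
    def test_bayes_enumeration_example(self):
        lc = latent_conditional(1, 2, 0.5, 0.5)
        assert lc.q == pytest.approx(1 / 3)
        assert lc.pmf([1, 2]) == pytest.approx([2 / 3, 1 / 3])

    def test_perfect_detection_collapses_to_observed(self):
        lc = latent_conditional(2, 7, 0.4, 1.0)
        assert lc.q == 0.0 and lc.pmf(2) == pytest.approx(1.0)

    def test_saturated_count_has_point_support(self):
        lc = latent_conditional(5, 5, 0.3, 0.6)
        assert lc.support.tolist() == [5]

    def test_certain_detection_with_missing_species_is_impossible(self):
        with pytest.raises(ValueError, match="impossible"):
            latent_conditional(1, 3, 1.0, 1.0)

    def test_matches_bayes_rule_on_spot_grid(self):
        # posterior over X by direct Bayes: Bin(X;N,p) Bin(D;X,d) normalized
        for N in (2, 5, 8):
            for p in (0.2, 0.7):
                for d in (0.3, 0.9):
                    for D in range(N + 1):
                        xs = np.arange(D, N + 1)
                        w = binom.pmf(xs, N, p) * binom.pmf(D, xs, d)
                        lc = latent_conditional(D, N, p, d)
                        assert lc.pmf(xs) == pytest.approx(w / w.sum(),
                                                           abs=1e-12)


class TestGelmanRubin:
    def test_well_mixed_iid_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = [rng.normal(size=1000), rng.normal(size=1000)]
        assert gelman_rubin(chains) < 1.05

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = [rng.normal(0, 1, 1000), rng.normal(5, 1, 1000)]
        assert gelman_rubin(chains) > 1.5

    def test_constant_equal_chains_define_one(self):
        assert gelman_rubin([np.ones(10), np.ones(10)]) == 1.0

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin([np.arange(10.0)])


class TestSampler:
    def test_saturated_data_concentrates_presence_near_one(self):
        # 50 surveys all detecting every one of 20 species, detection known
        # perfect: the presence probability must be estimated near 1.
        m = _matrix(np.full((50, 1), 20), [20])
        cfg = ZIBConfig.desk(seed=3, detection_structure="fixed_known",
                             fixed_d=1.0)
        res = ZIBModel(m, covariates=None).fit(cfg)
        p_mean = 1 / (1 + np.exp(-res.alpha_draws)).mean()
        assert p_mean > 0.9

    def test_posterior_mean_tracks_empirical_proportion(self):
        # intercept-only, perfect detection: posterior presence probability
        # should approach the empirical D/N fraction
        rng = np.random.default_rng(9)
        D = rng.binomial(50, 0.35, size=(120, 1))
        m = _matrix(D, [50])
        cfg = ZIBConfig.desk(seed=4, detection_structure="fixed_known",
                             fixed_d=1.0)
        res = ZIBModel(m, covariates=None).fit(cfg)
        p_mean = (1 / (1 + np.exp(-res.alpha_draws))).mean()
        assert p_mean == pytest.approx(D.mean() / 50, abs=0.02)

    def test_identical_seeds_give_bit_identical_draws(self):
        m = _matrix(np.array([[3, 1], [5, 2], [2, 0], [4, 2]]), [8, 4])
        cfg = ZIBConfig(n_chains=2, n_iter=600, burn_in=200, thin=2, seed=11)
        r1 = ZIBModel(m).fit(cfg)
        r2 = ZIBModel(m).fit(cfg)
        assert np.array_equal(r1.alpha_draws, r2.alpha_draws)
        assert np.array_equal(r1.d_draws, r2.d_draws)
        r3 = ZIBModel(m).fit(ZIBConfig(n_chains=2, n_iter=600, burn_in=200,
                                       thin=2, seed=12))
        assert not np.array_equal(r1.alpha_draws, r3.alpha_draws)

    def test_retained_draw_count_burnin_then_thin(self):
        cfg = ZIBConfig(n_chains=2, n_iter=1000, burn_in=300, thin=7, seed=0)
        assert cfg.n_retained == 100
        m = _matrix(np.array([[2], [3]]), [5])
        res = ZIBModel(m).fit(cfg)
        assert res.alpha_draws.shape == (2, 100, 1)

    def test_conjugate_detection_update_matches_beta_law(self):
        # With D = N the latent count is pinned at N, so the constant-d
        # Gibbs draws are iid Beta(1 + sum D, 1 + sum(X - D)) = Beta(1+sumD, 1)
        D = np.full((6, 1), 4)
        m = _matrix(D, [4])
        cfg = ZIBConfig(n_chains=1, n_iter=10_500, burn_in=500, thin=1,
                        seed=21, detection_structure="constant")
        res = ZIBModel(m).fit(cfg)
        draws = res.d_draws.ravel()
        stat = kstest(draws, "beta", args=(1 + D.sum(), 1.0))
        assert stat.pvalue > 0.01

    def test_nonpositive_config_rejected(self):
        with pytest.raises(ValueError):
            ZIBConfig(burn_in=500, n_iter=400)
        with pytest.raises(ValueError):
            ZIBConfig(thin=0)
        with pytest.raises(ValueError):
            ZIBConfig(prior_variance=0.0)


class TestSummaries:
    def _results(self, draws):
        # two identical chains around fabricated draws for one coefficient
        draws = np.asarray(draws, dtype=float)
        n = len(draws)
        model = SimpleNamespace(data=SimpleNamespace(groups=["G"]),
                                exog_names=["T"])
        return ZIBResults(model=model, config=ZIBConfig.desk(),
                          alpha_draws=np.zeros((2, n, 1)),
                          beta_draws=np.tile(draws.reshape(1, n, 1, 1),
                                             (2, 1, 1, 1)),
                          d_draws=None)

    def test_point_mass_is_significant_at_both_levels(self):
        s = self._results(np.full(100, 2.0)).summary()
        row = s[s["covariate"] == "T"].iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sig95"] and row["sig99"]

    def test_symmetric_draws_are_not_significant(self):
        s = self._results(np.concatenate([np.linspace(-1, 1, 200)])).summary()
        row = s[s["covariate"] == "T"].iloc[0]
        assert not row["sig95"] and not row["sig99"]

    def test_shifted_normal_flags_and_mean(self):
        rng = np.random.default_rng(5)
        res = self._results(rng.normal(3.0, 1.0, 10_000))
        row = res.summary()[lambda f: f["covariate"] == "T"].iloc[0]
        assert row["sig95"]
        assert row["mean"] == pytest.approx(3.0, abs=0.05)
        # wider interval contains the narrower one
        assert row["ci99_lo"] <= row["ci95_lo"] <= row["ci95_hi"] <= row["ci99_hi"]

    def test_sig99_implies_sig95(self):
        rng = np.random.default_rng(6)
        for loc in (0.0, 0.5, 1.0, 3.0):
            s = self._results(rng.normal(loc, 1.0, 2000)).summary()
            row = s[s["covariate"] == "T"].iloc[0]
            assert (not row["sig99"]) or row["sig95"]

    def test_summarize_posterior_matches_results_summary(self):
        res = self._results(np.linspace(0.5, 1.5, 50))
        assert summarize_posterior(res).equals(res.summary())
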