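"""Deviance, DIC, odds-ratio tables, prevalence and spatial classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit, logit

from geoadditive import (
    MCMCConfig,
    bernoulli_deviance,
    classify_spatial_effects,
    dic,
    posterior_odds_ratios,
    predicted_prevalence,
    prevalence_decline,
    weighted_prevalence_table,
)
from geoadditive.penalties import identity_penalty
from geoadditive.sampler import PosteriorSamples
from geoadditive.terms import ModelTerm


def make_samples(coef, terms, tau2=None, config=None):
    return PosteriorSamples(
        terms=terms,
        coef=coef,
        tau2=tau2 or {},
        acceptance={},
        config=config or MCMCConfig(n_iter=10, burn_in=0, thin=1),
    )


def fixed_term(n, labels, components):
    x = np.ones((n, len(labels)))
    return ModelTerm(name="fixed", kind="fixed", n_coef=len(labels), X=x,
                     column_labels=labels, components=components)


class TestBernoulliDeviance:
    def test_saturated_fit_zero(self):
        total, per = bernoulli_deviance([3, 5], [10, 10], [0.3, 0.5])
        assert total == pytest.approx(0.0, abs=1e-10)

    def test_single_trial_half(self):
        total, _ = bernoulli_deviance([1], [1], [0.5])
        assert total == pytest.approx(2 * np.log(2))

    def test_matches_likelihood_oracle(self, rng):
        """D = -2 (loglik - saturated loglik) via an independent binomial oracle."""
        n = rng.integers(1, 30, size=8)
        y = np.array([rng.integers(0, k + 1) for k in n])
        mu = rng.uniform(0.05, 0.95, 8)
        total, per = bernoulli_deviance(y, n, mu)
        ll = stats.binom.logpmf(y, n, mu).sum()
        ll_sat = stats.binom.logpmf(y, n, np.where(n > 0, y / n, 0.5)).sum()
        assert total == pytest.approx(-2 * (ll - ll_sat))
        assert per.sum() == pytest.approx(total)

    def test_contradictory_boundary_probability(self):
        with pytest.raises(ValueError, match="infinite"):
            bernoulli_deviance([1], [1], [0.0])

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            bernoulli_deviance([5], [3], [0.5])


class TestDIC:
    def _samples_with_eta(self, etas, n):
        # encode arbitrary eta draws through a one-column identity design
        term = ModelTerm(name="fixed", kind="fixed", n_coef=1, X=np.ones((n, 1)),
                         column_labels=["intercept"],
                         components={"intercept": (slice(0, 1), ["intercept"], None)})
        return make_samples({"fixed": etas[:, None]}, [term])

    def test_degenerate_posterior_pd_zero(self):
        y = np.array([1.0, 0.0, 1.0])
        s = self._samples_with_eta(np.array([0.3, 0.3, 0.3]), 3)
        d, p_d, d_bar, d_hat = dic(s, y)
        assert p_d == pytest.approx(0.0, abs=1e-10)
        assert d == pytest.approx(d_bar)

    def test_matches_beta_binomial_oracle(self, rng):
        """DIC from exact conjugate posterior draws vs a closed-form evaluation.

        Intercept-only Bernoulli with a Beta(1,1) prior: p | y ~ Beta(1+s, 1+n-s).
        Sampling eta = logit(p) exactly lets an independent numerical integral
        of E[D] stand in for the MCMC average.
        """
        y = rng.integers(0, 2, 50).astype(float)
        s, n = y.sum(), len(y)
        post = stats.beta(1 + s, 1 + n - s)
        p_draws = post.rvs(size=4000, random_state=17)
        samples = self._samples_with_eta(logit(p_draws), n)
        d, p_d, d_bar, d_hat = dic(samples, y)

        grid = np.linspace(1e-6, 1 - 1e-6, 20001)
        dev = -2 * (s * np.log(grid) + (n - s) * np.log1p(-grid))
        d_bar_oracle = np.trapezoid(dev * post.pdf(grid), grid)
        assert d_bar == pytest.approx(d_bar_oracle, rel=0.01)

    def test_decomposition_identity(self, rng):
        etas = rng.normal(0, 0.5, size=40)
        samples = self._samples_with_eta(etas, 25)
        y = rng.integers(0, 2, 25).astype(float)
        d, p_d, d_bar, d_hat = dic(samples, y)
        assert d == pytest.approx(d_bar + p_d)
        assert p_d == pytest.approx(d_bar - d_hat)

    def test_needs_two_draws(self):
        s = self._samples_with_eta(np.array([0.1]), 3)
        with pytest.raises(ValueError):
            dic(s, np.zeros(3))


class TestPosteriorOddsRatios:
    def _samples(self, draws):
        term = fixed_term(5, ["intercept", "education:None"],
                          {"intercept": (slice(0, 1), ["intercept"], None),
                           "education": (slice(1, 2), ["Higher", "None"], "Higher")})
        coef = {"fixed": np.column_stack([np.zeros(len(draws)), draws])}
        return make_samples(coef, [term])

    def test_zero_draws_unit_odds(self):
        tab = posterior_odds_ratios(self._samples(np.zeros(100)), "education")
        row = tab[tab.level == "None"].iloc[0]
        assert (row.por, row.lower, row.upper) == (1.0, 1.0, 1.0)

    def test_reference_row_is_one(self):
        tab = posterior_odds_ratios(self._samples(np.zeros(10)), "education")
        ref = tab[tab.level.str.contains("ref")].iloc[0]
        assert ref.por == 1.0 and np.isnan(ref.lower)

    def test_lognormal_quantile_oracle(self, rng):
        """draws ~ N(log 2, 0.01^2): POR ~= 2, CI = 2*exp(+-1.96*0.01)."""
        draws = rng.normal(np.log(2), 0.01, 200000)
        tab = posterior_odds_ratios(self._samples(draws), "education")
        row = tab[tab.level == "None"].iloc[0]
        assert row.por == pytest.approx(2 * np.exp(0.01**2 / 2), rel=1e-3)
        assert row.lower == pytest.approx(2 * np.exp(-1.96 * 0.01), rel=1e-3)
        assert row.upper == pytest.approx(2 * np.exp(+1.96 * 0.01), rel=1e-3)

    def test_non_fixed_term_rejected(self):
        s = self._samples(np.zeros(5))
        with pytest.raises(ValueError, match="odds ratios"):
            posterior_odds_ratios(s, "f_str")


class TestPredictedPrevalence:
    def _spatial_samples(self, draws_by_region, states, n_regions):
        groups = np.asarray(states) - 1
        term = ModelTerm(name="f_unstr", kind="iid_region", n_coef=n_regions,
                         groups=groups, penalty=identity_penalty(n_regions),
                         column_labels=[str(i) for i in range(n_regions)])
        return make_samples({"f_unstr": draws_by_region}, [term])

    def test_zero_eta_half_everywhere(self):
        states = [1, 1, 2, 2, 2]
        s = self._spatial_samples(np.zeros((20, 2)), states, 2)
        tab = predicted_prevalence(s, states, 2)
        assert np.allclose(tab["prevalence"], 0.5)

    def test_monotone_in_constant_shift(self, rng):
        states = rng.integers(1, 4, 60)
        base = rng.normal(0, 0.3, (30, 3))
        lo = predicted_prevalence(self._spatial_samples(base, states, 3), states, 3)
        hi = predicted_prevalence(self._spatial_samples(base + 1.0, states, 3), states, 3)
        assert (hi["prevalence"] > lo["prevalence"]).all()

    def test_empty_region_flagged_borrowed(self):
        states = [1, 1, 2]
        s = self._spatial_samples(np.zeros((5, 3)), states, 3)
        tab = predicted_prevalence(s, states, 3)
        assert bool(tab.loc[tab.state == 3, "borrowed"].iloc[0])
        assert np.isnan(tab.loc[tab.state == 3, "prevalence"].iloc[0])


class TestClassifySpatialEffects:
    def _samples(self, str_draws, unstr_draws, states):
        n_regions = str_draws.shape[1]
        groups = np.asarray(states) - 1
        kw = dict(n_coef=n_regions, groups=groups,
                  column_labels=[f"s{i}" for i in range(n_regions)])
        t1 = ModelTerm(name="f_str", kind="mrf", penalty=None_or_mrf(n_regions), **kw)
        t2 = ModelTerm(name="f_unstr", kind="iid_region",
                       penalty=identity_penalty(n_regions), **kw)
        return make_samples({"f_str": str_draws, "f_unstr": unstr_draws}, [t1, t2])

    def test_all_positive_draws_high(self, rng):
        draws = np.abs(rng.normal(1, 0.1, (50, 2)))
        s = self._samples(draws, np.zeros((50, 2)), [1, 2])
        assert (classify_spatial_effects(s)["class"] == "high").all()

    def test_symmetric_draws_nonsignificant(self, rng):
        draws = rng.normal(0, 1, (400, 2))
        s = self._samples(draws, np.zeros((400, 2)), [1, 2])
        assert (classify_spatial_effects(s)["class"] == "nonsignificant").all()

    def test_structured_only_switch(self, rng):
        str_d = np.abs(rng.normal(1, 0.05, (50, 2)))
        unstr_d = -str_d  # cancels the total
        s = self._samples(str_d, unstr_d, [1, 2])
        total = classify_spatial_effects(s, which="total")
        structured = classify_spatial_effects(s, which="structured")
        assert (total["class"] == "nonsignificant").all()
        assert (structured["class"] == "high").all()


def None_or_mrf(n):
    from geoadditive import make_lattice_graph, mrf_precision

    return mrf_precision(make_lattice_graph(1, n))


class TestWeightedPrevalence:
    def test_equal_weights_match_unweighted(self, rng):
        tab = pd.DataFrame({"fgm": rng.integers(0, 2, 200),
                            "residence": rng.choice(["Urban", "Rural"], 200)})
        out = weighted_prevalence_table(tab, np.ones(200), by="residence")
        for _, row in out.iterrows():
            sub = tab[tab.residence == row["residence"]]
            assert row["weighted_percent_cut"] == pytest.approx(100 * sub.fgm.mean())
            assert row["weighted_n"] == len(sub)

    def test_double_weight_matches_row_replication(self, rng):
        """Doubling one stratum's weight equals physically duplicating its rows."""
        tab = pd.DataFrame({"fgm": rng.integers(0, 2, 120),
                            "residence": rng.choice(["Urban", "Rural"], 120)})
        w = np.where(tab.residence == "Rural", 2.0, 1.0)
        weighted = weighted_prevalence_table(tab, w, by="residence")
        expanded = pd.concat([tab, tab[tab.residence == "Rural"]], ignore_index=True)
        oracle = weighted_prevalence_table(expanded, np.ones(len(expanded)), by="residence")
        pd.testing.assert_frame_equal(weighted, oracle)

    def test_unknown_covariate(self):
        tab = pd.DataFrame({"fgm": [0, 1]})
        with pytest.raises(ValueError, match="unknown covariate"):
            weighted_prevalence_table(tab, np.ones(2), by="zodiac")

    def test_nonpositive_weights_rejected(self):
        tab = pd.DataFrame({"fgm": [0, 1], "residence": ["Urban", "Rural"]})
        with pytest.raises(ValueError):
            weighted_prevalence_table(tab, np.array([1.0, 0.0]), by="residence")


def test_prevalence_decline_arithmetic():
    """30.0% in 2008 to 25.3% in 2016 is a 4.7 percentage-point decline."""
    assert prevalence_decline(30.0, 25.3) == pytest.approx(4.7)
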