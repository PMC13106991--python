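"""Daily-survival model: likelihood, diagnostics, MLE oracle and the
posterior sampler contract."""

import numpy as np
import pytest
from scipy.special import expit, logit

from ruffnest import (DesignMatrices, DsrModelSpec, ExposureHistory,
                      classify_effects, daily_survival_probability,
                      gelman_rubin, mle_oracle_fit, sample_posterior,
                      scenario_log_likelihood)
from ruffnest.dsrmodel import PosteriorDraws


def _history(y, nid="n1", scenario="overall", variant="all_nests"):
    terminal = "failed" if y and y[-1] == 0 else "censored"
    return ExposureHistory(nest_id=nid, scenario=scenario, variant=variant,
                           y=tuple(y), terminal=terminal)


def _intercept_design(n_days, n_failures, years=(2018,)):
    """Intercept-only stacked design: one row per exposure day."""
    X = np.ones((n_days, 1))
    y = np.ones(n_days)
    y[:n_failures] = 0.0
    return DesignMatrices(
        X=X, y=y, year_index=np.zeros(n_days, dtype=int),
        nest_ids=np.array([f"n{i}" for i in range(n_days)]),
        columns=("intercept",), years=tuple(years), scenario="overall",
        variant="all_nests", scaling={}, age_scaling={})


class TestDailySurvival:
    def test_all_terms_zero_gives_half(self):
        assert daily_survival_probability({}, {}) == pytest.approx(0.5)

    def test_intercept_three(self):
        s = daily_survival_probability({}, {"intercept": 3.0})
        assert s == pytest.approx(0.95257, abs=1e-5)

    def test_age_effect(self):
        s = daily_survival_probability({"nest_age": 1.0},
                                       {"intercept": 3.0, "nest_age": -1.0})
        assert s == pytest.approx(0.88080, abs=1e-5)

    def test_nonfinite_predictor_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            daily_survival_probability({"nest_age": np.inf},
                                       {"intercept": 0.0, "nest_age": 1.0})

    def test_strictly_decreasing_in_age_when_beta_negative(self):
        coef = {"intercept": 3.0, "nest_age": -0.8}
        s = [daily_survival_probability({"nest_age": a}, coef)
             for a in np.linspace(-2, 2, 25)]
        assert all(a > b for a, b in zip(s, s[1:]))


class TestScenarioLogLikelihood:
    def test_failure_after_three_days(self):
        h = _history([1, 1, 1, 0])
        got = scenario_log_likelihood([h], 0.9)
        assert got == pytest.approx(3 * np.log(0.9) + np.log(0.1), abs=1e-5)
        assert got == pytest.approx(-2.61867, abs=1e-5)

    def test_censored_after_three_days(self):
        got = scenario_log_likelihood([_history([1, 1, 1])], 0.9)
        assert got == pytest.approx(3 * np.log(0.9), abs=1e-5)
        assert got == pytest.approx(-0.31608, abs=1e-5)

    def test_perfect_survival_is_zero(self):
        hs = [_history([1, 1, 1]), _history([1] * 26, nid="n2")]
        assert scenario_log_likelihood(hs, 1.0) == 0.0

    def test_impossible_transition_is_minus_inf(self):
        assert scenario_log_likelihood([_history([1, 0])], 1.0) == -np.inf

    def test_matches_bruteforce_bernoulli_products(self):
        """Oracle equivalence on random small datasets: the likelihood must
        equal the log of the per-day product of Bernoulli terms."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(1, 8)
            hists, svals = [], {}
            for i in range(n):
                T = int(rng.integers(1, 10))
                failed = rng.random() < 0.5
                y = [1] * (T - 1) + [0 if failed else 1]
                hists.append(_history(y, nid=f"n{i}"))
                svals[f"n{i}"] = rng.uniform(0.05, 0.95, size=T)
            brute = 1.0
            for h in hists:
                for t, out in enumerate(h.y, start=1):
                    s = svals[h.nest_id][t - 1]
                    brute *= s if out == 1 else (1 - s)
            got = scenario_log_likelihood(hists, svals)
            assert abs(got - np.log(brute)) < 1e-10

    def test_censoring_neutrality(self):
        """Days appended after the censoring point must not change the
        likelihood once the history is re-censored at the same day."""
        short = _history([1, 1, 1])
        extended = _history([1, 1, 1, 1, 1])
        recensored = _history(list(extended.y[:3]))
        s = {"n1": np.linspace(0.8, 0.95, 5)}
        assert scenario_log_likelihood([short], s) == \
            scenario_log_likelihood([recensored], s)


class TestMleOracle:
    def test_intercept_only_closed_form(self):
        design = _intercept_design(100, 5)
        coef, info = mle_oracle_fit(design)
        assert expit(coef["intercept"]) == pytest.approx(0.95, abs=1e-5)
        assert info["loglik"] == pytest.approx(
            95 * np.log(0.95) + 5 * np.log(0.05), abs=1e-6)

    def test_zero_failures_flagged(self):
        with pytest.warns(UserWarning, match="separation|zero failures"):
            _, info = mle_oracle_fit(_intercept_design(50, 0))
        assert info["separated"]

    def test_recovers_known_coefficients_on_large_data(self):
        rng = np.random.default_rng(1)
        n = 10_000
        X = np.column_stack([np.ones(n), rng.standard_normal(n),
                             rng.standard_normal(n)])
        beta_true = np.array([2.5, 0.7, -0.5])
        y = (rng.random(n) < expit(X @ beta_true)).astype(float)
        design = DesignMatrices(
            X=X, y=y, year_index=np.zeros(n, dtype=int),
            nest_ids=np.array(["n"] * n), columns=("intercept", "a", "b"),
            years=(2018,), scenario="overall", variant="all_nests",
            scaling={}, age_scaling={})
        coef, info = mle_oracle_fit(design)
        # asymptotic SEs from the Fisher information
        s = expit(X @ np.array(list(coef.values())))
        fisher = X.T @ (X * (s * (1 - s))[:, None])
        se = np.sqrt(np.diag(np.linalg.inv(fisher)))
        for j, name in enumerate(design.columns):
            assert abs(coef[name] - beta_true[j]) < 3 * se[j]


class TestGelmanRubin:
    def test_iid_chains_converged(self):
        rng = np.random.default_rng(2)
        assert gelman_rubin(rng.standard_normal((4, 1000))) < 1.05

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(3)
        x = np.stack([rng.standard_normal(500), rng.standard_normal(500) + 10])
        assert gelman_rubin(x) > 1.10

    def test_identical_short_chains_hand_value(self):
        # unsplit branch (n < 4): W = 1, B = 0, var+ = 2/3
        got = gelman_rubin(np.array([[1.0, 2, 3], [1, 2, 3]]))
        assert got == pytest.approx(np.sqrt(2 / 3))

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            gelman_rubin(np.ones((1, 100)))

    def test_matches_arviz_split_rhat(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(4)
        x = rng.standard_normal((4, 500)) * 3 + 1
        theirs = float(np.asarray(
            az.rhat(az.convert_to_dataset(x[:, :, None]),
                    method="split")["x"].values).ravel()[0])
        assert gelman_rubin(x) == pytest.approx(theirs, abs=1e-12)


class TestClassifyEffects:
    def _draws_from(self, samples_by_name):
        names = tuple(samples_by_name)
        arr = np.stack([np.asarray(v) for v in samples_by_name.values()], axis=1)
        return PosteriorDraws(array=arr[None, :, :], names=names,
                              spec=DsrModelSpec(rng_seed=0), columns=names,
                              years=(), scaling={}, age_scaling={})

    @staticmethod
    def _normal_grid(lo, hi, n=4001):
        """Deterministic draws whose 2.5%/97.5% quantiles equal (lo, hi)."""
        from scipy import stats
        loc, scale = (lo + hi) / 2, (hi - lo) / (2 * 1.959964)
        probs = np.linspace(0.0005, 0.9995, n)
        return stats.norm.ppf(probs, loc=loc, scale=scale)

    def test_interval_sign_rule(self):
        draws = self._draws_from({
            # interval entirely positive, as for the nest-distance effect
            "pos": self._normal_grid(2.57, 3.86),
            # interval straddling zero, as for the lek-distance effect
            "straddle": self._normal_grid(-0.18, 0.27),
            # upper bound barely above zero: still not clear
            "barely": self._normal_grid(-0.84, 0.01),
            "neg": self._normal_grid(-1.21, -0.71),
        })
        got = classify_effects(draws)
        assert got == {"pos": "clear", "straddle": "not_clear",
                       "barely": "not_clear", "neg": "clear"}


class TestSamplePosterior:
    spec = DsrModelSpec(chains=4, iterations=600, warmup=300, rng_seed=10)

    def test_same_seed_identical_draws(self):
        design = _intercept_design(150, 8)
        d1 = sample_posterior(self.spec, design)
        d2 = sample_posterior(self.spec, design)
        assert np.array_equal(d1.array, d2.array)
        assert d1.array.shape == (4, 300, 1 + 1 + 2 * 1)

    def test_posterior_mean_near_mle_intercept_only(self):
        """With N exposure days and d failures under a diffuse prior, the
        posterior daily survival is close to the MLE 1 - d/N."""
        design = _intercept_design(400, 20)
        draws = sample_posterior(
            DsrModelSpec(chains=4, iterations=1200, warmup=600, rng_seed=3),
            design)
        # composite linear predictor: intercept + year effect
        eta = draws.draws("intercept") + draws.draws("year_2018")
        s_mean = expit(eta).mean()
        assert s_mean == pytest.approx(0.95, abs=0.01)

    def test_no_failures_warns(self):
        with pytest.warns(UserWarning, match="weakly identified"):
            sample_posterior(self.spec, _intercept_design(60, 0))

    def test_sigma_concentrates_when_years_homogeneous(self, default_dataset,
                                                       default_distance_table):
        """Limit agreement: on data generated with a vanishing year spread,
        sigma_year's posterior concentrates at small values and the fixed
        effects match the no-random-effect MLE."""
        from dataclasses import replace
        from ruffnest import build_design, simulate_dataset
        from conftest import predation_only_config

        cfg = predation_only_config(21)
        cfg.true_params = replace(cfg.true_params, sigma_year=1e-9,
                                  year_effects=[0.0] * cfg.n_years)
        nests, land = simulate_dataset(cfg)
        from ruffnest import nest_distance_table
        design = build_design(nests, nest_distance_table(nests, land),
                              "overall", "all_nests")
        draws = sample_posterior(
            DsrModelSpec(chains=4, iterations=1000, warmup=500, rng_seed=1),
            design)
        assert np.median(draws.draws("sigma_year")) < 0.4
        coef, _ = mle_oracle_fit(design)
        for name in ("dist_nests", "nest_age"):
            x = draws.draws(name)
            mcse = x.std() / np.sqrt(50)  # conservative ESS guess
            assert abs(x.mean() - coef[name]) < max(4 * mcse, 0.05)
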