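"""Hierarchical Bayesian model contracts: convergence statistics against
independent implementations, sum-to-zero constraints, moment recovery on
simulated data, leverage re-runs and fit serialization."""

import numpy as np
import pandas as pd
import pytest

import reefbayes as rb
from reefbayes.hier import HIERARCHY_COLUMNS, MCMCSchedule

TINY = MCMCSchedule(n_init=300, n_burn=300, n_keep=600, n_chains=3)


def _hier_frame(n, rng, n_years=3, n_datasets=2, n_moku=4):
    return pd.DataFrame({
        "year": rng.integers(2004, 2004 + n_years, n),
        "dataset": rng.choice([f"ds{i}" for i in range(n_datasets)], n),
        "moku": rng.choice([f"m{i}" for i in range(n_moku)], n),
    })


def _constant_hier(n):
    return pd.DataFrame({"year": [2010] * n, "dataset": ["d"] * n,
                         "moku": ["m"] * n})


class TestGelmanRubin:
    def test_identical_chains_near_one(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(size=500)
        assert rb.gelman_rubin(np.vstack([chain, chain])) == pytest.approx(
            1.0, abs=0.01
        )

    def test_separated_chains_match_direct_formula(self):
        rng = np.random.default_rng(1)
        chains = np.vstack([rng.normal(0, 1, 400), rng.normal(5, 1, 400)])
        got = rb.gelman_rubin(chains)
        # independent evaluation of the between/within formula
        m, n = chains.shape
        w = sum(np.var(chains[j], ddof=1) for j in range(m)) / m
        grand = chains.mean()
        b = n / (m - 1) * sum((chains[j].mean() - grand) ** 2 for j in range(m))
        expected = np.sqrt(((n - 1) / n * w + b / n) / w)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got > 2.0

    def test_agrees_with_arviz_on_mixed_chains(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(3, 1000))
        ours = rb.gelman_rubin(chains)
        theirs = float(az.rhat(az.convert_to_dataset(chains))["x"].values)
        assert ours == pytest.approx(1.0, abs=0.02)
        assert ours == pytest.approx(theirs, abs=0.05)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            rb.gelman_rubin(np.zeros((1, 100)))


class TestGammaModel:
    def test_intercept_only_recovers_sample_mean(self):
        rng = np.random.default_rng(3)
        n, kappa, mu = 2000, 3.0, 2.5
        y = rng.gamma(kappa, np.exp(mu) / kappa, n)
        X = pd.DataFrame(index=range(n))
        model = rb.HierarchicalGammaRegression(schedule=TINY, seed=1)
        model.fit(X, y, _constant_hier(n))
        post_mean = np.exp(model.intercept_draws_).mean()
        se = y.mean() / np.sqrt(kappa * n)
        assert abs(post_mean - y.mean()) < 3.5 * se
        assert np.median(model.kappa_draws_) == pytest.approx(kappa, rel=0.25)

    def test_sum_to_zero_exact_every_draw(self, fitted_gamma):
        model, _, _ = fitted_gamma
        for h in HIERARCHY_COLUMNS:
            sums = model.effect_draws_[h].sum(axis=1)
            assert np.all(sums == 0.0)

    def test_kappa_within_prior_bounds(self, fitted_gamma):
        model, _, _ = fitted_gamma
        assert np.all(model.kappa_draws_ > 0)
        assert np.all(model.kappa_draws_ <= model.kappa_max)

    def test_mean_link_fitted_slope_near_one(self, fitted_gamma):
        model, design, data = fitted_gamma
        fitted = model.predict(design, moku=data["moku_id"].to_numpy())
        y = data["biomass_total"].to_numpy()
        slope = np.dot(fitted, y) / np.dot(fitted, fitted)
        assert slope == pytest.approx(1.0, abs=0.15)

    def test_nonpositive_response_rejected(self):
        model = rb.HierarchicalGammaRegression(schedule=TINY)
        X = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(ValueError, match="positive"):
            model.fit(X, np.array([1.0, 0.0]), _constant_hier(2))

    def test_unknown_moku_rejected_then_population_fallback(self, fitted_gamma):
        model, design, data = fitted_gamma
        X1 = design.values.iloc[:2]
        with pytest.raises(ValueError, match="unknown moku"):
            model.posterior_linpred(X1, moku=np.array(["mx", "mx"]))
        mu = model.posterior_linpred(X1, moku=np.array(["mx", "mx"]),
                                     unknown_moku="population")
        mu0 = model.posterior_linpred(X1, moku=None)
        np.testing.assert_allclose(mu, mu0)

    def test_row_permutation_leaves_posterior_unchanged(self):
        rng = np.random.default_rng(4)
        n = 400
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        mu = 2.0 + 0.5 * X["a"] - 0.3 * X["b"]
        y = rng.gamma(3.0, np.exp(mu) / 3.0)
        hier = _hier_frame(n, rng)
        perm = rng.permutation(n)
        m1 = rb.HierarchicalGammaRegression(schedule=TINY, seed=7).fit(
            X, y, hier
        )
        m2 = rb.HierarchicalGammaRegression(schedule=TINY, seed=7).fit(
            X.iloc[perm].reset_index(drop=True), y[perm],
            hier.iloc[perm].reset_index(drop=True),
        )
        for j in range(2):
            d1, d2 = m1.coef_draws_[:, j], m2.coef_draws_[:, j]
            mcse = np.sqrt(d1.var() / 150 + d2.var() / 150)
            assert abs(d1.mean() - d2.mean()) < 4 * mcse

    def test_reduced_schedule_matches_full_schedule(self):
        # same synthetic data, short vs full iteration plan: point
        # estimates agree within Monte-Carlo error
        rng = np.random.default_rng(5)
        n = 400
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = rng.gamma(3.0, np.exp(2.0 + 0.4 * X["a"]) / 3.0)
        hier = _hier_frame(n, rng)
        quick = rb.HierarchicalGammaRegression(schedule=TINY, seed=2).fit(
            X, y, hier
        )
        full = rb.HierarchicalGammaRegression(schedule="paper", seed=3).fit(
            X, y, hier
        )
        for j in range(2):
            dq, df_ = quick.coef_draws_[:, j], full.coef_draws_[:, j]
            mcse = np.sqrt(dq.var() / 100 + df_.var() / 500)
            assert abs(dq.mean() - df_.mean()) < 3 * mcse


class TestNormalModel:
    @pytest.fixture(scope="class")
    def noise_fit(self):
        rng = np.random.default_rng(6)
        n = 2000
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        y = rng.normal(size=n)
        model = rb.HierarchicalNormalRegression(schedule=TINY, seed=4)
        return model.fit(X, y, _hier_frame(n, rng))

    def test_pure_noise_bayes_r2_near_zero(self, noise_fit):
        assert np.median(noise_fit.bayes_r2_) < 0.05

    def test_sigma_draws_positive(self, noise_fit):
        assert np.all(noise_fit.sigma_draws_ > 0)

    def test_bayes_r2_in_unit_interval(self, noise_fit):
        assert np.all((noise_fit.bayes_r2_ >= 0) & (noise_fit.bayes_r2_ <= 1))

    def test_recovers_three_way_interaction(self, small_grid):
        truth = rb.make_truth({"benthic_beta": {
            "intercept": 0.2, "grazer": 0.3, "scraper": 0.5, "browser": 0.2,
            "grazer:scraper": -0.1, "grazer:browser": -0.08,
            "scraper:browser": -0.06, "grazer:scraper:browser": 0.15,
        }, "sigma_benthic": 0.5, "seed": 21})
        reps, _ = rb.simulate_surveys(small_grid, truth, 1200, seed=8)
        st = rb.DriverStandardizer(columns=["sst_mean"]).fit(small_grid)
        design = rb.build_design(reps, [], st, model="benthic")
        hier = pd.DataFrame({"year": reps["year"],
                             "dataset": reps["source_dataset"],
                             "moku": reps["moku_id"]})
        model = rb.HierarchicalNormalRegression(schedule=TINY, seed=9)
        model.fit(design, reps["benthic_logratio"].to_numpy(), hier)
        j = model.coef_names_.index("grazer:scraper:browser")
        lo, hi = np.quantile(model.coef_draws_[:, j], [0.025, 0.975])
        # the triple interaction is invariant to centering of the mains
        assert lo < 0.15 < hi

    def test_literal_sigma_inverse_reading_available(self):
        rng = np.random.default_rng(7)
        n = 300
        y = rng.normal(0, 2.0, n)
        model = rb.HierarchicalNormalRegression(
            schedule=TINY, seed=1, tau_is_sd_inverse=True
        )
        model.fit(pd.DataFrame(index=range(n)), y, _constant_hier(n))
        assert np.median(model.sigma_draws_) == pytest.approx(2.0, rel=0.2)


class TestDiagnostics:
    def test_report_contents(self, fitted_gamma):
        model, _, _ = fitted_gamma
        diag = rb.diagnose_fit(model)
        assert set(diag) >= {"rhat", "max_rhat", "ppc", "bayes_r2"}
        assert 0.0 < diag["ppc"]["p_mean"] < 1.0
        assert 0.0 <= diag["bayes_r2"]["median"] <= 1.0
        assert diag["max_rhat"] == pytest.approx(model.rhat_.max())

    def test_single_chain_schedule_rejected(self):
        with pytest.raises(ValueError, match="chains"):
            MCMCSchedule(n_chains=1)

    def test_unfitted_model_rejected(self):
        with pytest.raises(RuntimeError):
            rb.diagnose_fit(rb.HierarchicalGammaRegression())


class TestLeverageRerun:
    @pytest.fixture(scope="class")
    def confounded_data(self):
        rng = np.random.default_rng(10)
        n = 600
        # pollution-style drivers: non-negative with a native floor at 0,
        # so "set the flagged values to zero" is a meaningful replacement
        data = pd.DataFrame({
            "sediment": rng.gamma(2.0, 1.0, n),
            "sst_mean": rng.normal(10, 2, n),
            "cesspool_effluent": rng.gamma(2.0, 1.0, n),
        })
        mu = 2.0 + 0.3 * (data["sst_mean"] - 10) / 2
        # a site-level anomaly: high-sediment rows also have high biomass
        # for reasons unrelated to sediment
        flag = data["sediment"] >= data["sediment"].quantile(0.9)
        mu = mu + 1.2 * flag
        y = rng.gamma(3.0, np.exp(mu) / 3.0)
        hier = _hier_frame(n, rng)
        return data.assign(biomass=y), hier, flag.to_numpy()

    def test_spurious_effect_attenuates(self, confounded_data):
        data, hier, flag = confounded_data
        out = rb.leverage_rerun(
            rb.HierarchicalGammaRegression(schedule=TINY, seed=3),
            data, "biomass", hier,
            drivers=["sediment", "sst_mean", "cesspool_effluent"],
            driver="sediment", flagged=flag,
        )
        assert out["original"]["distinguishable_from_zero"]
        assert out["attenuated"]
        assert abs(out["rerun"]["median"]) < abs(out["original"]["median"])

    def test_null_driver_stays_null(self, confounded_data):
        data, hier, _ = confounded_data
        out = rb.leverage_rerun(
            rb.HierarchicalGammaRegression(schedule=TINY, seed=3),
            data, "biomass", hier,
            drivers=["sediment", "sst_mean", "cesspool_effluent"],
            driver="cesspool_effluent",
        )
        assert not out["original"]["distinguishable_from_zero"]
        assert not out["rerun"]["distinguishable_from_zero"]

    def test_unknown_driver_rejected(self, confounded_data):
        data, hier, _ = confounded_data
        with pytest.raises(KeyError):
            rb.leverage_rerun(
                rb.HierarchicalGammaRegression(schedule=TINY),
                data, "biomass", hier, drivers=["sediment"], driver="zzz",
            )

    def test_no_flagged_rows_rejected(self, confounded_data):
        data, hier, _ = confounded_data
        with pytest.raises(ValueError, match="flagged"):
            rb.leverage_rerun(
                rb.HierarchicalGammaRegression(schedule=TINY),
                data, "biomass", hier, drivers=["sediment"],
                driver="sediment", flagged=np.zeros(len(data), bool),
            )


class TestSerialization:
    def test_save_load_round_trip(self, fitted_gamma, tmp_path):
        model, design, data = fitted_gamma
        rb.save_fit(model, tmp_path / "fit")
        loaded = rb.load_fit(tmp_path / "fit")
        X = design.values.iloc[:5]
        moku = data["moku_id"].to_numpy()[:5]
        np.testing.assert_allclose(
            loaded.posterior_linpred(X, moku=moku),
            model.posterior_linpred(X, moku=moku),
        )
        assert loaded.coef_names_ == model.coef_names_
        assert loaded.converged_ == model.converged_
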