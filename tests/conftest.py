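"""Shared fixtures: a small synthetic study and hand-built posterior fits.

The hand-built fits (``synthetic_gamma_fit`` / ``synthetic_normal_fit``)
carry posterior draws constructed directly from known parameters, so the
counterfactual and threshold machinery can be exercised against closed
forms without running MCMC.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import reefbayes as rb
from reefbayes.hier import HIERARCHY_COLUMNS

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

FIVE_DRIVERS = ["spear_shore", "net_boat", "urban_runoff", "sst_mean", "rugosity"]
FIVE_BETAS = {"spear_shore": -0.5, "net_boat": 0.3, "urban_runoff": -0.25,
              "sst_mean": 0.2, "rugosity": 0.4}


@pytest.fixture(scope="session")
def small_grid():
    return rb.make_driver_grid(n_pixels=800, n_moku=4, correlation_level=0.3,
                               seed=7)


@pytest.fixture(scope="session")
def truth5():
    return rb.make_truth({"beta": FIVE_BETAS, "kappa": 3.0, "seed": 11})


@pytest.fixture(scope="session")
def surveys_small(small_grid, truth5):
    reps, fish = rb.simulate_surveys(
        small_grid, truth5, n_replicates=800, n_years=3, n_datasets=2, seed=3
    )
    return reps, fish


@pytest.fixture(scope="session")
def fitted_gamma(small_grid, surveys_small):
    """A real MCMC fit of the gamma biomass model on the small study."""
    reps, _ = surveys_small
    data = reps.drop(columns=["depth"]).merge(
        small_grid[["pixel_id"] + rb.DRIVER_NAMES], on="pixel_id"
    )
    st = rb.DriverStandardizer(columns=FIVE_DRIVERS).fit(small_grid)
    design = rb.build_design(data, FIVE_DRIVERS, st, model="herbivore")
    hier = pd.DataFrame({"year": data["year"], "dataset": data["source_dataset"],
                         "moku": data["moku_id"]})
    model = rb.HierarchicalGammaRegression(schedule="ci", seed=5)
    model.fit(design, data["biomass_total"].to_numpy(), hier)
    return model, design, data


def make_synthetic_gamma_fit(coef_names, intercept, betas, beta_sd=0.0,
                             n_draws=800, seed=0, moku_levels=None):
    """Hand-built 'fitted' gamma model: draws around known coefficients."""
    rng = np.random.default_rng(seed)
    fit = rb.HierarchicalGammaRegression()
    fit.coef_names_ = list(coef_names)
    p = len(coef_names)
    fit.intercept_draws_ = np.full(n_draws, float(intercept))
    fit.coef_draws_ = (
        np.tile(np.asarray(betas, float), (n_draws, 1))
        + beta_sd * rng.standard_normal((n_draws, p))
    )
    fit.kappa_draws_ = np.full(n_draws, 3.0)
    levels = {h: [0] for h in HIERARCHY_COLUMNS}
    if moku_levels is not None:
        levels["moku"] = list(moku_levels)
    fit.levels_ = levels
    fit.effect_draws_ = {
        h: np.zeros((n_draws, len(levels[h]))) for h in HIERARCHY_COLUMNS
    }
    fit.sd_draws_ = {h: np.zeros(n_draws) for h in HIERARCHY_COLUMNS}
    fit.n_features_in_ = p
    return fit


def make_synthetic_normal_fit(coef_names, intercept_sd, betas, beta_sd,
                              n_draws=800, seed=0):
    """Hand-built 'fitted' normal (benthic) model."""
    rng = np.random.default_rng(seed)
    fit = rb.HierarchicalNormalRegression()
    fit.coef_names_ = list(coef_names)
    p = len(coef_names)
    fit.intercept_draws_ = intercept_sd * rng.standard_normal(n_draws)
    fit.coef_draws_ = (
        np.tile(np.asarray(betas, float), (n_draws, 1))
        + np.asarray(beta_sd, float) * rng.standard_normal((n_draws, p))
    )
    fit.sigma_draws_ = np.full(n_draws, 0.5)
    fit.tau_draws_ = fit.sigma_draws_ ** -2
    fit.levels_ = {h: [0] for h in HIERARCHY_COLUMNS}
    fit.effect_draws_ = {h: np.zeros((n_draws, 1)) for h in HIERARCHY_COLUMNS}
    fit.sd_draws_ = {h: np.zeros(n_draws) for h in HIERARCHY_COLUMNS}
    fit.n_features_in_ = p
    return fit


def type7_quantile(values, q):
    """Independent sort-based quantile oracle (linear interpolation)."""
    x = np.sort(np.asarray(values, float))
    n = x.size
    h = (n - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    return x[lo] + (h - lo) * (x[hi] - x[lo])
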