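"""Binomial-gamma hurdle analysis of management effects on parrotfish
biomass.

Zero-inflated biomass across management levels (e.g. before/after a
closure, open/protected) is modelled in two parts: presence/absence with
a binomial GLM (logit link) and biomass-when-present with a gamma GLM
(log link), both on the management factor. The combined prediction per
level is presence probability x conditional mean. Uncertainty comes from
non-parametric bootstrapping (resampling rows with replacement, stratified
by level so no level can empty out) with bias-corrected percentile
intervals; BCa (jackknife acceleration) is available. When a stratum has
no zeros at all the hurdle collapses to a plain gamma model
(``model_mode`` = "gamma-only").

For the one-factor model fitted here the GLM maximum-likelihood estimates
are the per-level presence fraction and the per-level mean of positive
biomass; bootstrap refits use those closed forms directly, which is
algebraically identical to refitting the GLMs and orders of magnitude
faster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import ndtr, ndtri
from scipy.stats import norm, t as t_dist


def _level_dummies(levels_series, levels):
    X = np.ones((len(levels_series), len(levels)))
    for j, lev in enumerate(levels[1:], start=1):
        X[:, j] = (levels_series == lev).astype(float)
    return X


class HurdleModel:
    """Two-part binomial-gamma model of biomass across management levels.

    Fitted attributes: ``levels_``, ``presence_`` (per-level presence
    probability), ``conditional_mean_`` (per-level mean biomass when
    present, g m^-2), ``combined_`` (their product), ``model_mode_``
    ("hurdle" or "gamma-only"), ``binomial_result_`` / ``gamma_result_``
    (statsmodels fits) and ``wald_`` (per-contrast test statistics with
    residual df, against the first level as reference).
    """

    def __init__(self, level_column="management", biomass_column="biomass"):
        self.level_column = level_column
        self.biomass_column = biomass_column

    def get_params(self, deep=True):
        return {"level_column": self.level_column,
                "biomass_column": self.biomass_column}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, data: pd.DataFrame):
        lev_col, bio_col = self.level_column, self.biomass_column
        for c in (lev_col, bio_col):
            if c not in data.columns:
                raise KeyError(f"data has no {c!r} column")
        y = data[bio_col].to_numpy(float)
        if np.any(y < 0):
            raise ValueError("biomass must be non-negative")
        levels = sorted(data[lev_col].unique())
        if len(levels) < 2:
            raise ValueError("hurdle model needs >= 2 management levels")
        self.levels_ = levels
        lev = data[lev_col]

        present = (y > 0).astype(float)
        self.presence_ = {
            l: float(present[lev == l].mean()) for l in levels
        }
        pos_mask = y > 0
        self.conditional_mean_ = {}
        for l in levels:
            sel = pos_mask & (lev == l).to_numpy()
            if sel.any():
                self.conditional_mean_[l] = float(y[sel].mean())
            else:
                warnings.warn(
                    f"level {l!r} has no positive biomass; combined "
                    "prediction is 0 and its gamma contrast is undefined"
                )
                self.conditional_mean_[l] = np.nan
        self.combined_ = {
            l: (self.presence_[l] * self.conditional_mean_[l]
                if np.isfinite(self.conditional_mean_[l]) else 0.0)
            for l in levels
        }

        self.model_mode_ = "hurdle" if (present == 0).any() else "gamma-only"
        self.wald_ = {}

        X = _level_dummies(lev, levels)
        if self.model_mode_ == "hurdle":
            bin_res = sm.GLM(present, X, family=sm.families.Binomial()).fit()
            self.binomial_result_ = bin_res
            df = int(bin_res.df_resid)
            for j, l in enumerate(levels[1:], start=1):
                z = bin_res.params[j] / bin_res.bse[j]
                self.wald_[("binomial", l)] = {
                    "stat": float(z), "df": df,
                    "p": float(2 * norm.sf(abs(z))),
                }
        else:
            self.binomial_result_ = None

        Xp = _level_dummies(lev[pos_mask], levels)
        fitted_levels = [l for l in levels
                         if np.isfinite(self.conditional_mean_[l])]
        if len(fitted_levels) == len(levels):
            gam_res = sm.GLM(
                y[pos_mask], Xp,
                family=sm.families.Gamma(link=sm.families.links.Log()),
            ).fit()
            self.gamma_result_ = gam_res
            df = int(gam_res.df_resid)
            for j, l in enumerate(levels[1:], start=1):
                tval = gam_res.params[j] / gam_res.bse[j]
                self.wald_[("gamma", l)] = {
                    "stat": float(tval), "df": df,
                    "p": float(2 * t_dist.sf(abs(tval), df)),
                }
        else:
            self.gamma_result_ = None
        return self

    def predict_level(self, level):
        """Combined prediction p x E[y | y>0] for one level (g m^-2)."""
        if level not in self.levels_:
            raise KeyError(f"unknown management level {level!r}")
        return self.combined_[level]


def fit_hurdle(data: pd.DataFrame, level_column="management",
               biomass_column="biomass") -> HurdleModel:
    """Fit the binomial-gamma hurdle model; see HurdleModel."""
    return HurdleModel(level_column, biomass_column).fit(data)


def _bias_corrected_interval(draws, point, alpha=0.05, accel=0.0):
    draws = np.asarray(draws, float)
    draws = draws[np.isfinite(draws)]
    B = draws.size
    if B < 10:
        return (np.nan, np.nan)
    prop = np.clip(np.mean(draws < point), 1.0 / (B + 1), B / (B + 1.0))
    z0 = ndtri(prop)
    out = []
    for z in (ndtri(alpha / 2), ndtri(1 - alpha / 2)):
        adj = z0 + (z0 + z) / (1.0 - accel * (z0 + z))
        out.append(float(np.quantile(draws, np.clip(ndtr(adj), 0.0, 1.0))))
    return tuple(out)


def _closed_form(levels, lev_arr, y):
    """Per-level (presence, conditional mean, combined) — the exact GLM MLE
    for the one-factor hurdle model."""
    p, m, c = {}, {}, {}
    for l in levels:
        sel = lev_arr == l
        yl = y[sel]
        p[l] = yl.astype(bool).mean() if yl.size else np.nan
        pos = yl[yl > 0]
        m[l] = pos.mean() if pos.size else np.nan
        c[l] = p[l] * m[l] if pos.size else 0.0
    return p, m, c


def _jackknife_accel(stat_loo):
    theta_dot = stat_loo.mean()
    d = theta_dot - stat_loo
    denom = 6.0 * (np.sum(d**2)) ** 1.5
    return float(np.sum(d**3) / denom) if denom > 0 else 0.0


def combine_and_bootstrap(
    data: pd.DataFrame,
    B: int = 5000,
    seed: int = 0,
    level_column: str = "management",
    biomass_column: str = "biomass",
    fold_levels: tuple | None = None,
    alpha: float = 0.05,
    method: str = "bc",
) -> dict:
    """Bootstrapped combined predictions with bias-corrected 95% CIs.

    Rows are resampled with replacement B times, stratified by management
    level; both model parts are refit on each resample (closed form, see
    module docstring) and the combined prediction per level recomputed.
    Point estimates come from the original data; intervals are
    bias-corrected percentile ("bc", default) or BCa ("bca", jackknife
    acceleration). ``fold_levels=(a, b)`` additionally reports the
    fold-change combined(b) / combined(a) with its interval. Bootstrap
    draws where a level loses all positive observations are discarded and
    counted.
    """
    if B < 200:
        raise ValueError("B must be >= 200")
    fit = fit_hurdle(data, level_column, biomass_column)
    levels = fit.levels_
    y = data[biomass_column].to_numpy(float)
    lev_arr = data[level_column].to_numpy()
    rng = np.random.default_rng(seed)

    strata = {l: np.flatnonzero(lev_arr == l) for l in levels}
    boot = {l: np.empty(B) for l in levels}
    discarded = 0
    for b in range(B):
        ok = True
        vals = {}
        for l in levels:
            idx = strata[l]
            take = rng.integers(0, idx.size, idx.size)
            yb = y[idx[take]]
            pos = yb[yb > 0]
            if pos.size == 0:
                if fit.combined_[l] == 0.0:
                    vals[l] = 0.0  # level had no positives originally
                else:
                    ok = False
                    break
            else:
                vals[l] = yb.astype(bool).mean() * pos.mean()
        if ok:
            for l in levels:
                boot[l][b] = vals[l]
        else:
            discarded += 1
            for l in levels:
                boot[l][b] = np.nan

    out = {"levels": levels, "model_mode": fit.model_mode_,
           "discarded_draws": discarded, "fit": fit, "per_level": {}}

    accel = {l: 0.0 for l in levels}
    if method == "bca":
        for l in levels:
            idx = strata[l]
            yl = y[idx]
            n = yl.size
            pos = yl > 0
            npos = pos.sum()
            if npos in (0, n) and npos == 0:
                continue
            spos = yl[pos].sum()
            loo = np.empty(n)
            for i in range(n):
                k = pos.sum() - (1 if pos[i] else 0)
                s = spos - (yl[i] if pos[i] else 0.0)
                loo[i] = (k / (n - 1)) * (s / k) if k > 0 else 0.0
            accel[l] = _jackknife_accel(loo)
    elif method != "bc":
        raise ValueError("method must be 'bc' or 'bca'")

    for l in levels:
        point = fit.combined_[l]
        ci = _bias_corrected_interval(boot[l], point, alpha, accel[l])
        out["per_level"][l] = {
            "combined": point, "presence": fit.presence_[l],
            "conditional_mean": fit.conditional_mean_[l],
            "ci": ci, "draws": boot[l],
        }

    if fold_levels is not None:
        a, b_ = fold_levels
        for l in (a, b_):
            if l not in levels:
                raise KeyError(f"unknown management level {l!r}")
        if fit.combined_[a] == 0:
            raise ValueError(f"fold change undefined: level {a!r} predicts 0")
        point = fit.combined_[b_] / fit.combined_[a]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = boot[b_] / boot[a]
        ci = _bias_corrected_interval(ratio, point, alpha)
        out["fold_change"] = {"levels": (a, b_), "estimate": float(point),
                              "ci": ci}
    return out
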