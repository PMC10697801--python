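"""Counterfactual fishing depletion and the benthic-impact threshold.

For every grid pixel the fitted herbivore model gives a posterior of
*expected* biomass (measured drivers) and *potential* biomass (fishing
drivers set to zero in native units before standardization, everything
else held at measured values). Their draw-wise ratio, as a percentage, is
the fishing-depletion index "% potential biomass". Feeding expected and
potential functional-group biomass through the benthic model yields a
paired posterior of benthic condition per pixel; a pixel is *affected* by
fishing when the 25th percentile of condition under potential biomass
exceeds the 75th percentile under expected biomass (non-overlapping 50%
intervals, potential higher). A logistic regression of unaffected(1) /
affected(0) on median % potential biomass is then inverted at probability
0.99 to give the depletion threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logit

from ._utils import quantile
from .drivers import DriverStandardizer, build_design
from .synthetic import DRIVER_GROUPS


@dataclass
class PixelCounterfactual:
    """Matched posterior draws of expected and potential biomass per pixel."""

    pixel_id: np.ndarray
    expected: np.ndarray   # (n_draws, n_pixels), g m^-2
    potential: np.ndarray  # (n_draws, n_pixels), g m^-2
    percent: np.ndarray    # (n_draws, n_pixels), % potential biomass

    @property
    def median_percent(self) -> np.ndarray:
        return np.median(self.percent, axis=0)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pixel_id": self.pixel_id,
            "expected_median": np.median(self.expected, axis=0),
            "potential_median": np.median(self.potential, axis=0),
            "percent_potential_median": self.median_percent,
        })


def predict_counterfactual(
    fit,
    grid: pd.DataFrame,
    drivers: list[str],
    standardizer: DriverStandardizer,
    n_draws: int | None = 500,
    unknown_moku: str = "error",
    habitat_reference: str = "other",
) -> PixelCounterfactual:
    """Expected vs potential biomass posteriors on matched draws.

    Potential biomass re-standardizes the grid after zeroing the fishing
    drivers natively, so a pixel that is already unfished has expected ==
    potential draw-for-draw and % potential biomass exactly 100. Year and
    dataset effects sit at 0 (their sum-to-zero mean); the moku effect is
    taken from the fitted level.
    """
    fishing = [d for d in drivers if DRIVER_GROUPS.get(d) == "fishing"]
    design_exp = build_design(
        grid, drivers, standardizer, model="herbivore",
        habitat_reference=habitat_reference,
    )
    grid_pot = grid.copy()
    grid_pot[fishing] = 0.0
    design_pot = build_design(
        grid_pot, drivers, standardizer, model="herbivore",
        habitat_reference=habitat_reference,
    )
    moku = grid["moku_id"].to_numpy() if "moku_id" in grid.columns else None
    mu_exp = fit.posterior_linpred(
        design_exp, moku=moku, n_draws=n_draws, unknown_moku=unknown_moku
    )
    mu_pot = fit.posterior_linpred(
        design_pot, moku=moku, n_draws=n_draws, unknown_moku=unknown_moku
    )
    percent = 100.0 * np.exp(mu_exp - mu_pot)
    return PixelCounterfactual(
        pixel_id=grid["pixel_id"].to_numpy(),
        expected=np.exp(mu_exp),
        potential=np.exp(mu_pot),
        percent=percent,
    )


def benthic_counterfactual(
    benthic_fit,
    grid: pd.DataFrame,
    expected_fg: pd.DataFrame,
    potential_fg: pd.DataFrame,
    drivers: list[str],
    standardizer: DriverStandardizer,
    fg_centers: dict,
    n_draws: int | None = 500,
    unknown_moku: str = "error",
):
    """Paired posteriors of benthic condition under expected vs potential
    herbivore biomass.

    ``expected_fg`` / ``potential_fg`` carry the posterior-mean
    biomass_grazer / biomass_scraper / biomass_browser per pixel for each
    scenario. Both scenarios use the measured (non-fishing) drivers and
    the training-set centering of the log1p functional-group biomasses.
    The returned draws are of the linear predictor — condition itself, no
    observation noise.
    """
    for name, fg in (("expected_fg", expected_fg), ("potential_fg", potential_fg)):
        if fg is None or len(fg) != len(grid):
            raise ValueError(f"{name} must align with the grid")
    moku = grid["moku_id"].to_numpy() if "moku_id" in grid.columns else None
    out = []
    for fg in (expected_fg, potential_fg):
        frame = pd.concat(
            [grid.reset_index(drop=True), fg.reset_index(drop=True)], axis=1
        )
        design = build_design(
            frame, drivers, standardizer, model="benthic", fg_centers=fg_centers
        )
        out.append(benthic_fit.posterior_linpred(
            design, moku=moku, n_draws=n_draws, unknown_moku=unknown_moku
        ))
    return out[0], out[1]


def classify_pixel(expected_draws, potential_draws) -> np.ndarray | bool:
    """Affected iff Q25(potential) > Q75(expected).

    Accepts 1-D draw vectors (returns a bool) or (n_draws, n_pixels)
    arrays (returns a bool per pixel). Affected means the 50% intervals do
    not overlap and condition under potential biomass is higher — fishing
    has measurably depressed benthic condition.
    """
    e = np.asarray(expected_draws, float)
    p = np.asarray(potential_draws, float)
    if e.size == 0 or p.size == 0:
        raise ValueError("empty draw vectors")
    if e.ndim == 1:
        return bool(quantile(p, 0.25) > quantile(e, 0.75))
    return np.quantile(p, 0.25, axis=0) > np.quantile(e, 0.75, axis=0)


@dataclass
class ThresholdResult:
    """Fitted logistic threshold of benthic impact on % potential biomass."""

    intercept: float
    slope: float
    threshold: float          # % potential biomass where P(unaffected)=p_star
    p_star: float
    separation: bool = False  # complete separation -> mid-gap threshold
    reliable: bool = True     # False when the slope CI contains 0
    slope_ci: tuple = (np.nan, np.nan)
    classifications: pd.DataFrame | None = field(default=None, repr=False)

    def prob_unaffected(self, x):
        eta = self.intercept + self.slope * np.asarray(x, float)
        return 1.0 / (1.0 + np.exp(-eta))


def fit_threshold_logistic(
    unaffected, percent_potential, p_star: float = 0.99
) -> ThresholdResult:
    """Maximum-likelihood logistic fit of unaffected(1)/affected(0) on
    median % potential biomass, solved at P(unaffected) = p_star.

    The threshold is exact logit inversion of the fitted curve:
    x* = (logit(p_star) - b0) / b1. Complete separation returns the
    mid-gap threshold with ``separation=True``; a single class present is
    an error; a slope whose 95% Wald CI contains 0 flags the threshold
    unreliable.
    """
    y = np.asarray(unaffected).astype(float)
    x = np.asarray(percent_potential, float)
    if y.size != x.size or y.size == 0:
        raise ValueError("labels and percent_potential must align")
    if not 0 < p_star < 1:
        raise ValueError("p_star must be in (0, 1)")
    ones, zeros = y == 1, y == 0
    if not ones.any() or not zeros.any():
        raise ValueError(
            "cannot fit a threshold with a single class present"
        )
    table = pd.DataFrame({"percent_potential": x, "unaffected": y.astype(int)})

    if x[zeros].max() < x[ones].min():
        mid = 0.5 * (x[zeros].max() + x[ones].min())
        return ThresholdResult(
            intercept=np.nan, slope=np.nan, threshold=float(mid),
            p_star=p_star, separation=True, classifications=table,
        )

    X = sm.add_constant(x)
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    b0, b1 = res.params
    se1 = res.bse[1]
    ci = (b1 - 1.96 * se1, b1 + 1.96 * se1)
    reliable = not (ci[0] <= 0 <= ci[1])
    if b1 == 0:
        raise ValueError("degenerate logistic fit: zero slope")
    xstar = (logit(p_star) - b0) / b1
    return ThresholdResult(
        intercept=float(b0), slope=float(b1), threshold=float(xstar),
        p_star=p_star, reliable=bool(reliable),
        slope_ci=(float(ci[0]), float(ci[1])), classifications=table,
    )


def threshold_coverage(
    grid: pd.DataFrame,
    median_percent: np.ndarray,
    threshold: float,
    hardbottom_only: bool = True,
) -> dict:
    """Fraction of (hard-bottom) pixels below the depletion threshold,
    overall and per moku."""
    df = pd.DataFrame({
        "moku_id": grid["moku_id"].to_numpy(),
        "below": np.asarray(median_percent, float) < threshold,
    })
    if hardbottom_only and "hardbottom_flag" in grid.columns:
        df = df[grid["hardbottom_flag"].to_numpy(bool)]
    overall = float(df["below"].mean()) if len(df) else np.nan
    per_moku = df.groupby("moku_id")["below"].mean()
    return {"overall": overall, "per_moku": per_moku}
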