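"""Driver standardization, collinearity screening and design matrices.

Continuous drivers enter the models standardized to zero mean and unit
sample variance; the moments estimated on the training replicates are
reused verbatim on prediction grids. Within the four driver groups
(fishing, pollution, oceanography, habitat), predictors correlated above
|Spearman rho| = 0.7 are screened down to one representative. The benthic
model's herbivore block is built from log(1+x)-transformed functional-group
biomasses: three centered main effects, their three pairwise products and
the triple product (7 columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import DRIVER_GROUPS, HABITAT_CLASSES

FG_NAMES = ("grazer", "scraper", "browser")


class DriverStandardizer:
    """Column-wise (x - mean) / sd transformer with frozen training moments.

    sklearn-style: ``fit`` learns per-column mean and sample SD (ddof=1),
    ``transform`` applies them without re-estimation, so grids are scaled
    exactly as the training replicates were.
    """

    def __init__(self, columns=None):
        self.columns = columns

    def get_params(self, deep=True):
        return {"columns": self.columns}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y=None):
        cols = list(self.columns) if self.columns is not None else list(X.columns)
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise KeyError(f"columns not in table: {missing}")
        vals = X[cols].to_numpy(float)
        if np.isnan(vals).any():
            raise ValueError("drivers contain missing values")
        mean = vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=1)
        degenerate = [c for c, s in zip(cols, sd) if not s > 0]
        if degenerate:
            raise ValueError(f"degenerate (constant) drivers: {degenerate}")
        self.columns_ = cols
        self.mean_ = pd.Series(mean, index=cols)
        self.scale_ = pd.Series(sd, index=cols)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "mean_"):
            raise RuntimeError("standardizer is not fitted")
        missing = [c for c in self.columns_ if c not in X.columns]
        if missing:
            raise KeyError(f"columns not in table: {missing}")
        return (X[self.columns_] - self.mean_) / self.scale_

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)

    def transform_value(self, column: str, native_value) -> np.ndarray:
        """Standardize a native-unit value (e.g. fishing driver at zero)."""
        return (np.asarray(native_value, float) - self.mean_[column]) / self.scale_[column]


def standardize_drivers(values: pd.DataFrame, columns=None):
    """Standardize driver columns; returns (table, fitted standardizer)."""
    st = DriverStandardizer(columns=columns)
    return st.fit_transform(values), st


def correlation_screen(
    values: pd.DataFrame,
    threshold: float = 0.7,
    keep_preferences: list[str] | None = None,
):
    """Drop drivers until no retained pair has |Spearman rho| > threshold.

    Conflicting pairs are resolved highest-correlation first. Within a
    pair, the driver earlier in ``keep_preferences`` wins; absent a stated
    preference, the driver with the lower total absolute correlation to
    everything else is kept (it carries more unique signal). Returns the
    retained column list and a report of dropped pairs.
    """
    cols = list(values.columns)
    if len(cols) < 2:
        raise ValueError("correlation_screen needs at least 2 drivers")
    prefs = {c: i for i, c in enumerate(keep_preferences or [])}
    corr = values.corr(method="spearman").abs()
    np.fill_diagonal(corr.values, 0.0)
    retained = sorted(cols)
    dropped = []
    while True:
        sub = corr.loc[retained, retained]
        hi = sub.to_numpy().max() if len(retained) > 1 else 0.0
        if hi <= threshold:
            break
        i, j = np.unravel_index(np.argmax(sub.to_numpy()), sub.shape)
        a, b = sorted((retained[i], retained[j]))
        pa, pb = prefs.get(a, np.inf), prefs.get(b, np.inf)
        if pa != pb:
            keep = a if pa < pb else b
        else:
            keep = a if sub.loc[a].sum() <= sub.loc[b].sum() else b
        drop = b if keep == a else a
        retained.remove(drop)
        dropped.append({"kept": keep, "dropped": drop,
                        "abs_spearman": float(sub.loc[a, b])})
    report = pd.DataFrame(dropped, columns=["kept", "dropped", "abs_spearman"])
    return [c for c in cols if c in retained], report


@dataclass
class DesignMatrix:
    """Numeric model matrix plus per-column group labels and build metadata."""

    values: pd.DataFrame
    groups: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("design matrix contains missing values")

    @property
    def columns(self):
        return list(self.values.columns)

    def to_numpy(self):
        return self.values.to_numpy(float)


def _habitat_indicators(data: pd.DataFrame, reference: str) -> pd.DataFrame:
    levels = [h for h in HABITAT_CLASSES if h != reference]
    out = {}
    for h in levels:
        out[f"habitat_{h}"] = (data["habitat_class"] == h).astype(float)
    return pd.DataFrame(out, index=data.index)


def build_design(
    data: pd.DataFrame,
    drivers: list[str],
    standardizer: DriverStandardizer,
    model: str = "herbivore",
    habitat_reference: str = "other",
    fg_centers: dict | None = None,
) -> DesignMatrix:
    """Assemble the model matrix for the herbivore or benthic model.

    herbivore: retained drivers standardized with the stored training
    moments, plus habitat-class indicators against the "other hard bottom"
    reference.

    benthic: the 7-column herbivore block — log1p functional-group
    biomasses centered (training centers reused on grids via
    ``fg_centers``), their pairwise and triple products — plus the
    standardized non-fishing drivers. Fishing drivers are rejected here:
    fishing is hypothesized to act on the benthos only through herbivores.
    """
    missing = [c for c in drivers if c not in data.columns]
    if missing:
        raise KeyError(f"model spec refers to missing drivers: {missing}")
    blocks = []
    groups: dict[str, str] = {}

    if model == "herbivore":
        std = standardizer.transform(data)[drivers]
        blocks.append(std)
        groups.update({d: DRIVER_GROUPS.get(d, "driver") for d in drivers})
        if "habitat_class" in data.columns:
            hab = _habitat_indicators(data, habitat_reference)
            blocks.append(hab)
            groups.update({c: "habitat_class" for c in hab.columns})
        meta = {"model": "herbivore", "habitat_reference": habitat_reference}
    elif model == "benthic":
        fishing = [d for d in drivers if DRIVER_GROUPS.get(d) == "fishing"]
        if fishing:
            raise ValueError(
                f"fishing drivers not allowed in the benthic model: {fishing}"
            )
        fg_cols = [f"biomass_{g}" for g in FG_NAMES]
        miss = [c for c in fg_cols if c not in data.columns]
        if miss:
            raise KeyError(f"benthic model needs functional-group biomass: {miss}")
        logged = {g: np.log1p(data[f"biomass_{g}"].to_numpy(float))
                  for g in FG_NAMES}
        if fg_centers is None:
            fg_centers = {g: float(v.mean()) for g, v in logged.items()}
        cen = {g: logged[g] - fg_centers[g] for g in FG_NAMES}
        herb = pd.DataFrame({
            "grazer": cen["grazer"],
            "scraper": cen["scraper"],
            "browser": cen["browser"],
            "grazer:scraper": cen["grazer"] * cen["scraper"],
            "grazer:browser": cen["grazer"] * cen["browser"],
            "scraper:browser": cen["scraper"] * cen["browser"],
            "grazer:scraper:browser":
                cen["grazer"] * cen["scraper"] * cen["browser"],
        }, index=data.index)
        blocks.append(herb)
        groups.update({c: "herbivore" for c in herb.columns})
        if drivers:
            std = standardizer.transform(data)[drivers]
            blocks.append(std)
            groups.update({d: DRIVER_GROUPS.get(d, "driver") for d in drivers})
        meta = {"model": "benthic", "fg_centers": fg_centers,
                "fg_transform": "log1p, centered before interactions"}
    else:
        raise ValueError(f"unknown model spec {model!r}")

    values = pd.concat(blocks, axis=1)
    return DesignMatrix(values=values, groups=groups, meta=meta)
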