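"""Survey-record processing: from raw multi-institution fish counts to
analysis replicates.

The analysis unit is the *replicate*: all transects sharing data source,
latitude, longitude, depth and year, averaged over member transects.
Upstream of that sit inter-method count calibration, allometric
length-weight biomass (W = a·TL^b, W in grams, TL in cm), truncation of
extreme schooling counts, the survey-domain filter (hard bottom, 0-30 m,
2004-2014), and the benthic condition statistic
log((coral + CCA + delta) / (macroalgae + delta)).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._utils import quantile

HERBIVORE_GROUPS = ("grazer", "scraper", "browser")


def _require_columns(df: pd.DataFrame, cols, where: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KeyError(f"{where}: missing required columns {missing}")


def calibrate_counts(
    observations: pd.DataFrame, calibration: pd.DataFrame
) -> pd.DataFrame:
    """Multiply counts by species x method calibration factors.

    ``calibration`` needs columns species_code, method, factor. Pairs absent
    from the table keep factor 1 and a warning lists them; a negative factor
    is an error.
    """
    _require_columns(observations, ["species_code", "source_dataset", "count"],
                     "observations")
    _require_columns(calibration, ["species_code", "method", "factor"],
                     "calibration table")
    if (calibration["factor"] < 0).any():
        raise ValueError("calibration factors must be non-negative")
    obs = observations.merge(
        calibration.rename(columns={"method": "source_dataset"}),
        on=["species_code", "source_dataset"], how="left",
    )
    missing = obs["factor"].isna()
    if missing.any():
        pairs = (
            obs.loc[missing, ["species_code", "source_dataset"]]
            .drop_duplicates().itertuples(index=False)
        )
        warnings.warn(
            "no calibration factor for pairs "
            + ", ".join(f"{s}/{m}" for s, m in pairs) + "; using 1.0"
        )
    out = observations.copy()
    out["count"] = observations["count"].to_numpy() * obs["factor"].fillna(1.0).to_numpy()
    return out


def compute_biomass(
    observations: pd.DataFrame,
    allometry: pd.DataFrame,
    survey_area: float,
) -> pd.Series:
    """Per-observation biomass density count · a · TL^b / area in g m^-2.

    ``allometry`` needs columns species_code, a, b. A species absent from
    the table is an error — silently dropping records would bias biomass
    low.
    """
    if survey_area <= 0:
        raise ValueError("survey_area must be > 0")
    _require_columns(observations, ["species_code", "count", "total_length"],
                     "observations")
    _require_columns(allometry, ["species_code", "a", "b"], "allometry table")
    if (allometry["a"] <= 0).any() or (allometry["b"] <= 0).any():
        raise ValueError("allometric a and b must be > 0")
    merged = observations.merge(
        allometry[["species_code", "a", "b"]], on="species_code", how="left"
    )
    if merged["a"].isna().any():
        unknown = sorted(
            merged.loc[merged["a"].isna(), "species_code"].unique()
        )
        raise KeyError(f"no allometric parameters for species: {unknown}")
    w = merged["a"] * merged["total_length"] ** merged["b"]
    out = merged["count"] * w / survey_area
    out.index = observations.index
    return out.rename("biomass")


def truncate_schooling(
    observations: pd.DataFrame,
    species_groups: pd.DataFrame | None = None,
    flag_quantile: float = 0.999,
    truncate_quantile: float = 0.99,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-stage truncation of extreme schooling counts.

    Stage 1 flags observations whose count exceeds the upper
    ``flag_quantile`` (99.9%) of all individual counts. Stage 2: for the
    *herbivore* species appearing among flagged observations, any count
    above the ``truncate_quantile`` (99%) of all counts is set to that
    quantile. Both quantiles use the shared sort-based rule. Returns the
    adjusted table and a report of affected observations.

    ``species_groups`` (species_code, functional_group) identifies
    herbivores; without it every flagged species is treated as herbivore.
    """
    if len(observations) == 0:
        raise ValueError("truncate_schooling requires a non-empty table")
    _require_columns(observations, ["species_code", "count"], "observations")
    counts = observations["count"].to_numpy(float)
    hi = quantile(counts, flag_quantile)
    flagged = counts > hi
    flagged_species = set(observations.loc[flagged, "species_code"])

    if species_groups is not None:
        _require_columns(species_groups, ["species_code", "functional_group"],
                         "species_groups")
        herb = set(
            species_groups.loc[
                species_groups["functional_group"].isin(HERBIVORE_GROUPS),
                "species_code",
            ]
        )
        flagged_species &= herb

    q99 = quantile(counts, truncate_quantile)
    target = (
        observations["species_code"].isin(flagged_species).to_numpy()
        & (counts > q99)
    )
    out = observations.copy()
    out.loc[target, "count"] = q99
    report = observations.loc[target, ["species_code", "count"]].copy()
    report["truncated_to"] = q99
    report["flagged_at"] = hi
    return out, report.reset_index(names="row")


def filter_domain(
    transects: pd.DataFrame,
    depth_range: tuple[float, float] = (0.0, 30.0),
    year_range: tuple[int, int] = (2004, 2014),
) -> pd.DataFrame:
    """Restrict to hard-bottom habitat, 0-30 m depth and the 2004-2014
    window (pre-bleaching reef condition)."""
    _require_columns(transects, ["hardbottom_flag", "depth", "year"], "transects")
    keep = (
        transects["hardbottom_flag"].astype(bool)
        & transects["depth"].between(*depth_range)
        & transects["year"].between(*year_range)
    )
    return transects.loc[keep].reset_index(drop=True)


REPLICATE_KEY = ["source_dataset", "latitude", "longitude", "depth", "year"]


def aggregate_replicates(
    transects: pd.DataFrame, coord_precision: int = 5
) -> pd.DataFrame:
    """Average transects into replicates keyed by
    (source, lat, lon, depth, year).

    Coordinates are rounded to ``coord_precision`` decimals before
    grouping (multi-source coordinates differ in recorded precision);
    numeric metrics take unweighted means over member transects,
    non-numeric metadata the first value.
    """
    _require_columns(transects, REPLICATE_KEY, "transects")
    df = transects.copy()
    for c in ("latitude", "longitude"):
        df[c] = df[c].round(coord_precision)
    num = [c for c in df.columns
           if c not in REPLICATE_KEY and pd.api.types.is_numeric_dtype(df[c])]
    other = [c for c in df.columns if c not in REPLICATE_KEY and c not in num]
    agg = {**{c: "mean" for c in num}, **{c: "first" for c in other}}
    out = df.groupby(REPLICATE_KEY, as_index=False, sort=True).agg(agg)
    out["n_transects"] = (
        df.groupby(REPLICATE_KEY, sort=True).size().to_numpy()
    )
    return out


def subsample_site(
    replicates: pd.DataFrame,
    site_label: str,
    keep_year: int,
    site_column: str = "site",
    center: tuple[float, float] | None = None,
    radius_km: float = 2.5,
) -> pd.DataFrame:
    """Keep only ``keep_year`` data at one heavily monitored site.

    Membership comes from an explicit site-label column when present, else
    from a radius rule around ``center`` (lat, lon; default radius 2.5 km).
    Replicates away from the site are untouched. If the site has no data in
    ``keep_year`` it is removed entirely, with a warning.
    """
    if site_column in replicates.columns:
        at_site = replicates[site_column] == site_label
        if not at_site.any() and center is None:
            raise ValueError(f"unknown site label {site_label!r}")
    elif center is not None:
        lat0, lon0 = center
        dlat = (replicates["latitude"] - lat0) * 111.32
        dlon = (replicates["longitude"] - lon0) * 111.32 * np.cos(np.deg2rad(lat0))
        at_site = np.hypot(dlat, dlon) <= radius_km
    else:
        raise ValueError(
            f"cannot resolve site {site_label!r}: no site column and no center"
        )
    keep = ~at_site | (replicates["year"] == keep_year)
    if at_site.any() and not (at_site & (replicates["year"] == keep_year)).any():
        warnings.warn(
            f"site {site_label!r} has no data in {keep_year}; removed entirely"
        )
    return replicates.loc[keep].reset_index(drop=True)


def drop_sparse_moku(replicates: pd.DataFrame, min_n: int = 5) -> pd.DataFrame:
    """Remove moku represented by fewer than ``min_n`` replicates."""
    _require_columns(replicates, ["moku_id"], "replicates")
    sizes = replicates.groupby("moku_id")["moku_id"].transform("size")
    out = replicates.loc[sizes >= min_n].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn("all moku are sparse; returning empty table")
    return out


def assign_functional_groups(
    species_codes, table: pd.DataFrame
) -> pd.Series:
    """Map species codes to {grazer, scraper, browser, other}.

    Herbivores must be mapped in ``table`` (species_code,
    functional_group); a code absent from the table is treated as
    non-herbivore 'other' only if the table carries an explicit
    ``herbivore`` flag saying so — otherwise unknown codes are an error.
    """
    _require_columns(table, ["species_code", "functional_group"], "species table")
    lookup = table.set_index("species_code")["functional_group"]
    codes = pd.Series(species_codes, name="species_code")
    mapped = codes.map(lookup)
    unknown = mapped.isna()
    if unknown.any():
        raise KeyError(
            "species without functional-group assignment: "
            f"{sorted(codes[unknown].unique())}"
        )
    bad = ~mapped.isin(HERBIVORE_GROUPS + ("other",))
    if bad.any():
        raise ValueError(
            f"unrecognized functional groups: {sorted(mapped[bad].unique())}"
        )
    return mapped.rename("functional_group")


def benthic_condition(coral, cca, macroalgae, floor: float = 0.1):
    """Benthic condition log-ratio of calcified to macroalgal cover.

    log((coral + cca + floor) / (macroalgae + floor)), covers in percent.
    Positive values mean calcifier-dominated benthos, negative
    macroalgae-dominated. The floor (default 0.1 % cover, added to both
    sides) keeps the statistic defined at zero cover and preserves the
    sign symmetry under swapping calcified and macroalgal cover.
    """
    coral = np.asarray(coral, dtype=float)
    cca = np.asarray(cca, dtype=float)
    macroalgae = np.asarray(macroalgae, dtype=float)
    for name, v in (("coral", coral), ("cca", cca), ("macroalgae", macroalgae)):
        if np.any((v < 0) | (v > 100)):
            raise ValueError(f"{name} cover must be in [0, 100]")
    if floor <= 0:
        raise ValueError("floor must be > 0")
    out = np.log((coral + cca + floor) / (macroalgae + floor))
    return out if out.ndim else float(out)
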