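"""Post-stratified prediction summaries over the 100 m grid.

Survey effort is unbalanced across habitats, so area-level biomass
estimates come from the prediction grid instead: every hard-bottom pixel
gets equal weight, and an area's posterior is the concatenation of its
member pixels' posterior draws. Summaries are the pooled mean and the
central 50% interval (25th-75th percentile, shared sort-based quantile
rule), plus quartile ranks across areas and comparisons against a
reference posterior (e.g. no-take reserves).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def mask_softbottom(grid: pd.DataFrame) -> pd.DataFrame:
    """Drop pixels dominated by soft bottom (survey domain is hard bottom)."""
    if "hardbottom_flag" not in grid.columns:
        raise KeyError("grid has no 'hardbottom_flag' column")
    out = grid[grid["hardbottom_flag"].astype(bool)].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn("no hard-bottom pixels remain")
    return out


def poststratify_area(
    pixel_draws: np.ndarray, area_ids, min_pixels: int = 1
) -> pd.DataFrame:
    """Pool member-pixel posteriors into one posterior per area.

    ``pixel_draws`` is (n_draws, n_pixels); ``area_ids`` labels each pixel
    (NaN/None = outside every area, skipped with a warning). Every pixel
    contributes all its draws with equal weight. Returns one row per area
    with the pooled mean, 50% interval bounds and pixel count.
    """
    pixel_draws = np.asarray(pixel_draws, float)
    if pixel_draws.ndim != 2:
        raise ValueError("pixel_draws must be (n_draws, n_pixels)")
    area_ids = pd.Series(list(area_ids))
    if len(area_ids) != pixel_draws.shape[1]:
        raise ValueError("area_ids must label every pixel")
    outside = area_ids.isna()
    if outside.any():
        warnings.warn(f"{int(outside.sum())} pixels outside all areas skipped")
    rows = []
    for area, members in area_ids[~outside].groupby(area_ids[~outside]):
        cols = members.index.to_numpy()
        if len(cols) < min_pixels:
            warnings.warn(f"area {area!r} has too few pixels; skipped")
            continue
        pooled = pixel_draws[:, cols].ravel()
        lo, hi = np.quantile(pooled, [0.25, 0.75])
        rows.append({
            "area_id": area, "mean": float(pooled.mean()),
            "q25": float(lo), "q75": float(hi), "n_pixels": len(cols),
        })
    return pd.DataFrame(rows, columns=["area_id", "mean", "q25", "q75", "n_pixels"])


def rank_areas(
    summaries: pd.DataFrame, reference_draws: np.ndarray | None = None
) -> pd.DataFrame:
    """Label areas by quartile of pooled mean; optionally compare each
    area's 50% interval against a reference posterior's.

    An area is below the reference when its 50% interval lies entirely
    below the reference's 50% interval (no overlap).
    """
    if len(summaries) < 4:
        raise ValueError("quartile ranking needs at least 4 areas")
    out = summaries.copy()
    out["quartile"] = pd.qcut(
        summaries["mean"].rank(method="first"), 4,
        labels=["Q1", "Q2", "Q3", "Q4"],
    )
    if reference_draws is not None:
        ref_lo, ref_hi = np.quantile(np.asarray(reference_draws, float).ravel(),
                                     [0.25, 0.75])
        out["below_reference"] = out["q75"] < ref_lo
        out.attrs["reference_interval"] = (float(ref_lo), float(ref_hi))
    return out
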