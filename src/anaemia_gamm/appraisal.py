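"""District performance appraisal from BLUPs of the district random effect.

The fitted district random effects are best linear unbiased predictions
(BLUPs) of each district's deviation, on the log-odds scale, after adjusting
for the child-, household- and cluster-level covariates and the spatial
surface.  A negative BLUP marks a district associated with decreased odds of
anaemia (a well performing district), a positive BLUP with increased odds.
Districts are standardized, ranked (rank 1 = lowest standardized BLUP =
best performing) and the top-k best and worst districts selected per country.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .gamm import FitResult

__all__ = ["extract_blups", "standardize_blups", "rank_districts", "appraise"]


def extract_blups(fit: FitResult, districts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-district BLUP and prediction SE from a converged fit.

    Districts observed in the data receive one row each; districts with more
    children shrink less toward zero.  If the district variance was estimated
    at the zero boundary all BLUPs are exactly zero (with a warning), since
    the model then carries no evidence of district heterogeneity.

    ``districts`` optionally maps ``district_id`` to ``country`` (and any
    other metadata) to join onto the table.
    """
    if len(fit.district_ids) == 0:
        raise ValueError("fit contains no district random effect")
    if fit.theta.get("district", 0.0) == 0.0:
        warnings.warn("district variance at zero boundary: all BLUPs are 0")
    out = fit.district_table()
    if districts is not None:
        out = out.merge(districts, on="district_id", how="left")
    return out


def standardize_blups(blups: pd.DataFrame, mode: str = "se") -> pd.DataFrame:
    """Standardize district BLUPs for ranking.

    ``mode='se'`` (default) divides each BLUP by its own prediction SE, a
    conditional z-like score that accounts for how precisely each district is
    estimated.  ``mode='zscore'`` centres and scales across districts, which
    ignores per-district precision and can reorder districts; it raises when
    the BLUPs have zero spread.  Signs are preserved either way.
    """
    if len(blups) < 2:
        raise ValueError("standardization needs >= 2 districts")
    out = blups.copy()
    if mode == "se":
        se = out["prediction_se"].to_numpy(dtype=float)
        if np.any(se <= 0):
            raise ValueError("zero prediction SE; cannot standardize by SE")
        out["standardized_blup"] = out["blup"].to_numpy(dtype=float) / se
    elif mode == "zscore":
        vals = out["blup"].to_numpy(dtype=float)
        sd = vals.std(ddof=1)
        if sd == 0:
            raise ValueError("all BLUPs equal; z-score standardization undefined")
        out["standardized_blup"] = (vals - vals.mean()) / sd
    else:
        raise ValueError("mode must be 'se' or 'zscore'")
    return out


def rank_districts(appraisal: pd.DataFrame, k: int = 3,
                   within: str = "country") -> pd.DataFrame:
    """Rank standardized BLUPs ascending and flag top-k best/worst districts.

    Rank 1 is the lowest standardized BLUP (best performing).  Ties break by
    district identifier so the selection is deterministic.  ``within`` groups
    ranking per country (default) or pools all districts (``'global'``).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if "standardized_blup" not in appraisal.columns:
        raise ValueError("run standardize_blups first")
    out = appraisal.copy()
    if within == "country":
        if "country" not in out.columns:
            raise ValueError("per-country ranking needs a 'country' column")
        groups = [g for _, g in out.groupby("country", sort=True)]
    elif within == "global":
        groups = [out]
    else:
        raise ValueError("within must be 'country' or 'global'")
    ranked = []
    for g in groups:
        if k > len(g):
            where = g["country"].iloc[0] if within == "country" else "pooled"
            raise ValueError(f"k={k} exceeds {len(g)} districts in {where!r}")
        g = g.sort_values(["standardized_blup", "district_id"],
                          kind="mergesort").reset_index(drop=True)
        g["rank_within_country" if within == "country" else "rank"] = \
            np.arange(1, len(g) + 1)
        n = len(g)
        g["flag"] = ""
        g.loc[:k - 1, "flag"] = "best"
        g.loc[n - k:, "flag"] = "worst"
        ranked.append(g)
    return pd.concat(ranked, ignore_index=True)


def appraise(fit: FitResult, districts: pd.DataFrame | None = None,
             k: int = 3, mode: str = "se", within: str = "country") -> pd.DataFrame:
    """Extract, standardize and rank in one call; returns the league table."""
    table = extract_blups(fit, districts)
    table = standardize_blups(table, mode=mode)
    return rank_districts(table, k=k, within=within)
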