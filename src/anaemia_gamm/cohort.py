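"""Child-level analysis records: outcome construction, design encoding, screening.

The analysis record is one child aged 6-59 months from a two-stage cluster
household survey, nested as child (k) within household (j) within cluster (i)
within district (h).  The binary outcome is anaemia: altitude-adjusted
haemoglobin below 11 g/dl (WHO definition for this age group).  Categorical
covariates are dummy-coded against fixed reference levels (male, RDT negative,
urban, no education, male household head, no toilet facilities, Malawi), and
candidate covariates can be screened by univariate logistic models at a 10%
significance level before model fitting, with all two-way interactions of the
retained fixed effects explored by likelihood-ratio tests.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import sparse, stats

log = logging.getLogger(__name__)

__all__ = [
    "CATEGORY_LEVELS",
    "ModelSpec",
    "DesignMatrices",
    "adjust_hb_for_altitude",
    "classify_anaemia",
    "derive_outcome",
    "validate_records",
    "load_records",
    "encode_design",
    "univariate_screen",
    "screen_covariates",
    "screen_interactions",
]

# Closed categorical sets; the first level of each is the reference.
CATEGORY_LEVELS: dict[str, list[str]] = {
    "gender": ["male", "female"],
    "rdt_result": ["negative", "positive"],
    "residence": ["urban", "rural"],
    "education": ["none", "primary", "secondary_higher", "unknown"],
    "head_gender": ["male", "female"],
    "toilet": ["none", "pit_latrine", "flush", "other"],
    "country": ["Malawi", "Kenya", "Tanzania", "Uganda"],
}

# Continuous covariates entered linearly, with the reporting rescale applied
# at encoding time (altitude per 100 m, EVI per 1000 units).
CONTINUOUS_SCALES: dict[str, float] = {
    "household_size": 1.0,
    "wealth_z": 1.0,
    "altitude": 0.01,
    "evi": 0.001,
    "lst": 1.0,
    "head_age": 1.0,
    "age_months": 1.0,
}

_FT_PER_M = 0.0032808399


def adjust_hb_for_altitude(hb, altitude):
    """Altitude-adjusted haemoglobin (g/dl).

    Applies the CDC piecewise correction used in DHS anaemia reporting:
    no correction at or below 1000 m; above that the correction is
    ``-0.032 * A + 0.022 * A**2`` g/dl with ``A`` the altitude in thousands of
    feet, which is positive and increasing over the applied range.  The
    correction is subtracted from the measured Hb.
    """
    hb = np.asarray(hb, dtype=float)
    altitude = np.asarray(altitude, dtype=float)
    if np.any(~np.isfinite(hb)) or np.any(hb <= 0):
        raise ValueError("hb must be positive and finite (g/dl)")
    if np.any(~np.isfinite(altitude)):
        raise ValueError("altitude must be finite (metres)")
    A = altitude * _FT_PER_M  # thousands of feet
    corr = np.where(altitude > 1000.0, np.maximum(0.0, -0.032 * A + 0.022 * A**2), 0.0)
    out = hb - corr
    return float(out) if out.ndim == 0 else out


def classify_anaemia(adjusted_hb):
    """1 if altitude-adjusted Hb < 11 g/dl (anaemic), else 0.  Strict inequality."""
    adjusted_hb = np.asarray(adjusted_hb, dtype=float)
    if np.any(~np.isfinite(adjusted_hb)):
        raise ValueError("adjusted_hb must be finite")
    out = (adjusted_hb < 11.0).astype(int)
    return int(out) if out.ndim == 0 else out


def derive_outcome(records: pd.DataFrame) -> pd.DataFrame:
    """Fill the binary outcome ``y`` from Hb and altitude where not already set."""
    records = records.copy()
    if "y" not in records.columns:
        if "hb" not in records.columns:
            raise ValueError("records need either a 'y' or an 'hb' column")
        adj = adjust_hb_for_altitude(records["hb"].to_numpy(),
                                     records["altitude"].to_numpy())
        records["y"] = classify_anaemia(adj)
    return records


REQUIRED_COLUMNS = [
    "y", "age_months", "household_size", "wealth_z", "altitude", "evi", "lst",
    "head_age", "lon", "lat", "district_id", "cluster_id", "household_id",
    "child_id", *CATEGORY_LEVELS,
]


def validate_records(records: pd.DataFrame) -> dict:
    """Validate a child table against the closed schema.

    Raises on unknown categorical levels or out-of-range values; returns a
    small report (row count, prevalence) suitable for JSON serialization.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    for col, levels in CATEGORY_LEVELS.items():
        bad = ~records[col].isin(levels)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"unknown level {records[col].iloc[row]!r} in column {col!r} at row {row}"
            )
    y = records["y"].to_numpy()
    if not np.isin(y, [0, 1]).all():
        raise ValueError("outcome y must be 0/1")
    age = records["age_months"].to_numpy()
    if age.min() < 6 or age.max() > 59:
        raise ValueError("age_months must lie in [6, 59]")
    if (records["household_size"].to_numpy() < 1).any():
        raise ValueError("household_size must be >= 1")
    return {
        "n_records": int(len(records)),
        "n_districts": int(records["district_id"].nunique()),
        "n_clusters": int(records["cluster_id"].nunique()),
        "prevalence": float(y.mean()),
    }


def load_records(path, validate: bool = True,
                 report_path=None) -> pd.DataFrame:
    """Read a child table from CSV, derive the outcome, and validate."""
    records = derive_outcome(pd.read_csv(path))
    if validate:
        report = validate_records(records)
        if report_path is not None:
            with open(report_path, "w") as fh:
                json.dump(report, fh, indent=2)
    return records


@dataclass
class ModelSpec:
    """Terms of the additive model: linear fixed effects, smooths, interactions.

    ``linear`` mixes categorical and continuous names; ``smooth`` names
    covariates modelled by 1-D P-splines; ``interactions`` are pairs of
    categorical fixed effects; ``spatial`` switches the tensor-product
    cluster-coordinate smooth; ``district_effect`` the i.i.d. district
    random intercept.
    """

    linear: list[str] = field(default_factory=lambda: [
        "gender", "rdt_result", "household_size", "residence", "education",
        "head_gender", "toilet", "wealth_z", "country", "altitude", "evi", "lst",
    ])
    smooth: list[str] = field(default_factory=lambda: ["age_months"])
    interactions: list[tuple[str, str]] = field(
        default_factory=lambda: [("residence", "country")])
    spatial: bool = True
    district_effect: bool = True
    n_segments: int = 20
    degree: int = 3
    penalty_order: int = 2
    spatial_segments: int = 17
    knot_convention: str = "segments"

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        if "interactions" in d:
            d["interactions"] = [tuple(p) for p in d["interactions"]]
        return cls(**d)


@dataclass
class DesignMatrices:
    """Fixed-effect design, district indicators and raw smooth inputs."""

    X: np.ndarray
    columns: list[str]
    Z_district: sparse.csr_matrix
    district_ids: list
    smooth_inputs: dict[str, np.ndarray]
    column_map: dict[str, tuple[str, str | None, str | None]]


def _dummy_columns(records: pd.DataFrame, var: str):
    levels = CATEGORY_LEVELS[var]
    ref = levels[0]
    cols, names = [], []
    for lev in levels[1:]:
        cols.append((records[var] == lev).to_numpy(dtype=float))
        names.append(f"{var}[{lev}]")
    return cols, names, ref


def encode_design(records: pd.DataFrame, model_spec: ModelSpec) -> DesignMatrices:
    """Dummy-code the fixed effects with the study's reference levels.

    Categorical terms are coded against their reference (first level of the
    closed set); interaction columns are products of the non-reference
    dummies; continuous terms are rescaled per ``CONTINUOUS_SCALES``.  Smooth
    inputs are returned raw, uncoded.
    """
    for var in set(model_spec.linear) | {v for p in model_spec.interactions for v in p}:
        if var in CATEGORY_LEVELS:
            bad = ~records[var].isin(CATEGORY_LEVELS[var])
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"unknown level {records[var].iloc[row]!r} in column "
                    f"{var!r} at row {row}")
    n = len(records)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    column_map: dict[str, tuple[str, str | None, str | None]] = {
        "intercept": ("intercept", None, None)}
    for var in model_spec.linear:
        if var in CATEGORY_LEVELS:
            ccols, cnames, ref = _dummy_columns(records, var)
            cols += ccols
            names += cnames
            for nm, lev in zip(cnames, CATEGORY_LEVELS[var][1:]):
                column_map[nm] = (var, lev, ref)
        else:
            scale = CONTINUOUS_SCALES.get(var, 1.0)
            cols.append(records[var].to_numpy(dtype=float) * scale)
            names.append(var)
            column_map[var] = (var, None, None)
    for va, vb in model_spec.interactions:
        acols, anames, aref = _dummy_columns(records, va)
        bcols, bnames, bref = _dummy_columns(records, vb)
        for ca, na in zip(acols, anames):
            for cb, nb in zip(bcols, bnames):
                nm = f"{na}:{nb}"
                cols.append(ca * cb)
                names.append(nm)
                column_map[nm] = (f"{va}:{vb}", f"{na}:{nb}", f"{aref}:{bref}")
    X = np.column_stack(cols)

    districts = pd.Categorical(records["district_id"])
    district_ids = list(districts.categories)
    Z = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), districts.codes)),
        shape=(n, len(district_ids)))

    smooth_inputs = {v: records[v].to_numpy(dtype=float) for v in model_spec.smooth}
    smooth_inputs["lon"] = records["lon"].to_numpy(dtype=float)
    smooth_inputs["lat"] = records["lat"].to_numpy(dtype=float)
    return DesignMatrices(X=X, columns=names, Z_district=Z,
                          district_ids=district_ids,
                          smooth_inputs=smooth_inputs, column_map=column_map)


def _single_term_design(records: pd.DataFrame, var: str) -> np.ndarray:
    if var in CATEGORY_LEVELS:
        ccols, _, _ = _dummy_columns(records, var)
        return np.column_stack(ccols)
    return records[var].to_numpy(dtype=float)[:, None] * CONTINUOUS_SCALES.get(var, 1.0)


def univariate_screen(records: pd.DataFrame, candidate_variable: str,
                      alpha: float = 0.10, test: str = "lr"):
    """Single-covariate logistic screen.

    Fits ``y ~ 1 + variable`` and returns ``(p_value, keep)`` with
    ``keep = p < alpha``.  ``test='lr'`` uses the likelihood-ratio test
    against the intercept-only model (the only option that covers multi-level
    categoricals); ``test='wald'`` is available for single-column terms.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    y = records["y"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome is constant; screening model inestimable")
    Xc = _single_term_design(records, candidate_variable)
    X = sm.add_constant(Xc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        if test == "lr":
            null = sm.GLM(y, np.ones((len(y), 1)),
                          family=sm.families.Binomial()).fit()
            lr = 2 * (fit.llf - null.llf)
            p = float(stats.chi2.sf(max(lr, 0.0), Xc.shape[1]))
        elif test == "wald":
            if Xc.shape[1] != 1:
                raise ValueError("Wald screen applies to single-column terms")
            p = float(fit.pvalues[1])
        else:
            raise ValueError("test must be 'lr' or 'wald'")
    return p, bool(p < alpha)


def screen_covariates(records: pd.DataFrame, candidates: list[str],
                      alpha: float = 0.10, test: str = "lr") -> pd.DataFrame:
    """Univariate screen over a candidate list; returns a tidy decision table."""
    rows = []
    for var in candidates:
        p, keep = univariate_screen(records, var, alpha=alpha, test=test)
        rows.append({"variable": var, "p_value": p, "keep": keep})
    return pd.DataFrame(rows)


def screen_interactions(records: pd.DataFrame, fixed_terms: list[str],
                        alpha: float = 0.05) -> list[tuple[str, str, float]]:
    """Likelihood-ratio screen of all two-way interactions among fixed effects.

    For each pair the main-effects logistic model is compared with the model
    augmented by that pair's interaction columns; pairs with LR p < alpha are
    returned.  Inestimable augmented models (separation, perfect collinearity)
    are skipped with a warning.
    """
    if len(fixed_terms) < 2:
        return []
    y = records["y"].to_numpy(dtype=float)
    blocks = {v: _single_term_design(records, v) for v in fixed_terms}
    X_main = sm.add_constant(np.column_stack([blocks[v] for v in fixed_terms]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        main_fit = sm.GLM(y, X_main, family=sm.families.Binomial()).fit()
        out = []
        for va, vb in itertools.combinations(fixed_terms, 2):
            inter = np.column_stack([
                blocks[va][:, i] * blocks[vb][:, j]
                for i in range(blocks[va].shape[1])
                for j in range(blocks[vb].shape[1])])
            X_aug = np.column_stack([X_main, inter])
            try:
                aug_fit = sm.GLM(y, X_aug, family=sm.families.Binomial()).fit()
                lr = 2 * (aug_fit.llf - main_fit.llf)
                p = float(stats.chi2.sf(max(lr, 0.0), inter.shape[1]))
            except Exception as exc:  # separation / singular augmented design
                log.warning("interaction %s x %s skipped: %s", va, vb, exc)
                continue
            if not np.isfinite(p):
                log.warning("interaction %s x %s skipped: non-finite p", va, vb)
                continue
            if p < alpha:
                out.append((va, vb, p))
    return out
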