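"""Geoadditive logistic mixed model fitting.

The model for child ``k`` in household ``j``, cluster ``i``, district ``h`` is

    logit P(y_hijk = 1) = x'_hijk beta + U_h + f_age(age_hijk) + f_spat(lon_i, lat_i)

with linear fixed effects ``beta``, an i.i.d. district random intercept
``U_h ~ N(0, sigma2_U)``, a 1-D P-spline age smooth and a tensor-product
P-spline spatial surface.  After the mixed-model reparameterization of the
smooths, every penalized block is a random-effect block with variance
``tau^2 = 1/lambda``, and the whole model is a generalized linear mixed model
fitted by

* an inner loop of penalized iteratively weighted least squares (IWLS) on the
  working response, for the coefficients at fixed variance components, and
* an outer restricted maximum likelihood (REML) update of the variance
  components from the working linear mixed model, using Schall's fixed-point
  iteration (whose stationary point solves the working-model REML score
  equations); a direct numerical optimization of the working REML criterion
  is available as an alternative.

Variance components may hit the zero boundary and are then reported as 0.
The empirical-Bayes coefficient covariance is the inverse of the penalized
information matrix, which also supplies prediction standard errors for the
district BLUPs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import linalg, optimize, sparse
from scipy.special import expit

from . import cohort, splines
from .cohort import DesignMatrices, ModelSpec
from .splines import ReparamTerm, SplineTerm, TensorSpatialTerm

log = logging.getLogger(__name__)

Z975 = 1.959963984540054

__all__ = [
    "Tolerances",
    "ModelState",
    "FitResult",
    "assemble_model",
    "piwls_step",
    "reml_update",
    "fit",
    "residence_country_cells",
]


@dataclass
class Tolerances:
    inner_tol: float = 1e-6     # relative coefficient change, PIWLS
    outer_tol: float = 1e-5     # relative change in variance components
    max_inner: int = 200
    max_outer: int = 50
    prob_clip: float = 1e-10    # fitted-probability clipping for weights
    theta_floor: float = 1e-8   # variance floor; at-floor components report 0
    separation_bound: float = 30.0


@dataclass
class TermInfo:
    """Bookkeeping for one penalized smooth inside the assembled model."""

    name: str
    spline: SplineTerm | TensorSpatialTerm
    reparam: ReparamTerm
    null_idx: np.ndarray        # indices of null-space columns in the full design
    pen_slice: slice            # penalized columns in the full design
    obs_mean_row: np.ndarray    # mean evaluation row over observed data (centering)

    def eval_rows(self, *args) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(self.spline, TensorSpatialTerm):
            B = self.spline.basis(*args)
        else:
            B = self.spline.basis(args[0])
        return self.reparam.transform(B)


@dataclass
class ModelState:
    """Assembled design: dense fixed + smooth block, sparse district indicators.

    The full coefficient vector is ``[fixed (p_fixed) | smooth penalized
    columns | district effects]``; ``blocks`` maps each penalized/random
    block name to its slice of that vector.  The reparameterized smooth
    columns are dense (eigenvector mixing of the basis), so they live with
    the fixed columns in one dense matrix ``M`` handled by BLAS; the district
    indicator block stays sparse.
    """

    y: np.ndarray
    M: np.ndarray                   # n x (p_fixed + q_smooth), dense
    Zd: sparse.csr_matrix | None    # n x n_districts indicator block, or None
    columns: list[str]              # fixed-effect column names (incl. smooth null cols)
    p_fixed: int
    blocks: dict[str, slice]        # penalized/random blocks by name (full-vector slices)
    terms: dict[str, TermInfo]
    district_ids: list
    column_map: dict
    family: str = "binomial"

    @property
    def n_obs(self) -> int:
        return self.M.shape[0]

    @property
    def n_coef(self) -> int:
        return self.M.shape[1] + (self.Zd.shape[1] if self.Zd is not None else 0)

    def linpred(self, delta: np.ndarray) -> np.ndarray:
        m = self.M.shape[1]
        eta = self.M @ delta[:m]
        if self.Zd is not None:
            eta = eta + self.Zd @ delta[m:]
        return eta

    def penalty_diag(self, theta: Mapping[str, float]) -> np.ndarray:
        d = np.zeros(self.n_coef)
        for name, sl in self.blocks.items():
            d[sl] = 1.0 / theta[name]
        return d


def _find_collinear(X: np.ndarray, columns: list[str]) -> list[str]:
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [columns[piv[i]] for i in range(len(diag)) if diag[i] < tol]


def assemble_model(design: DesignMatrices, model_spec: ModelSpec,
                   family: str = "binomial", y: np.ndarray | None = None,
                   ) -> ModelState:
    """Assemble the full design: fixed block, smooth blocks, district block.

    Unpenalized null-space columns of each smooth (e.g. the linear trend of a
    second-order-penalty age smooth) are absorbed into the fixed-effect block;
    the constant direction of every smooth is dropped against the intercept.
    Raises if the combined fixed design is rank deficient, naming the
    collinear columns.
    """
    X = design.X
    columns = list(design.columns)
    terms: dict[str, TermInfo] = {}
    pen_blocks: list[tuple[str, np.ndarray]] = []

    for var in model_spec.smooth:
        vals = design.smooth_inputs[var]
        st = SplineTerm.from_data(var, vals, n_segments=model_spec.n_segments,
                                  degree=model_spec.degree,
                                  order=model_spec.penalty_order,
                                  knot_convention=model_spec.knot_convention)
        rp = splines.reparameterize(st.penalty(), name=var)
        B = st.basis(vals)
        null_cols, pen_cols = rp.transform(B)
        null_idx = []
        for j in range(null_cols.shape[1]):
            columns.append(f"{var}_poly{j + 1}")
            null_idx.append(X.shape[1] + j)
        X = np.column_stack([X, null_cols]) if null_cols.shape[1] else X
        obs_mean = np.concatenate([null_cols.mean(axis=0), pen_cols.mean(axis=0)])
        terms[var] = TermInfo(name=var, spline=st, reparam=rp,
                              null_idx=np.array(null_idx, dtype=int),
                              pen_slice=slice(0, 0), obs_mean_row=obs_mean)
        pen_blocks.append((var, pen_cols))

    if model_spec.spatial:
        ts = TensorSpatialTerm.from_data(design.smooth_inputs["lon"],
                                         design.smooth_inputs["lat"],
                                         n_segments=model_spec.spatial_segments,
                                         degree=model_spec.degree)
        rp = splines.reparameterize(ts.penalty(), name="spatial")
        B = ts.basis(design.smooth_inputs["lon"], design.smooth_inputs["lat"])
        null_cols, pen_cols = rp.transform(B)  # null space = constant only -> empty
        obs_mean = np.concatenate([null_cols.mean(axis=0), pen_cols.mean(axis=0)])
        terms["spatial"] = TermInfo(name="spatial", spline=ts, reparam=rp,
                                    null_idx=np.array([], dtype=int),
                                    pen_slice=slice(0, 0), obs_mean_row=obs_mean)
        pen_blocks.append(("spatial", pen_cols))

    bad = _find_collinear(X, columns)
    if bad:
        raise ValueError(f"fixed design is rank deficient; collinear columns: {bad}")

    p = X.shape[1]
    dense_parts = [X]
    blocks: dict[str, slice] = {}
    start = p
    for name, cols in pen_blocks:
        q = cols.shape[1]
        blocks[name] = slice(start, start + q)
        if name in terms:
            terms[name].pen_slice = blocks[name]
        dense_parts.append(cols)
        start += q

    district_ids: list = []
    Zd = None
    if model_spec.district_effect:
        Zd = design.Z_district.tocsr()
        if Zd.shape[1] < 2:
            raise ValueError("district random effect needs >= 2 districts")
        blocks["district"] = slice(start, start + Zd.shape[1])
        district_ids = list(design.district_ids)
        start += Zd.shape[1]

    M = np.ascontiguousarray(np.column_stack(dense_parts)
                             if len(dense_parts) > 1 else X)
    return ModelState(y=np.asarray(y, dtype=float) if y is not None else None,
                      M=M, Zd=Zd, columns=columns, p_fixed=p,
                      blocks=blocks, terms=terms, district_ids=district_ids,
                      column_map=dict(design.column_map), family=family)


def _working(state: ModelState, delta: np.ndarray, tol: Tolerances, phi: float):
    """Working response and weights at the current coefficients."""
    eta = state.linpred(delta)
    if state.family == "binomial":
        mu = expit(eta)
        clipped = (mu < tol.prob_clip) | (mu > 1 - tol.prob_clip)
        if clipped.any():
            log.debug("clipped %d fitted probabilities", int(clipped.sum()))
            mu = np.clip(mu, tol.prob_clip, 1 - tol.prob_clip)
        w = mu * (1.0 - mu)
        z = eta + (state.y - mu) / w
    else:
        w = np.full(state.n_obs, 1.0)
        z = state.y
    return eta, w / phi, z


def _deviance(state: ModelState, delta: np.ndarray, phi: float) -> float:
    eta = state.linpred(delta)
    if state.family == "binomial":
        # -2 loglik up to a data-only constant, numerically safe form
        return float(2.0 * np.sum(np.logaddexp(0.0, eta) - state.y * eta))
    return float(np.sum((state.y - eta) ** 2) / phi)


def _pen_deviance(state: ModelState, delta: np.ndarray,
                  theta: Mapping[str, float], phi: float) -> float:
    pen = sum(float(delta[sl] @ delta[sl]) / theta[name]
              for name, sl in state.blocks.items())
    return _deviance(state, delta, phi) + pen


def _normal_equations(state: ModelState, w: np.ndarray, z: np.ndarray,
                      theta: Mapping[str, float]):
    """Penalized weighted normal equations ``A delta = rhs``.

    The dense block uses BLAS; the district indicator block contributes a
    diagonal and one sparse-times-dense cross product.
    """
    M = state.M
    m = M.shape[1]
    wz = w * z
    A = np.zeros((state.n_coef, state.n_coef))
    Mw = M * w[:, None]
    A[:m, :m] = M.T @ Mw
    rhs = np.zeros(state.n_coef)
    rhs[:m] = M.T @ wz
    if state.Zd is not None:
        ZtMw = state.Zd.T @ Mw            # n_districts x m
        A[m:, :m] = ZtMw
        A[:m, m:] = ZtMw.T
        A[m:, m:] = np.diag(np.asarray(state.Zd.T @ w).ravel())
        rhs[m:] = np.asarray(state.Zd.T @ wz).ravel()
    A[np.diag_indices_from(A)] += state.penalty_diag(theta)
    return A, rhs


def piwls_step(state: ModelState, theta: Mapping[str, float],
               delta: np.ndarray | None = None,
               tolerances: Tolerances | None = None,
               phi: float = 1.0) -> np.ndarray:
    """One penalized IWLS update: a weighted penalized least-squares solve on
    the working response, with step-halving toward the previous coefficients
    if the penalized deviance would increase."""
    tol = tolerances or Tolerances()
    if delta is None:
        delta = np.zeros(state.n_coef)
    _, w, z = _working(state, delta, tol, phi)
    A, rhs = _normal_equations(state, w, z, theta)
    new = linalg.cho_solve(linalg.cho_factor(A, lower=True), rhs)
    if state.family == "binomial":
        old_pd = _pen_deviance(state, delta, theta, phi)
        step = 1.0
        cand = new
        for _ in range(30):
            if _pen_deviance(state, cand, theta, phi) <= old_pd + 1e-12:
                break
            step *= 0.5
            cand = delta + step * (new - delta)
        new = cand
    return new


def _piwls_converge(state: ModelState, theta, delta, tol: Tolerances, phi: float):
    """Inner loop to convergence; returns (delta, A, w, z, n_iter, converged)."""
    if delta is None:
        delta = np.zeros(state.n_coef)
    n_iter = 0
    converged = False
    for n_iter in range(1, tol.max_inner + 1):
        new = piwls_step(state, theta, delta, tol, phi)
        rel = np.max(np.abs(new - delta)) / max(1.0, np.max(np.abs(new)))
        delta = new
        if rel < tol.inner_tol:
            converged = True
            break
        if state.family == "gaussian":
            converged = True
            break  # linear model: one solve is exact
    _, w, z = _working(state, delta, tol, phi)
    A, _ = _normal_equations(state, w, z, theta)
    return delta, A, w, z, n_iter, converged


def reml_update(state: ModelState, theta: Mapping[str, float],
                delta: np.ndarray, A: np.ndarray,
                tolerances: Tolerances | None = None,
                phi: float = 1.0) -> tuple[dict, float]:
    """One REML (Schall) update of the variance components.

    For each block ``r`` with current variance ``theta_r`` the update is
    ``theta_r <- b_r' b_r / (q_r - tr(A^{-1})_rr / theta_r)``, the fixed point
    of the working-model REML score equations.  For a Gaussian response the
    dispersion is updated as ``RSS / (n - total effective df)``.
    """
    tol = tolerances or Tolerances()
    if not np.all(np.isfinite(A)):
        raise ValueError(f"REML criterion non-finite at theta={dict(theta)}")
    Ainv = linalg.cho_solve(linalg.cho_factor(A, lower=True),
                            np.eye(A.shape[0]))
    new = {}
    edf_total = float(state.p_fixed)
    for name, sl in state.blocks.items():
        b = delta[sl]
        q_r = sl.stop - sl.start
        tr = float(np.trace(Ainv[sl, sl]))
        edf = q_r - tr / theta[name]
        edf = max(edf, 1e-10)
        edf_total += edf
        val = float(b @ b) / edf
        new[name] = max(val, tol.theta_floor)
    phi_new = phi
    if state.family == "gaussian":
        resid = state.y - state.linpred(delta)
        phi_new = float(resid @ resid) / max(state.n_obs - edf_total, 1e-10)
    return new, phi_new


def _reml_criterion(state: ModelState, theta, delta, A, w, z, phi: float) -> float:
    """-2 x restricted log-likelihood of the working linear mixed model
    (constants dropped)."""
    resid = z - state.linpred(delta)
    rss_w = float((w * resid * resid).sum())
    pen = sum(float(delta[sl] @ delta[sl]) / theta[name]
              for name, sl in state.blocks.items())
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0 or not np.isfinite(logdetA):
        raise ValueError(f"REML criterion non-finite at theta={dict(theta)}")
    qlog = sum((sl.stop - sl.start) * math.log(theta[name])
               for name, sl in state.blocks.items())
    return rss_w + pen + logdetA + qlog - float(np.log(w).sum())


@dataclass
class FitResult:
    """Converged model fit: estimates, variance components, BLUPs, diagnostics."""

    columns: list[str]
    beta: np.ndarray
    cov_beta: np.ndarray
    theta: dict[str, float]            # at-floor components reported as 0.0
    theta_internal: dict[str, float]
    phi: float
    delta: np.ndarray
    V: np.ndarray                      # full coefficient covariance (A^{-1})
    state: ModelState
    district_ids: list
    blup: np.ndarray
    blup_se: np.ndarray
    converged: bool
    n_outer: int
    convergence_log: list[dict]
    pen_deviance: float
    reml_criterion: float
    column_map: dict

    # -- reporting -----------------------------------------------------------

    def coef_series(self) -> pd.Series:
        return pd.Series(self.beta, index=self.columns)

    def aor_table(self) -> pd.DataFrame:
        """Adjusted odds ratios with Wald 95% CIs for the linear fixed effects.

        Main effects are listed before interaction terms; the significance
        star marks coefficients whose CI excludes 1 (5% level).  Smooth
        null-space columns and the intercept are model structure, not
        reported odds ratios.
        """
        if self.cov_beta is None:
            raise ValueError("fit carries no coefficient covariance")
        se = np.sqrt(np.diag(self.cov_beta))
        rows = []
        for j, name in enumerate(self.columns):
            if name == "intercept" or name not in self.column_map:
                continue
            var, level, ref = self.column_map[name]
            lo, hi = self.beta[j] - Z975 * se[j], self.beta[j] + Z975 * se[j]
            rows.append({
                "term": name, "variable": var, "level": level, "reference": ref,
                "kind": "interaction" if ":" in name else "main",
                "log_odds": self.beta[j], "se": se[j],
                "aor": math.exp(self.beta[j]),
                "ci_low": math.exp(lo), "ci_high": math.exp(hi),
                "significant_5pct": bool(lo > 0 or hi < 0),
            })
        df = pd.DataFrame(rows)
        return pd.concat([df[df["kind"] == "main"], df[df["kind"] == "interaction"]],
                         ignore_index=True)

    def _term_eval(self, name: str, *args):
        info = self.state.terms[name]
        null_rows, pen_rows = info.eval_rows(*args)
        idx = np.concatenate([info.null_idx,
                              np.arange(info.pen_slice.start, info.pen_slice.stop)])
        rows = np.column_stack([null_rows, pen_rows]) if null_rows.size else pen_rows
        rows = rows - info.obs_mean_row  # sum-to-zero centering over observed data
        est = rows @ self.delta[idx]
        Vsub = self.V[np.ix_(idx, idx)]
        var = np.einsum("ij,jk,ik->i", rows, Vsub, rows)
        return est, np.sqrt(np.maximum(var, 0.0))

    def smooth_curve(self, term: str, grid: np.ndarray) -> pd.DataFrame:
        """Centered smooth estimate with a pointwise 95% band on ``grid``."""
        est, se = self._term_eval(term, np.asarray(grid, dtype=float))
        return pd.DataFrame({"grid": np.asarray(grid, dtype=float),
                             "estimate": est, "se": se,
                             "ci_low": est - Z975 * se,
                             "ci_high": est + Z975 * se})

    def spatial_surface(self, lon: np.ndarray, lat: np.ndarray) -> pd.DataFrame:
        """Centered spatial effect at the given points (log-odds scale)."""
        if "spatial" not in self.state.terms:
            raise ValueError("model has no spatial term")
        est, se = self._term_eval("spatial", np.asarray(lon, float),
                                  np.asarray(lat, float))
        return pd.DataFrame({"lon": lon, "lat": lat, "estimate": est, "se": se})

    def total_residence_country_effects(self) -> pd.DataFrame:
        """Total log-odds contribution of each (residence, country) cell.

        Sums the residence and country main effects and their interaction per
        cell (reference cell urban/Malawi = 0), with delta-method SEs.
        """
        inter = [c for c in self.columns if ":" in c and c.startswith("residence")]
        if not inter:
            raise ValueError(
                "no residence x country interaction in the fit; use the main "
                "effects directly")
        coefs = dict(zip(self.columns, self.beta))
        cells = residence_country_cells(coefs)
        ses = []
        for _, row in cells.iterrows():
            a = np.zeros(len(self.columns))
            for name in row["terms"]:
                a[self.columns.index(name)] = 1.0
            ses.append(float(np.sqrt(a @ self.cov_beta_full() @ a)))
        cells = cells.drop(columns=["terms"])
        cells["se"] = ses
        return cells

    def cov_beta_full(self) -> np.ndarray:
        return self.V[:len(self.columns), :len(self.columns)]

    def district_table(self) -> pd.DataFrame:
        return pd.DataFrame({"district_id": self.district_ids,
                             "blup": self.blup, "prediction_se": self.blup_se})

    def to_json_dict(self) -> dict:
        return {
            "columns": self.columns,
            "beta": self.beta.tolist(),
            "theta": self.theta,
            "phi": self.phi,
            "converged": self.converged,
            "n_outer": self.n_outer,
            "pen_deviance": self.pen_deviance,
            "reml_criterion": self.reml_criterion,
            "convergence_log": self.convergence_log,
            "districts": {
                "ids": [str(d) for d in self.district_ids],
                "blup": self.blup.tolist(),
                "prediction_se": self.blup_se.tolist(),
            },
        }


def residence_country_cells(coefs: Mapping[str, float],
                            countries: list[str] | None = None) -> pd.DataFrame:
    """Total log-odds per (residence, country) cell from named coefficients.

    ``coefs`` maps design column names (``residence[rural]``,
    ``country[Kenya]``, ``residence[rural]:country[Kenya]``...) to log-odds
    values — fitted or external (e.g. logs of published odds ratios).  The
    urban/Malawi reference cell is exactly 0.
    """
    countries = countries or cohort.CATEGORY_LEVELS["country"]
    rows = []
    for res in cohort.CATEGORY_LEVELS["residence"]:
        for ctry in countries:
            terms = []
            if res != "urban":
                terms.append(f"residence[{res}]")
            if ctry != "Malawi":
                terms.append(f"country[{ctry}]")
            if res != "urban" and ctry != "Malawi":
                terms.append(f"residence[{res}]:country[{ctry}]")
            total = sum(coefs.get(t, 0.0) for t in terms)
            rows.append({"residence": res, "country": ctry,
                         "total_log_odds": total, "terms": terms})
    return pd.DataFrame(rows)


def fit(dataset, model_spec: ModelSpec | None = None,
        tolerances: Tolerances | None = None,
        family: str = "binomial",
        theta0: Mapping[str, float] | None = None,
        estimate_theta: bool = True,
        reml_method: str = "schall") -> FitResult:
    """Fit the geoadditive logistic mixed model.

    ``dataset`` is a validated child table (DataFrame) or a
    ``SyntheticDataset``.  Alternates inner penalized IWLS with outer REML
    variance-component updates until joint convergence; deterministic given
    the data and starting values.  ``reml_method='optimize'`` replaces the
    Schall fixed-point outer loop with direct numerical optimization of the
    working-model REML criterion.
    """
    records = getattr(dataset, "records", dataset)
    model_spec = model_spec or ModelSpec()
    tol = tolerances or Tolerances()
    design = cohort.encode_design(records, model_spec)
    y = records["y"].to_numpy(dtype=float)
    state = assemble_model(design, model_spec, family=family, y=y)
    return _fit_state(state, tol, theta0, estimate_theta, reml_method)


def _fit_state(state: ModelState, tol: Tolerances,
               theta0: Mapping[str, float] | None,
               estimate_theta: bool, reml_method: str) -> FitResult:
    theta = {name: 0.1 for name in state.blocks}
    if theta0:
        theta.update(theta0)
    theta = {k: max(float(v), tol.theta_floor) for k, v in theta.items()}
    phi = 1.0
    delta = None
    conv_log: list[dict] = []
    converged = not estimate_theta or not state.blocks
    n_outer = 0

    if estimate_theta and state.blocks and reml_method == "optimize":
        names = sorted(state.blocks)

        def crit(x):
            nonlocal delta
            th = dict(zip(names, np.exp(x)))
            ph = math.exp(x[-1]) if state.family == "gaussian" else 1.0
            d, A, w, z, _, _ = _piwls_converge(state, th, delta, tol, ph)
            delta = d
            return _reml_criterion(state, th, d, A, w, z, ph)

        x0 = np.log([theta[n] for n in names])
        if state.family == "gaussian":
            x0 = np.append(x0, 0.0)
        res = optimize.minimize(crit, x0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10,
                                         "maxiter": 4000})
        xs = res.x
        theta = dict(zip(names, np.exp(xs[:len(names)])))
        theta = {k: max(v, tol.theta_floor) for k, v in theta.items()}
        if state.family == "gaussian":
            phi = math.exp(xs[-1])
        converged = bool(res.success)
        n_outer = int(res.nit)
        conv_log.append({"outer": n_outer, "criterion": float(res.fun),
                         "theta": dict(theta)})
    elif estimate_theta and state.blocks:
        prev = dict(theta)
        at_floor: set[str] = set()
        pin = max(100.0 * tol.theta_floor, 1e-6)
        decay_runs = {k: 0 for k in theta}
        for n_outer in range(1, tol.max_outer + 1):
            delta, A, w, z, n_inner, inner_ok = _piwls_converge(
                state, theta, delta, tol, phi)
            theta, phi = reml_update(state, theta, delta, A, tol, phi)
            # a component collapsing toward zero is a boundary solution: pin
            # it at the floor so the outer loop can converge.  Collapse shows
            # either as a value below the pin threshold or as a persistent
            # geometric decay of an already negligible component.
            for k, v in theta.items():
                if v < 1e-3 and v < 0.95 * prev[k]:
                    decay_runs[k] += 1
                else:
                    decay_runs[k] = 0
                if k in at_floor or v < pin or decay_runs[k] >= 8:
                    theta[k] = tol.theta_floor
                    at_floor.add(k)
            free = [k for k in theta if k not in at_floor]
            rel = max((abs(math.log(theta[k]) - math.log(prev[k]))
                       for k in free), default=0.0)
            conv_log.append({"outer": n_outer, "inner_iters": n_inner,
                             "theta": dict(theta), "phi": phi,
                             "rel_change": rel})
            prev = dict(theta)
            if rel < tol.outer_tol:
                converged = True
                break
        else:
            log.warning("outer REML loop hit max iterations (%d)", tol.max_outer)

    delta, A, w, z, n_inner, inner_ok = _piwls_converge(state, theta, delta,
                                                        tol, phi)
    if not inner_ok:
        raise RuntimeError(
            f"PIWLS failed to converge in {tol.max_inner} iterations "
            f"(last theta={theta})")
    if state.family == "binomial":
        beta_fixed = delta[:state.p_fixed]
        worst = int(np.argmax(np.abs(beta_fixed)))
        if abs(beta_fixed[worst]) > tol.separation_bound:
            raise RuntimeError(
                f"apparent complete separation: coefficient for "
                f"{state.columns[worst]!r} diverged ({beta_fixed[worst]:.2f})")

    V = linalg.cho_solve(linalg.cho_factor(A, lower=True), np.eye(A.shape[0]))
    reml_c = _reml_criterion(state, theta, delta, A, w, z, phi) if state.blocks \
        else float("nan")

    theta_rep = {k: (0.0 if v <= tol.theta_floor * 1.0001 else float(v))
                 for k, v in theta.items()}
    if "district" in state.blocks:
        sl = state.blocks["district"]
        blup = delta[sl].copy()
        blup_se = np.sqrt(np.maximum(np.diag(V)[sl], 0.0))
        if theta_rep.get("district", 1.0) == 0.0:
            blup = np.zeros_like(blup)
    else:
        blup = np.zeros(0)
        blup_se = np.zeros(0)

    p = state.p_fixed
    return FitResult(
        columns=state.columns, beta=delta[:p].copy(), cov_beta=V[:p, :p],
        theta=theta_rep, theta_internal=dict(theta), phi=phi, delta=delta,
        V=V, state=state, district_ids=list(state.district_ids),
        blup=blup, blup_se=blup_se, converged=converged,
        n_outer=n_outer, convergence_log=conv_log,
        pen_deviance=_pen_deviance(state, delta, theta, phi),
        reml_criterion=reml_c, column_map=state.column_map)
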