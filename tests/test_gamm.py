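"""Fitting machinery: PIWLS, REML variance components, reporting quantities."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, sparse
from scipy.special import expit

from anaemia_gamm import cohort, gamm, synthetic_data as sd
from anaemia_gamm.cohort import ModelSpec


def _logistic_state(seed=0, n=60, p=2):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    beta = rng.normal(size=p)
    y = (rng.random(n) < expit(X @ beta)).astype(float)
    return gamm.ModelState(y=y, M=X, Zd=None, columns=[f"x{i}" for i in range(p)],
                           p_fixed=p, blocks={}, terms={}, district_ids=[],
                           column_map={}), X, y


def _oneway_gaussian_state(a=12, n_per=20, mu=2.0, s2u=0.5, s2e=1.0, seed=5):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, math.sqrt(s2u), a)
    y = mu + np.repeat(u, n_per) + rng.normal(0, math.sqrt(s2e), a * n_per)
    n = a * n_per
    X = np.ones((n, 1))
    Z = sparse.csr_matrix((np.ones(n), (np.arange(n), np.repeat(np.arange(a), n_per))))
    state = gamm.ModelState(y=y, M=X, Zd=Z, columns=["intercept"], p_fixed=1,
                            blocks={"district": slice(1, 1 + a)}, terms={},
                            district_ids=list(range(a)), column_map={},
                            family="gaussian")
    return state, y.reshape(a, n_per)


class TestPIWLS:
    def test_working_response_at_zero_coefficients(self, tiny_records):
        spec = ModelSpec(spatial=False, smooth=[], district_effect=False,
                         linear=["gender"])
        design = cohort.encode_design(tiny_records, spec)
        y = tiny_records["y"].to_numpy(float)
        state = gamm.assemble_model(design, spec, y=y)
        _, w, z = gamm._working(state, np.zeros(state.n_coef),
                                gamm.Tolerances(), 1.0)
        assert np.allclose(z, 4.0 * (y - 0.5))
        assert np.allclose(w, 0.25)

    def test_matches_newton_raphson_without_penalty(self):
        state, X, y = _logistic_state(seed=1)
        # hand-rolled Newton oracle
        beta = np.zeros(X.shape[1])
        for _ in range(2):
            mu = expit(X @ beta)
            W = mu * (1 - mu)
            beta = beta + np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (y - mu))
        delta = np.zeros(state.n_coef)
        for _ in range(2):
            delta = gamm.piwls_step(state, {}, delta)
        assert np.max(np.abs(delta - beta)) < 1e-10

    def test_penalized_fit_matches_generic_optimizer(self, tiny_records):
        """PIWLS at fixed variance components solves the penalized Bernoulli
        likelihood: compare against a quasi-Newton minimizer."""
        spec = ModelSpec(linear=["gender", "rdt_result", "wealth_z"],
                         interactions=[], smooth=["age_months"], n_segments=6,
                         spatial=False)
        design = cohort.encode_design(tiny_records, spec)
        y = tiny_records["y"].to_numpy(float)
        state = gamm.assemble_model(design, spec, y=y)
        theta = {"age_months": 0.5, "district": 0.3}
        delta, *_ = gamm._piwls_converge(state, theta, None,
                                         gamm.Tolerances(inner_tol=1e-10), 1.0)
        M = np.column_stack([state.M, state.Zd.toarray()])
        pen = state.penalty_diag(theta)

        def nll(d):
            eta = M @ d
            return np.sum(np.logaddexp(0, eta) - y * eta) + 0.5 * np.sum(pen * d * d)

        def grad(d):
            return M.T @ (expit(M @ d) - y) + pen * d

        res = optimize.minimize(nll, np.zeros(state.n_coef), jac=grad,
                                method="BFGS",
                                options={"gtol": 1e-12, "maxiter": 5000})
        assert np.max(np.abs(delta - res.x)) < 1e-6

    def test_penalized_deviance_monotone(self, tiny_records):
        spec = ModelSpec(linear=["gender", "rdt_result"], interactions=[],
                         smooth=["age_months"], n_segments=6, spatial=False)
        design = cohort.encode_design(tiny_records, spec)
        y = tiny_records["y"].to_numpy(float)
        state = gamm.assemble_model(design, spec, y=y)
        theta = {"age_months": 0.2, "district": 0.2}
        delta = np.zeros(state.n_coef)
        devs = [gamm._pen_deviance(state, delta, theta, 1.0)]
        for _ in range(8):
            delta = gamm.piwls_step(state, theta, delta)
            devs.append(gamm._pen_deviance(state, delta, theta, 1.0))
        assert all(b <= a + 1e-9 for a, b in zip(devs, devs[1:]))

    def test_large_penalty_collapses_to_parametric_fit(self, tiny_records):
        """tau^2 -> 0 on the age smooth leaves intercept + linear age only."""
        spec = ModelSpec(linear=["gender"], interactions=[],
                         smooth=["age_months"], n_segments=6, spatial=False,
                         district_effect=False)
        design = cohort.encode_design(tiny_records, spec)
        y = tiny_records["y"].to_numpy(float)
        state = gamm.assemble_model(design, spec, y=y)
        delta, *_ = gamm._piwls_converge(state, {"age_months": 1e-12}, None,
                                         gamm.Tolerances(inner_tol=1e-10), 1.0)
        # oracle: plain logistic on intercept + gender + the smooth's linear column
        Xp = state.M[:, :state.p_fixed]
        beta = np.zeros(Xp.shape[1])
        for _ in range(50):
            mu = expit(Xp @ beta)
            W = mu * (1 - mu)
            beta = beta + np.linalg.solve(Xp.T @ (W[:, None] * Xp), Xp.T @ (y - mu))
        assert np.max(np.abs(delta[:state.p_fixed] - beta)) < 1e-4
        assert np.max(np.abs(delta[state.p_fixed:])) < 1e-5


class TestAssembly:
    def test_plain_logistic_reduction(self, tiny_records):
        spec = ModelSpec(linear=["gender"], interactions=[], smooth=[],
                         spatial=False, district_effect=False)
        design = cohort.encode_design(tiny_records, spec)
        state = gamm.assemble_model(design, spec,
                                    y=tiny_records["y"].to_numpy(float))
        assert state.blocks == {}
        assert state.n_coef == state.p_fixed == 2

    def test_order2_smooth_adds_linear_null_column(self, tiny_records):
        spec = ModelSpec(linear=["gender"], interactions=[],
                         smooth=["age_months"], penalty_order=2, spatial=False)
        design = cohort.encode_design(tiny_records, spec)
        state = gamm.assemble_model(design, spec,
                                    y=tiny_records["y"].to_numpy(float))
        assert "age_months_poly1" in state.columns
        assert state.terms["age_months"].reparam.null_dim == 2
        assert state.terms["age_months"].reparam.n_null == 1

    def test_duplicate_column_rejected(self, tiny_records):
        spec = ModelSpec(linear=["gender"], interactions=[], smooth=[],
                         spatial=False, district_effect=False)
        design = cohort.encode_design(tiny_records, spec)
        design.X = np.column_stack([design.X, design.X[:, -1]])
        design.columns = design.columns + ["gender_dup"]
        with pytest.raises(ValueError, match="collinear"):
            gamm.assemble_model(design, spec,
                                y=tiny_records["y"].to_numpy(float))


class TestREML:
    def test_gaussian_oneway_matches_closed_form(self):
        """Balanced one-way layout: Schall fixed point = ANOVA REML."""
        state, ymat = _oneway_gaussian_state()
        res = gamm._fit_state(state, gamm.Tolerances(outer_tol=1e-12,
                                                     max_outer=3000),
                              None, True, "schall")
        a, n_per = ymat.shape
        ybar = ymat.mean(axis=1)
        msb = n_per * np.sum((ybar - ymat.mean()) ** 2) / (a - 1)
        msw = np.sum((ymat - ybar[:, None]) ** 2) / (a * (n_per - 1))
        s2u = max(0.0, (msb - msw) / n_per)
        assert res.theta["district"] == pytest.approx(s2u, abs=1e-6)
        assert res.phi == pytest.approx(msw, abs=1e-6)

    def test_gaussian_optimize_method_agrees(self):
        state, ymat = _oneway_gaussian_state(a=8, n_per=10)
        r1 = gamm._fit_state(state, gamm.Tolerances(outer_tol=1e-12,
                                                    max_outer=3000),
                             None, True, "schall")
        r2 = gamm._fit_state(state, gamm.Tolerances(), None, True, "optimize")
        assert r2.theta["district"] == pytest.approx(r1.theta["district"],
                                                     rel=1e-3)
        assert r2.phi == pytest.approx(r1.phi, rel=1e-3)

    def test_lambda_is_inverse_variance_in_penalty(self, tiny_records):
        spec = ModelSpec(linear=["gender"], interactions=[],
                         smooth=["age_months"], n_segments=6, spatial=False,
                         district_effect=False)
        design = cohort.encode_design(tiny_records, spec)
        state = gamm.assemble_model(design, spec,
                                    y=tiny_records["y"].to_numpy(float))
        d1 = state.penalty_diag({"age_months": 0.5})
        d2 = state.penalty_diag({"age_months": 0.25})
        # halving tau^2 doubles the penalty (lambda = 1/tau^2)
        assert np.allclose(d2[state.p_fixed:], 2 * d1[state.p_fixed:])

    def test_separation_raises_named_error(self):
        rng = np.random.default_rng(7)
        n = 80
        x = rng.normal(size=n)
        y = (x > 0).astype(float)  # perfectly separated
        X = np.column_stack([np.ones(n), x])
        state = gamm.ModelState(y=y, M=X, Zd=None, columns=["intercept", "xsep"],
                                p_fixed=2, blocks={}, terms={}, district_ids=[],
                                column_map={})
        with pytest.raises(RuntimeError):
            gamm._fit_state(state, gamm.Tolerances(max_inner=500), None,
                            False, "schall")


@pytest.fixture(scope="module")
def fit_small(small_dataset):
    spec = ModelSpec(spatial_segments=5)
    return gamm.fit(small_dataset, spec,
                    tolerances=gamm.Tolerances(outer_tol=1e-4))


class TestFitEndToEnd:
    def test_fit_converges(self, fit_small):
        assert fit_small.converged
        assert all(v >= 0 for v in fit_small.theta.values())

    def test_refit_bit_identical(self, small_dataset):
        spec = ModelSpec(spatial_segments=4)
        tol = gamm.Tolerances(outer_tol=1e-3)
        r1 = gamm.fit(small_dataset, spec, tolerances=tol)
        r2 = gamm.fit(small_dataset, spec, tolerances=tol)
        assert np.array_equal(r1.delta, r2.delta)
        assert r1.theta == r2.theta

    def test_aor_table_closed_form(self, fit_small):
        tab = fit_small.aor_table().set_index("term")
        coefs = fit_small.coef_series()
        se = pd.Series(np.sqrt(np.diag(fit_small.cov_beta)),
                       index=fit_small.columns)
        for term, row in tab.iterrows():
            assert row["aor"] == pytest.approx(math.exp(coefs[term]), abs=1e-10)
            assert row["ci_low"] == pytest.approx(
                math.exp(coefs[term] - gamm.Z975 * se[term]), abs=1e-10)
            assert row["significant_5pct"] == (row["ci_low"] > 1
                                               or row["ci_high"] < 1)

    def test_aor_identity_coefficient_ci(self):
        # beta=0, SE=0.1: AOR 1, CI (0.822, 1.217)
        lo, hi = math.exp(-gamm.Z975 * 0.1), math.exp(gamm.Z975 * 0.1)
        assert lo == pytest.approx(0.822, abs=5e-4)
        assert hi == pytest.approx(1.217, abs=5e-4)

    def test_smooth_centered_over_observed_values(self, fit_small,
                                                  small_dataset):
        ages = small_dataset.records["age_months"].to_numpy(float)
        curve = fit_small.smooth_curve("age_months", ages)
        assert abs(curve["estimate"].mean()) < 1e-8

    def test_smooth_curve_rejects_outside_domain(self, fit_small):
        with pytest.raises(ValueError, match="outside"):
            fit_small.smooth_curve("age_months", np.array([200.0]))

    def test_surface_linear_in_coefficients(self, fit_small, small_dataset):
        """Surface values reproduce as basis-row dot coefficients."""
        cl = small_dataset.geography.clusters.head(20)
        surf = fit_small.spatial_surface(cl["lon"].to_numpy(),
                                         cl["lat"].to_numpy())
        info = fit_small.state.terms["spatial"]
        _, pen_rows = info.eval_rows(cl["lon"].to_numpy(), cl["lat"].to_numpy())
        manual = (pen_rows - info.obs_mean_row) @ \
            fit_small.delta[info.pen_slice]
        assert np.max(np.abs(surf["estimate"].to_numpy() - manual)) < 1e-10

    def test_blup_length_and_se_positive(self, fit_small, small_dataset):
        assert len(fit_small.blup) == small_dataset.geography.n_districts
        assert (fit_small.blup_se > 0).all()


class TestResidenceCountryCells:
    def test_reference_cell_zero(self):
        cells = gamm.residence_country_cells({})
        ref = cells[(cells.residence == "urban") & (cells.country == "Malawi")]
        assert ref["total_log_odds"].iloc[0] == 0.0

    def test_rural_kenya_sum(self):
        coefs = {"residence[rural]": 0.5, "country[Kenya]": -1.0,
                 "residence[rural]:country[Kenya]": 0.3}
        cells = gamm.residence_country_cells(coefs).set_index(
            ["residence", "country"])
        assert cells.loc[("rural", "Kenya"), "total_log_odds"] == \
            pytest.approx(0.5 - 1.0 + 0.3)

    def test_published_aor_fixture(self):
        """Cell formula on the published odds ratios for rural Kenya."""
        coefs = {"residence[rural]": math.log(0.738),
                 "country[Kenya]": math.log(0.316),
                 "residence[rural]:country[Kenya]": math.log(1.376)}
        cells = gamm.residence_country_cells(coefs).set_index(
            ["residence", "country"])
        assert cells.loc[("rural", "Kenya"), "total_log_odds"] == \
            pytest.approx(-1.136, abs=2e-3)

    def test_fit_requires_interaction(self, small_dataset):
        spec = ModelSpec(interactions=[], spatial=False, smooth=[],
                         district_effect=False,
                         linear=["gender", "residence", "country"])
        res = gamm.fit(small_dataset.records, spec)
        with pytest.raises(ValueError, match="main effects"):
            res.total_residence_country_effects()
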