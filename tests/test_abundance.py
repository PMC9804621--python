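"""Likelihood correctness, quadrature accuracy, fitting, and AIC selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import climdecomp as cd
from climdecomp.abundance import ModelError, _find_modes
from climdecomp.covariates import DesignMatrices
from climdecomp.synthetic_data import simulate_counts_from_design


def make_design(X: pd.DataFrame, y, route, offset=None, zi_cols=None):
    n = len(X)
    route = np.asarray(route)
    ids = np.unique(route)
    return DesignMatrices(
        X=X, X_zi=X[zi_cols] if zi_cols else X.copy(),
        offset=np.zeros(n) if offset is None else np.asarray(offset, float),
        route=route, route_ids=ids,
        frame=pd.DataFrame({"route_id": route, "year": 2000}),
        y=None if y is None else np.asarray(y, float),
    )


class TestConditionalLoglik:
    def test_poisson_zero_count_closed_form(self):
        # P(0) = exp(-mu) -> log density -mu = -1 at mu = 1
        ll = cd.conditional_loglik(np.array([0]), np.array([0.0]), "poisson")
        assert ll[0] == pytest.approx(-1.0)

    def test_nb2_zero_count_closed_form(self):
        # theta * log(theta / (theta + mu)) = log(1/2) at theta = mu = 1
        ll = cd.conditional_loglik(np.array([0]), np.array([0.0]), "nb", theta=1.0)
        assert ll[0] == pytest.approx(np.log(0.5))

    @pytest.mark.parametrize("family,theta", [("poisson", None), ("nb", 2.5)])
    def test_matches_scipy_pmfs(self, family, theta):
        y = np.arange(0, 30, dtype=float)
        eta = np.linspace(-1, 2.5, len(y))
        mu = np.exp(eta)
        ll = cd.conditional_loglik(y, eta, family, theta=theta)
        if family == "poisson":
            oracle = stats.poisson.logpmf(y, mu)
        else:
            oracle = stats.nbinom.logpmf(y, theta, theta / (theta + mu))
        np.testing.assert_allclose(ll, oracle, atol=1e-10)

    def test_zinb_pi_zero_equals_nb(self):
        y = np.array([0, 1, 5, 0, 12], dtype=float)
        eta = np.array([0.0, 0.5, 1.0, -1.0, 2.0])
        nb = cd.conditional_loglik(y, eta, "nb", theta=1.3)
        zinb = cd.conditional_loglik(
            y, eta, "zinb", theta=1.3, zi_eta=np.full(5, -40.0)
        )
        np.testing.assert_allclose(zinb, nb, atol=1e-10)

    def test_zip_mixture_at_zero(self):
        # log(pi + (1 - pi) * exp(-mu)) at pi = 0.5, mu = 1
        ll = cd.conditional_loglik(
            np.array([0]), np.array([0.0]), "zip", zi_eta=np.array([0.0])
        )
        assert ll[0] == pytest.approx(np.log(0.5 + 0.5 * np.exp(-1)))

    def test_nb_tends_to_poisson_for_large_theta(self):
        # the NB2 log-pmf differs from Poisson by ((y-mu)^2 - y)/(2 theta) +
        # O(theta^-2): at theta = 1e8 the probabilities agree to < 1e-6
        # everywhere and the log densities shrink at the 1/theta rate
        y = np.arange(0, 51, dtype=float)
        for mu in (0.5, 2.0, 20.0):
            eta = np.full_like(y, np.log(mu))
            po = cd.conditional_loglik(y, eta, "poisson")
            gaps = {
                theta: np.max(np.abs(
                    cd.conditional_loglik(y, eta, "nb", theta=theta) - po
                ))
                for theta in (1e6, 1e8)
            }
            nb8 = cd.conditional_loglik(y, eta, "nb", theta=1e8)
            assert np.max(np.abs(np.exp(nb8) - np.exp(po))) <= 1e-6
            assert gaps[1e8] <= 2e-5
            assert gaps[1e8] < 0.02 * gaps[1e6]   # ~ 1/theta decay

    def test_invalid_counts_rejected(self):
        with pytest.raises(ModelError):
            cd.conditional_loglik(np.array([-1]), np.array([0.0]), "poisson")
        with pytest.raises(ModelError):
            cd.conditional_loglik(np.array([1.5]), np.array([0.0]), "poisson")
        with pytest.raises(ModelError):
            cd.conditional_loglik(np.array([1]), np.array([0.0]), "nb", theta=0.0)


class TestMarginalLoglik:
    def test_sigma_zero_is_conditional_sum(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(3.0, size=20).astype(float)
        eta = np.full(20, np.log(3.0))
        route = np.repeat(np.arange(4), 5)
        ll = cd.marginal_loglik(y, eta, route, sigma_u=0.0, family="poisson")
        assert ll == pytest.approx(
            cd.conditional_loglik(y, eta, "poisson").sum()
        )

    @pytest.mark.parametrize("y0,sigma", [(0, 0.5), (3, 0.8), (7, 1.2)])
    def test_single_route_matches_trapezoid_oracle(self, y0, sigma):
        # brute-force integral over u on a dense grid
        eta0, theta = 0.7, 1.5
        u = np.linspace(-10 * sigma, 10 * sigma, 40001)
        f = (
            stats.nbinom.logpmf(y0, theta, theta / (theta + np.exp(eta0 + u)))
            + stats.norm.logpdf(u, 0, sigma)
        )
        oracle = np.log(np.trapezoid(np.exp(f), u))
        ll = cd.marginal_loglik(
            np.array([float(y0)]), np.array([eta0]), np.array([0]),
            sigma_u=sigma, family="nb", theta=theta, order=15,
        )
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_quadrature_order_convergence(self):
        rng = np.random.default_rng(1)
        route = np.repeat(np.arange(10), 6)
        eta = rng.normal(1.0, 0.5, size=60)
        u_true = rng.normal(0, 0.7, size=10)
        y = rng.poisson(np.exp(eta + u_true[route])).astype(float)
        vals = {
            k: cd.marginal_loglik(y, eta, route, 0.7, "poisson", order=k)
            for k in (1, 7, 15, 25)
        }
        assert abs(vals[15] - vals[25]) <= abs(vals[7] - vals[25]) + 1e-12
        assert abs(vals[7] - vals[25]) <= abs(vals[1] - vals[25]) + 1e-12
        assert abs(vals[15] - vals[25]) < 1e-8

    def test_invariant_to_route_relabeling_and_order(self):
        rng = np.random.default_rng(2)
        n, R = 60, 12
        route = rng.integers(0, R, size=n)
        eta = rng.normal(0.5, 0.4, size=n)
        y = rng.poisson(np.exp(eta)).astype(float)
        ll = cd.marginal_loglik(y, eta, route, 0.6, "poisson")
        perm = rng.permutation(n)
        ll_obs = cd.marginal_loglik(y[perm], eta[perm], route[perm], 0.6, "poisson")
        relab = rng.permutation(R)
        ll_lab = cd.marginal_loglik(y, eta, relab[route], 0.6, "poisson")
        assert ll_obs == pytest.approx(ll, abs=1e-9)
        assert ll_lab == pytest.approx(ll, abs=1e-9)

    def test_mode_finder_at_stationary_point(self):
        rng = np.random.default_rng(3)
        route = np.repeat(np.arange(5), 8)
        eta = rng.normal(1.0, 0.3, size=40)
        y = rng.poisson(np.exp(eta)).astype(float)
        u, H = _find_modes(y, eta, route, 5, 0.8, "poisson", None, None)
        # gradient of the joint log density vanishes at the mode
        mu = np.exp(eta + u[route])
        grad = np.bincount(route, weights=y - mu) - u / 0.8**2
        np.testing.assert_allclose(grad, 0, atol=1e-6)
        assert np.all(H < 0)


def poisson_test_data(seed=0, n_routes=25, n_per=8, sigma_u=0.0):
    rng = np.random.default_rng(seed)
    n = n_routes * n_per
    X = pd.DataFrame({
        "intercept": np.ones(n),
        "x1": rng.normal(size=n),
        "x2": rng.normal(size=n),
    })
    route = np.repeat(np.arange(n_routes), n_per)
    beta = np.array([1.0, 0.4, -0.3])
    offset = np.log(rng.integers(2, 9, size=n).astype(float))
    u = rng.normal(0, sigma_u, size=n_routes)
    mu = np.exp(X.to_numpy() @ beta + offset + u[route])
    y = rng.poisson(mu).astype(float)
    return make_design(X, y, route, offset), beta


class TestFit:
    def test_matches_irls_glm_oracle_when_sigma_zero(self):
        import statsmodels.api as sm

        design, _ = poisson_test_data(seed=1, sigma_u=0.0)
        fm = cd.fit(design, cd.ModelSpec(family="poisson"), compute_cov=False)
        oracle = sm.GLM(
            design.y, design.X, family=sm.families.Poisson(),
            offset=design.offset,
        ).fit()
        np.testing.assert_allclose(
            fm.beta.to_numpy(), oracle.params.to_numpy(), atol=1e-4
        )

    def test_recovers_random_intercept_scale(self):
        design, beta = poisson_test_data(seed=2, n_routes=80, n_per=10, sigma_u=0.6)
        fm = cd.fit(design, cd.ModelSpec(family="poisson"), compute_cov=False)
        assert fm.converged
        # slopes are tightly identified; the intercept carries the
        # random-intercept sampling noise (SE ~ sigma_u / sqrt(R))
        np.testing.assert_allclose(fm.beta.to_numpy()[1:], beta[1:], atol=0.05)
        assert fm.beta.iloc[0] == pytest.approx(beta[0], abs=0.25)
        assert 0.4 < fm.sigma_u < 0.8

    def test_zip_with_vanishing_zi_reproduces_poisson(self):
        design, _ = poisson_test_data(seed=3, n_routes=60, n_per=10, sigma_u=0.4)
        po = cd.fit(design, cd.ModelSpec(family="poisson"), compute_cov=False)
        zip_ = cd.fit(design, cd.ModelSpec(family="zip"), compute_cov=False)
        assert zip_.converged
        np.testing.assert_allclose(
            zip_.beta.to_numpy(), po.beta.to_numpy(), atol=1e-3
        )
        assert zip_.loglik >= po.loglik - 1e-3

    def test_duplicate_column_rank_error(self):
        design, _ = poisson_test_data(seed=4)
        design.X = design.X.assign(dup=design.X["x1"])
        with pytest.raises(ModelError, match="rank"):
            cd.fit(design, cd.ModelSpec(family="poisson"))

    def test_aic_definition(self):
        fm = cd.FittedModel(
            spec=cd.ModelSpec(family="poisson"), beta=pd.Series(dtype=float),
            gamma=pd.Series(dtype=float), theta=None, sigma_u=0.0,
            u_modes=np.zeros(1), route_ids=np.arange(1), loglik=-100.0, k=5,
            n_obs=10, converged=True,
        )
        assert fm.aic == pytest.approx(210.0)

    def test_wald_se_available(self):
        design, _ = poisson_test_data(seed=5, n_routes=40, n_per=8, sigma_u=0.3)
        fm = cd.fit(design, cd.ModelSpec(family="poisson"), compute_cov=True)
        se = fm.se()
        assert se is not None
        assert np.all(se[["x1", "x2"]] > 0)

    def test_serialization_roundtrip(self, tmp_path):
        from climdecomp.pipeline import load_model, save_model

        design, _ = poisson_test_data(seed=6)
        fm = cd.fit(design, cd.ModelSpec(family="poisson"), compute_cov=False)
        save_model(fm, tmp_path / "m.json")
        back = load_model(tmp_path / "m.json")
        pd.testing.assert_series_equal(back.beta, fm.beta)
        assert back.aic == pytest.approx(fm.aic)


class TestSelection:
    def test_family_table_and_tie_break(self):
        design, _ = poisson_test_data(seed=7, n_routes=50, n_per=8, sigma_u=0.3)
        sel = cd.select_family(design)
        assert set(sel.table["family"]) <= {"poisson", "nb", "zip", "zinb"}
        assert sel.best.aic == pytest.approx(sel.table["aic"].min())
        # on poisson data the zero-inflated/overdispersed candidates cannot
        # beat poisson by more than the parameter penalty
        po_aic = float(sel.table.set_index("family").loc["poisson", "aic"])
        assert sel.best.aic >= po_aic - 1e-6

    def test_block_elimination_drops_null_temporal(self, small_dataset):
        # generate counts whose temporal coefficients are exactly zero
        ds = small_dataset
        params = cd.TrueParameters(
            beta_count={
                "intercept": 0.6,
                "spatial_temp": -0.6, "spatial_prec": 0.35,
                "mountain_vegetation": 0.3,
            },
            sigma_u=0.3, family="poisson",
            habitat=("mountain_vegetation",),
        )
        _, design = cd.generate_counts(
            ds["routes"], ds["dec_t"], ds["dec_p"], params,
            covariates=ds["habitat"], seed=901,
        )
        sel = cd.select_covariates(design, family="poisson")
        # true effects always survive; AIC keeps a null block with
        # P ~ 0.16 each, so require most (not all) null blocks to drop
        assert sel.retained["spatial_temp"]
        assert sel.retained["spatial_prec"]
        null_blocks = ("temporal_temp", "temporal_prec",
                       "residual_temp", "residual_prec")
        dropped = sum(not sel.retained[b] for b in null_blocks)
        assert dropped >= 2
        # elimination path only ever lowers the AIC
        assert sel.table["aic"].is_monotonic_decreasing
        # interactions are only retained when both mains are
        kept = set(sel.best.beta.index)
        if "temporal_temp:temporal_prec" in kept:
            assert {"temporal_temp", "temporal_prec"} <= kept

    def test_all_blocks_retained_when_effects_large(self, small_dataset):
        ds = small_dataset
        params = cd.TrueParameters(
            beta_count={
                "intercept": 0.5,
                "spatial_temp": -0.6, "spatial_prec": 0.5,
                "temporal_temp": -0.5, "temporal_prec": 0.5,
                "residual_temp": -0.5, "residual_prec": 0.4,
            },
            sigma_u=0.3, family="poisson",
        )
        _, design = cd.generate_counts(
            ds["routes"], ds["dec_t"], ds["dec_p"], params, seed=902,
        )
        full = cd.fit(design, cd.ModelSpec(family="poisson"), compute_cov=False)
        sel = cd.select_covariates(design, family="poisson")
        assert all(sel.retained.values())
        # full model already lowest AIC -> returned unchanged
        assert sel.best.aic == pytest.approx(full.aic, abs=1e-6)


class TestPredictMean:
    def test_zero_inflation_halves_mean(self):
        fm = cd.FittedModel(
            spec=cd.ModelSpec(family="zinb", count_terms=("intercept",),
                              zi_terms=("intercept",)),
            beta=pd.Series({"intercept": np.log(4.0)}),
            gamma=pd.Series({"intercept": 0.0}),   # pi = 0.5
            theta=1.0, sigma_u=0.0, u_modes=np.zeros(1),
            route_ids=np.arange(1), loglik=0.0, k=3, n_obs=1, converged=True,
        )
        X = pd.DataFrame({"intercept": [1.0]})
        mu = cd.predict_mean(fm, X)
        assert mu[0] == pytest.approx(2.0)

    def test_intercept_only_at_reference(self):
        fm = cd.FittedModel(
            spec=cd.ModelSpec(family="poisson", count_terms=("intercept", "x")),
            beta=pd.Series({"intercept": 1.2, "x": 0.7}),
            gamma=pd.Series(dtype=float), theta=None, sigma_u=0.0,
            u_modes=np.zeros(1), route_ids=np.arange(1),
            loglik=0.0, k=2, n_obs=1, converged=True,
        )
        X = pd.DataFrame({"intercept": [1.0], "x": [0.0]})
        assert cd.predict_mean(fm, X)[0] == pytest.approx(np.exp(1.2))

    def test_training_predictions_track_observations(self, small_dataset, nb_fit):
        design = small_dataset["design"]
        pred = cd.predict_mean(
            nb_fit, design.X, offset=design.offset, X_zi=design.X_zi,
            route=design.route, include_random=True,
        )
        r = np.corrcoef(design.y, pred)[0, 1]
        assert r > 0.5

    def test_missing_column_rejected(self, nb_fit):
        with pytest.raises(ModelError, match="missing"):
            cd.predict_mean(nb_fit, pd.DataFrame({"intercept": [1.0]}))
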