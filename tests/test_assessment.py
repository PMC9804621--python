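"""Effect grids, rank correlations, classification, and diagnostics."""

import numpy as np
import pandas as pd
import pytest

import climdecomp as cd
from climdecomp.assessment import AssessmentError, subset_design


def brute_force_spearman(a, b):
    """Average-rank oracle: Pearson correlation of hand-computed ranks."""
    def ranks(v):
        v = np.asarray(v, dtype=float)
        out = np.empty(len(v))
        for i, x in enumerate(v):
            less = np.sum(v < x)
            equal = np.sum(v == x)
            out[i] = less + (equal + 1) / 2.0
        return out

    ra, rb = ranks(a), ranks(b)
    ra -= ra.mean()
    rb -= rb.mean()
    return float((ra @ rb) / np.sqrt((ra @ ra) * (rb @ rb)))


def brute_force_morans(values, W):
    """Double-sum oracle for Moran's I."""
    z = np.asarray(values, dtype=float)
    z = z - z.mean()
    n = len(z)
    num, s0 = 0.0, 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                num += W[i, j] * z[i] * z[j]
                s0 += W[i, j]
    return n / s0 * num / np.sum(z**2)


class TestSpearman:
    def test_perfect_monotone(self):
        assert cd.spearman([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert cd.spearman([1, 2, 3], [6, 4, 2]) == pytest.approx(-1.0)

    def test_tied_values_average_ranks(self):
        # ranks (1.5, 1.5, 3) vs (1, 2, 3) -> 1.5 / sqrt(3) = 0.8660
        assert cd.spearman([1, 1, 2], [1, 2, 3]) == pytest.approx(
            np.sqrt(3) / 2, abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 21))
        a = rng.integers(0, 6, size=n).astype(float)   # ties likely
        b = rng.normal(size=n)
        assert cd.spearman(a, b) == pytest.approx(
            brute_force_spearman(a, b), abs=1e-12
        )

    def test_invariant_to_monotone_transforms(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=30), rng.normal(size=30)
        r = cd.spearman(a, b)
        assert cd.spearman(np.exp(a), b) == pytest.approx(r, abs=1e-12)
        assert cd.spearman(a, b**3) == pytest.approx(r, abs=1e-12)

    def test_zero_variance_undefined(self):
        assert np.isnan(cd.spearman([1, 1, 1], [1, 2, 3]))

    def test_length_mismatch(self):
        with pytest.raises(AssessmentError):
            cd.spearman([1, 2], [1, 2, 3])


class TestMoransI:
    def test_two_antisymmetric_points_unit_weights(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        res = cd.morans_i([1.0, -1.0], weights=W, n_perm=9)
        assert res["I"] == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 21))
        coords = rng.uniform(0, 10, size=(n, 2))
        values = rng.normal(size=n)
        res = cd.morans_i(values, coords=coords, n_perm=9)
        d = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        with np.errstate(divide="ignore"):
            W = 1.0 / d
        np.fill_diagonal(W, 0.0)
        assert res["I"] == pytest.approx(
            brute_force_morans(values, W), abs=1e-12
        )

    def test_smooth_gradient_detected(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 10, size=(60, 2))
        values = coords[:, 0] + 0.5 * coords[:, 1]
        res = cd.morans_i(values, coords=coords, n_perm=199, seed=2)
        assert res["I"] > 0
        assert res["p"] <= 0.01

    def test_iid_values_near_expectation(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 10, size=(100, 2))
        vals = [
            cd.morans_i(rng.normal(size=100), coords=coords, n_perm=0)["I"]
            for _ in range(20)
        ]
        assert np.mean(vals) == pytest.approx(-1 / 99, abs=0.02)

    def test_constant_values_flagged(self):
        res = cd.morans_i([2.0, 2.0, 2.0], coords=np.eye(3)[:, :2], n_perm=9)
        assert not res["defined"]

    def test_knn_weights_supported(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 10, size=(30, 2))
        res = cd.morans_i(
            rng.normal(size=30), coords=coords, method="k_nearest", k=4, n_perm=9
        )
        assert np.isfinite(res["I"])


def toy_fit(beta: dict, design, family="poisson"):
    """A FittedModel built directly from chosen coefficients."""
    return cd.FittedModel(
        spec=cd.ModelSpec(family=family, count_terms=tuple(beta)),
        beta=pd.Series(beta), gamma=pd.Series(dtype=float),
        theta=None, sigma_u=0.0,
        u_modes=np.zeros(design.n_routes),
        route_ids=design.route_ids, loglik=0.0, k=len(beta),
        n_obs=len(design.X), converged=True,
        scalers=dict(design.scalers),
    )


@pytest.fixture(scope="module")
def grid_inputs(small_dataset):
    ds = small_dataset
    return ds["design"], ds["dec_t"], ds["dec_p"]


class TestEffectGrids:
    def test_levels_evenly_spaced_over_observed_range(self, grid_inputs):
        design, dec_t, dec_p = grid_inputs
        fm = toy_fit(
            {"intercept": 0.0, "spatial_temp": 0.5, "spatial_prec": 0.1},
            design,
        )
        g = cd.build_component_grid(fm, design, dec_t, dec_p, "spatial")
        np.testing.assert_allclose(
            g.temp_levels,
            np.linspace(dec_t.spatial.min(), dec_t.spatial.max(), 10),
        )
        assert np.all(np.diff(g.temp_levels) > 0)
        assert g.abundance.shape == (10, 10)
        assert np.all(g.abundance >= 0)

    def test_positive_temperature_effect_monotone(self, grid_inputs):
        design, dec_t, dec_p = grid_inputs
        fm = toy_fit(
            {"intercept": 0.0, "spatial_temp": 0.8, "spatial_prec": 0.0},
            design,
        )
        g = cd.build_component_grid(fm, design, dec_t, dec_p, "spatial")
        for j in range(10):
            assert np.all(np.diff(g.abundance[:, j]) > 0)

    def test_absent_component_constant_grid(self, grid_inputs):
        design, dec_t, dec_p = grid_inputs
        fm = toy_fit(
            {"intercept": 0.2, "spatial_temp": 0.5, "spatial_prec": 0.3},
            design,
        )
        g = cd.build_component_grid(fm, design, dec_t, dec_p, "temporal")
        assert not g.retained
        assert np.ptp(g.abundance) == pytest.approx(0.0, abs=1e-9)

    def test_equal_coefficient_vectors_give_rs_exactly_one(self, grid_inputs):
        design, dec_t, dec_p = grid_inputs
        beta = {
            "intercept": 0.1,
            "spatial_temp": -0.4, "spatial_prec": 0.25,
            "temporal_temp": -0.4, "temporal_prec": 0.25,
        }
        fm = toy_fit(beta, design)
        grids = {
            c: cd.build_component_grid(fm, design, dec_t, dec_p, c)
            for c in ("spatial", "temporal", "residual")
        }
        summary = cd.correlate_components(grids)
        # single-variable profiles are monotone in the level index: ranks
        # agree exactly; the joint surface can differ by adjacent swaps
        # because the two grids have different level spacings
        assert summary.r(("spatial", "temporal"), "temperature") == pytest.approx(
            1.0, abs=1e-12
        )
        assert summary.r(("spatial", "temporal"), "precipitation") == pytest.approx(
            1.0, abs=1e-12
        )
        assert summary.r(("spatial", "temporal"), "joint") > 0.99

    def test_negated_coefficients_give_rs_minus_one(self, grid_inputs):
        design, dec_t, dec_p = grid_inputs
        beta = {
            "intercept": 0.1,
            "spatial_temp": -0.4, "spatial_prec": 0.25,
            "temporal_temp": 0.4, "temporal_prec": -0.25,
        }
        fm = toy_fit(beta, design)
        grids = {
            c: cd.build_component_grid(fm, design, dec_t, dec_p, c)
            for c in ("spatial", "temporal", "residual")
        }
        summary = cd.correlate_components(grids)
        assert summary.r(("spatial", "temporal"), "temperature") == pytest.approx(
            -1.0, abs=1e-12
        )
        assert summary.r(("spatial", "temporal"), "joint") < -0.99

    def test_absent_component_reporting_conventions(self, grid_inputs):
        design, dec_t, dec_p = grid_inputs
        fm = toy_fit(
            {"intercept": 0.1, "spatial_temp": -0.4, "spatial_prec": 0.25},
            design,
        )
        grids = {
            c: cd.build_component_grid(fm, design, dec_t, dec_p, c)
            for c in ("spatial", "temporal", "residual")
        }
        summary = cd.correlate_components(grids)
        # spatial present, temporal absent -> 0 with flag
        assert summary.r(("spatial", "temporal"), "joint") == 0.0
        assert summary.status(("spatial", "temporal"), "joint") == "one-absent"
        # temporal and residual both absent -> 1 with flag
        assert summary.r(("temporal", "residual"), "joint") == 1.0
        assert summary.status(("temporal", "residual"), "joint") == "both-absent"


class TestClassification:
    def _summary(self, r):
        rows = [{
            "pair": "spatial-temporal", "gradient": "temperature",
            "r_s": r, "status": "both-retained",
        }]
        return cd.CorrelationSummary(table=pd.DataFrame(rows))

    def _spatial_grid(self, cold=True):
        ab = np.zeros((10, 10))
        ab[1 if cold else 8, 5] = 10.0
        return cd.EffectGrid(
            component="spatial", temp_levels=np.linspace(-3, 3, 10),
            prec_levels=np.linspace(-50, 50, 10), abundance=ab,
        )

    @pytest.mark.parametrize("r,label", [
        (0.8, "consistent"), (-0.8, "opposite"), (0.1, "complex_or_none"),
        (0.5, "complex_or_none"), (-0.5, "complex_or_none"),
    ])
    def test_threshold_rule(self, r, label):
        cls = cd.classify_species(self._summary(r), self._spatial_grid())
        assert cls.label == label

    def test_cold_warm_baseline(self):
        assert cd.classify_species(
            self._summary(0.8), self._spatial_grid(cold=True)
        ).combined == "consistent-cold"
        assert cd.classify_species(
            self._summary(0.8), self._spatial_grid(cold=False)
        ).baseline == "warm"

    def test_one_absent_label(self):
        rows = [{
            "pair": "spatial-temporal", "gradient": "temperature",
            "r_s": 0.0, "status": "one-absent",
        }]
        cls = cd.classify_species(
            cd.CorrelationSummary(table=pd.DataFrame(rows)), self._spatial_grid()
        )
        assert cls.label == "one_absent"


class TestPerformance:
    def test_perfect_fit_passes(self, small_dataset, nb_fit):
        rep = cd.performance_pearson(nb_fit, small_dataset["design"])
        assert set(rep.per_group["group"]) == {"NO", "SE", "FI"}
        assert -1 <= rep.pooled_r <= 1

    def test_identity_predictions_r_one(self, small_dataset, nb_fit):
        # degenerate check of the statistic itself
        design = small_dataset["design"]
        y = design.y
        assert np.corrcoef(y, y)[0, 1] == pytest.approx(1.0)

    def test_null_predictions_fail_screen(self, small_dataset):
        ds = small_dataset
        design = ds["design"]
        rng = np.random.default_rng(0)
        # a model whose coefficients carry no information about y
        fm = toy_fit({"intercept": 0.0}, design)
        rep = cd.performance_pearson(fm, design)
        # constant predictions modulated only by offset: low correlation
        assert not rep.passed or rep.pooled_r < 0.5


class TestLOYO:
    def test_three_year_dataset_three_refits(self):
        rng = np.random.default_rng(0)
        n_routes, years = 30, (2000, 2001, 2002)
        rows = []
        for r in range(n_routes):
            for y in years:
                rows.append({"route_id": f"R{r}", "year": y})
        frame = pd.DataFrame(rows)
        n = len(frame)
        X = pd.DataFrame({"intercept": np.ones(n), "x": rng.normal(size=n)})
        route = frame["route_id"].astype("category").cat.codes.to_numpy()
        mu = np.exp(1.0 + 0.8 * X["x"].to_numpy())
        from climdecomp.covariates import DesignMatrices

        design = DesignMatrices(
            X=X, X_zi=X.copy(), offset=np.zeros(n), route=route,
            route_ids=np.unique(frame["route_id"]), frame=frame,
            y=rng.poisson(mu).astype(float),
        )
        res = cd.loyo_cv(design, cd.ModelSpec(family="poisson"))
        assert len(res) == 3
        assert res["r"].min() > 0.3

    def test_subset_design_recodes_routes(self, small_dataset):
        design = small_dataset["design"]
        mask = (design.frame["year"] != design.frame["year"].iloc[0]).to_numpy()
        sub = subset_design(design, mask)
        assert len(sub.X) == mask.sum()
        assert sub.route.max() == len(sub.route_ids) - 1
        # identical rows survive in order
        np.testing.assert_allclose(sub.offset, design.offset[mask])
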