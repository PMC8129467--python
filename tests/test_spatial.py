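import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from phylospat.grids import GridSpec
from phylospat.spatial import (akaike_weights, all_subsets_average, fit_ols,
                               fit_sar_error, grid_neighbors, modified_ttest,
                               nagelkerke_r2, zscore)

GRID = GridSpec(1.0)


def lattice(ncol, nrow, col0=240, row0=110):
    cols, rows = np.meshgrid(np.arange(ncol) + col0, np.arange(nrow) + row0)
    return (rows * GRID.ncol + cols).ravel()


class TestWeights:
    def test_queen_center_of_full_block(self):
        w = grid_neighbors(lattice(3, 3), GRID)
        center = 4  # sorted cell order: row-major
        row = w.W[center]
        assert np.allclose(row[row > 0], 1 / 8)
        assert row.sum() == pytest.approx(1.0)
        assert np.count_nonzero(row) == 8

    def test_diagonal_cells_are_mutual_neighbors(self):
        cells = [GRID.cell_id(100.5, 30.5), GRID.cell_id(101.5, 31.5)]
        w = grid_neighbors(cells, GRID)
        assert w.W[0, 1] == 1.0 and w.W[1, 0] == 1.0

    def test_adjacency_symmetric_before_standardization(self):
        r = np.random.default_rng(0)
        cells = np.unique(GRID.cell_id(r.uniform(60, 80, 40), r.uniform(20, 40, 40)))
        w = grid_neighbors(cells, GRID)
        d = np.count_nonzero(w.W, axis=1)
        A = w.W * d[:, None]
        for i in range(w.n):
            for j in range(w.n):
                assert A[i, j] == pytest.approx(A[j, i], abs=1e-12)

    def test_islands_get_knn_links(self):
        # two far-apart singleton cells have no queen neighbor, so each
        # attaches to its nearest cells
        cells = [GRID.cell_id(60.5, 20.5), GRID.cell_id(100.5, 50.5),
                 GRID.cell_id(101.5, 50.5)]
        w = grid_neighbors(cells, GRID, k=1)
        assert (w.W.sum(axis=1) > 0).all()

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            grid_neighbors([1234], GRID)

    def test_eigenvalue_logdet_matches_dense_oracle(self):
        w = grid_neighbors(lattice(10, 8), GRID)
        lam = 0.57
        dense = np.linalg.slogdet(np.eye(w.n) - lam * w.W)[1]
        from_eigs = np.log1p(-lam * w.eigenvalues).sum()
        assert from_eigs == pytest.approx(dense, abs=1e-10)


class TestOLS:
    def test_exact_linear_relation(self):
        r = np.random.default_rng(1)
        X = pd.DataFrame({"x1": r.normal(size=50), "x2": r.normal(size=50)})
        y = pd.Series(2.0 + 3.0 * X.x1 - 1.0 * X.x2)
        fit = fit_ols(y, X)
        assert fit.beta["x1"] == pytest.approx(3.0, abs=1e-10)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-18)

    def test_single_standardized_predictor_beta_is_pearson_r(self):
        r = np.random.default_rng(2)
        x = r.normal(size=400)
        y = 0.6 * x + r.normal(size=400)
        X = zscore(pd.DataFrame({"x": x}))
        fit = fit_ols(zscore(pd.Series(y)), X)
        assert fit.beta["x"] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)

    def test_coefficient_recovery(self):
        r = np.random.default_rng(3)
        x = r.normal(size=10_000)
        y = pd.Series(0.5 * x + r.normal(size=10_000))
        fit = fit_ols(y, pd.DataFrame({"x": x}))
        assert fit.beta["x"] == pytest.approx(0.5, abs=0.05)

    def test_rank_deficiency_names_collinear_columns(self):
        r = np.random.default_rng(4)
        x = r.normal(size=60)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": r.normal(size=60)})
        with pytest.raises(ValueError) as err:
            fit_ols(pd.Series(r.normal(size=60)), X)
        assert "a" in str(err.value) and "b" in str(err.value)


class TestSARError:
    @pytest.fixture(scope="class")
    def weights(self):
        return grid_neighbors(lattice(20, 20), GRID)

    def test_fixed_lambda_zero_reproduces_ols(self, weights):
        r = np.random.default_rng(5)
        X = pd.DataFrame({"x": r.normal(size=weights.n)})
        y = pd.Series(0.8 * X.x + r.normal(size=weights.n))
        sar = fit_sar_error(y, X, weights, lam=0.0)
        ols = fit_ols(y, X)
        assert np.allclose(sar.beta, ols.beta, atol=1e-12)
        assert sar.loglik == pytest.approx(ols.loglik, abs=1e-10)
        assert sar.aic == pytest.approx(ols.aic, abs=1e-10)

    def test_lambda_recovery_on_lattice(self, weights):
        r = np.random.default_rng(6)
        n = weights.n
        A = np.linalg.inv(np.eye(n) - 0.6 * weights.W)
        X = pd.DataFrame({"x": r.normal(size=n)})
        lams = []
        for _ in range(30):
            y = pd.Series(0.7 * X.x.to_numpy() + A @ r.normal(size=n))
            lams.append(fit_sar_error(y, X, weights).lam)
        assert np.mean(lams) == pytest.approx(0.6, abs=0.1)

    def test_loglik_matches_dense_mvn_density(self, weights):
        r = np.random.default_rng(7)
        n = weights.n
        X = pd.DataFrame({"x": r.normal(size=n)})
        y = pd.Series(X.x.to_numpy() + r.normal(size=n))
        fit = fit_sar_error(y, X, weights)
        B = np.eye(n) - fit.lam * weights.W
        Sigma = fit.sigma2 * np.linalg.inv(B.T @ B)
        mu = np.column_stack([np.ones(n), X.to_numpy()]) @ fit.beta.to_numpy()
        assert fit.loglik == pytest.approx(
            multivariate_normal.logpdf(y, mu, Sigma), abs=1e-8)


class TestNagelkerke:
    def make_fit(self, loglik, n=100, k=3):
        from phylospat.spatial import SARFit
        beta = pd.Series({"(Intercept)": 0.0})
        return SARFit(0.0, beta, beta, 1.0, loglik, n, k)

    def test_null_model_scores_zero(self):
        f = self.make_fit(-150.0)
        assert nagelkerke_r2(f, f) == 0.0

    def test_closed_form_example(self):
        val = nagelkerke_r2(self.make_fit(-100.0), self.make_fit(-150.0))
        expected = (1 - np.exp(-2 / 100 * 50)) / (1 - np.exp(2 / 100 * -150))
        assert val == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx((1 - np.exp(-1.0)) / (1 - np.exp(-3.0)))

    def test_saturated_limit_approaches_one(self):
        val = nagelkerke_r2(self.make_fit(-1e-9), self.make_fit(-150.0))
        assert val == pytest.approx(1.0, abs=1e-3)

    def test_worse_than_null_warns(self):
        with pytest.warns(UserWarning):
            assert nagelkerke_r2(self.make_fit(-160.0), self.make_fit(-150.0)) <= 0


class TestModelAveraging:
    def test_two_model_closed_form(self):
        w = akaike_weights([0.0, 2.0])
        assert w[0] == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-9)
        assert w.tolist() == pytest.approx([0.731, 0.269], abs=1e-3)

    @pytest.fixture(scope="class")
    def model_set(self):
        weights = grid_neighbors(lattice(12, 12), GRID)
        r = np.random.default_rng(8)
        n = weights.n
        X = pd.DataFrame({"a": r.normal(size=n), "b": r.normal(size=n),
                          "c": r.normal(size=n)})
        y = pd.Series(0.8 * X.a - 0.4 * X.b + r.normal(size=n))
        return all_subsets_average(y, X, weights, standardize=False)

    def test_weights_sum_to_one_and_support_bounded(self, model_set):
        assert model_set.models["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert ((model_set.support >= 0) & (model_set.support <= 1)).all()
        assert model_set.support["a"] > 0.99   # the dominant predictor

    def test_averaged_coefficient_bounded_by_per_model_extremes(self, model_set):
        assert abs(model_set.coef_ave["a"]) <= 0.9   # |full average| <= |max coef|
        assert model_set.coef_ave["a"] == pytest.approx(0.8, abs=0.15)

    def test_aic_ordering_invariant_to_column_order(self):
        weights = grid_neighbors(lattice(8, 8), GRID)
        r = np.random.default_rng(9)
        n = weights.n
        X = pd.DataFrame({"a": r.normal(size=n), "b": r.normal(size=n)})
        y = pd.Series(0.5 * X.a + r.normal(size=n))
        m1 = all_subsets_average(y, X, weights)
        m2 = all_subsets_average(y, X[["b", "a"]], weights)
        assert sorted(m1.models["aic"].round(9)) == sorted(m2.models["aic"].round(9))
        assert m1.r2 == pytest.approx(m2.r2, abs=1e-9)

    def test_collinear_predictors_refused(self):
        weights = grid_neighbors(lattice(8, 8), GRID)
        r = np.random.default_rng(10)
        n = weights.n
        a = r.normal(size=n)
        X = pd.DataFrame({"a": a, "b": a + 0.1 * r.normal(size=n)})
        with pytest.raises(ValueError, match="split these predictors"):
            all_subsets_average(pd.Series(r.normal(size=n)), X, weights)


class TestModifiedTTest:
    def coords(self, n_side=20):
        lon, lat = np.meshgrid(np.arange(n_side) + 60.5, np.arange(n_side) + 20.5)
        return lon.ravel(), lat.ravel()

    def test_iid_data_recover_classical_sample_size(self):
        lon, lat = self.coords()
        r = np.random.default_rng(11)
        res = modified_ttest(r.normal(size=400), r.normal(size=400), lon, lat)
        assert 0.9 <= res.m_hat / 400 <= 1.1
        assert res.m_hat <= 400

    def test_autocorrelation_shrinks_effective_sample_size(self):
        from scipy.ndimage import gaussian_filter
        lon, lat = self.coords()
        r = np.random.default_rng(12)
        m_hats = []
        for sigma in (1.0, 3.0):
            vals = []
            for _ in range(10):
                x = gaussian_filter(r.normal(size=(20, 20)), sigma, mode="wrap").ravel()
                y = gaussian_filter(r.normal(size=(20, 20)), sigma, mode="wrap").ravel()
                vals.append(modified_ttest(x, y, lon, lat).m_hat)
            m_hats.append(np.mean(vals))
        assert m_hats[1] < m_hats[0] < 400

    def test_constant_variable_rejected(self):
        lon, lat = self.coords()
        with pytest.raises(ValueError, match="degenerate"):
            modified_ttest(np.ones(400), np.random.default_rng(0).normal(size=400),
                           lon, lat)

    def test_perfect_correlation_detected(self):
        lon, lat = self.coords()
        r = np.random.default_rng(13)
        x = r.normal(size=400)
        res = modified_ttest(x, 2 * x + 0.01 * r.normal(size=400), lon, lat)
        assert res.r > 0.99 and res.p < 1e-6
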