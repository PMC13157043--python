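"""Penalized solver oracles: standardization, lambda grid, coordinate
descent vs closed forms, KKT conditions, scoring."""
import numpy as np
import pytest

from admixpgs import model
from admixpgs.io import MISSING
from conftest import make_genotypes


def random_standardized(rng, n, m):
    X = rng.normal(size=(n, m))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    y = rng.normal(size=n)
    y = (y - y.mean()) / y.std(ddof=1)
    return X, y


def ista_reference(X, y, lam, alpha, iters=200000, tol=1e-12):
    """Slow proximal-gradient reference for the elastic-net endpoints."""
    n, m = X.shape
    L = np.linalg.eigvalsh(X.T @ X / n).max() + lam * (1 - alpha)
    beta = np.zeros(m)
    obj_prev = np.inf
    for _ in range(iters):
        grad = X.T @ (X @ beta - y) / n + lam * (1 - alpha) * beta
        z = beta - grad / L
        beta = np.sign(z) * np.maximum(np.abs(z) - lam * alpha / L, 0)
        r = y - X @ beta
        obj = r @ r / (2 * n) + lam * (alpha * np.abs(beta).sum() + (1 - alpha) * beta @ beta / 2)
        if obj_prev - obj < tol:
            break
        obj_prev = obj
    return beta, obj


class TestStandardizeGenotypes:
    def test_hand_computed_column(self):
        g = make_genotypes(np.array([[0], [1], [2], [1]]))
        X, stats = model.standardize_genotypes(g)
        assert stats.mean[0] == pytest.approx(1.0)
        assert stats.sd[0] == pytest.approx(np.sqrt(2 / 3))
        assert X[:, 0] == pytest.approx([-1.2247, 0.0, 1.2247, 0.0], abs=1e-4)

    def test_missing_imputed_to_mean(self):
        g = make_genotypes(np.array([[0], [2], [MISSING]]))
        X, stats = model.standardize_genotypes(g)
        assert stats.mean[0] == pytest.approx(1.0)
        assert X[2, 0] == pytest.approx(0.0)  # imputed to the mean -> z = 0

    def test_columns_standardized(self):
        rng = np.random.default_rng(0)
        g = make_genotypes(rng.integers(0, 3, size=(50, 10)).astype(np.int8))
        X, _ = model.standardize_genotypes(g)
        assert np.abs(X.mean(0)).max() < 1e-10
        assert np.abs(X.std(0, ddof=1) - 1).max() < 1e-10

    def test_zero_sd_column_dropped_and_reported(self):
        counts = np.array([[0, 2], [1, 2], [2, 2]], dtype=np.int8)
        g = make_genotypes(counts)
        X, stats = model.standardize_genotypes(g)
        assert X.shape[1] == 1
        assert stats.dropped_zero_sd == ["v1"]


class TestLambdaGrid:
    def test_lasso_zero_at_lambda_max(self):
        rng = np.random.default_rng(1)
        X, y = random_standardized(rng, 60, 8)
        lams = model.make_lambda_grid(X, y, 1.0)
        path = model.fit_path(X, y, 1.0, lams)
        assert np.all(path.weights[:, 0] == 0)

    def test_log_spacing_constant_ratio(self):
        rng = np.random.default_rng(2)
        X, y = random_standardized(rng, 40, 5)
        lams = model.make_lambda_grid(X, y, 1.0)
        ratios = lams[1:] / lams[:-1]
        assert np.abs(ratios - ratios[0]).max() < 1e-12
        assert len(lams) == 10

    def test_single_predictor_formula(self):
        n = 50
        x = np.linspace(-1, 1, n)
        x = (x - x.mean()) / x.std(ddof=1)
        y = 0.4 * n * x / (x @ x)  # so that x'y / n = 0.4 exactly
        lam_max = model.make_lambda_grid(x[:, None], y, 1.0)[0]
        assert lam_max == pytest.approx(0.4)


class TestFitPath:
    def test_lasso_orthonormal_soft_threshold(self):
        rng = np.random.default_rng(3)
        n, m = 64, 8
        Q, _ = np.linalg.qr(rng.normal(size=(n, n)))
        X = Q[:, :m] * np.sqrt(n)  # X'X = n I
        y = rng.normal(size=n)
        lams = model.make_lambda_grid(X, y, 1.0)
        path = model.fit_path(X, y, 1.0, lams)
        z = X.T @ y / n
        for li, lam in enumerate(lams):
            ref = np.sign(z) * np.maximum(np.abs(z) - lam, 0)
            assert np.abs(path.weights[:, li] - ref).max() < 1e-8

    def test_ridge_closed_form(self):
        rng = np.random.default_rng(4)
        X, y = random_standardized(rng, 50, 10)
        lams = model.make_lambda_grid(X, y, 0.0)
        path = model.fit_path(X, y, 0.0, lams)
        for li, lam in enumerate(lams):
            ref = np.linalg.solve(X.T @ X + 50 * lam * np.eye(10), X.T @ y)
            assert np.abs(path.weights[:, li] - ref).max() < 1e-8

    def test_small_lambda_limit_is_ols(self):
        rng = np.random.default_rng(5)
        X, y = random_standardized(rng, 400, 5)
        lams = np.array([1e-2, 1e-4, 1e-6, 1e-8])
        path = model.fit_path(X, y, 1.0, lams, tol=1e-10)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.abs(path.weights[:, -1] - ols).max() < 1e-6

    def test_kkt_conditions_at_convergence(self):
        rng = np.random.default_rng(6)
        X, y = random_standardized(rng, 80, 20)
        lams = model.make_lambda_grid(X, y, 1.0)
        tol = 1e-9
        path = model.fit_path(X, y, 1.0, lams, tol=tol)
        n = X.shape[0]
        for li, lam in enumerate(lams):
            beta = path.weights[:, li]
            grad = X.T @ (y - X @ beta) / n
            zero = beta == 0
            assert (np.abs(grad[zero]) <= lam + 10 * tol * 100).all()
            active = ~zero
            if active.any():
                assert np.abs(grad[active] - lam * np.sign(beta[active])).max() < 1e-5

    def test_matches_proximal_gradient_reference(self):
        rng = np.random.default_rng(7)
        for t in range(5):
            X, y = random_standardized(rng, 50, 10)
            lams = model.make_lambda_grid(X, y, 1.0)[[2, 5, 8]]
            path = model.fit_path(X, y, 1.0, np.sort(lams)[::-1])
            for li, lam in enumerate(np.sort(lams)[::-1]):
                _, obj_ref = ista_reference(X, y, lam, 1.0)
                beta = path.weights[:, li]
                r = y - X @ beta
                obj = r @ r / 100 + lam * np.abs(beta).sum()
                assert obj <= obj_ref * (1 + 1e-6) + 1e-12

    def test_objective_monotone_within_lambda(self):
        rng = np.random.default_rng(8)
        X, y = random_standardized(rng, 60, 15)
        lams = model.make_lambda_grid(X, y, 1.0)
        path = model.fit_path(X, y, 1.0, lams, track_objective=True)
        for trace in path.objective:
            assert (np.diff(trace) <= 1e-12).all()

    def test_lasso_sparsity_monotone_in_lambda(self):
        rng = np.random.default_rng(9)
        X, y = random_standardized(rng, 100, 30)
        lams = model.make_lambda_grid(X, y, 1.0)
        path = model.fit_path(X, y, 1.0, lams)
        nz = path.nonzero_counts()
        # lambdas decrease along the path, so nonzero counts may only grow
        assert (np.diff(nz) >= 0).all()

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            model.fit_path(np.eye(3), np.ones(3), 0.5, np.array([1.0, 0.5]))


class TestScore:
    def _path(self, weights, lambdas=None):
        weights = np.asarray(weights, dtype=float)
        if lambdas is None:
            lambdas = 0.5 ** np.arange(weights.shape[1])
        return model.WeightPath(lambdas=np.asarray(lambdas, dtype=float),
                                weights=weights, alpha=1.0,
                                n_iter=np.zeros(weights.shape[1], dtype=int))

    def _stats(self, mean, sd):
        return model.StandardizationStats(
            variant_ids=[f"v{j}" for j in range(len(mean))],
            mean=np.asarray(mean, dtype=float),
            sd=np.asarray(sd, dtype=float),
            dropped_zero_sd=[],
        )

    def test_zero_weights_zero_scores(self):
        g = make_genotypes([[0, 1], [2, 1]])
        out = model.score(g, self._path(np.zeros((2, 3))), self._stats([1, 1], [1, 1]))
        assert all(np.all(v.values == 0) for v in out)

    def test_single_snp_hand_computation(self):
        g = make_genotypes([[2]])
        out = model.score(g, self._path([[1.0]]), self._stats([1.0], [0.7071]))
        assert out[0].values[0] == pytest.approx((2 - 1) / 0.7071, abs=1e-4)

    def test_linearity_in_weights(self):
        rng = np.random.default_rng(10)
        g = make_genotypes(rng.integers(0, 3, size=(20, 4)).astype(np.int8))
        W = rng.normal(size=(4, 2))
        stats = self._stats(np.full(4, 1.0), np.full(4, 0.8))
        s1 = model.score(g, self._path(W), stats)
        s2 = model.score(g, self._path(2 * W), stats)
        for a, b in zip(s1, s2):
            assert np.allclose(2 * a.values, b.values)

    def test_training_scores_equal_fit_design_product(self):
        rng = np.random.default_rng(11)
        g = make_genotypes(rng.integers(0, 3, size=(60, 6)).astype(np.int8))
        X, stats = model.standardize_genotypes(g)
        y = rng.normal(size=60)
        y = (y - y.mean()) / y.std(ddof=1)
        lams = model.make_lambda_grid(X, y, 1.0)
        path = model.fit_path(X, y, 1.0, lams)
        scored = model.score(g, path, stats)
        for li, v in enumerate(scored):
            assert np.abs(v.values - X @ path.weights[:, li]).max() < 1e-10

    def test_variant_mismatch_rejected(self):
        g = make_genotypes([[0, 1]])
        stats = self._stats([1.0], [1.0])
        with pytest.raises(ValueError, match="aligned"):
            model.score(g, self._path([[1.0]]), stats)


class TestSelectBestLambda:
    def _scores(self, arrays):
        return [
            model.PGSVector(values=np.asarray(a, dtype=float), lambda_index=i, alpha=1.0)
            for i, a in enumerate(arrays)
        ]

    def test_exact_match_selected(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        idx, r2 = model.select_best_lambda(self._scores([y, y[::-1] * 0.1]), y)
        assert idx == 0 and r2 == pytest.approx(1.0)

    def test_sign_blindness(self):
        y = np.array([1.0, -2.0, 3.0, 0.5])
        idx, r2 = model.select_best_lambda(self._scores([-y]), y)
        assert r2 == pytest.approx(1.0)

    def test_tie_broken_toward_larger_lambda(self):
        y = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        weak = np.array([1.0, 0.0, 2.0, 1.0, 2.0])
        tied = 2 * y + 1
        idx, _ = model.select_best_lambda(self._scores([weak, tied, tied / 2]), y)
        assert idx == 1  # first (larger-lambda) member of the perfect tie

    def test_zero_variance_score_gets_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        idx, r2 = model.select_best_lambda(self._scores([np.ones(3)]), y)
        assert r2 == 0.0
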