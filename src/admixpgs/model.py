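"""Lasso/ridge SNP-weight estimation over a lambda path, and scoring.

The solver minimizes the elastic-net objective restricted to its two
endpoint mixing values,

    (1/2n) ||y - X b||^2 + lambda * (alpha ||b||_1 + (1 - alpha) ||b||^2 / 2),

with alpha = 1 (Lasso) or alpha = 0 (ridge), by cyclic coordinate descent
with soft-thresholding updates and warm starts along a decreasing
10-value lambda path. Genotypes are standardized with training-cohort
statistics (missing calls mean-imputed); scores for new cohorts apply the
same training statistics, which makes the score an affine transform of the
raw allele-count score and leaves squared-correlation metrics unchanged.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .io import MISSING, GenotypeMatrix

__all__ = [
    "StandardizationStats",
    "WeightPath",
    "PGSVector",
    "standardize_genotypes",
    "make_lambda_grid",
    "fit_path",
    "score",
    "select_best_lambda",
]

N_LAMBDA_DEFAULT = 10


class SolverError(RuntimeError):
    """Raised when coordinate descent fails to converge."""


@dataclasses.dataclass
class StandardizationStats:
    """Per-variant training mean and SD (allele-count units) used for scoring."""

    variant_ids: list[str]
    mean: np.ndarray
    sd: np.ndarray
    dropped_zero_sd: list[str]


@dataclasses.dataclass
class WeightPath:
    """SNP weights for each lambda, on the standardized-genotype scale."""

    lambdas: np.ndarray  # decreasing, length n_lambda
    weights: np.ndarray  # (M, n_lambda)
    alpha: float
    n_iter: np.ndarray  # coordinate-descent cycles per lambda
    objective: list[np.ndarray] | None = None  # per-cycle objective, if tracked

    def nonzero_counts(self) -> np.ndarray:
        return (self.weights != 0).sum(axis=0)

    def per_allele_weights(self, stats: StandardizationStats) -> np.ndarray:
        """Weights applicable to raw allele counts: beta_j / sd_j."""
        return self.weights / stats.sd[:, None]


@dataclasses.dataclass
class PGSVector:
    """Polygenic scores for one weight set."""

    values: np.ndarray
    lambda_index: int
    alpha: float
    tau: float | None = None


def standardize_genotypes(g: GenotypeMatrix) -> tuple[np.ndarray, StandardizationStats]:
    """Mean-impute missing calls and scale each variant to mean 0, SD 1.

    SDs use the n-1 denominator. Zero-SD variants are dropped and reported in
    the returned statistics.
    """
    counts = g.counts.astype(float)
    obs = g.counts != MISSING
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        raise ValueError("variant with no called genotypes; run QC first")
    sums = np.where(obs, counts, 0.0).sum(axis=0)
    mean = sums / n_obs
    counts = np.where(obs, counts, mean[None, :])
    sd = counts.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [v for v, k in zip(g.variants["variant_id"], keep) if not k]
    if not keep.any():
        raise ValueError("every variant has zero variance")
    X = (counts[:, keep] - mean[keep][None, :]) / sd[keep][None, :]
    stats = StandardizationStats(
        variant_ids=[v for v, k in zip(g.variants["variant_id"], keep) if k],
        mean=mean[keep],
        sd=sd[keep],
        dropped_zero_sd=dropped,
    )
    return X, stats


def make_lambda_grid(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    n_lambda: int = N_LAMBDA_DEFAULT,
    lambda_min_ratio: float = 0.01,
) -> np.ndarray:
    """Log-equispaced decreasing lambda grid from lambda_max downwards.

    ``lambda_max = max_j |x_j' y| / (n * max(alpha, 0.001))``; at this value
    the Lasso solution is exactly zero. The ``max(alpha, 0.001)`` guard keeps
    ridge (alpha = 0) finite.
    """
    n = X.shape[0]
    lam_max = float(np.max(np.abs(X.T @ y)) / (n * max(alpha, 0.001)))
    if lam_max == 0:
        raise ValueError("X'y is identically zero; cannot anchor the lambda path")
    return lam_max * lambda_min_ratio ** (np.arange(n_lambda) / (n_lambda - 1))


def _objective(X, y, beta, lam, alpha) -> float:
    r = y - X @ beta
    n = X.shape[0]
    pen = alpha * np.abs(beta).sum() + (1 - alpha) * 0.5 * float(beta @ beta)
    return float(r @ r) / (2 * n) + lam * pen


def _soft(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


def fit_path(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lambdas: np.ndarray,
    tol: float = 1e-7,
    max_iter: int = 100000,
    track_objective: bool = False,
    ridge_closed_form_max_m: int = 2000,
) -> WeightPath:
    """Fit the penalized path by cyclic coordinate descent with warm starts.

    Convergence per lambda is declared when the largest coefficient change in
    a full cycle drops below ``tol``. Ridge uses the closed form
    ``(X'X + n lambda I)^{-1} X'y`` when the design is narrow enough.
    """
    if alpha not in (0.0, 1.0):
        raise ValueError("alpha must be 1 (Lasso) or 0 (ridge)")
    lambdas = np.asarray(lambdas, dtype=float)
    if (np.diff(lambdas) >= 0).any() or (lambdas <= 0).any():
        raise ValueError("lambdas must be strictly decreasing and positive")
    n, m = X.shape
    weights = np.zeros((m, lambdas.size))
    n_iter = np.zeros(lambdas.size, dtype=int)
    objectives: list[np.ndarray] | None = [] if track_objective else None

    if alpha == 0.0 and m <= ridge_closed_form_max_m:
        G = X.T @ X
        Xty = X.T @ y
        for li, lam in enumerate(lambdas):
            weights[:, li] = np.linalg.solve(G + n * lam * np.eye(m), Xty)
            if track_objective:
                objectives.append(np.array([_objective(X, y, weights[:, li], lam, alpha)]))
        return WeightPath(lambdas=lambdas, weights=weights, alpha=alpha,
                          n_iter=n_iter, objective=objectives)

    v = (X * X).sum(axis=0) / n  # per-coordinate quadratic terms
    beta = np.zeros(m)
    r = y.astype(float).copy()
    cols = [np.ascontiguousarray(X[:, j]) for j in range(m)]
    for li, lam in enumerate(lambdas):
        thresh = lam * alpha
        denom = v + lam * (1.0 - alpha)
        obj_trace = []
        converged = False
        last_delta = np.inf
        for cycle in range(max_iter):
            delta_max = 0.0
            for j in range(m):
                bj = beta[j]
                xj = cols[j]
                z = (xj @ r) / n + v[j] * bj
                bnew = _soft(z, thresh) / denom[j]
                if bnew != bj:
                    r += xj * (bj - bnew)
                    beta[j] = bnew
                    d = abs(bnew - bj)
                    if d > delta_max:
                        delta_max = d
            if track_objective:
                obj_trace.append(_objective(X, y, beta, lam, alpha))
            last_delta = delta_max
            if delta_max < tol:
                n_iter[li] = cycle + 1
                converged = True
                break
        if not converged:
            raise SolverError(
                f"coordinate descent did not converge at lambda index {li} "
                f"(lambda={lam:g}); last max coefficient change {last_delta:g}"
            )
        weights[:, li] = beta
        if track_objective:
            objectives.append(np.asarray(obj_trace))
    return WeightPath(lambdas=lambdas, weights=weights, alpha=alpha,
                      n_iter=n_iter, objective=objectives)


def score(
    g: GenotypeMatrix,
    path: WeightPath,
    stats: StandardizationStats,
    tau: float | None = None,
) -> list[PGSVector]:
    """Score a cohort with every weight set on the path.

    ``PGS_i = sum_j beta_j (g_ij - mean_j) / sd_j`` with training-cohort
    mean/SD; missing calls are imputed to the training mean (standardized 0).
    """
    ids = list(g.variants["variant_id"])
    if ids != stats.variant_ids:
        offenders = [v for v in stats.variant_ids if v not in set(ids)][:5]
        raise ValueError(
            "cohort variants are not aligned with the training panel; "
            f"first mismatches: {offenders or 'ordering differs'}"
        )
    counts = g.counts.astype(float)
    obs = g.counts != MISSING
    counts = np.where(obs, counts, stats.mean[None, :])
    Z = (counts - stats.mean[None, :]) / stats.sd[None, :]
    scores = Z @ path.weights  # (N, n_lambda)
    return [
        PGSVector(values=scores[:, li], lambda_index=li, alpha=path.alpha, tau=tau)
        for li in range(path.weights.shape[1])
    ]


def _r2(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def select_best_lambda(scores: list[PGSVector], y: np.ndarray) -> tuple[int, float]:
    """Index of the weight set whose PGS best predicts y (squared Pearson).

    Zero-variance scores get r2 = 0. Ties break toward the larger lambda
    (earlier index on the decreasing path), i.e. the sparser Lasso model.
    """
    r2s = np.array([_r2(s.values, np.asarray(y, dtype=float)) for s in scores])
    best = float(r2s.max())
    idx = int(np.flatnonzero(r2s >= best - 1e-12)[0])
    return idx, float(r2s[idx])
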