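"""Two-stage PGS + ancestry-PC prediction with kinship-constrained splits.

The evaluation protocol: repeatedly split the target cohort 80/20 with every
member of a related cluster (pairwise kinship above the third-degree cutoff
0.0442) forced into the test fraction; in the 80% fit the stage-two linear
model

    y = b0 + b1 * PGS + b2 * PC1 + ... + b_{k+1} * PCk (+ extra covariates),

apply its coefficients to the 20%, and measure prediction accuracy as the
squared Pearson correlation between observed and predicted phenotype. The
reported accuracy per (PC-count) cell is the mean over iterations, with the
iteration SD retained for error bars.

Lambda selection happens inside each iteration's 80% by default, so the
test fraction never informs the choice of weight set; ``full_cohort_lambda=True``
instead selects the lambda once on the full cohort, reproducing protocols
that select on the entire validation cohort.
"""
from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .io import KinshipTable
from .model import PGSVector, select_best_lambda

__all__ = [
    "KINSHIP_THIRD_DEGREE",
    "DEFAULT_PC_GRID",
    "SplitScheme",
    "Stage2Model",
    "EvalResult",
    "kinship_clusters",
    "make_split",
    "fit_stage2",
    "predict",
    "predict_and_score",
    "repeat_splits",
    "stratified_eval",
]

#: Conventional third-degree-relative kinship cutoff.
KINSHIP_THIRD_DEGREE = 0.0442

DEFAULT_PC_GRID = (0, 1, 2, 3, 4, 5, 10, 20, 40)


class SplitError(ValueError):
    """Raised when a feasible kinship-constrained split does not exist."""


@dataclasses.dataclass
class SplitScheme:
    seed: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    forced_idx: np.ndarray


@dataclasses.dataclass
class Stage2Model:
    intercept: float
    coefficients: np.ndarray  # PGS first, then PCs, then extras
    names: list[str]
    k: int


@dataclasses.dataclass
class EvalResult:
    """Prediction accuracy surface over (PC count x iteration)."""

    pc_grid: tuple[int, ...]
    r2: np.ndarray  # (len(pc_grid), n_iter), NaN where skipped
    n_iter: int
    skipped: int

    @property
    def mean(self) -> np.ndarray:
        return np.nanmean(self.r2, axis=1)

    @property
    def sd(self) -> np.ndarray:
        return np.nanstd(self.r2, axis=1, ddof=1)

    def delta_r2(self, k_from: int, k_to: int) -> float:
        i, j = self.pc_grid.index(k_from), self.pc_grid.index(k_to)
        return float(self.mean[j] - self.mean[i])

    def to_dict(self) -> dict:
        return {
            str(k): {
                "mean_r2": float(m),
                "sd_r2": float(s),
                "n_iter": int(self.n_iter),
                "skipped": int(self.skipped),
            }
            for k, m, s in zip(self.pc_grid, self.mean, self.sd)
        }


def kinship_clusters(
    kinship: KinshipTable,
    ids: list[str],
    threshold: float = KINSHIP_THIRD_DEGREE,
) -> list[list[str]]:
    """Connected components of the relatedness graph (kinship strictly above
    the threshold); singleton components are omitted."""
    index = {s: i for i, s in enumerate(ids)}
    rows, cols = [], []
    for a, b, k in kinship.pairs():
        if k > threshold and a in index and b in index:
            rows.append(index[a])
            cols.append(index[b])
    if not rows:
        return []
    n = len(ids)
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    clusters: dict[int, list[str]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(ids[i])
    return sorted(
        (members for members in clusters.values() if len(members) > 1),
        key=lambda ms: ms[0],
    )


def make_split(
    ids: list[str],
    clusters: list[list[str]],
    test_frac: float = 0.2,
    seed: int = 0,
) -> SplitScheme:
    """Seeded 80/20 split with all related-cluster members forced to test."""
    n = len(ids)
    n_test = math.ceil(test_frac * n)
    index = {s: i for i, s in enumerate(ids)}
    forced = sorted({index[s] for cluster in clusters for s in cluster})
    if len(forced) > n_test:
        raise SplitError(
            f"{len(forced)} related individuals exceed the test budget of "
            f"{n_test} ({test_frac:.0%} of {n})"
        )
    rng = np.random.default_rng(seed)
    forced_set = set(forced)
    pool = np.array([i for i in range(n) if i not in forced_set])
    extra = rng.choice(pool, size=n_test - len(forced), replace=False)
    test = np.sort(np.concatenate([np.array(forced, dtype=int), extra.astype(int)]))
    mask = np.zeros(n, dtype=bool)
    mask[test] = True
    train = np.flatnonzero(~mask)
    return SplitScheme(seed=seed, train_idx=train, test_idx=test,
                       forced_idx=np.array(forced, dtype=int))


def _as_values(pgs) -> np.ndarray:
    return pgs.values if isinstance(pgs, PGSVector) else np.asarray(pgs, dtype=float)


def fit_stage2(
    y: np.ndarray,
    pgs,
    pcs: np.ndarray,
    k: int,
    extra_covariates: np.ndarray | None = None,
    extra_names: list[str] | None = None,
) -> Stage2Model:
    """OLS of y on intercept + PGS + the first k PCs (+ extra covariates)."""
    pgs = _as_values(pgs)
    pcs = np.asarray(pcs, dtype=float)
    if k > pcs.shape[1]:
        raise ValueError(f"k={k} PCs requested but only {pcs.shape[1]} available")
    cols = [np.ones(pgs.size), pgs] + [pcs[:, i] for i in range(k)]
    names = ["intercept", "PGS"] + [f"PC{i + 1}" for i in range(k)]
    if extra_covariates is not None:
        extra_covariates = np.atleast_2d(np.asarray(extra_covariates, dtype=float))
        if extra_covariates.shape[0] != pgs.size:
            extra_covariates = extra_covariates.T
        for i in range(extra_covariates.shape[1]):
            cols.append(extra_covariates[:, i])
            names.append((extra_names or [f"extra{j + 1}" for j in range(extra_covariates.shape[1])])[i])
    X = np.column_stack(cols)
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    bad = [names[i] for i in range(len(names)) if diag[i] < 1e-10 * max(diag.max(), 1.0)]
    if bad:
        raise ValueError(f"rank-deficient stage-two design; collinear column(s): {bad}")
    coef, *_ = np.linalg.lstsq(X, np.asarray(y, dtype=float), rcond=None)
    return Stage2Model(intercept=float(coef[0]), coefficients=coef[1:], names=names[1:], k=k)


def predict(model: Stage2Model, pgs, pcs: np.ndarray,
            extra_covariates: np.ndarray | None = None) -> np.ndarray:
    pgs = _as_values(pgs)
    pcs = np.asarray(pcs, dtype=float)
    cols = [pgs] + [pcs[:, i] for i in range(model.k)]
    if extra_covariates is not None:
        extra_covariates = np.atleast_2d(np.asarray(extra_covariates, dtype=float))
        if extra_covariates.shape[0] != pgs.size:
            extra_covariates = extra_covariates.T
        cols.extend(extra_covariates[:, i] for i in range(extra_covariates.shape[1]))
    X = np.column_stack(cols)
    return model.intercept + X @ model.coefficients


def predict_and_score(model: Stage2Model, y_test: np.ndarray, pgs_test,
                      pcs_test: np.ndarray,
                      extra_covariates: np.ndarray | None = None) -> float:
    """Squared Pearson correlation between observed and predicted phenotype."""
    yhat = predict(model, pgs_test, pcs_test, extra_covariates)
    y_test = np.asarray(y_test, dtype=float)
    if yhat.std() == 0 or y_test.std() == 0:
        warnings.warn("zero-variance prediction; reporting r2 = 0", stacklevel=2)
        return 0.0
    return float(np.corrcoef(y_test, yhat)[0, 1] ** 2)


def repeat_splits(
    y: np.ndarray,
    scores: list[PGSVector],
    pcs: np.ndarray,
    ids: list[str],
    clusters: list[list[str]],
    pc_grid: tuple[int, ...] = DEFAULT_PC_GRID,
    n_iter: int = 1000,
    base_seed: int = 0,
    test_frac: float = 0.2,
    full_cohort_lambda: bool = False,
    extra_covariates: np.ndarray | None = None,
    max_skip_frac: float = 0.01,
) -> EvalResult:
    """Iterate kinship-constrained splits and aggregate out-of-split accuracy.

    Iteration ``i`` uses seed ``base_seed + i``. Within each iteration the
    best lambda is chosen on the 80% (or once on the full cohort when
    ``full_cohort_lambda``), the stage-two model is fitted for every PC count in
    ``pc_grid``, and accuracy is measured on the 20%.
    """
    y = np.asarray(y, dtype=float)
    pcs = np.asarray(pcs, dtype=float)
    pc_grid = tuple(k for k in pc_grid if k <= pcs.shape[1])
    score_mat = np.column_stack([s.values for s in scores])
    r2 = np.full((len(pc_grid), n_iter), np.nan)
    skipped = 0
    global_idx = None
    if full_cohort_lambda:
        global_idx, _ = select_best_lambda(scores, y)
    for i in range(n_iter):
        try:
            split = make_split(ids, clusters, test_frac, seed=base_seed + i)
            tr, te = split.train_idx, split.test_idx
            if full_cohort_lambda:
                li = global_idx
            else:
                sub_scores = [
                    PGSVector(values=score_mat[tr, j], lambda_index=j, alpha=scores[j].alpha)
                    for j in range(score_mat.shape[1])
                ]
                li, _ = select_best_lambda(sub_scores, y[tr])
            pgs = score_mat[:, li]
            ex_tr = extra_covariates[tr] if extra_covariates is not None else None
            ex_te = extra_covariates[te] if extra_covariates is not None else None
            for ki, k in enumerate(pc_grid):
                m = fit_stage2(y[tr], pgs[tr], pcs[tr], k, ex_tr)
                r2[ki, i] = predict_and_score(m, y[te], pgs[te], pcs[te], ex_te)
        except (SplitError, ValueError) as exc:
            skipped += 1
            warnings.warn(f"iteration {i} skipped: {exc}", stacklevel=2)
    if skipped > max_skip_frac * n_iter:
        raise RuntimeError(
            f"{skipped}/{n_iter} evaluation iterations failed; aborting"
        )
    return EvalResult(pc_grid=pc_grid, r2=r2, n_iter=n_iter, skipped=skipped)


def stratified_eval(
    y: np.ndarray,
    scores: list[PGSVector],
    pcs: np.ndarray,
    ids: list[str],
    kinship: KinshipTable,
    labels: np.ndarray,
    group_names: dict[int, str] | None = None,
    min_group_size: int = 50,
    kinship_threshold: float = KINSHIP_THIRD_DEGREE,
    **kwargs,
) -> dict[str, tuple[int, EvalResult]]:
    """Run :func:`repeat_splits` independently within each predominant-
    ancestry subgroup; groups below ``min_group_size`` are skipped."""
    labels = np.asarray(labels)
    out: dict[str, tuple[int, EvalResult]] = {}
    for lab in sorted(set(labels.tolist())):
        name = (group_names or {}).get(lab, str(lab))
        idx = np.flatnonzero(labels == lab)
        if idx.size < min_group_size:
            warnings.warn(
                f"ancestry group {name} has {idx.size} members "
                f"(< {min_group_size}); skipped",
                stacklevel=2,
            )
            continue
        sub_ids = [ids[i] for i in idx]
        sub_scores = [
            PGSVector(values=s.values[idx], lambda_index=s.lambda_index, alpha=s.alpha, tau=s.tau)
            for s in scores
        ]
        clusters = kinship_clusters(kinship, sub_ids, threshold=kinship_threshold)
        res = repeat_splits(
            np.asarray(y, dtype=float)[idx], sub_scores, np.asarray(pcs)[idx],
            sub_ids, clusters, **kwargs,
        )
        out[name] = (int(idx.size), res)
    return out
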