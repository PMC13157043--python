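"""Genotype PCA, supervised admixture-proportion estimation, and
predominant-ancestry classification.

PCA operates on the column-standardized, mean-imputed genotype matrix via an
exact eigendecomposition of whichever Gram matrix (samples x samples or
variants x variants) is smaller, which is deterministic and cheap at the
cohort sizes this package targets. Sample coordinates are left singular
vectors scaled by their singular values, so leading PCs track continental
ancestry in structured cohorts.

Admixture proportions are estimated per sample by maximizing the binomial
log-likelihood

    L(q_i) = sum_j [ g_ij log pi_ij + (2 - g_ij) log(1 - pi_ij) ],
    pi_ij = sum_k q_ik p_kj,

over the K-simplex with the ancestral allele frequencies ``p_kj`` held fixed
(the supervised setting: in simulation they are ground truth, for real data
they must be supplied). The maximization uses expectation-maximization
multiplicative updates, which are monotone in the likelihood and preserve
the simplex exactly; initialization is the uniform 1/K point, so estimates
are deterministic.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .io import MISSING, GenotypeMatrix
from .model import standardize_genotypes
from .simulate import AncestralModel

__all__ = ["PCResult", "AncestryProfile", "compute_pcs", "estimate_ancestry_proportions", "classify_predominant"]


@dataclasses.dataclass
class PCResult:
    """Top principal components of a genotype matrix."""

    coords: np.ndarray  # (N, P), PC i scaled by its singular value
    explained_variance_fraction: np.ndarray  # (P,), non-increasing
    loadings: np.ndarray  # (M_kept, P), unit-norm variant loadings
    variant_ids: list[str]

    @property
    def n_pcs(self) -> int:
        return self.coords.shape[1]

    def frame(self, ids: list[str]) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coords, columns=[f"PC{i + 1}" for i in range(self.n_pcs)]
        )
        df.insert(0, "IID", ids)
        return df


@dataclasses.dataclass
class AncestryProfile:
    """Per-sample admixture proportions and predominant-ancestry labels."""

    ids: list[str]
    proportions: np.ndarray  # (N, K), rows on the simplex
    labels: np.ndarray  # (N,), argmax component index
    true_proportions: np.ndarray | None = None

    def frame(self) -> pd.DataFrame:
        K = self.proportions.shape[1]
        df = pd.DataFrame(self.proportions, columns=[f"Q{k + 1}" for k in range(K)])
        df.insert(0, "IID", self.ids)
        df["LABEL"] = self.labels
        return df


def compute_pcs(g: GenotypeMatrix, n_pcs: int) -> PCResult:
    """Exact top-``n_pcs`` PCA of the standardized genotype matrix.

    Sign convention: on each PC the variant loading of largest absolute value
    is made positive, so results are reproducible across platforms. Requests
    beyond the matrix rank are truncated with a warning.
    """
    Z, stats = standardize_genotypes(g)
    n, m = Z.shape
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    n_pcs = min(n_pcs, n, m)
    total_var = float((Z * Z).sum())

    if n <= m:
        G = Z @ Z.T
        k = min(n_pcs, n)
        evals, evecs = sla.eigh(G, subset_by_index=[n - k, n - 1])
        order = np.argsort(evals)[::-1]
        evals = evals[order]
        U = evecs[:, order]
    else:
        C = Z.T @ Z
        k = min(n_pcs, m)
        evals, evecs = sla.eigh(C, subset_by_index=[m - k, m - 1])
        order = np.argsort(evals)[::-1]
        evals = evals[order]
        V = evecs[:, order]
        with np.errstate(invalid="ignore", divide="ignore"):
            U = (Z @ V) / np.sqrt(np.maximum(evals, 1e-300))[None, :]

    evals = np.maximum(evals, 0.0)
    positive = evals > max(evals.max(), 1.0) * 1e-12
    if positive.sum() < n_pcs:
        warnings.warn(
            f"requested {n_pcs} PCs but rank supports {int(positive.sum())}; truncating",
            stacklevel=2,
        )
        evals = evals[positive]
        U = U[:, positive]
    sv = np.sqrt(evals)

    # variant loadings, then the deterministic sign convention
    with np.errstate(invalid="ignore", divide="ignore"):
        V = Z.T @ U / np.where(sv > 0, sv, 1.0)[None, :]
    for i in range(V.shape[1]):
        jmax = int(np.argmax(np.abs(V[:, i])))
        if V[jmax, i] < 0:
            V[:, i] = -V[:, i]
            U[:, i] = -U[:, i]
    coords = U * sv[None, :]
    evf = evals / total_var if total_var > 0 else np.zeros_like(evals)
    return PCResult(
        coords=coords,
        explained_variance_fraction=evf,
        loadings=V,
        variant_ids=stats.variant_ids,
    )


def estimate_ancestry_proportions(
    g: GenotypeMatrix,
    model: AncestralModel,
    tol: float = 1e-8,
    max_iter: int = 10000,
    true_proportions: np.ndarray | None = None,
) -> AncestryProfile:
    """Supervised per-sample admixture MLE with known ancestral frequencies."""
    if model.M != g.n_variants:
        raise ValueError("ancestral model and genotypes disagree on variant count")
    P = model.ancestral_freqs  # (K, M)
    K = model.K
    counts = g.counts.astype(float)
    obs = (g.counts != MISSING).astype(float)
    counts = np.where(obs > 0, counts, 0.0)
    n = g.n_samples

    if K == 1:
        q = np.ones((n, 1))
        return AncestryProfile(ids=list(g.samples), proportions=q,
                               labels=np.zeros(n, dtype=int),
                               true_proportions=true_proportions)

    q = np.full((n, K), 1.0 / K)
    two_m = 2.0 * obs.sum(axis=1, keepdims=True)  # per-sample called allele copies

    def loglik(pi: np.ndarray) -> float:
        return float(
            (obs * (counts * np.log(pi) + (2.0 - counts) * np.log1p(-pi))).sum()
        )

    pi = q @ P
    ll = loglik(pi)
    for it in range(max_iter):
        # E-step responsibilities folded into the multiplicative update
        a = counts / pi  # weight on allele-1 copies
        b = (2.0 - counts) / (1.0 - pi)  # weight on allele-2 copies
        upd = (obs * a) @ P.T + (obs * b) @ (1.0 - P).T  # (N, K)
        q = q * upd / two_m
        q = q / q.sum(axis=1, keepdims=True)  # guard drift
        pi = q @ P
        ll_new = loglik(pi)
        # relative tolerance: log-likelihoods scale with N * M
        if abs(ll_new - ll) < tol * max(1.0, abs(ll_new)):
            ll = ll_new
            break
        ll = ll_new
    else:
        raise RuntimeError(
            f"ancestry estimation did not converge within {max_iter} iterations"
        )
    labels = classify_predominant_rows(q)
    return AncestryProfile(ids=list(g.samples), proportions=q, labels=labels,
                           true_proportions=true_proportions)


def classify_predominant_rows(q: np.ndarray) -> np.ndarray:
    """Argmax component per row; exact ties break to the lowest index."""
    return np.argmax(q, axis=1)


def classify_predominant(profile: AncestryProfile) -> np.ndarray:
    """Predominant-ancestry label per sample (maximum admixture proportion)."""
    return classify_predominant_rows(profile.proportions)
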