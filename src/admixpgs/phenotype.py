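"""Trait residualization, standardization and outlier exclusion.

Two phenotype configurations are first-class:

* **training** — residualize the raw trait on age, sex and the leading
  genotype PCs (the PC count is configurable) before weight estimation;
* **evaluation** — residualize on age and sex only, so that ancestry PCs
  retain predictable variance in the two-stage prediction model.

Both configurations then standardize the residuals, exclude samples with
|z| >= 4 in a single pass (the boundary value is excluded), and
re-standardize the survivors to mean 0, SD 1. Standard deviations use the
n-1 denominator throughout.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = ["PreparedPhenotype", "residualize", "standardize_and_filter", "prepare_phenotype"]

#: |z| at or above which a sample is excluded as an extreme outlier.
OUTLIER_Z = 4.0


class DesignError(ValueError):
    """Raised for rank-deficient or otherwise unusable regression designs."""


@dataclasses.dataclass
class PreparedPhenotype:
    """Standardized residual trait for the retained samples.

    ``excluded`` is aligned with the *input* sample order; ``z`` and ``ids``
    cover retained samples only.
    """

    ids: list[str]
    z: np.ndarray
    excluded: np.ndarray  # boolean mask over input order
    reasons: list[str]  # reason code per excluded sample, input order
    covariates: list[str]
    coefficients: np.ndarray

    @property
    def n_excluded(self) -> int:
        return int(self.excluded.sum())

    def frame(self) -> pd.DataFrame:
        """Long-format export (IID, Z, EXCLUDED, REASON) over retained samples."""
        return pd.DataFrame(
            {"IID": self.ids, "Z": self.z, "EXCLUDED": 0, "REASON": ""}
        )


def _design_matrix(pheno: pd.DataFrame, covariates: list[str], pcs: np.ndarray | None):
    cols = [np.ones(len(pheno))]
    names = ["intercept"]
    for c in covariates:
        if c not in pheno.columns:
            raise DesignError(f"covariate {c!r} not present in phenotype table")
        cols.append(pheno[c].to_numpy(dtype=float))
        names.append(c)
    if pcs is not None:
        pcs = np.asarray(pcs, dtype=float)
        for i in range(pcs.shape[1]):
            cols.append(pcs[:, i])
            names.append(f"PC{i + 1}")
    X = np.column_stack(cols)
    return X, names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    # pinpoint collinear columns via the QR diagonal
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    scale = max(diag.max(), 1.0)
    bad = [names[i] for i in range(len(names)) if diag[i] < 1e-10 * scale]
    if bad:
        raise DesignError(f"rank-deficient design; collinear column(s): {bad}")


def residualize(
    pheno: pd.DataFrame,
    trait: str = "HEIGHT",
    covariates: list[str] | None = None,
    pcs: np.ndarray | None = None,
) -> np.ndarray:
    """OLS residuals of the trait on intercept + covariates (+ PC columns).

    The returned residuals are orthogonal to every covariate column.
    """
    covariates = list(covariates or [])
    if trait not in pheno.columns:
        raise DesignError(f"trait column {trait!r} not present")
    y = pheno[trait].to_numpy(dtype=float)
    X, names = _design_matrix(pheno, covariates, pcs)
    _check_full_rank(X, names)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def standardize_and_filter(residuals: np.ndarray, ids: list[str] | None = None) -> PreparedPhenotype:
    """Standardize residuals, exclude |z| >= 4 outliers once, re-standardize.

    The exclusion is a single pass: one z computation, one cut, one
    re-standardization — it is deliberately not iterated to convergence.
    """
    x = np.asarray(residuals, dtype=float)
    if x.size < 3:
        raise DesignError("need at least 3 phenotype values")
    if ids is None:
        ids = [str(i) for i in range(x.size)]
    sd = x.std(ddof=1)
    if sd == 0:
        raise DesignError("zero-variance phenotype")
    z = (x - x.mean()) / sd
    excluded = np.abs(z) >= OUTLIER_Z
    keep = ~excluded
    survivors = x[keep]
    sd2 = survivors.std(ddof=1)
    if sd2 == 0:
        raise DesignError("zero-variance phenotype after outlier exclusion")
    z_out = (survivors - survivors.mean()) / sd2
    reasons = ["outlier_z_ge_4" if e else "" for e in excluded]
    return PreparedPhenotype(
        ids=[i for i, k in zip(ids, keep) if k],
        z=z_out,
        excluded=excluded,
        reasons=reasons,
        covariates=[],
        coefficients=np.array([]),
    )


def prepare_phenotype(
    pheno: pd.DataFrame,
    trait: str = "HEIGHT",
    covariates: list[str] = ("AGE", "SEX"),
    pcs: np.ndarray | None = None,
) -> PreparedPhenotype:
    """Residualize then standardize-and-filter, the standard preparation path."""
    res = residualize(pheno, trait, list(covariates), pcs=pcs)
    prepared = standardize_and_filter(res, ids=pheno["IID"].tolist())
    prepared.covariates = list(covariates) + (
        [f"PC{i + 1}" for i in range(pcs.shape[1])] if pcs is not None else []
    )
    return prepared
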