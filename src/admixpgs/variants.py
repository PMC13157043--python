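"""Variant QC, cross-dataset harmonization and p-value thresholding.

QC filters (applied in order, first failure recorded as the drop reason):

1. missingness — drop variants with more than ``max_missing`` missing calls;
2. MAF — drop variants with minor-allele frequency below ``min_maf``
   (computed from non-missing calls);
3. HWE — drop variants whose exact Hardy-Weinberg test p-value falls below
   ``hwe_p_min``.

Harmonization keys on variant ID and verifies allele pairs across summary
statistics and both genotype cohorts, resolving effect/other swaps (flipping
the effect sign) and strand complements; self-complementary (A/T, C/G)
variants are strand-ambiguous and dropped unconditionally.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .io import MISSING, GenotypeMatrix, ValidationError

__all__ = [
    "DEFAULT_THRESHOLDS",
    "HarmonizedPanel",
    "hwe_exact_test",
    "qc_filter",
    "harmonize",
    "threshold_select",
    "oriented_counts",
]

#: Discovery p-value thresholds swept by the pipeline.
DEFAULT_THRESHOLDS = (1e-16, 1e-12, 1e-8, 1e-4, 1e-3, 1e-2, 1e-1)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact two-sided Hardy-Weinberg equilibrium test.

    Conditional on the observed allele counts, the p-value is the total
    probability of all heterozygote counts whose conditional probability does
    not exceed that of the observed count.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValidationError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValidationError("need at least one genotyped individual")
    n_a = 2 * n_hom1 + n_het
    n_b = 2 * n_hom2 + n_het
    minor = min(n_a, n_b)
    if minor == 0:
        return 1.0
    hets = np.arange(minor % 2, minor + 1, 2)
    # log P(h) up to the shared normalizer, from the conditional distribution
    # of the heterozygote count given the minor-allele count
    logw = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln((n_a - hets) / 2 + 1)
        - gammaln((n_b - hets) / 2 + 1)
    )
    logp = logw - logsumexp(logw)
    obs_idx = int(np.searchsorted(hets, n_het))
    log_obs = logp[obs_idx]
    # relative tolerance admits exact ties computed along different float paths
    include = logp <= log_obs + 1e-10
    return float(min(np.exp(logsumexp(logp[include])), 1.0))


def _genotype_tallies(counts: np.ndarray):
    """Per-variant (hom_allele1, het, hom_allele2, missing) tallies."""
    n_hom1 = (counts == 2).sum(axis=0)
    n_het = (counts == 1).sum(axis=0)
    n_hom2 = (counts == 0).sum(axis=0)
    n_miss = (counts == MISSING).sum(axis=0)
    return n_hom1, n_het, n_hom2, n_miss


def qc_filter(
    g: GenotypeMatrix,
    max_missing: float = 0.10,
    min_maf: float = 0.001,
    hwe_p_min: float = 1e-10,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop variants failing missingness, MAF or HWE filters.

    Returns the filtered matrix and a per-variant report frame with columns
    ``variant_id``, ``kept`` and ``reason`` (empty when kept; otherwise the
    first failing filter among ``missingness``, ``maf``, ``hwe``).
    """
    n = g.n_samples
    n_hom1, n_het, n_hom2, n_miss = _genotype_tallies(g.counts)
    n_called = n - n_miss
    reasons = np.array([""] * g.n_variants, dtype=object)

    miss_frac = n_miss / n
    fail_miss = miss_frac > max_missing
    reasons[fail_miss] = "missingness"

    with np.errstate(invalid="ignore", divide="ignore"):
        freq1 = np.where(n_called > 0, (2 * n_hom1 + n_het) / np.maximum(2 * n_called, 1), 0.0)
    maf = np.minimum(freq1, 1 - freq1)
    fail_maf = (maf < min_maf) & ~fail_miss
    reasons[fail_maf] = "maf"

    undecided = np.flatnonzero(~fail_miss & ~fail_maf)
    for j in undecided:
        if n_called[j] == 0:
            continue  # already impossible: zero calls implies missingness failure
        p = hwe_exact_test(int(n_hom1[j]), int(n_het[j]), int(n_hom2[j]))
        if p < hwe_p_min:
            reasons[j] = "hwe"

    kept = reasons == ""
    report = pd.DataFrame(
        {
            "variant_id": g.variants["variant_id"],
            "kept": kept,
            "reason": reasons,
        }
    )
    if not kept.any():
        warnings.warn("qc_filter removed every variant", stacklevel=2)
    filtered = g.select_variants(np.flatnonzero(kept))
    return filtered, report


@dataclasses.dataclass
class HarmonizedPanel:
    """Variants present in summary stats and both genotype cohorts, with the
    discovery effect re-expressed on the training cohort's allele1."""

    table: pd.DataFrame
    # columns: variant_id, effect_allele, beta, se, pvalue,
    #          sign_flip, strand_flip, target_flip

    def __len__(self) -> int:
        return len(self.table)

    @property
    def pvalues(self) -> np.ndarray:
        return self.table["pvalue"].to_numpy()


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


def _orient(a1: str, a2: str, b1: str, b2: str):
    """How does allele pair (b1, b2) map onto (a1, a2)?

    Returns (swap, strand) or None if incompatible. ``swap`` means effect and
    other allele are interchanged (effect sign flips); ``strand`` means the
    pair is on the opposite strand.
    """
    if (b1, b2) == (a1, a2):
        return False, False
    if (b1, b2) == (a2, a1):
        return True, False
    c1, c2 = _COMPLEMENT[b1], _COMPLEMENT[b2]
    if (c1, c2) == (a1, a2):
        return False, True
    if (c1, c2) == (a2, a1):
        return True, True
    return None


def harmonize(
    stats: pd.DataFrame,
    train: GenotypeMatrix,
    target: GenotypeMatrix,
) -> HarmonizedPanel:
    """Intersect summary stats with both cohorts and harmonize alleles.

    The harmonized effect allele is the training cohort's allele1; ``beta``
    is sign-adjusted accordingly. ``target_flip`` marks variants whose target
    cohort counts must be reflected (g -> 2 - g) to count the same allele.
    """
    t_idx = {v: i for i, v in enumerate(train.variants["variant_id"])}
    g_idx = {v: i for i, v in enumerate(target.variants["variant_id"])}

    rows = []
    seen = set()
    dropped_dup = set()
    for rec in stats.itertuples(index=False):
        vid = rec.SNP
        if vid in seen:
            dropped_dup.add(vid)
            continue
        seen.add(vid)
        if vid not in t_idx or vid not in g_idx:
            continue
        s1, s2 = rec.A1, rec.A2
        if _is_ambiguous(s1, s2):
            continue
        ti = t_idx[vid]
        t1 = train.variants["allele1"].iat[ti]
        t2 = train.variants["allele2"].iat[ti]
        if _is_ambiguous(t1, t2):
            continue
        o_train = _orient(t1, t2, s1, s2)
        if o_train is None:
            continue
        swap, strand = o_train
        gi = g_idx[vid]
        u1 = target.variants["allele1"].iat[gi]
        u2 = target.variants["allele2"].iat[gi]
        o_target = _orient(t1, t2, u1, u2)
        if o_target is None:
            continue
        target_swap, _ = o_target
        rows.append(
            {
                "variant_id": vid,
                "effect_allele": t1,
                "beta": -rec.BETA if swap else rec.BETA,
                "se": rec.SE,
                "pvalue": rec.P,
                "sign_flip": swap,
                "strand_flip": strand,
                "target_flip": target_swap,
            }
        )
    # duplicates are dropped entirely (first occurrence included above is fine
    # only if unique; remove IDs that occurred more than once)
    table = pd.DataFrame(
        rows,
        columns=[
            "variant_id",
            "effect_allele",
            "beta",
            "se",
            "pvalue",
            "sign_flip",
            "strand_flip",
            "target_flip",
        ],
    )
    if dropped_dup:
        table = table[~table["variant_id"].isin(dropped_dup)].reset_index(drop=True)
    if len(table) == 0:
        raise ValidationError(
            "empty intersection between summary statistics and cohorts; "
            "check that variant ID schemes match"
        )
    return HarmonizedPanel(table=table)


def threshold_select(panel: HarmonizedPanel, tau: float) -> HarmonizedPanel:
    """Subset the panel to variants with discovery p-value strictly below tau."""
    if not 0.0 < tau <= 1.0:
        raise ValidationError("threshold must lie in (0, 1]")
    keep = panel.table["pvalue"] < tau
    if not keep.any():
        warnings.warn(f"no variants pass p < {tau:g}", stacklevel=2)
    return HarmonizedPanel(table=panel.table[keep].reset_index(drop=True))


def oriented_counts(panel: HarmonizedPanel, g: GenotypeMatrix, target: bool = False) -> GenotypeMatrix:
    """Subset a cohort to the panel's variants, in panel order, counting the
    harmonized effect allele (reflecting counts where the panel says so)."""
    idx = {v: i for i, v in enumerate(g.variants["variant_id"])}
    missing_ids = [v for v in panel.table["variant_id"] if v not in idx]
    if missing_ids:
        raise ValidationError(f"cohort lacks panel variants, e.g. {missing_ids[:5]}")
    order = np.array([idx[v] for v in panel.table["variant_id"]], dtype=int)
    sub = g.select_variants(order)
    if target:
        flip = panel.table["target_flip"].to_numpy(dtype=bool)
        if flip.any():
            flipped = sub.counts.copy()
            cols = np.flatnonzero(flip)
            vals = flipped[:, cols]
            flipped[:, cols] = np.where(vals == MISSING, MISSING, 2 - vals)
            variants = sub.variants.copy()
            a1 = variants.loc[cols, "allele1"].copy()
            variants.loc[cols, "allele1"] = variants.loc[cols, "allele2"]
            variants.loc[cols, "allele2"] = a1
            sub = GenotypeMatrix(samples=sub.samples, variants=variants, counts=flipped)
    return sub
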