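"""Synthetic cohort generator: ancestral allele frequencies, admixture,
genotypes, family structure, trait models and a simulated discovery GWAS.

The generator emulates the study design this package targets: a large
ancestry-homogeneous *discovery* cohort that yields GWAS summary statistics,
an ancestry-homogeneous *training* cohort for penalized-regression weight
estimation, and an admixed *target* cohort with three-way continental
ancestry, ancestry-associated trait variation, and sibling pairs.

Ancestral allele frequencies follow the Balding-Nichols model: for each
variant a shared base frequency ``p_j ~ Uniform(0.05, 0.95)`` drifts in each
ancestral population ``k`` as

    p_kj ~ Beta(p_j (1 - F_k) / F_k,  (1 - p_j)(1 - F_k) / F_k)

so that E[p_kj] = p_j and Var[p_kj] = F_k p_j (1 - p_j).

Ancestry components are ordered (European, Amerindian, African) throughout;
admixture proportion rows live on the K-simplex. SNPs are simulated without
linkage disequilibrium by default; :func:`add_ld_partners` provides a
duplicate-with-noise mode that creates correlated predictor pairs so the
penalized solver can be exercised on non-orthogonal designs.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import MISSING, GenotypeMatrix, KinshipTable

__all__ = [
    "AncestralModel",
    "CohortSpec",
    "TraitModel",
    "SimulatedCohort",
    "ANCESTRY_LABELS",
    "EUR_ALPHA",
    "ADMIXED_MIXTURE",
    "DEFAULT_FST",
    "draw_ancestral_frequencies",
    "draw_admixture_proportions",
    "admixed_mixture_proportions",
    "simulate_genotypes",
    "add_sib_pairs",
    "add_ld_partners",
    "simulate_phenotype",
    "run_discovery_gwas",
]

#: Component order used by every preset and default.
ANCESTRY_LABELS = ("EUR", "AMR", "AFR")

#: Continental-scale differentiation defaults, one F_ST per component.
DEFAULT_FST = (0.10, 0.12, 0.16)

#: Dirichlet concentration for an ancestry-homogeneous European-like cohort.
EUR_ALPHA = (100.0, 0.1, 0.1)

#: Admixed-cohort mixture: per-individual Dirichlet alphas drawn from three
#: sub-group presets (mainland-like, Cuban-like, Caribbean-like) with the
#: given mixing weights, qualitatively emulating a US Latino cohort in which
#: mainland groups carry high Amerindian ancestry, Cuban groups high European
#: ancestry, and Caribbean groups elevated African ancestry.
ADMIXED_MIXTURE = (
    ((2.0, 6.0, 1.0), 0.4),
    ((8.0, 1.0, 1.0), 0.3),
    ((5.0, 1.0, 4.0), 0.3),
)


class ParameterError(ValueError):
    """Raised for out-of-domain simulation parameters."""


@dataclasses.dataclass
class AncestralModel:
    """Balding-Nichols ancestral frequency model for K populations."""

    base_freqs: np.ndarray  # (M,)
    fst: np.ndarray  # (K,)
    ancestral_freqs: np.ndarray  # (K, M)

    @property
    def K(self) -> int:
        return self.ancestral_freqs.shape[0]

    @property
    def M(self) -> int:
        return self.ancestral_freqs.shape[1]

    def __post_init__(self) -> None:
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        self.fst = np.asarray(self.fst, dtype=float)
        self.ancestral_freqs = np.asarray(self.ancestral_freqs, dtype=float)
        if self.K < 2 or self.M < 1:
            raise ParameterError("need K >= 2 ancestral populations and M >= 1 variants")
        for name, arr in (("base_freqs", self.base_freqs), ("ancestral_freqs", self.ancestral_freqs)):
            if ((arr <= 0) | (arr >= 1)).any():
                raise ParameterError(f"{name} must lie strictly inside (0, 1)")


@dataclasses.dataclass
class CohortSpec:
    """Size, admixture concentration and family structure of one cohort."""

    n: int
    dirichlet_alpha: tuple[float, ...]
    n_sib_pairs: int = 0
    label: str = "cohort"

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ParameterError("Dirichlet alpha entries must be > 0")
        if self.n_sib_pairs < 0 or self.n <= 2 * self.n_sib_pairs:
            raise ParameterError("need n > 2 * n_sib_pairs")


@dataclasses.dataclass
class TraitModel:
    """Generative model for the quantitative trait.

    ``h2`` is the proportion of (pre-covariate) trait variance carried by the
    causal allele counts; ``ancestry_shift`` is in trait-SD units per unit
    ancestry proportion; ``age_effect`` and ``sex_effect`` are in trait-SD
    units per SD of age and per unit of sex respectively.
    """

    m_causal: int
    h2: float
    ancestry_shift: tuple[float, ...] = (0.0, 0.0, 0.0)
    age_effect: float = 0.3
    sex_effect: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 < 1.0:
            raise ParameterError("h2 must lie in [0, 1)")
        if self.m_causal < 0:
            raise ParameterError("m_causal must be >= 0")


@dataclasses.dataclass
class SimulatedCohort:
    """A fully realized cohort: genotypes, truth, phenotypes, kinship."""

    genotypes: GenotypeMatrix
    true_q: np.ndarray  # (N, K) admixture proportions
    phenotypes: pd.DataFrame | None = None
    kinship: KinshipTable = dataclasses.field(default_factory=KinshipTable)
    true_betas: np.ndarray | None = None
    label: str = "cohort"


def _variant_table(M: int) -> pd.DataFrame:
    # deterministic biallelic non-ambiguous SNVs (A/G) on chromosome 1
    return pd.DataFrame(
        {
            "variant_id": [f"snp{j:06d}" for j in range(M)],
            "chromosome": "1",
            "position": np.arange(1, M + 1) * 1000,
            "allele1": "A",
            "allele2": "G",
        }
    )


def draw_ancestral_frequencies(
    M: int,
    fst: tuple[float, ...] = DEFAULT_FST,
    seed: int = 0,
) -> AncestralModel:
    """Draw base and population-specific allele frequencies (Balding-Nichols)."""
    fst = np.asarray(fst, dtype=float)
    if ((fst <= 0) | (fst >= 1)).any():
        raise ParameterError("each F_ST must lie in (0, 1)")
    if M < 1:
        raise ParameterError("M must be >= 1")
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, size=M)
    scale = (1.0 - fst) / fst  # (K,)
    a = p[None, :] * scale[:, None]
    b = (1.0 - p)[None, :] * scale[:, None]
    pk = rng.beta(a, b)
    pk = np.clip(pk, 0.001, 0.999)
    return AncestralModel(base_freqs=p, fst=fst, ancestral_freqs=pk)


def draw_admixture_proportions(spec: CohortSpec, K: int, seed: int = 0) -> np.ndarray:
    """Draw i.i.d. Dirichlet admixture rows for a cohort."""
    if len(spec.dirichlet_alpha) != K:
        raise ParameterError(
            f"spec has {len(spec.dirichlet_alpha)} alpha entries, expected K={K}"
        )
    rng = np.random.default_rng(seed)
    return rng.dirichlet(spec.dirichlet_alpha, size=spec.n)


def admixed_mixture_proportions(
    n: int,
    mixture=ADMIXED_MIXTURE,
    seed: int = 0,
) -> np.ndarray:
    """Admixture rows for a heterogeneous cohort: each individual's Dirichlet
    alpha is drawn from sub-group presets with the given mixing weights."""
    rng = np.random.default_rng(seed)
    alphas = np.array([m[0] for m in mixture], dtype=float)
    weights = np.array([m[1] for m in mixture], dtype=float)
    weights = weights / weights.sum()
    groups = rng.choice(len(mixture), size=n, p=weights)
    q = np.empty((n, alphas.shape[1]))
    for gi in range(len(mixture)):
        mask = groups == gi
        if mask.any():
            q[mask] = rng.dirichlet(alphas[gi], size=int(mask.sum()))
    return q


def simulate_genotypes(
    model: AncestralModel,
    q: np.ndarray,
    seed: int = 0,
    sample_prefix: str = "s",
    block: int = 4096,
) -> GenotypeMatrix:
    """Draw genotypes g_ij ~ Binomial(2, pi_ij) with pi = q @ ancestral_freqs.

    No missingness is generated; inject it separately when exercising QC.
    """
    q = np.asarray(q, dtype=float)
    if q.ndim != 2 or q.shape[1] != model.K:
        raise ParameterError(f"q must be (n, {model.K})")
    rng = np.random.default_rng(seed)
    n = q.shape[0]
    counts = np.empty((n, model.M), dtype=np.int8)
    for start in range(0, n, block):
        stop = min(start + block, n)
        pi = q[start:stop] @ model.ancestral_freqs
        counts[start:stop] = rng.binomial(2, pi).astype(np.int8)
    samples = [f"{sample_prefix}{i:06d}" for i in range(n)]
    return GenotypeMatrix(samples=samples, variants=_variant_table(model.M), counts=counts)


def add_sib_pairs(
    cohort: SimulatedCohort,
    n_pairs: int,
    model: AncestralModel,
    seed: int = 0,
) -> SimulatedCohort:
    """Replace the last ``2 * n_pairs`` individuals with full-sibling pairs.

    For each pair, two unobserved parents are drawn with the pair's shared
    admixture row and the siblings are formed by independent Mendelian
    transmission of one allele per parent per SNP. The kinship table gains
    each pair at coefficient 0.25; parents are not retained.
    """
    if n_pairs < 1:
        raise ParameterError("n_pairs must be >= 1")
    n = cohort.genotypes.n_samples
    if 2 * n_pairs > n:
        raise ParameterError("more sibling slots than cohort members")
    rng = np.random.default_rng(seed)
    counts = cohort.genotypes.counts.copy()
    q = cohort.true_q.copy()
    kinship = KinshipTable(dict(((a, b), k) for a, b, k in cohort.kinship.pairs()))
    samples = cohort.genotypes.samples
    for p in range(n_pairs):
        i1, i2 = n - 2 * n_pairs + 2 * p, n - 2 * n_pairs + 2 * p + 1
        q_pair = q[i1]
        q[i2] = q_pair
        pi = q_pair @ model.ancestral_freqs  # (M,)
        parents = rng.binomial(2, np.tile(pi, (2, 1)))  # (2, M) parental counts
        # each child receives one allele per parent, Bernoulli(g_parent / 2)
        for child in (i1, i2):
            transmitted = rng.random((2, model.M)) < parents / 2.0
            counts[child] = transmitted.sum(axis=0).astype(np.int8)
        kinship.add(samples[i1], samples[i2], 0.25)
    genotypes = GenotypeMatrix(
        samples=list(samples), variants=cohort.genotypes.variants.copy(), counts=counts
    )
    return dataclasses.replace(
        cohort, genotypes=genotypes, true_q=q, kinship=kinship
    )


def add_ld_partners(
    g: GenotypeMatrix,
    n_partners: int,
    flip_prob: float = 0.1,
    seed: int = 0,
) -> GenotypeMatrix:
    """Duplicate-with-noise LD mode: append copies of the first ``n_partners``
    variants in which each allele is flipped with probability ``flip_prob``,
    creating correlated predictor pairs without haplotype machinery."""
    if not 0.0 <= flip_prob <= 0.5:
        raise ParameterError("flip_prob must lie in [0, 0.5]")
    if n_partners > g.n_variants:
        raise ParameterError("n_partners exceeds variant count")
    rng = np.random.default_rng(seed)
    src = g.counts[:, :n_partners].astype(np.int16)
    # per allele copy, flip towards the complementary count with prob flip_prob
    flips = rng.binomial(src.clip(min=0), flip_prob) - rng.binomial(
        (2 - src).clip(min=0), flip_prob
    )
    partner = np.where(src == MISSING, MISSING, np.clip(src - flips, 0, 2)).astype(np.int8)
    extra = g.variants.iloc[:n_partners].copy()
    extra["variant_id"] = extra["variant_id"] + "_ld"
    extra["position"] = extra["position"] + 1
    variants = pd.concat([g.variants, extra], ignore_index=True)
    counts = np.concatenate([g.counts, partner], axis=1)
    return GenotypeMatrix(samples=list(g.samples), variants=variants, counts=counts)


def simulate_phenotype(
    cohort: SimulatedCohort,
    trait: TraitModel,
    seed: int = 0,
    betas: np.ndarray | None = None,
) -> SimulatedCohort:
    """Simulate the quantitative trait and attach phenotypes to the cohort.

    The causal set is the first ``m_causal`` variants. Raw causal effects are
    drawn N(0, 1) and rescaled so the realized genetic-score variance equals
    ``h2`` in this cohort; pass ``betas`` to reuse effects realized in another
    cohort (required when several cohorts must share one genetic architecture).
    The trait is

        y_i = sum_j beta_j g_ij + sum_k delta_k q_ik
              + age_effect * z(age_i) + sex_effect * sex_i + eps_i

    with eps ~ N(0, 1 - h2), age ~ Uniform(18, 74) years, sex ~ Bernoulli(0.5).
    """
    g = cohort.genotypes
    M = g.n_variants
    if trait.m_causal > M:
        raise ParameterError("m_causal exceeds number of variants")
    if len(trait.ancestry_shift) != cohort.true_q.shape[1]:
        raise ParameterError("ancestry_shift length must equal K")
    rng = np.random.default_rng(seed)
    counts = g.counts.astype(float)
    if (g.counts == MISSING).any():
        col_mean = np.where(
            (g.counts != MISSING).sum(0) > 0,
            np.where(g.counts == MISSING, 0, g.counts).sum(0)
            / np.maximum((g.counts != MISSING).sum(0), 1),
            0.0,
        )
        counts = np.where(g.counts == MISSING, col_mean[None, :], counts)

    if betas is None:
        betas = np.zeros(M)
        if trait.m_causal > 0 and trait.h2 > 0:
            raw = rng.normal(size=trait.m_causal)
            score = counts[:, : trait.m_causal] @ raw
            sd = score.std(ddof=1)
            if sd == 0:
                raise ParameterError("degenerate genotypes: causal score has zero variance")
            betas[: trait.m_causal] = raw * np.sqrt(trait.h2) / sd
        else:
            rng.normal(size=max(trait.m_causal, 1))  # keep stream alignment
    else:
        betas = np.asarray(betas, dtype=float)
        rng.normal(size=max(trait.m_causal, 1))

    genetic = counts @ betas
    ancestry = cohort.true_q @ np.asarray(trait.ancestry_shift, dtype=float)
    age = rng.uniform(18.0, 74.0, size=g.n_samples)
    sex = rng.integers(0, 2, size=g.n_samples)
    z_age = (age - age.mean()) / age.std(ddof=1)
    noise = rng.normal(scale=np.sqrt(1.0 - trait.h2), size=g.n_samples)
    y = genetic + ancestry + trait.age_effect * z_age + trait.sex_effect * sex + noise

    pheno = pd.DataFrame(
        {"IID": g.samples, "HEIGHT": y, "AGE": age, "SEX": sex.astype(int)}
    )
    return dataclasses.replace(cohort, phenotypes=pheno, true_betas=betas)


def run_discovery_gwas(
    cohort: SimulatedCohort,
    covariate_pcs: int = 0,
    seed: int = 0,
    block: int = 256,
) -> pd.DataFrame:
    """Per-variant simple linear regression yielding summary statistics.

    The phenotype is pre-residualized on age, sex (and the leading
    ``covariate_pcs`` genotype PCs) and standardized; each variant is then
    tested with simple OLS of the residual on its allele count. Returns a
    summary-statistics frame (SNP, CHR, POS, A1, A2, BETA, SE, P) with a
    ``MONO`` flag column marking monomorphic variants (beta 0, p 1).
    """
    if cohort.phenotypes is None:
        raise ParameterError("simulate the phenotype before running the GWAS")
    from .phenotype import residualize  # local import to avoid a cycle

    pheno = cohort.phenotypes
    pcs = None
    if covariate_pcs > 0:
        from .ancestry import compute_pcs

        pcr = compute_pcs(cohort.genotypes, covariate_pcs)
        pcs = pcr.coords
    y = residualize(pheno, "HEIGHT", ["AGE", "SEX"], pcs=pcs)
    y = (y - y.mean()) / y.std(ddof=1)

    g = cohort.genotypes
    n = g.n_samples
    M = g.n_variants
    beta = np.zeros(M)
    se = np.full(M, np.nan)
    pval = np.ones(M)
    mono = np.zeros(M, dtype=bool)
    syy = float(y @ y)  # y is mean-zero
    for start in range(0, M, block):
        stop = min(start + block, M)
        X = g.counts[:, start:stop].astype(float)
        xm = X.mean(axis=0)
        Xc = X - xm
        sxx = (Xc * Xc).sum(axis=0)
        is_mono = sxx == 0
        sxy = Xc.T @ y
        with np.errstate(divide="ignore", invalid="ignore"):
            b = np.where(is_mono, 0.0, sxy / np.where(is_mono, 1.0, sxx))
            rss = syy - b * sxy
            s2 = rss / (n - 2)
            se_b = np.sqrt(np.maximum(s2, 0) / np.where(is_mono, 1.0, sxx))
            t = np.where(se_b > 0, b / np.where(se_b > 0, se_b, 1.0), 0.0)
        p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
        beta[start:stop] = b
        se[start:stop] = np.where(is_mono, np.nan, se_b)
        pval[start:stop] = np.where(is_mono, 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
        mono[start:stop] = is_mono
    out = pd.DataFrame(
        {
            "SNP": g.variants["variant_id"],
            "CHR": g.variants["chromosome"],
            "POS": g.variants["position"],
            "A1": g.variants["allele1"],
            "A2": g.variants["allele2"],
            "BETA": beta,
            "SE": se,
            "P": pval,
            "MONO": mono,
        }
    )
    return out
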