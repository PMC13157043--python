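"""End-to-end study-scale experiments built from the library primitives.

These functions wire the full workflow together — simulate a discovery
cohort and its GWAS, a European-like training cohort, an ancestry-matched
held-out cohort and an admixed target cohort; select and harmonize SNPs;
train the penalized path; and evaluate one- and two-stage prediction — at
parameterizable problem sizes. They back both the reproducibility script
and the heavier end-to-end tests.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from . import simulate as sim
from .ancestry import compute_pcs, estimate_ancestry_proportions
from .evaluate import kinship_clusters, repeat_splits
from .io import GenotypeMatrix
from .model import (
    fit_path,
    make_lambda_grid,
    score,
    select_best_lambda,
    standardize_genotypes,
)
from .phenotype import prepare_phenotype
from .variants import harmonize, oriented_counts, qc_filter, threshold_select

__all__ = ["StudyData", "simulate_study", "train_weights", "pgs_recovery", "delta_r2_experiment"]


@dataclasses.dataclass
class StudyData:
    """All simulated cohorts of one study replicate, sharing one trait model."""

    model: sim.AncestralModel
    trait: sim.TraitModel
    discovery: sim.SimulatedCohort
    training: sim.SimulatedCohort
    matched: sim.SimulatedCohort  # ancestry-matched held-out validation cohort
    target: sim.SimulatedCohort  # admixed cohort with sibling pairs
    sumstats: "object"  # summary-statistics frame from the discovery GWAS


def simulate_study(
    seed: int,
    M: int = 2000,
    m_causal: int = 200,
    h2: float = 0.5,
    ancestry_shift: tuple[float, float, float] = (0.5, 0.0, -0.5),
    n_discovery: int = 20000,
    n_training: int = 8000,
    n_matched: int = 3000,
    n_target: int = 3000,
    n_sib_pairs: int = 50,
    fst: tuple[float, ...] = sim.DEFAULT_FST,
) -> StudyData:
    """Simulate one full study: discovery GWAS plus three analysis cohorts.

    The discovery, training and matched cohorts are European-like; the target
    cohort is admixed with three-way ancestry and ``n_sib_pairs`` full-sib
    pairs. All cohorts share the causal-effect vector realized in the
    discovery cohort, so weights are transferable by construction.
    """
    model = sim.draw_ancestral_frequencies(M, fst=fst, seed=seed)
    trait = sim.TraitModel(m_causal=m_causal, h2=h2, ancestry_shift=ancestry_shift)
    K = model.K

    def eur_cohort(n: int, sub: int, prefix: str) -> sim.SimulatedCohort:
        spec = sim.CohortSpec(n=n, dirichlet_alpha=sim.EUR_ALPHA, label=prefix)
        q = sim.draw_admixture_proportions(spec, K, seed=seed + sub)
        g = sim.simulate_genotypes(model, q, seed=seed + sub + 1, sample_prefix=prefix)
        return sim.SimulatedCohort(genotypes=g, true_q=q, label=prefix)

    discovery = eur_cohort(n_discovery, 10, "d")
    discovery = sim.simulate_phenotype(discovery, trait, seed=seed + 12)
    betas = discovery.true_betas

    training = eur_cohort(n_training, 20, "r")
    training = sim.simulate_phenotype(training, trait, seed=seed + 22, betas=betas)

    matched = eur_cohort(n_matched, 30, "m")
    matched = sim.simulate_phenotype(matched, trait, seed=seed + 32, betas=betas)

    q_t = sim.admixed_mixture_proportions(n_target, seed=seed + 40)
    g_t = sim.simulate_genotypes(model, q_t, seed=seed + 41, sample_prefix="t")
    target = sim.SimulatedCohort(genotypes=g_t, true_q=q_t, label="target")
    if n_sib_pairs > 0:
        target = sim.add_sib_pairs(target, n_sib_pairs, model, seed=seed + 42)
    target = sim.simulate_phenotype(target, trait, seed=seed + 43, betas=betas)

    stats = sim.run_discovery_gwas(discovery, covariate_pcs=0, seed=seed + 50)
    stats = stats[~stats["MONO"]].drop(columns="MONO").reset_index(drop=True)
    return StudyData(
        model=model,
        trait=trait,
        discovery=discovery,
        training=training,
        matched=matched,
        target=target,
        sumstats=stats,
    )


def train_weights(
    study: StudyData,
    tau: float,
    alpha: float = 1.0,
    n_lambda: int = 10,
    train_frac: float = 0.9,
    seed: int = 0,
):
    """QC, harmonize, threshold, fit the penalized path, pick the lambda.

    The training cohort is split ``train_frac`` / rest; the path is fitted on
    the first part and the lambda chosen by PGS accuracy on the held-back
    part, so lambda selection never sees a downstream evaluation cohort.
    Returns (panel, path, stats, best_lambda_index, fit genotypes matrix).
    """
    train_qc, _ = qc_filter(study.training.genotypes)
    target_qc, _ = qc_filter(study.target.genotypes)
    panel = harmonize(study.sumstats, train_qc, target_qc)
    panel = threshold_select(panel, tau)

    g_train = oriented_counts(panel, train_qc)
    rng = np.random.default_rng(seed)
    n = g_train.n_samples
    perm = rng.permutation(n)
    n_fit = int(round(train_frac * n))
    fit_idx, sel_idx = perm[:n_fit], perm[n_fit:]

    prepared = prepare_phenotype(study.training.phenotypes, "HEIGHT", ["AGE", "SEX"])
    keep = ~prepared.excluded
    y_full = np.full(n, np.nan)
    y_full[keep] = prepared.z
    fit_idx = fit_idx[keep[fit_idx]]
    sel_idx = sel_idx[keep[sel_idx]]

    g_fit = g_train.select_samples(fit_idx)
    X, stats = standardize_genotypes(g_fit)
    y_fit = y_full[fit_idx]
    y_fit = (y_fit - y_fit.mean()) / y_fit.std(ddof=1)
    lambdas = make_lambda_grid(X, y_fit, alpha, n_lambda=n_lambda)
    path = fit_path(X, y_fit, alpha, lambdas)

    # align the panel to variants that survived standardization
    kept = set(stats.variant_ids)
    panel_kept = dataclasses.replace(
        panel, table=panel.table[panel.table["variant_id"].isin(kept)].reset_index(drop=True)
    )
    g_sel = _aligned(panel_kept, g_train, stats).select_samples(sel_idx)
    sel_scores = score(g_sel, path, stats)
    best, _ = select_best_lambda(sel_scores, y_full[sel_idx])
    return panel_kept, path, stats, best


def _aligned(panel, g: GenotypeMatrix, stats) -> GenotypeMatrix:
    idx = {v: i for i, v in enumerate(g.variants["variant_id"])}
    order = np.array([idx[v] for v in stats.variant_ids], dtype=int)
    return g.select_variants(order)


def score_cohort(cohort: sim.SimulatedCohort, panel, path, stats,
                 target: bool = False):
    """Prepared phenotype and per-lambda PGS for an evaluation cohort.

    Returns (ids, y, scores, keep_index) restricted to samples surviving the
    outlier filter; genotypes are oriented to the panel's effect alleles.
    The panel (defined by QC on the training and target cohorts) fixes the
    variant set; evaluation cohorts are scored on it as-is.
    """
    g = oriented_counts(panel, cohort.genotypes, target=target)
    g = _aligned(panel, g, stats)
    prepared = prepare_phenotype(cohort.phenotypes, "HEIGHT", ["AGE", "SEX"])
    keep = np.flatnonzero(~prepared.excluded)
    g = g.select_samples(keep)
    scores = score(g, path, stats)
    return prepared.ids, prepared.z, scores, keep


def pgs_recovery(seed: int, tau: float = 1e-3, **study_kwargs) -> dict:
    """Train a Lasso PGS and measure transfer to the matched held-out cohort.

    Reports the out-of-sample accuracy (squared correlation), the 99th
    percentile of a phenotype-permutation null for that accuracy, and the
    correlation between fitted per-allele weights and the true causal
    effects over the panel.
    """
    study = simulate_study(seed, **study_kwargs)
    panel, path, stats, best = train_weights(study, tau=tau, alpha=1.0, seed=seed + 60)

    _, y_m, scores_m, _ = score_cohort(study.matched, panel, path, stats)
    pgs = scores_m[best].values
    r2 = float(np.corrcoef(pgs, y_m)[0, 1] ** 2)

    rng = np.random.default_rng(seed + 70)
    null = np.empty(500)
    for i in range(null.size):
        null[i] = np.corrcoef(pgs, rng.permutation(y_m))[0, 1] ** 2
    null_p99 = float(np.quantile(null, 0.99))

    # per-allele fitted weights vs true causal effects, over panel variants
    vid_to_col = {v: j for j, v in enumerate(study.training.genotypes.variants["variant_id"])}
    truth = np.array([study.discovery.true_betas[vid_to_col[v]] for v in stats.variant_ids])
    w = path.per_allele_weights(stats)[:, best]
    sign = np.where(panel.table["sign_flip"].to_numpy(), -1.0, 1.0)
    truth_oriented = truth * sign
    weight_corr = float(np.corrcoef(w, truth_oriented)[0, 1])
    return {
        "r2_matched": r2,
        "null_p99": null_p99,
        "weight_truth_corr": weight_corr,
        "n_panel": len(stats.variant_ids),
        "best_lambda_index": int(best),
    }


def delta_r2_experiment(
    seed: int,
    tau: float = 1e-3,
    n_iter: int = 100,
    pc_grid: tuple[int, ...] = (0, 3, 10),
    n_pcs: int = 10,
    **study_kwargs,
) -> dict:
    """One replicate of the ancestry-gain comparison.

    Trains a Lasso PGS in the European-like cohort and evaluates the
    two-stage model in both the admixed target and the ancestry-matched
    held-out cohort, returning the accuracy surface over the PC grid for
    each, plus the headline contrasts: the gain from the first 3 PCs in each
    cohort and the saturation ratio (gain 3 -> 10 over gain 0 -> 3).
    """
    study = simulate_study(seed, **study_kwargs)
    panel, path, stats, _ = train_weights(study, tau=tau, alpha=1.0, seed=seed + 60)

    out = {}
    for name, cohort, is_target in (
        ("matched", study.matched, False),
        ("admixed", study.target, True),
    ):
        ids, y, scores, keep = score_cohort(cohort, panel, path, stats,
                                            target=is_target)
        pcr = compute_pcs(cohort.genotypes.select_samples(keep), n_pcs)
        clusters = kinship_clusters(cohort.kinship, ids)
        res = repeat_splits(
            y, scores, pcr.coords, ids, clusters,
            pc_grid=pc_grid, n_iter=n_iter, base_seed=seed + 80,
        )
        out[name] = res
    d_adm = out["admixed"].delta_r2(0, 3)
    d_match = out["matched"].delta_r2(0, 3)
    sat = out["admixed"].delta_r2(3, 10)
    return {
        "results": out,
        "delta_admixed_0_3": d_adm,
        "delta_matched_0_3": d_match,
        "delta_admixed_3_10": sat,
        "saturation_ratio": sat / d_adm if d_adm != 0 else np.inf,
    }
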