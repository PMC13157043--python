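"""Config-driven end-to-end runner: simulate -> select -> train -> score ->
evaluate -> report, with seeded stages and a run manifest.

Every stage reads its inputs from, and writes its outputs to, the run
directory, so stages can be re-run individually from the command line. A
single global seed fans out to per-stage seeds by fixed offsets. Re-running
with an identical config reproduces every numeric artifact bit-for-bit.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, simulate as sim
from .ancestry import compute_pcs, estimate_ancestry_proportions
from .evaluate import (
    KINSHIP_THIRD_DEGREE,
    kinship_clusters,
    repeat_splits,
    stratified_eval,
)
from .io import (
    GenotypeMatrix,
    read_kinship,
    read_phenotypes,
    read_plink,
    read_summary_stats,
    write_kinship,
    write_phenotypes,
    write_plink,
    write_summary_stats,
)
from .model import (
    PGSVector,
    fit_path,
    make_lambda_grid,
    score,
    standardize_genotypes,
)
from .phenotype import prepare_phenotype
from .variants import (
    DEFAULT_THRESHOLDS,
    HarmonizedPanel,
    harmonize,
    oriented_counts,
    qc_filter,
    threshold_select,
)

__all__ = ["RunConfig", "load_config", "run_pipeline", "report", "STAGES"]


class ConfigError(ValueError):
    """Raised for unknown keys or invalid values in a run configuration."""


@dataclasses.dataclass
class CohortConfig:
    n: int = 1000
    preset: str = "eur"  # "eur" or "admixed"
    n_sib_pairs: int = 0


@dataclasses.dataclass
class TraitConfig:
    m_causal: int = 50
    h2: float = 0.5
    ancestry_shift: tuple = (0.5, 0.0, -0.5)
    age_effect: float = 0.3
    sex_effect: float = 1.0


@dataclasses.dataclass
class SimulatorConfig:
    m_variants: int = 500
    fst: tuple = sim.DEFAULT_FST
    discovery: CohortConfig = dataclasses.field(default_factory=lambda: CohortConfig(n=5000))
    training: CohortConfig = dataclasses.field(default_factory=lambda: CohortConfig(n=2000))
    target: CohortConfig = dataclasses.field(
        default_factory=lambda: CohortConfig(n=1000, preset="admixed", n_sib_pairs=30)
    )
    trait: TraitConfig = dataclasses.field(default_factory=TraitConfig)
    discovery_pcs: int = 0


@dataclasses.dataclass
class SelectionConfig:
    thresholds: tuple = DEFAULT_THRESHOLDS
    max_missing: float = 0.10
    min_maf: float = 0.001
    hwe_p_min: float = 1e-10


@dataclasses.dataclass
class ModelConfig:
    alpha: float = 1.0
    n_lambda: int = 10
    tol: float = 1e-7
    train_frac: float = 0.9


@dataclasses.dataclass
class EvaluationConfig:
    test_frac: float = 0.2
    n_iter: int = 50
    pc_grid: tuple = (0, 1, 2, 3, 4, 5, 10)
    kinship_threshold: float = KINSHIP_THIRD_DEGREE
    full_cohort_lambda: bool = False
    stratify: bool = True
    min_group_size: int = 50


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "run"
    simulator: SimulatorConfig = dataclasses.field(default_factory=SimulatorConfig)
    selection: SelectionConfig = dataclasses.field(default_factory=SelectionConfig)
    model: ModelConfig = dataclasses.field(default_factory=ModelConfig)
    evaluation: EvaluationConfig = dataclasses.field(default_factory=EvaluationConfig)


def _build(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown config key(s) at {path}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        target = {
            "CohortConfig": CohortConfig,
            "TraitConfig": TraitConfig,
            "SimulatorConfig": SimulatorConfig,
            "SelectionConfig": SelectionConfig,
            "ModelConfig": ModelConfig,
            "EvaluationConfig": EvaluationConfig,
        }.get(str(ftype).split(".")[-1])
        if target is not None and isinstance(value, dict):
            kwargs[name] = _build(target, value, f"{path}.{name}")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run configuration; unknown keys are errors."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data.update(overrides)
    return _build(RunConfig, data, "config")


def config_to_dict(cfg) -> dict:
    return dataclasses.asdict(cfg)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _outdir(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _cohort_q(cc: CohortConfig, K: int, seed: int) -> np.ndarray:
    if cc.preset == "eur":
        spec = sim.CohortSpec(n=cc.n, dirichlet_alpha=sim.EUR_ALPHA,
                              n_sib_pairs=cc.n_sib_pairs)
        return sim.draw_admixture_proportions(spec, K, seed=seed)
    if cc.preset == "admixed":
        return sim.admixed_mixture_proportions(cc.n, seed=seed)
    raise ConfigError(f"unknown cohort preset {cc.preset!r}")


def stage_simulate(cfg: RunConfig) -> None:
    out = _outdir(cfg)
    sc = cfg.simulator
    model = sim.draw_ancestral_frequencies(sc.m_variants, fst=sc.fst, seed=cfg.seed)
    trait = sim.TraitModel(
        m_causal=sc.trait.m_causal,
        h2=sc.trait.h2,
        ancestry_shift=tuple(sc.trait.ancestry_shift),
        age_effect=sc.trait.age_effect,
        sex_effect=sc.trait.sex_effect,
    )
    betas = None
    for i, (label, cc) in enumerate(
        (("discovery", sc.discovery), ("training", sc.training), ("target", sc.target))
    ):
        base = cfg.seed + 100 + 10 * i
        q = _cohort_q(cc, model.K, base)
        g = sim.simulate_genotypes(model, q, seed=base + 1, sample_prefix=label[0])
        cohort = sim.SimulatedCohort(genotypes=g, true_q=q, label=label)
        if cc.n_sib_pairs > 0:
            cohort = sim.add_sib_pairs(cohort, cc.n_sib_pairs, model, seed=base + 2)
        cohort = sim.simulate_phenotype(cohort, trait, seed=base + 3, betas=betas)
        if label == "discovery":
            betas = cohort.true_betas
            stats = sim.run_discovery_gwas(cohort, covariate_pcs=sc.discovery_pcs,
                                           seed=base + 4)
            stats = stats[~stats["MONO"]].drop(columns="MONO")
            write_summary_stats(stats, out / "sumstats.tsv")
        write_plink(cohort.genotypes, out / label)
        write_phenotypes(cohort.phenotypes, out / f"{label}_pheno.tsv")
        write_kinship(cohort.kinship, out / f"{label}_kinship.tsv")
        qdf = pd.DataFrame(q, columns=[f"Q{k + 1}" for k in range(model.K)])
        qdf.insert(0, "IID", cohort.genotypes.samples)
        qdf.to_csv(out / f"{label}_true_q.tsv", sep="\t", index=False,
                   float_format="%.17g")
    freqs = pd.DataFrame(model.ancestral_freqs.T,
                         columns=[f"P_{lab}" for lab in sim.ANCESTRY_LABELS[: model.K]])
    freqs.insert(0, "variant_id", [f"snp{j:06d}" for j in range(model.M)])
    freqs.insert(1, "base_freq", model.base_freqs)
    freqs.to_csv(out / "ancestral_freqs.tsv", sep="\t", index=False,
                 float_format="%.17g")
    truth = pd.DataFrame({
        "variant_id": [f"snp{j:06d}" for j in range(model.M)],
        "true_beta": betas,
    })
    truth.to_csv(out / "true_betas.tsv", sep="\t", index=False, float_format="%.17g")


def stage_select(cfg: RunConfig) -> None:
    out = _outdir(cfg)
    sel = cfg.selection
    stats = read_summary_stats(out / "sumstats.tsv")
    train = read_plink(out / "training")
    target = read_plink(out / "target")
    train_qc, train_report = qc_filter(train, sel.max_missing, sel.min_maf, sel.hwe_p_min)
    target_qc, target_report = qc_filter(target, sel.max_missing, sel.min_maf, sel.hwe_p_min)
    train_report.to_csv(out / "qc_training.tsv", sep="\t", index=False)
    target_report.to_csv(out / "qc_target.tsv", sep="\t", index=False)
    panel = harmonize(stats, train_qc, target_qc)
    table = panel.table.copy()
    table.to_csv(out / "panel.tsv", sep="\t", index=False, float_format="%.17g")
    counts = pd.DataFrame(
        {
            "threshold": list(sel.thresholds),
            "n_snps": [len(threshold_select(panel, t)) for t in sel.thresholds],
        }
    )
    counts.to_csv(out / "snp_counts.tsv", sep="\t", index=False, float_format="%.17g")


def _load_panel(out: Path) -> HarmonizedPanel:
    table = pd.read_csv(out / "panel.tsv", sep="\t",
                        dtype={"variant_id": str, "effect_allele": str})
    for c in ("sign_flip", "strand_flip", "target_flip"):
        table[c] = table[c].astype(bool)
    return HarmonizedPanel(table=table)


def stage_train(cfg: RunConfig) -> None:
    """Fit the penalized path per threshold on the training cohort."""
    out = _outdir(cfg)
    mc = cfg.model
    panel = _load_panel(out)
    train = read_plink(out / "training")
    pheno = read_phenotypes(out / f"training_pheno.tsv")
    prepared = prepare_phenotype(pheno, "HEIGHT", ["AGE", "SEX"])
    keep = ~prepared.excluded

    rng = np.random.default_rng(cfg.seed + 500)
    n = train.n_samples
    perm = rng.permutation(n)
    n_fit = int(round(mc.train_frac * n))
    fit_idx = np.array([i for i in perm[:n_fit] if keep[i]], dtype=int)
    sel_idx = np.array([i for i in perm[n_fit:] if keep[i]], dtype=int)
    y_full = np.full(n, np.nan)
    y_full[keep] = prepared.z

    fit_log = []
    for ti, tau in enumerate(cfg.selection.thresholds):
        sub = threshold_select(panel, tau)
        if len(sub) == 0:
            continue
        g = oriented_counts(sub, train)
        X, stats = standardize_genotypes(g.select_samples(fit_idx))
        y = y_full[fit_idx]
        y = (y - y.mean()) / y.std(ddof=1)
        lambdas = make_lambda_grid(X, y, mc.alpha, n_lambda=mc.n_lambda)
        path = fit_path(X, y, mc.alpha, lambdas, tol=mc.tol)
        per_allele = path.per_allele_weights(stats)
        frames = []
        for li in range(path.weights.shape[1]):
            frames.append(pd.DataFrame({
                "SNP": stats.variant_ids,
                "EFFECT_ALLELE": sub.table.set_index("variant_id")
                .loc[stats.variant_ids, "effect_allele"].to_numpy(),
                "LAMBDA_INDEX": li,
                "LAMBDA": lambdas[li],
                "WEIGHT": path.weights[:, li],
                "WEIGHT_PER_ALLELE": per_allele[:, li],
                "MEAN": stats.mean,
                "SD": stats.sd,
            }))
        pd.concat(frames, ignore_index=True).to_csv(
            out / f"weights_t{ti}.tsv", sep="\t", index=False, float_format="%.17g"
        )
        fit_log.append({
            "threshold_index": ti,
            "threshold": float(tau),
            "n_snps": len(stats.variant_ids),
            "lambdas": [float(x) for x in lambdas],
            "nonzero": [int(x) for x in path.nonzero_counts()],
            "cycles": [int(x) for x in path.n_iter],
        })
    (out / "fit_log.json").write_text(json.dumps(fit_log, indent=2, sort_keys=True))
    sel_df = pd.DataFrame({"IID": [train.samples[i] for i in sel_idx]})
    sel_df.to_csv(out / "lambda_selection_samples.tsv", sep="\t", index=False)


def _scores_for(cfg: RunConfig, ti: int, cohort: GenotypeMatrix,
                panel: HarmonizedPanel, target: bool) -> tuple[list[str], np.ndarray] | None:
    out = Path(cfg.out_dir)
    wpath = out / f"weights_t{ti}.tsv"
    if not wpath.exists():
        return None
    w = pd.read_csv(wpath, sep="\t", dtype={"SNP": str})
    n_lambda = w["LAMBDA_INDEX"].nunique()
    first = w[w["LAMBDA_INDEX"] == 0]
    vids = first["SNP"].tolist()
    sub = HarmonizedPanel(
        table=panel.table.set_index("variant_id").loc[vids].reset_index()
    )
    g = oriented_counts(sub, cohort, target=target)
    counts = g.counts.astype(float)
    obs = counts >= 0
    mean = first["MEAN"].to_numpy()
    sd = first["SD"].to_numpy()
    counts = np.where(obs, counts, mean[None, :])
    Z = (counts - mean[None, :]) / sd[None, :]
    weights = w.pivot_table(index="SNP", columns="LAMBDA_INDEX", values="WEIGHT",
                            sort=False).loc[vids].to_numpy()
    return g.samples, Z @ weights[:, :n_lambda]


def stage_score(cfg: RunConfig) -> None:
    """Score the target cohort (all lambdas, all thresholds)."""
    out = _outdir(cfg)
    panel = _load_panel(out)
    target = read_plink(out / "target")
    for ti in range(len(cfg.selection.thresholds)):
        got = _scores_for(cfg, ti, target, panel, target=True)
        if got is None:
            continue
        samples, S = got
        df = pd.DataFrame(S, columns=[f"PGS_L{li}" for li in range(S.shape[1])])
        df.insert(0, "IID", samples)
        df.to_csv(out / f"scores_target_t{ti}.tsv", sep="\t", index=False,
                  float_format="%.17g")


def stage_evaluate(cfg: RunConfig) -> None:
    out = _outdir(cfg)
    ev = cfg.evaluation
    target = read_plink(out / "target")
    pheno = read_phenotypes(out / "target_pheno.tsv")
    kinship = read_kinship(out / "target_kinship.tsv")
    prepared = prepare_phenotype(pheno, "HEIGHT", ["AGE", "SEX"])
    keep = np.flatnonzero(~prepared.excluded)
    ids = prepared.ids
    y = prepared.z

    n_pcs = max(max(ev.pc_grid), 1)
    pcr = compute_pcs(target.select_samples(keep), n_pcs)
    pcr.frame(ids).to_csv(out / "target_pcs.tsv", sep="\t", index=False,
                          float_format="%.17g")
    ev_frame = pd.DataFrame({
        "PC": np.arange(1, pcr.n_pcs + 1),
        "EXPLAINED_VARIANCE_FRACTION": pcr.explained_variance_fraction,
    })
    ev_frame.to_csv(out / "target_pc_variance.tsv", sep="\t", index=False,
                    float_format="%.17g")

    profile = None
    if ev.stratify:
        freqs = pd.read_csv(out / "ancestral_freqs.tsv", sep="\t")
        pcols = [c for c in freqs.columns if c.startswith("P_")]
        model = sim.AncestralModel(
            base_freqs=freqs["base_freq"].to_numpy(),
            fst=np.asarray(cfg.simulator.fst, dtype=float),
            ancestral_freqs=freqs[pcols].to_numpy().T,
        )
        profile = estimate_ancestry_proportions(target.select_samples(keep), model)
        profile.frame().to_csv(out / "target_ancestry.tsv", sep="\t", index=False,
                               float_format="%.17g")

    clusters = kinship_clusters(kinship, ids, threshold=ev.kinship_threshold)
    results: dict = {"thresholds": {}, "groups": {}}
    for ti, tau in enumerate(cfg.selection.thresholds):
        spath = out / f"scores_target_t{ti}.tsv"
        if not spath.exists():
            continue
        sdf = pd.read_csv(spath, sep="\t", dtype={"IID": str}).set_index("IID")
        sdf = sdf.loc[ids]
        scores = [
            PGSVector(values=sdf[c].to_numpy(), lambda_index=li, alpha=cfg.model.alpha,
                      tau=tau)
            for li, c in enumerate(sdf.columns)
        ]
        res = repeat_splits(
            y, scores, pcr.coords, ids, clusters,
            pc_grid=tuple(ev.pc_grid), n_iter=ev.n_iter,
            base_seed=cfg.seed + 700, test_frac=ev.test_frac,
            full_cohort_lambda=ev.full_cohort_lambda,
        )
        results["thresholds"][f"{tau:g}"] = res.to_dict()
        if profile is not None:
            names = {k: sim.ANCESTRY_LABELS[k] for k in range(len(sim.ANCESTRY_LABELS))}
            strat = stratified_eval(
                y, scores, pcr.coords, ids, kinship, profile.labels,
                group_names=names, min_group_size=ev.min_group_size,
                kinship_threshold=ev.kinship_threshold,
                pc_grid=tuple(ev.pc_grid), n_iter=ev.n_iter,
                base_seed=cfg.seed + 700, test_frac=ev.test_frac,
                full_cohort_lambda=ev.full_cohort_lambda,
            )
            results["groups"][f"{tau:g}"] = {
                name: {"n": n_grp, **res_g.to_dict()}
                for name, (n_grp, res_g) in strat.items()
            }
    (out / "results.json").write_text(json.dumps(results, indent=2, sort_keys=True))


def report(run_dir: str | Path) -> str:
    """Text summary (and a plot) of the accuracy surface of a completed run."""
    out = Path(run_dir)
    rpath = out / "results.json"
    if not rpath.exists():
        raise FileNotFoundError(f"no results.json under {out}; run the evaluate stage")
    results = json.loads(rpath.read_text())
    lines = ["prediction accuracy (mean R^2 over splits; SD in parentheses)", ""]
    header = None
    rows = []
    for tau, cells in sorted(results["thresholds"].items(), key=lambda kv: float(kv[0])):
        ks = sorted(cells, key=int)
        if header is None:
            header = ["p<"] + [f"k={k}" for k in ks]
        row = [tau] + [f"{cells[k]['mean_r2']:.4f} ({cells[k]['sd_r2']:.4f})" for k in ks]
        rows.append(row)
    if header:
        widths = [max(len(r[i]) for r in [header] + rows) for i in range(len(header))]
        for r in [header] + rows:
            lines.append("  ".join(s.ljust(w) for s, w in zip(r, widths)))
        lines.append("")
        lines.append("delta R^2 relative to k=0:")
        for tau, cells in sorted(results["thresholds"].items(), key=lambda kv: float(kv[0])):
            base = cells["0"]["mean_r2"] if "0" in cells else None
            if base is None:
                continue
            deltas = ", ".join(
                f"k={k}: {cells[k]['mean_r2'] - base:+.4f}" for k in sorted(cells, key=int)
            )
            lines.append(f"  p<{tau}: {deltas}")
    text = "\n".join(lines)
    (out / "report.txt").write_text(text + "\n")
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4.5))
        for tau, cells in sorted(results["thresholds"].items(), key=lambda kv: float(kv[0])):
            ks = sorted((int(k) for k in cells), key=int)
            means = [cells[str(k)]["mean_r2"] for k in ks]
            sds = [cells[str(k)]["sd_r2"] for k in ks]
            ax.errorbar(ks, means, yerr=sds, marker="o", capsize=3, label=f"p<{tau}")
        ax.set_xlabel("number of PCs in the prediction model")
        ax.set_ylabel("mean $R^2$")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(out / "report.png", dpi=120)
        plt.close(fig)
    except Exception:  # plotting is best-effort; the text table is the artifact
        pass
    return text


STAGES = {
    "simulate": stage_simulate,
    "select": stage_select,
    "train": stage_train,
    "score": stage_score,
    "evaluate": stage_evaluate,
}


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages in order and write the run manifest."""
    out = _outdir(cfg)
    (out / "config.yaml").write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))
    timings = {}
    for name, stage in STAGES.items():
        t0 = time.perf_counter()
        try:
            stage(cfg)
        except Exception as exc:
            manifest = {
                "config": config_to_dict(cfg),
                "failed_stage": name,
                "error": str(exc),
                "version": __version__,
            }
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
    report(out)
    manifest = {
        "config": config_to_dict(cfg),
        "version": __version__,
        "stage_seconds": timings,
        "artifacts": {
            p.name: _checksum(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name not in {"manifest.json", "report.png"}
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return out
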