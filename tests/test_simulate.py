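"""Statistical properties of the synthetic-cohort generator."""
import numpy as np
import pytest

from admixpgs import simulate as sim
from admixpgs.io import MISSING


class TestAncestralFrequencies:
    def test_zero_drift_limit(self):
        """As F_ST -> 0 the population frequencies collapse onto the base."""
        m = sim.draw_ancestral_frequencies(100, fst=(1e-5, 1e-5, 1e-5), seed=1)
        assert np.abs(m.ancestral_freqs - m.base_freqs[None, :]).max() < 0.01

    def test_beta_mean_matches_base_frequency(self):
        """E[p_kj | p_j] = p_j under the drift model (Monte-Carlo)."""
        rng = np.random.default_rng(2)
        p, F = 0.3, 0.1
        scale = (1 - F) / F
        draws = rng.beta(p * scale, (1 - p) * scale, size=10000)
        se = np.sqrt(F * p * (1 - p) / draws.size)
        assert abs(draws.mean() - p) < 3 * se

    def test_variance_is_fst_times_binomial_variance(self):
        m = sim.draw_ancestral_frequencies(10000, fst=(0.2, 0.2), seed=3)
        # condition on base freq near 0.5 to check Var = F p (1-p)
        sel = np.abs(m.base_freqs - 0.5) < 0.02
        resid = m.ancestral_freqs[0, sel] - m.base_freqs[sel]
        expected = 0.2 * 0.5 * 0.5
        assert abs(resid.var() - expected) < 0.1 * expected

    def test_bad_fst_rejected(self):
        with pytest.raises(sim.ParameterError):
            sim.draw_ancestral_frequencies(10, fst=(0.1, 1.0), seed=0)

    def test_reproducible(self):
        a = sim.draw_ancestral_frequencies(50, seed=9)
        b = sim.draw_ancestral_frequencies(50, seed=9)
        assert np.array_equal(a.ancestral_freqs, b.ancestral_freqs)


class TestAdmixtureProportions:
    def test_concentrated_alpha_is_nearly_one_hot(self):
        spec = sim.CohortSpec(n=200, dirichlet_alpha=(1e6, 1.0, 1.0))
        q = sim.draw_admixture_proportions(spec, 3, seed=4)
        assert (q[:, 0] > 0.99).all()

    def test_symmetric_alpha_component_means(self):
        spec = sim.CohortSpec(n=10000, dirichlet_alpha=(1.0, 1.0, 1.0))
        q = sim.draw_admixture_proportions(spec, 3, seed=5)
        se = np.sqrt((1 / 3) * (2 / 3) / (3 + 1) / q.shape[0])
        assert np.abs(q.mean(axis=0) - 1 / 3).max() < 3 * se

    def test_rows_on_simplex(self):
        q = sim.admixed_mixture_proportions(500, seed=6)
        assert np.abs(q.sum(axis=1) - 1).max() < 1e-12
        assert (q >= 0).all()


class TestGenotypes:
    def test_low_frequency_floor_yields_rare_counts(self):
        model = sim.AncestralModel(
            base_freqs=np.full(5, 0.001),
            fst=np.array([0.1, 0.1]),
            ancestral_freqs=np.full((2, 5), 0.001),
        )
        q = np.tile([0.5, 0.5], (1000, 1))
        g = sim.simulate_genotypes(model, q, seed=7)
        assert g.counts.mean() <= 0.01

    def test_single_population_frequency_recovery(self):
        model = sim.draw_ancestral_frequencies(200, seed=8)
        q = np.tile([1.0, 0.0, 0.0], (2000, 1))
        g = sim.simulate_genotypes(model, q, seed=9)
        freq = g.counts.mean(axis=0) / 2
        p = model.ancestral_freqs[0]
        se = np.sqrt(p * (1 - p) / (2 * 2000))
        assert (np.abs(freq - p) < 3 * se).mean() > 0.98

    def test_mean_genotype_matches_admixed_expectation(self):
        model = sim.draw_ancestral_frequencies(300, seed=10)
        q = sim.admixed_mixture_proportions(5000, seed=11)
        g = sim.simulate_genotypes(model, q, seed=12)
        pi = q @ model.ancestral_freqs
        expected = 2 * pi.mean(axis=0)
        se = np.sqrt((2 * pi * (1 - pi)).sum(axis=0)) / q.shape[0]
        assert (np.abs(g.counts.mean(axis=0) - expected) < 3 * se + 1e-9).mean() > 0.98


class TestSibPairs:
    def test_mendelian_certainty(self):
        """Both parents homozygous for the counted allele -> both sibs count 2."""
        model = sim.AncestralModel(
            base_freqs=np.full(50, 0.999),
            fst=np.array([0.1, 0.1]),
            ancestral_freqs=np.full((2, 50), 0.999),
        )
        q = np.tile([0.5, 0.5], (10, 1))
        g = sim.simulate_genotypes(model, q, seed=13)
        cohort = sim.SimulatedCohort(genotypes=g, true_q=q)
        cohort = sim.add_sib_pairs(cohort, 2, model, seed=14)
        # at p = 0.999 essentially every parent is homozygous count-2
        assert (cohort.genotypes.counts[-4:] == 2).mean() > 0.98

    def test_sib_genotype_correlation_near_half(self):
        model = sim.draw_ancestral_frequencies(2000, fst=(0.01, 0.01, 0.01), seed=15)
        q = np.tile([1.0, 0.0, 0.0], (40, 1))
        g = sim.simulate_genotypes(model, q, seed=16)
        cohort = sim.SimulatedCohort(genotypes=g, true_q=q)
        cohort = sim.add_sib_pairs(cohort, 10, model, seed=17)
        # center each SNP by the cohort mean: otherwise shared allele-frequency
        # variation across SNPs inflates the correlation
        centered = cohort.genotypes.counts.astype(float)
        centered -= centered.mean(axis=0)
        cors = []
        for p in range(10):
            a = centered[40 - 20 + 2 * p]
            b = centered[40 - 20 + 2 * p + 1]
            cors.append(np.corrcoef(a, b)[0, 1])
        assert 0.45 < np.mean(cors) < 0.55

    def test_kinship_entries_added(self):
        model = sim.draw_ancestral_frequencies(100, seed=18)
        q = sim.admixed_mixture_proportions(30, seed=19)
        cohort = sim.SimulatedCohort(genotypes=sim.simulate_genotypes(model, q, seed=20),
                                     true_q=q)
        cohort = sim.add_sib_pairs(cohort, 5, model, seed=21)
        entries = list(cohort.kinship.pairs())
        assert len(entries) == 5
        assert all(k == 0.25 for _, _, k in entries)


class TestPhenotype:
    def test_variance_bookkeeping(self):
        model = sim.draw_ancestral_frequencies(500, seed=22)
        q = np.tile([1.0, 0.0, 0.0], (5000, 1))
        g = sim.simulate_genotypes(model, q, seed=23)
        cohort = sim.SimulatedCohort(genotypes=g, true_q=q)
        trait = sim.TraitModel(m_causal=100, h2=0.5, ancestry_shift=(0, 0, 0),
                               age_effect=0.0, sex_effect=0.0)
        cohort = sim.simulate_phenotype(cohort, trait, seed=24)
        y = cohort.phenotypes["HEIGHT"].to_numpy()
        assert abs(y.var(ddof=1) - 1.0) < 0.1

    def test_null_trait_uncorrelated_with_genetics(self):
        model = sim.draw_ancestral_frequencies(200, seed=25)
        q = np.tile([1.0, 0.0, 0.0], (3000, 1))
        g = sim.simulate_genotypes(model, q, seed=26)
        cohort = sim.SimulatedCohort(genotypes=g, true_q=q)
        trait = sim.TraitModel(m_causal=0, h2=0.5, age_effect=0.0, sex_effect=0.0)
        cohort = sim.simulate_phenotype(cohort, trait, seed=27)
        y = cohort.phenotypes["HEIGHT"].to_numpy()
        proxy = g.counts[:, :50].astype(float).sum(axis=1)  # arbitrary genetic score
        assert abs(np.corrcoef(y, proxy)[0, 1]) < 3 / np.sqrt(len(y))

    def test_ancestry_shift_group_difference(self):
        model = sim.draw_ancestral_frequencies(100, seed=28)
        q = np.vstack([np.tile([1.0, 0, 0], (2000, 1)), np.tile([0, 0, 1.0], (2000, 1))])
        g = sim.simulate_genotypes(model, q, seed=29)
        cohort = sim.SimulatedCohort(genotypes=g, true_q=q)
        trait = sim.TraitModel(m_causal=0, h2=0.5, ancestry_shift=(0.5, 0.0, -0.5),
                               age_effect=0.0, sex_effect=0.0)
        cohort = sim.simulate_phenotype(cohort, trait, seed=30)
        y = cohort.phenotypes["HEIGHT"].to_numpy()
        diff = y[:2000].mean() - y[2000:].mean()
        assert abs(diff - 1.0) < 0.1

    def test_heritability_recovered_by_true_score_regression(self):
        model = sim.draw_ancestral_frequencies(500, seed=31)
        q = np.tile([1.0, 0.0, 0.0], (5000, 1))
        g = sim.simulate_genotypes(model, q, seed=32)
        cohort = sim.SimulatedCohort(genotypes=g, true_q=q)
        trait = sim.TraitModel(m_causal=100, h2=0.5, ancestry_shift=(0, 0, 0),
                               age_effect=0.0, sex_effect=0.0)
        cohort = sim.simulate_phenotype(cohort, trait, seed=33)
        y = cohort.phenotypes["HEIGHT"].to_numpy()
        score = g.counts.astype(float) @ cohort.true_betas
        slope = np.polyfit(score, y, 1)[0]
        r2 = np.corrcoef(score, y)[0, 1] ** 2
        assert abs(slope - 1.0) < 0.05
        assert abs(r2 - 0.5) < 0.05

    def test_h2_one_rejected(self):
        with pytest.raises(sim.ParameterError):
            sim.TraitModel(m_causal=5, h2=1.0)


class TestDiscoveryGwas:
    @pytest.fixture(scope="class")
    def eur_cohort(self):
        model = sim.draw_ancestral_frequencies(1200, seed=34)
        q = np.tile([1.0, 0.0, 0.0], (6000, 1))
        g = sim.simulate_genotypes(model, q, seed=35)
        cohort = sim.SimulatedCohort(genotypes=g, true_q=q)
        trait = sim.TraitModel(m_causal=10, h2=0.5, ancestry_shift=(0, 0, 0))
        return sim.simulate_phenotype(cohort, trait, seed=36)

    def test_large_effect_snp_is_genome_wide_significant(self, eur_cohort):
        stats = sim.run_discovery_gwas(eur_cohort, seed=37)
        # the strongest causal SNP carries several percent of trait variance
        causal = stats.iloc[:10]
        assert causal["P"].min() < 1e-16

    def test_null_p_values_uniform_in_unstructured_cohort(self, eur_cohort):
        stats = sim.run_discovery_gwas(eur_cohort, seed=38)
        null_p = stats["P"].iloc[200:1200]  # non-causal block
        frac = (null_p < 0.05).mean()
        assert abs(frac - 0.05) < 0.02

    def test_monomorphic_snp_flagged(self):
        model = sim.AncestralModel(
            base_freqs=np.full(3, 0.5),
            fst=np.array([0.1, 0.1]),
            ancestral_freqs=np.full((2, 3), 0.5),
        )
        q = np.tile([0.5, 0.5], (50, 1))
        g = sim.simulate_genotypes(model, q, seed=39)
        g.counts[:, 0] = 2  # force monomorphic
        cohort = sim.SimulatedCohort(genotypes=g, true_q=q)
        trait = sim.TraitModel(m_causal=0, h2=0.3, ancestry_shift=(0.0, 0.0))
        cohort = sim.simulate_phenotype(cohort, trait, seed=40)
        stats = sim.run_discovery_gwas(cohort, seed=41)
        assert bool(stats["MONO"].iloc[0])
        assert stats["BETA"].iloc[0] == 0.0
        assert stats["P"].iloc[0] == 1.0

    def test_stratification_inflates_unadjusted_null(self):
        """Ancestry-differentiated null SNPs show excess small p-values when
        the trait tracks ancestry and no PCs are used; PC adjustment fixes it."""
        model = sim.draw_ancestral_frequencies(600, fst=(0.2, 0.2, 0.2), seed=42)
        q = np.vstack([np.tile([1.0, 0, 0], (1500, 1)), np.tile([0, 1.0, 0], (1500, 1))])
        g = sim.simulate_genotypes(model, q, seed=43)
        cohort = sim.SimulatedCohort(genotypes=g, true_q=q)
        trait = sim.TraitModel(m_causal=0, h2=0.3, ancestry_shift=(1.0, -1.0, 0.0),
                               age_effect=0.0, sex_effect=0.0)
        cohort = sim.simulate_phenotype(cohort, trait, seed=44)
        raw = sim.run_discovery_gwas(cohort, covariate_pcs=0, seed=45)
        adj = sim.run_discovery_gwas(cohort, covariate_pcs=2, seed=46)
        assert (raw["P"] < 0.05).mean() > 0.15
        assert abs((adj["P"] < 0.05).mean() - 0.05) < 0.03


def test_ld_partner_mode_creates_correlated_pairs():
    model = sim.draw_ancestral_frequencies(100, seed=47)
    q = np.tile([1.0, 0.0, 0.0], (1000, 1))
    g = sim.simulate_genotypes(model, q, seed=48)
    g2 = sim.add_ld_partners(g, 20, flip_prob=0.1, seed=49)
    assert g2.n_variants == 120
    cors = [
        np.corrcoef(g2.counts[:, j].astype(float), g2.counts[:, 100 + j].astype(float))[0, 1]
        for j in range(20)
    ]
    assert np.mean(cors) > 0.5


def test_reproducible_end_to_end_draws():
    """Identical seeds reproduce genotypes and phenotypes bit-for-bit."""
    out = []
    for _ in range(2):
        model = sim.draw_ancestral_frequencies(120, seed=50)
        q = sim.admixed_mixture_proportions(60, seed=51)
        g = sim.simulate_genotypes(model, q, seed=52)
        cohort = sim.SimulatedCohort(genotypes=g, true_q=q)
        cohort = sim.simulate_phenotype(cohort, sim.TraitModel(m_causal=10, h2=0.4), seed=53)
        out.append((g.counts.copy(), cohort.phenotypes["HEIGHT"].to_numpy().copy()))
    assert np.array_equal(out[0][0], out[1][0])
    assert np.array_equal(out[0][1], out[1][1])
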