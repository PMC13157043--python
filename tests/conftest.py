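import numpy as np
import pandas as pd
import pytest

from admixpgs import simulate as sim
from admixpgs.io import GenotypeMatrix


def make_genotypes(counts, sample_prefix="s", variant_prefix="v"):
    """GenotypeMatrix from a raw count array with boilerplate metadata."""
    counts = np.asarray(counts, dtype=np.int8)
    n, m = counts.shape
    variants = pd.DataFrame(
        {
            "variant_id": [f"{variant_prefix}{j}" for j in range(m)],
            "chromosome": "1",
            "position": np.arange(1, m + 1),
            "allele1": "A",
            "allele2": "G",
        }
    )
    return GenotypeMatrix(
        samples=[f"{sample_prefix}{i}" for i in range(n)],
        variants=variants,
        counts=counts,
    )


@pytest.fixture(scope="session")
def admixed_cohort():
    """A mid-sized admixed cohort with sib pairs and a simulated trait."""
    model = sim.draw_ancestral_frequencies(800, seed=101)
    q = sim.admixed_mixture_proportions(400, seed=102)
    g = sim.simulate_genotypes(model, q, seed=103)
    cohort = sim.SimulatedCohort(genotypes=g, true_q=q)
    cohort = sim.add_sib_pairs(cohort, 15, model, seed=104)
    cohort = sim.simulate_phenotype(
        cohort, sim.TraitModel(m_causal=80, h2=0.5, ancestry_shift=(0.5, 0.0, -0.5)),
        seed=105,
    )
    return model, cohort
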