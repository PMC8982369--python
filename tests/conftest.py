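"""Shared fixtures: small simulated populations and toy panels."""

import numpy as np
import pandas as pd
import pytest

from gpforward import pheno, simulate as sim
from gpforward.qc import GenotypePanel


def make_panel(dosages, chrom=None, cm=None):
    """Build a GenotypePanel from a raw dosage array with default map."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    chrom = np.ones(m, dtype=int) if chrom is None else np.asarray(chrom)
    if cm is None:
        cm = np.empty(m)
        for c in np.unique(chrom):
            idx = np.flatnonzero(chrom == c)
            cm[idx] = np.arange(1.0, idx.size + 1.0)
    snp_ids = np.array([f"s{j}" for j in range(m)], dtype=object)
    return GenotypePanel(
        animal_ids=np.array([f"a{i}" for i in range(n)], dtype=object),
        snp_ids=snp_ids,
        dosages=dosages,
        snp_map=pd.DataFrame({"snp_id": snp_ids, "chrom": chrom, "cm": cm}),
    )


SMALL_DESIGN = sim.PopulationDesign(generation_sizes=(40, 20, 80, 70, 40, 80))


@pytest.fixture(scope="session")
def small_population():
    """6-generation population, 330 animals x 400 SNPs."""
    founders = sim.simulate_founders(400, 4, (0.1, 0.5), seed=11)
    return sim.drop_generations(founders, SMALL_DESIGN, seed=12)


@pytest.fixture(scope="session")
def additive_dataset(small_population):
    """Additive trait (h2=0.4) with diet/sex fixed effects, precorrected."""
    ds = sim.simulate_trait(
        small_population.panel,
        sim.TraitArchitecture(
            n_additive_qtl=100, h2_additive=0.4,
            fixed_effect_sizes={"diet": 0.5, "sex": 0.3},
        ),
        seed=13,
        meta=small_population.meta,
        trait_name="addtrait",
    )
    traits = pheno.precorrect(ds.traits)
    return ds, traits
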