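import numpy as np
import pytest

from gwadl import geno
from gwadl.simulate import SimConfig, simulate_dataset


def genotype_mean_trait(g, p, trait="trait1"):
    """Genotype-mean trait vector aligned to the panel's sample order."""
    return p.genotype_means(trait).reindex(g.sample_ids).to_numpy(float)


@pytest.fixture(scope="session")
def small_dataset():
    """120 x 600 structured panel with 3% missing calls and a sparse trait."""
    cfg = SimConfig(n_individuals=120, n_snps=600, n_qtns=4,
                    polygenic_fraction=0.2, missing_rate=0.03, seed=11)
    g, p, truth = simulate_dataset(cfg)
    return cfg, g, p, truth


@pytest.fixture(scope="session")
def imputed_dataset(small_dataset):
    cfg, g, p, truth = small_dataset
    gf = geno.filter_variants(g)
    return cfg, geno.impute_mean(gf), p, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
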