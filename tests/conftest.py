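import numpy as np
import pandas as pd
import pytest

from coexpred import preprocess, quantgen, synthdata


@pytest.fixture(scope="session")
def small_bundle():
    """Small synthetic study shared across tests: 6 populations, 60 genotypes,
    120 genes in 2 modules plus a grey fraction."""
    return synthdata.generate_bundle(
        n_pops=6, n_genotypes=60, n_genes=120, n_modules=2,
        grey_fraction=0.4, n_snps=400, n_traits=2, seed=11,
    )


@pytest.fixture(scope="session")
def small_normalized(small_bundle):
    filtered, _ = preprocess.filter_low_expressed(small_bundle.counts)
    factors = preprocess.tmm_factors(filtered)
    return preprocess.log_cpm(filtered, factors)


@pytest.fixture(scope="session")
def small_kinship_pair(small_bundle):
    pops = pd.Series(
        small_bundle.design.drop_duplicates("genotype")
        .set_index("genotype")["population"]
    ).reindex(small_bundle.kinship.index)
    return quantgen.split_kinship(small_bundle.kinship, pops)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
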