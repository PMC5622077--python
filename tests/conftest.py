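import numpy as np
import pytest

from gwas2drug.synthetic import SyntheticConfig, gen_gwas


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        seed=7,
        n_genes=80,
        snps_per_gene=6,
        n_drugs=60,
        n_classes=3,
        n_pathways=20,
        n_pathway_clusters=2,
    )


@pytest.fixture(scope="session")
def small_gwas(small_config):
    return gen_gwas(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
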