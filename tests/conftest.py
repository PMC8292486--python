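import numpy as np
import pytest

import socgwas


@pytest.fixture(scope="session")
def small_config():
    return socgwas.SimConfig(
        n_individuals=120, n_snps=300, n_ld_blocks=30,
        founder_haplotypes_per_block=6, n_litters=12, group_size=6, seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    """(geno, cohort, traits, visits, truth) at desk scale."""
    return socgwas.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_grm(small_sim):
    return socgwas.grm_centered(small_sim[0])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
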