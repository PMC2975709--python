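import numpy as np
import pytest

import hawmap as hm


@pytest.fixture(scope="session")
def elegans_model():
    return hm.default_elegans_model()


@pytest.fixture(scope="session")
def small_model():
    """Three 2 Mb / 50 cM chromosomes — fast stand-in genome."""
    specs = [
        hm.ChromosomeSpec("chr1", 2_000_000),
        hm.ChromosomeSpec("chr2", 2_000_000),
        hm.ChromosomeSpec("chr3", 2_000_000),
    ]
    return hm.build_genome_model(specs)


@pytest.fixture(scope="session")
def small_catalog(small_model):
    return hm.generate_snp_catalog(small_model, density=1e-3, blacklist_fraction=0.0,
                                   seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
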