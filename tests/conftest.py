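import numpy as np
import pandas as pd
import pytest

from polespectra import MutationCatalog, ReferenceGenome
from polespectra.synthetic import (
    GeneratorConfig,
    simulate_genome,
    simulate_landscape,
    simulate_methylation,
)


@pytest.fixture(scope="session")
def toy_genome():
    # 60 bp, no N, hand-checkable
    seq = "ACGTACGTTCGATTTCCGGAATCGATCGGCTAGCTAACGTTTACGCATGCATTCAGGACT"
    return ReferenceGenome({"chr1": seq})


@pytest.fixture(scope="session")
def small_bundle():
    """Shared 300 kb genome with methylation and landscape; no mutations yet."""
    cfg = GeneratorConfig(seed=11, genome_length=300_000, timing_period=100_000,
                          motif_spacing=10_000, n_genes=30)
    rng = np.random.default_rng(cfg.seed)
    genome = simulate_genome(cfg, rng)
    meth = simulate_methylation(genome, cfg, rng)
    landscape = simulate_landscape(genome, cfg, rng)
    return cfg, genome, meth, landscape


def make_catalog(rows):
    return MutationCatalog(pd.DataFrame(rows, columns=MutationCatalog.COLUMNS))


@pytest.fixture
def catalog_factory():
    return make_catalog
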