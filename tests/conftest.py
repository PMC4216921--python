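import numpy as np
import pytest

import codonbalance as cb


@pytest.fixture(scope="session")
def code():
    return cb.load_genetic_code()


@pytest.fixture(scope="session")
def small_sim():
    """One small synthetic dataset shared by read-only tests."""
    cfg = cb.SimConfig(n_pc_genes=300, n_trna_genes=200, seed=42,
                       mean_cds_codons=80)
    genome = cb.generate_genome(cfg)
    mrna, trna, truth = cb.generate_counts(cfg, genome)
    return cfg, genome, mrna, trna, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
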