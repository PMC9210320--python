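import sys
from pathlib import Path

import dataclasses

import pytest

import barhem

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py


@pytest.fixture(scope="session")
def small_config():
    return barhem.SimConfig(n_genes=8, gene_length_bp=300, intergenic_bp=100,
                            inserts_per_allele_mean=4.0, tnseq_depth_mean=20.0,
                            barseq_depth_mean=60.0, seed=11)


@pytest.fixture(scope="session")
def small_screen(small_config):
    """One small simulated screen shared across read-level tests."""
    cfg = small_config
    genome, features = barhem.generate_hybrid_genome(cfg)
    truth = barhem.generate_pool(genome, features, cfg)
    counts, sheet = barhem.simulate_competition(truth, cfg)
    return {"config": cfg, "genome": genome, "features": features,
            "truth": truth, "counts": counts, "sheet": sheet}


@pytest.fixture()
def errorfree_config(small_config):
    return dataclasses.replace(small_config, base_error_rate=0.0)
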