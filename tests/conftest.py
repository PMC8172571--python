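import numpy as np
import pytest

from circnet import SimConfig, emit_caller_tables, emit_sequences, simulate_counts


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_circ=60, n_mirna=25, n_mrna=80, n_reps=4, n_triplets=4,
                     de_fraction=0.15, sponge_strength=0.9, seed=42)


@pytest.fixture(scope="session")
def sim_dataset(small_config):
    """One fully emitted synthetic dataset shared across read-only tests."""
    matrices, truth = simulate_counts(small_config)
    sequences = emit_sequences(truth, small_config)
    table_a, table_b, gtf = emit_caller_tables(truth, small_config)
    return {
        "config": small_config,
        "matrices": matrices,
        "truth": truth,
        "sequences": sequences,
        "table_a": table_a,
        "table_b": table_b,
        "gtf": gtf,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
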