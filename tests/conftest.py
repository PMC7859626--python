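import numpy as np
import pandas as pd
import pytest

from preemiexpr.matrix import CountMatrix
from preemiexpr.preprocess import run_preprocess
from preemiexpr.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def tiny_counts() -> CountMatrix:
    """6 subjects x 5 genes with known zero patterns for filter oracles."""
    rng = np.random.default_rng(42)
    data = rng.integers(10, 200, size=(5, 6))
    df = pd.DataFrame(data, index=[f"g{i}" for i in range(5)],
                      columns=[f"s{j}" for j in range(6)])
    return CountMatrix(df)


@pytest.fixture(scope="session")
def small_cohort():
    """Small synthetic cohort with planted BPD signal, shared across tests."""
    cfg = SimulationConfig(n_subjects=60, n_genes=600, n_pathways=30,
                           genes_per_pathway=(6, 10),
                           frac_signal_genes=0.05, signal_log2fc=1.2,
                           seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_norm(small_cohort):
    return run_preprocess(small_cohort.counts)
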