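import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from hyposig.io import ClinicalTable, CountMatrix
from hyposig.simulate import (CellLineSimConfig, CohortSimConfig,
                              simulate_cell_line_counts, simulate_tumor_cohort)

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cell_line_sim():
    """500-gene, 2-line simulation shared by fast unit tests."""
    cfg = CellLineSimConfig(n_genes=500, n_lines=2, n_program_genes=20,
                            line_support_probs={1: 0.4, 2: 0.6}, seed=11)
    return simulate_cell_line_counts(cfg)


@pytest.fixture(scope="session")
def default_cell_line_sim():
    """One draw at the packaged study conditions."""
    return simulate_cell_line_counts(CellLineSimConfig(seed=7))


@pytest.fixture(scope="session")
def small_cohort_sim():
    """250-sample cohort with a 35-gene program plus 200 noise genes."""
    cfg = CohortSimConfig(n_samples=250,
                          program_genes=[f"P{i:03d}" for i in range(35)],
                          n_background_genes=200, effect_size=1.5, seed=5)
    return simulate_tumor_cohort(cfg)


@pytest.fixture
def toy_counts():
    """4-gene, 2-condition toy count matrix with hand-checkable structure."""
    counts = pd.DataFrame(
        {
            "L1_hyp_r1": [10, 100, 40, 0],
            "L1_hyp_r2": [12, 110, 38, 0],
            "L1_nor_r1": [11, 25, 42, 1],
            "L1_nor_r2": [9, 30, 41, 0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    meta = pd.DataFrame(
        {
            "line": ["L1"] * 4,
            "condition": ["hypoxia", "hypoxia", "normoxia", "normoxia"],
            "replicate": [1, 2, 1, 2],
        },
        index=counts.columns,
    )
    return CountMatrix(counts, meta)


@pytest.fixture
def toy_clinical():
    df = pd.DataFrame(
        {
            "time": [80.0, 59.0, 30.0, 120.0, 12.0, 45.0],
            "event": [1, 1, 0, 1, 1, 0],
            "stage": [1, 0, 0, 1, 1, 0],
            "sex": [0, 1, 1, 0, 1, 0],
        },
        index=[f"s{i}" for i in range(6)],
    )
    return ClinicalTable(df)
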