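import numpy as np
import pandas as pd
import pytest

from tric4 import reference
from tric4.cohort import SimulationConfig, sample_genotypes, simulate_cohort


@pytest.fixture(scope="session")
def ref_table():
    return reference.hla_trisnp_table()


@pytest.fixture(scope="session")
def small_cohort():
    """2000-subject simulated cohort with outcomes (session-cached)."""
    return simulate_cohort(SimulationConfig(n_subjects=2000), seed=3)


@pytest.fixture(scope="session")
def small_genotypes():
    return sample_genotypes(SimulationConfig(n_subjects=500), seed=11)


def roster_from_table(table):
    """Expand a contingency table back into (row_label, col_label) pairs."""
    pairs = []
    for i, r in enumerate(table.row_labels):
        for j, c in enumerate(table.col_labels):
            pairs.extend([(r, c)] * int(table.counts[i, j]))
    return pairs
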