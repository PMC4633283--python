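import numpy as np
import pandas as pd
import pytest

from switchgrain.data import Comparison, CountMatrix, StudyDesign
from switchgrain.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def design() -> StudyDesign:
    return StudyDesign()


@pytest.fixture
def two_sample_design() -> StudyDesign:
    return StudyDesign(samples=("A", "B"), replicates=3)


def make_matrix(values, design, level="gene", unit="raw", mapped_totals=None, ids=None):
    """Build a CountMatrix from a 2-D array against a design."""
    values = np.asarray(values, float)
    ids = ids or [f"e{i}" for i in range(values.shape[0])]
    cols = list(design.columns)
    totals = pd.Series(
        np.full(len(cols), 1e6) if mapped_totals is None else np.asarray(mapped_totals, float),
        index=cols,
    )
    return CountMatrix(
        data=pd.DataFrame(values, index=ids, columns=cols),
        mapped_totals=totals, design=design, level=level, unit=unit,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A modest simulated dataset shared by read-only tests."""
    cfg = SimulationConfig(
        n_genes=250, depth=1_000_000.0, dispersion=0.1, seed=42,
        expression_range=(5.0, 800.0), low_expression_fraction=0.15,
        fraction_induced=0.05, fraction_repressed=0.05, fraction_switch=0.05,
        isoforms_per_gene={1: 0.3, 2: 0.35, 3: 0.2, 4: 0.1, 5: 0.05},
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def pair_24fe_ut() -> Comparison:
    return Comparison("24Fe", "UT")
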