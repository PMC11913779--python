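import numpy as np
import pandas as pd
import pytest

from icibiomarkers import (
    SimulationConfig,
    normalize_log,
    simulate_pseudobulk_panel,
    simulate_single_cell_reference,
)
from icibiomarkers.datatypes import ExpressionMatrix


@pytest.fixture(scope="session")
def small_config():
    """A compact but structurally faithful simulation setup."""
    return SimulationConfig(
        n_genes=400,
        n_cell_types=4,
        n_markers_per_type=20,
        cells_per_type=80,
        cells_per_pseudobulk=250,
        n_patients=16,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_reference(small_config):
    return simulate_single_cell_reference(small_config)


@pytest.fixture(scope="session")
def small_panel(small_config, small_reference):
    return simulate_pseudobulk_panel(small_reference, 12, small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def paired_log_matrix():
    """A tiny paired pre/on cohort on the log scale with one induced gene."""
    rng = np.random.default_rng(5)
    genes = [f"g{i}" for i in range(40)]
    patients = [f"P{i}" for i in range(8)]
    cols, meta = {}, []
    base = rng.uniform(2, 6, size=(40, 8))
    for j, p in enumerate(patients):
        pre = base[:, j] + rng.normal(0, 0.05, 40)
        on = base[:, j] + rng.normal(0, 0.05, 40)
        on[0] += 2.0  # strongly induced gene
        cols[f"{p}_pre"], cols[f"{p}_on"] = pre, on
        meta += [
            {"patient": p, "timepoint": "PreTx"},
            {"patient": p, "timepoint": "ICI-4W"},
        ]
    values = pd.DataFrame(cols, index=genes)
    samples = pd.DataFrame(meta, index=values.columns)
    return ExpressionMatrix(values, samples, scale="log")
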