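import numpy as np
import pandas as pd
import pytest

from rflesion.config import default_config
from rflesion.processing import oracle_index_fn, process_traces, resample_trace
from rflesion.synthetic import cohort_traces, simulate_cohort


@pytest.fixture(scope="session")
def constants():
    """Calibrated stand-in metric constants (AI=400 @ 7 s, LSI=4 @ 20 s)."""
    return default_config().constants


@pytest.fixture(scope="session")
def uniform_grid():
    """A 10 s analysis grid at 997 Hz."""
    return np.arange(0, 10, 1 / 997.0)


@pytest.fixture(scope="session")
def midsize_lesions(constants):
    """Lesion table from a 120-lesion synthetic cohort processed with the
    ground-truth index oracle; shared by the statistics-level tests."""
    traces = cohort_traces(simulate_cohort(120, seed=21))
    return process_traces(traces, oracle_index_fn(constants))


@pytest.fixture(scope="session")
def small_indexed_traces(constants):
    """Twelve uniform-grid traces with their oracle AI/LSI series."""
    traces = [resample_trace(t) for t in cohort_traces(simulate_cohort(12, seed=5))]
    fn = oracle_index_fn(constants)
    return [(t, *fn(t)) for t in traces]
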