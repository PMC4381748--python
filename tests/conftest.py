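import numpy as np
import pandas as pd
import pytest

from dimspipe.core import PeakMatrix, SampleRecord, records_to_frame
from dimspipe.synthetic_data import TruthParams, make_design, simulate_matrix


@pytest.fixture(scope="session")
def small_design():
    """Three-batch desk-scale design: 6 biologicals + 3 QCs + 1 blank/batch."""
    return make_design(n_batches=3, n_bio=6, qc_per_batch=3, n_blanks=1, seed=0)


@pytest.fixture(scope="session")
def default_design():
    return make_design(seed=0)


@pytest.fixture(scope="session")
def small_matrix(small_design):
    pm, truth = simulate_matrix(small_design, TruthParams(n_features=60), seed=7)
    return pm, truth


def toy_matrix(values, sample_types, batches=None, run_orders=None, classes=None,
               groups=None, feature_mz=None):
    """Build a PeakMatrix from a plain nested list (None = missing)."""
    values = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in values]
    )
    n, p = values.shape
    batches = batches or [1] * n
    run_orders = run_orders or list(range(1, n + 1))
    classes = classes or [
        "cow" if t == "biological" else "none" for t in sample_types
    ]
    groups = groups or [
        f"G{i}" if t == "biological" else ("QC" if t == "QC" else "")
        for i, t in enumerate(sample_types)
    ]
    records = [
        SampleRecord(f"S{i:02d}", sample_types[i], batches[i], run_orders[i],
                     classes[i], groups[i])
        for i in range(n)
    ]
    frame = records_to_frame(records)
    mz = feature_mz if feature_mz is not None else np.arange(1, p + 1) * 100.0
    data = pd.DataFrame(values, index=frame.index, columns=np.asarray(mz, float))
    return PeakMatrix(data, frame)
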