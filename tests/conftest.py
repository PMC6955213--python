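import numpy as np
import pandas as pd
import pytest

from epinet.containers import CountMatrix, NormalizedMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_counts(rng):
    """20 genes x 5 samples of random integer counts, no ERCC."""
    genes = [f"g{i}" for i in range(20)]
    samples = [f"s{j}" for j in range(5)]
    counts = pd.DataFrame(rng.integers(0, 200, size=(20, 5)) + 1,
                          index=genes, columns=samples)
    meta = pd.DataFrame({"batch": "b0", "stage": "st0"}, index=samples)
    return CountMatrix(counts=counts, is_ercc=pd.Series(False, index=genes),
                       metadata=meta)


def make_normalized(values: np.ndarray, log_scale=True, batch=None):
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    md = pd.DataFrame(index=samples)
    if batch is not None:
        md["batch"] = list(batch)
    return NormalizedMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        metadata=md, log_scale=log_scale,
    )
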