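import numpy as np
import pytest

from gmmfilt import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def small_matrix(rng):
    """30 genes x 8 samples, log2 scale, two clear expression modes."""
    means = np.r_[rng.normal(5.0, 0.5, 18), rng.normal(10.0, 0.5, 12)]
    values = means[:, None] + rng.normal(0, 0.4, (30, 8))
    return ExpressionMatrix(
        values,
        gene_ids=np.array([f"g{i}" for i in range(30)]),
        sample_ids=np.array([f"s{i}" for i in range(8)]),
        scale="log2",
    )


@pytest.fixture
def two_group_labels(small_matrix):
    return {s: ("a" if i < 4 else "b") for i, s in enumerate(small_matrix.sample_ids)}
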