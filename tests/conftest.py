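import numpy as np
import pytest

from mbfuse.data_model import MultiblockDataset, OmicsBlock, SampleMetadata
from mbfuse.synthetic_data import SimConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_block(matrix, name="block", state="raw", sample_ids=None,
               feature_ids=None):
    matrix = np.asarray(matrix, dtype=float)
    n, p = matrix.shape
    return OmicsBlock(
        name=name,
        matrix=matrix,
        sample_ids=sample_ids or tuple(f"S{i+1}" for i in range(n)),
        feature_ids=feature_ids or tuple(f"f{j+1}" for j in range(p)),
        state=state,
    )


def make_metadata(n, factor="group", levels=("A", "B"), sample_ids=None):
    half = n // 2
    values = tuple(levels[0] if i < half else levels[1] for i in range(n))
    return SampleMetadata(
        sample_ids=sample_ids or tuple(f"S{i+1}" for i in range(n)),
        factors={factor: values},
    )


def autoscaled_dataset(matrices, names=None, seed=0):
    """Build a block_scale-ready dataset from raw numeric matrices by
    autoscaling them directly (states forced; for ComDim unit tests)."""
    blocks = []
    n = np.asarray(matrices[0]).shape[0]
    sample_ids = tuple(f"S{i+1}" for i in range(n))
    for i, m in enumerate(matrices):
        m = np.asarray(m, dtype=float)
        m = m - m.mean(axis=0)
        sd = m.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        blocks.append(make_block(m / sd, name=(names[i] if names else f"b{i}"),
                                 state="autoscaled", sample_ids=sample_ids))
    metadata = SampleMetadata(sample_ids=sample_ids)
    return MultiblockDataset(blocks=tuple(blocks), metadata=metadata)


@pytest.fixture
def sim_dataset():
    return simulate(SimConfig(seed=7))
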