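import numpy as np
import pandas as pd
import pytest

from nmlineage.scar_data import GFP_UNSCARRED, ScarTable


def make_scar_table(rng, n_samples=6, n_scars=10, fish_id="F1", n_organs=3,
                    max_count=200, sparsity=0.5):
    """Random well-formed scar table with replicate structure."""
    counts = rng.integers(0, max_count, size=(n_samples, n_scars + 1))
    mask = rng.random((n_samples, n_scars + 1)) < sparsity
    counts = counts * mask
    counts[:, 0] = rng.integers(1, max_count, size=n_samples)  # GFP_unscarred
    organs = [f"organ{i % n_organs}" for i in range(n_samples)]
    reps = [f"r{i // n_organs + 1}" for i in range(n_samples)]
    index = [f"{fish_id}_{o}_{r}" for o, r in zip(organs, reps)]
    cols = [GFP_UNSCARRED] + [f"{s % 7}:d{s}" for s in range(n_scars)]
    meta = pd.DataFrame(
        {
            "fish_id": fish_id,
            "organ": organs,
            "axis_position": "NA",
            "replicate_id": reps,
        },
        index=pd.Index(index, name="sample_id"),
    )
    return ScarTable(
        pd.DataFrame(counts.astype(np.int64), index=meta.index, columns=cols),
        meta,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def scar_table_factory():
    return make_scar_table
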