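import numpy as np
import pandas as pd
import pytest

import founderrate as fr
from founderrate import synth


@pytest.fixture(scope="session")
def wrangel():
    return fr.wrangel_schedule()


@pytest.fixture(scope="session")
def table1():
    return synth.table1_fixture()


@pytest.fixture()
def make_dataset():
    """Build an AlignedDataset from a {sample_id: sequence} mapping."""

    def _make(seqs: dict, **meta_cols):
        meta = pd.DataFrame({"sample_id": list(seqs)}, **{}).set_index("sample_id")
        for k, v in meta_cols.items():
            meta[k] = v
        return fr.AlignedDataset(records=tuple(seqs.items()), metadata=meta)

    return _make


@pytest.fixture(scope="session")
def star_dataset():
    """A 14-sample, 7-haplotype star alignment with its generator truth."""
    records, truth = synth.generate_star_alignment(
        n_samples=14, n_haplotypes=7, max_steps=2, L=900, seed=11
    )
    meta = pd.DataFrame({"sample_id": [r[0] for r in records]}).set_index("sample_id")
    ds = fr.AlignedDataset(records=tuple(records), metadata=meta)
    return ds, truth
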