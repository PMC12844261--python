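import numpy as np
import pandas as pd
import pytest

from envqsar import (
    CompoundRecord,
    DescriptorVector,
    ReferenceDataset,
    default_config,
    gen_reference_dataset,
)


def make_dataset(X: pd.DataFrame, y, prop="logKoc", n_test=0) -> ReferenceDataset:
    """Wrap a plain DataFrame/response into a ReferenceDataset (first rows
    train, last ``n_test`` rows test)."""
    compounds, response, split = [], {}, {}
    yv = np.asarray(y, dtype=float)
    n = len(X)
    for i in range(n):
        cid = f"r{i:04d}"
        desc = DescriptorVector({c: float(X.iloc[i][c]) for c in X.columns})
        compounds.append(CompoundRecord(id=cid, descriptors=desc))
        response[cid] = float(yv[i])
        split[cid] = "test" if i >= n - n_test else "train"
    return ReferenceDataset(compounds=compounds, response=response, split=split, property=prop)


@pytest.fixture(scope="session")
def koc_dataset():
    """Synthetic log Koc reference set at the standard 500/132 split."""
    return gen_reference_dataset(default_config("logKoc", seed=101))


@pytest.fixture(scope="session")
def kpuu_dataset():
    """Small log Kp,uu set (60/14) with an 11-compound validation slice."""
    return gen_reference_dataset(default_config("logKpuu", seed=202, n_validation=11))
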