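import numpy as np
import pandas as pd
import pytest

from aktredox.matrix import OmicsMatrix
from aktredox.network import build_network, reference_parameters


def make_omics(values, treatments, times=None, scale="log2-normalized", feature_ids=None):
    """Build an OmicsMatrix from a 2-D array and per-column labels."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    if times is None:
        times = ["1 h"] * n_samp
    if feature_ids is None:
        feature_ids = [f"f{i:03d}" for i in range(n_feat)]
    sample_ids = [f"s{j}" for j in range(n_samp)]
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "treatment": treatments,
            "time": times,
            "replicate": list(range(1, n_samp + 1)),
            "channel": ["tmt%d" % (j % 6 + 1) for j in range(n_samp)],
        }
    )
    vals = pd.DataFrame(values, index=feature_ids, columns=sample_ids)
    return OmicsMatrix(values=vals, samples=samples, scale=scale)


@pytest.fixture(scope="session")
def network():
    return build_network()


@pytest.fixture(scope="session")
def ref_params():
    return reference_parameters()
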