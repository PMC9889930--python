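import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from eegdr.pipeline import FeatureMatrix


@pytest.fixture
def planted_matrix():
    """Factory for a two-class matrix with a few strongly informative
    features planted among Gaussian noise columns."""

    def make(n_per_class=30, n_informative=3, n_noise=50, effect=2.5, seed=0):
        rng = np.random.default_rng(seed)
        n = 2 * n_per_class
        X = rng.standard_normal((n, n_informative + n_noise))
        y = np.repeat([0, 1], n_per_class)
        X[y == 1, :n_informative] += effect
        cols = [f"inf_{i}" for i in range(n_informative)] + \
               [f"noise_{i}" for i in range(n_noise)]
        df = pd.DataFrame(X, columns=cols,
                          index=[f"s{i:03d}" for i in range(n)])
        return FeatureMatrix(X=df, y=y)

    return make


@pytest.fixture
def small_recording():
    from eegdr.io import Recording
    rng = np.random.default_rng(11)
    return Recording(channels=["c1", "c2"], data=rng.standard_normal((2, 2500)),
                     sampling_rate=250.0, subject_id="subj")
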