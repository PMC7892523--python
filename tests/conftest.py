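"""Shared fixtures: small synthetic datasets and fitted RDCV results.

Everything is generated programmatically with fixed seeds; session scope
keeps the cost of the fitted-results fixtures to one run each.
"""

import numpy as np
import pytest

from serscv.preprocess import preprocess_pipeline
from serscv.rdcv import RDCV, RDCVConfig
from serscv.simulate import SyntheticConfig, default_band_library, generate_dataset


@pytest.fixture(scope="session")
def band_library():
    return default_band_library()


@pytest.fixture(scope="session")
def raw_small():
    """20 samples/class x 3 replicates with a clear class effect."""
    return generate_dataset(
        SyntheticConfig(n_per_class=20, n_replicates=3, effect_size=0.5,
                        biological_cv=0.1, seed=101)
    )


@pytest.fixture(scope="session")
def processed_small(raw_small):
    processed, _ = preprocess_pipeline(raw_small)
    return processed


@pytest.fixture(scope="session")
def signal_results(processed_small):
    """Fitted RDCV on the small signal dataset (10 repetitions)."""
    cfg = RDCVConfig(n_rep=10, seed=202)
    return RDCV.from_spectra(processed_small, cfg).fit()


@pytest.fixture(scope="session")
def null_processed():
    """Null-model dataset: no class effect, 20 samples/class."""
    ss = generate_dataset(
        SyntheticConfig(n_per_class=20, n_replicates=2, effect_size=0.0,
                        seed=303)
    )
    processed, _ = preprocess_pipeline(ss)
    return processed


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
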