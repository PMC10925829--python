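import numpy as np
import pandas as pd
import pytest

from rootclines.synthetic import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study shared across tests."""
    cfg = SimConfig(n_train=40, n_target=120, n_descriptors=15, n_informative=4,
                    n_snps=400, n_genes=40, n_causal_genes=3,
                    trait_env_r2=0.5, trait_snp_h2=0.1, seed=11)
    return simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def blob_frame(rng):
    """Two well-separated Gaussian blobs with string ids."""
    X = np.vstack([rng.normal(0.0, 0.3, (20, 3)), rng.normal(5.0, 0.3, (20, 3))])
    ids = [f"b{i:02d}" for i in range(40)]
    return pd.DataFrame(X, index=ids), np.array([0] * 20 + [1] * 20)
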