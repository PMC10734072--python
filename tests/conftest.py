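import numpy as np
import pytest

from alssubtypes import (NsNMFConfig, SyntheticConfig, generate_discovery)
from alssubtypes.nsnmf import fit_cluster_model
from alssubtypes.preprocess import preprocess_counts


@pytest.fixture(scope="session")
def small_config():
    """A small planted-subtype configuration used across the suite."""
    return SyntheticConfig(n_genes=400, n_samples=60, k_clusters=3,
                           signature_size=25, log2_fold_change=2.0,
                           nb_dispersion=0.2, seed=11)


@pytest.fixture(scope="session")
def small_discovery(small_config):
    return generate_discovery(small_config)


@pytest.fixture(scope="session")
def small_fit(small_discovery):
    """Preprocessed matrix and fitted cluster model for the small cohort."""
    disc, _ = small_discovery
    norm, top = preprocess_counts(disc, n_top=200)
    V = norm.to_frame().loc[top].to_numpy()
    cfg = NsNMFConfig(k=3, theta=0.5, n_runs=3, max_iter=500, tol=1e-6,
                      seed=5)
    fact, cmodel = fit_cluster_model(V, cfg)
    return {"disc": disc, "norm": norm, "top": top, "V": V,
            "fact": fact, "cmodel": cmodel}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
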