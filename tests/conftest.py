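import numpy as np
import pytest
from hypothesis import settings

import bayesgrowth as bg

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def study_data():
    """One simulated mean-weight dataset per sex at the default design."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return bg.generate_mean_weights(seed=7)


@pytest.fixture(scope="session")
def vb_fits(study_data):
    """Von Bertalanffy fits for both sexes, shared across test modules."""
    cfg = lambda s: bg.ChainConfig(n_chains=4, n_iterations=2000, seed=s)
    return {
        "female": bg.fit_growth_model(
            "von_bertalanffy", study_data["female"], config=cfg(1)
        ),
        "male": bg.fit_growth_model(
            "von_bertalanffy", study_data["male"], config=cfg(2)
        ),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
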