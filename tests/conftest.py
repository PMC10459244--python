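import numpy as np
import pytest

from fiprisk.doseresponse import FIPRONIL_CONVULSION, fit_all_models
from fiprisk.mcmc import McmcSettings


@pytest.fixture(scope="session")
def convulsion_fits_small():
    """Reduced-scale fits of all 8 dichotomous models to the convulsion data.

    3 chains x 8,000 iterations is enough for stable medians and weights in
    unit tests; the acceptance tests re-fit at full scale.
    """
    settings = McmcSettings(n_chains=3, n_iter=8_000, warmup_fraction=0.5, seed=76_316)
    return fit_all_models(FIPRONIL_CONVULSION, settings)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230807)
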