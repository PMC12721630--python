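import numpy as np
import pytest

import redoxmr as rx


@pytest.fixture(scope="session")
def config20k() -> rx.SimulationConfig:
    """Default study conditions at a sample size where large-sample
    properties (variance calibration, mediation identity) are visible."""
    return rx.SimulationConfig(n_subjects=20000, seed=11)


@pytest.fixture(scope="session")
def cohort20k(config20k):
    gm, pheno = rx.simulate_cohort(config20k)
    grs = rx.build_grs(gm, gm.rsids)
    return gm, pheno, grs


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
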