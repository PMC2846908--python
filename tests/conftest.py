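import numpy as np
import pytest

from scanfuse.simulate import TruthModel, default_study_fixture, simulate_scanset


@pytest.fixture(scope="session")
def mini_fixture():
    """Reduced standard study: 2000 probes x 8 arrays x 3 scans."""
    return default_study_fixture(mini=True, seed=2010)


@pytest.fixture(scope="session")
def censored_cauchy_fixture():
    """5000 probes x 4 arrays with heavy high-scan saturation and Cauchy
    noise — the regime where fusing scans must beat any single scan."""
    model = TruthModel(n_probes=5000, n_arrays=4, n_negcontrols=50,
                       scan_gains=(1.0, 5.0, 25.0), background_mean=50.0,
                       background_sd=10.0, noise_model="cauchy",
                       noise_scale_coeff=0.05, expression_meanlog=6.2,
                       expression_sdlog=2.2, seed=11)
    return simulate_scanset(model)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
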