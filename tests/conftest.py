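import numpy as np
import pytest

from chronopk import ExperimentDesign, NoiseModel, TimedReplicates


@pytest.fixture(scope="session")
def design():
    return ExperimentDesign()


@pytest.fixture(scope="session")
def quiet_noise():
    """No stochastic noise anywhere: generators reproduce the model exactly."""
    return NoiseModel(expression_cv=0.0, pk_inter_animal_cv=0.0, pk_assay_cv=0.0,
                      biolum_sd=0.0, biolum_trend_slope=0.0)


@pytest.fixture(scope="session")
def cosine_replicates():
    """Noise-free single-cosine data: y(t) = 10 + 6.2 cos(2pi (t-10.5)/24)."""
    zts = np.arange(0, 24, 3.0)
    values = [[10 + 6.2 * np.cos(2 * np.pi * (t - 10.5) / 24)] for t in zts]
    return TimedReplicates(zt_hours=list(zts), values_per_zt=values, label="clean")
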