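import numpy as np
import pytest

from gehroc.synthetic import EcgGenParams, generate_ecg12


@pytest.fixture(scope="session")
def clean_record():
    """Noise-free 10-beat record with known vector geometry."""
    return generate_ecg12(
        EcgGenParams(
            qrs_peak_dir=(20.0, 60.0),
            t_peak_dir=(35.0, 45.0),
            noise_sd=0.0,
            baseline_wander_amp=0.0,
            seed=11,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
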