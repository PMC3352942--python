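import numpy as np
import pytest

from slnet import DEFAULT_BANDS, SLParams, montez_params
from slnet.recording import Recording


@pytest.fixture(scope="session")
def alpha_params() -> SLParams:
    """Frequency-adapted SL settings for a 12-s alpha-band epoch at 250 Hz."""
    return montez_params(250.0, DEFAULT_BANDS["alpha"], 3000)


@pytest.fixture(scope="session")
def quick_params() -> SLParams:
    """Settings usable on short (~300-sample) epochs for oracle comparisons."""
    return SLParams(m=3, l=2, p_ref=0.05, w1=5, w2=80)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def noise_recording(rng) -> Recording:
    return Recording(
        data=rng.standard_normal((4, 3000)), fs=250.0,
        labels=["c1", "c2", "c3", "c4"],
    )
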