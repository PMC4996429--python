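import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from snarfcal import CalibrationParameters, SyntheticConfig
from snarfcal.synth import simulate_ratio_series

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.filter_too_much, HealthCheck.too_slow],
)
settings.load_profile("default")

#: limiting intensities used throughout: channel 1 (586 nm) falls and
#: channel 2 (636 nm) rises with pH, as for a SNARF-type probe
INTENSITIES = dict(i1a=100.0, i1b=20.0, i2a=30.0, i2b=120.0)


@pytest.fixture
def bulk_cal() -> CalibrationParameters:
    """Bulk-solution-like calibration: pKa 7.46, no cooperativity."""
    return CalibrationParameters(pka=7.46, n=1.0, method_tag="eq9", **INTENSITIES)


@pytest.fixture
def mito_cal() -> CalibrationParameters:
    """In-organello-like calibration: pKa 8.51, anticooperative n 0.54."""
    return CalibrationParameters(pka=8.51, n=0.54, method_tag="eq9", **INTENSITIES)


@pytest.fixture
def mito_config() -> SyntheticConfig:
    """Default synthetic study conditions: 25 points, pH 4.8-11, 1% noise."""
    return SyntheticConfig()


@pytest.fixture
def noiseless_mito():
    """(dataset, ratio series, truth) with zero noise at the default truth."""
    return simulate_ratio_series(SyntheticConfig(noise_sd=0.0, seed=0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
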