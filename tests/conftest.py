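import pytest
from hypothesis import HealthCheck, settings

from escc_cea import default_config
from escc_cea.survival import WeibullParams

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# Weibull fits to the trial's digitized survival curves (months^-shape, -)
CTP_PFS = WeibullParams(scale=0.035843, shape=1.440454)
CTP_OS = WeibullParams(scale=0.005274, shape=1.798021)
PTP_PFS = WeibullParams(scale=0.030222, shape=1.824045)
PTP_OS = WeibullParams(scale=0.006991, shape=1.818036)


@pytest.fixture(scope="session")
def base_cfg():
    return default_config()


@pytest.fixture()
def cfg(base_cfg):
    """Fresh mutable copy of the packaged base case."""
    return base_cfg.copy()
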