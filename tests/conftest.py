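import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("det")

from aortasim import extract_features, simulate_config, standard_config  # noqa: E402


@pytest.fixture(scope="session")
def standard():
    return standard_config()


@pytest.fixture(scope="session")
def standard_waveforms(standard):
    """Root, AA and AB waveforms of the calibrated standard configuration."""
    g = standard.geometry
    root, aa, ab = simulate_config(
        standard, sensor_positions=[0.0, g.aa_position, g.ab_position]
    )
    return {"root": root, "aa": aa, "ab": ab}


@pytest.fixture(scope="session")
def standard_features(standard_waveforms):
    return extract_features(standard_waveforms["root"])
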