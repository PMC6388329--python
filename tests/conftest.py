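import pytest
from hypothesis import HealthCheck, settings

from pulsesim import SimulatorConfig, age_preset, run_to_steady_state

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def preset_results():
    """Steady-state runs of the three shipped age presets, computed once."""
    return {grp: run_to_steady_state(age_preset(grp))
            for grp in ("young", "middle", "older")}


@pytest.fixture(scope="session")
def default_result():
    """Steady-state run of the default (middle-aged-like) configuration."""
    return run_to_steady_state(SimulatorConfig())
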