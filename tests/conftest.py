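import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel_bundle():
    """One full synthetic eight-material study, shared across tests."""
    from nanosites.synthetic_data import gen_panel

    return gen_panel(seed=11)


@pytest.fixture(scope="session")
def panel_analysis(panel_bundle):
    from nanosites.workflow import analyze_panel

    return analyze_panel(panel_bundle)
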