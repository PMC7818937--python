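import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_ref():
    from circscreen import make_toy_reference

    return make_toy_reference(seed=7)


@pytest.fixture(scope="session")
def toy_windows(toy_ref):
    from circscreen import build_bsj_window

    return {rec.circ_id: build_bsj_window(rec, toy_ref.genome) for rec in toy_ref.circs}
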