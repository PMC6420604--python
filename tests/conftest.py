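import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_state_model():
    """Compact classifier trained/evaluated on animal-disjoint synthetic epochs."""
    from ictaloop.experiments import train_state_classifier

    model, evaluation, n_train, n_test = train_state_classifier(
        11,
        n_train_animals=3,
        n_test_animals=2,
        train_duration=450.0,
        test_duration=350.0,
        n_estimators=100,
    )
    return model, evaluation


@pytest.fixture(scope="session")
def pv0_session():
    """One rendered PV_ChR2 closed-loop session (0-s delay trials)."""
    from ictaloop.closed_loop import SchedulerPolicy, run_closed_loop_session

    policy = SchedulerPolicy(delay_classes=("0",), warmup=30.0)
    recording, stims = run_closed_loop_session("PV_ChR2", policy, 300.0, 9)
    return recording, stims


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
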