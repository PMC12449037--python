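import pytest
from hypothesis import HealthCheck, settings

from kounispv.synthetic import (
    SIGNAL_EVENT_PTS,
    GeneratorConfig,
    PlantedSignal,
    default_dictionary,
    generate,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def meddra():
    """The built-in synthetic terminology bundle."""
    return default_dictionary()


@pytest.fixture(scope="session")
def small_sim():
    """One moderately sized synthetic database with its ground truth."""
    cfg = GeneratorConfig(
        n_cases=4000,
        seed=7,
        planted_signals=(
            PlantedSignal(
                "Sugammadex", frozenset({SIGNAL_EVENT_PTS[0]}), 4.0,
                p_drug=0.05, p_event=0.05,
            ),
            PlantedSignal(
                "Eltrombopag", frozenset({SIGNAL_EVENT_PTS[1]}), 1.0,
                p_drug=0.05, p_event=0.05,
            ),
        ),
    )
    db, truth = generate(cfg)
    return cfg, db, truth
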