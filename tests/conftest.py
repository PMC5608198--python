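import numpy as np
import pytest

from emtqa.synthetic_phantom import BreathingModel, PhantomScenario, generate_plan, generate_recording


@pytest.fixture(scope="session")
def small_scenario() -> PhantomScenario:
    """Four arc catheters, eight dwell points each, calm chest breathing."""
    return PhantomScenario(
        n_catheters=4,
        catheter_length=50.0,
        n_dwells_per_catheter=8,
        breathing=BreathingModel.for_mode("chest"),
        noise_sd=0.5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_phantom(small_scenario):
    """(plan, recording, ground_truth) of the small scenario."""
    plan = generate_plan(small_scenario)
    recording, truth = generate_recording(plan, small_scenario)
    return plan, recording, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
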