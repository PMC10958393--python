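import pytest
from hypothesis import HealthCheck, settings

import opnote as op

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def catalog():
    return op.load_catalog()


@pytest.fixture(scope="session")
def small_noiseless(catalog):
    """A small, fast, noise-free dataset for unit-level pipeline tests."""
    config = op.SimulationConfig(
        n_videos=20,
        length_median_frames=600,
        length_sigma=0.3,
        # moderate core presence so every step sees training negatives
        presence_prob={"core": 0.7, "optional": 0.3, "instrument": 0.4},
        duration_range_frames=(20, 60),
        noise=op.NoiseConfig.degenerate(),
        seed=0,
    )
    return op.simulate_dataset(config, catalog)


def all_negative(catalog):
    return {s.step_id: False for s in catalog}
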