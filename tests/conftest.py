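import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_mixed_table():
    """5-column table: real, binary, nominal, real, real (one row of each
    structure), complete."""
    from aganimpute import MixedTypeTable

    values = np.array(
        [
            [0.5, 0.0, 0.0, 1.2, -3.5],
            [1.5, 1.0, 1.0, 2.2, -1.5],
            [2.5, 0.0, 2.0, 3.2, 0.5],
            [3.5, 1.0, 3.0, 4.2, 2.5],
            [4.25, 1.0, 1.0, 5.2, 4.5],
        ]
    )
    return MixedTypeTable(values, ["c1", "c2", "c3", "c4", "c5"])


@pytest.fixture
def quick_cfg():
    """A config small enough for sub-second training in unit tests."""
    from aganimpute import TrainingConfig

    return TrainingConfig(
        epochs=4, pretrain_epochs=2, batch_size=32, hidden_units=8, seed=0
    )


@pytest.fixture
def small_synthetic():
    from aganimpute import SyntheticSpec, generate

    return generate(SyntheticSpec(n=150, seed=11))
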