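import numpy as np
import pytest
from hypothesis import settings

from bzkymo import make_linear_layout

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from bzkymo.synth import LifecycleSchedule, StageSpec


@pytest.fixture
def single_droplet_layout():
    return make_linear_layout(1)


@pytest.fixture
def three_droplet_layout():
    return make_linear_layout(3)


def source_schedule(
    n_waves: int = 10,
    period_s: float = 50.0,
    origin: str = "low",
    induction_s: float = 10.0,
) -> LifecycleSchedule:
    """A droplet that emits ``n_waves`` evenly spaced waves and nothing else."""
    return LifecycleSchedule(
        induction_s=induction_s,
        initial=StageSpec(0.0, 1.0),
        main=StageSpec(n_waves * period_s, 1.0 / period_s, None, 80.0),
        late=StageSpec(0.0, 1.0),
        origin=origin,
        spiral_start_probability=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
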