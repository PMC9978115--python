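import numpy as np
import pytest
from hypothesis import settings

from meaburst import Recording, SpikeTrain

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")


def make_recording(trains: dict[str, list[float]], duration: float) -> Recording:
    return Recording(
        trains={
            eid: SpikeTrain(eid, np.asarray(t, dtype=float))
            for eid, t in trains.items()
        },
        duration=duration,
    )


@pytest.fixture
def small_recording() -> Recording:
    return make_recording(
        {"E1": [0.1, 0.3, 0.9], "E2": [0.2, 0.8], "E3": []}, duration=1.0
    )


def poisson_recording(
    rate_hz: float, n_electrodes: int, duration: float, seed: int
) -> Recording:
    rng = np.random.default_rng(seed)
    trains = {}
    for i in range(n_electrodes):
        n = rng.poisson(rate_hz * duration)
        trains[f"E{i:02d}"] = np.unique(rng.random(n) * duration)
    return make_recording(trains, duration)
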