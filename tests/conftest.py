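import numpy as np
import pytest

from groomsim import Cohort, Ethogram


@pytest.fixture
def simple_ethogram() -> Ethogram:
    labels = ["head_sweep"] * 100 + ["body_sweep"] * 100
    return Ethogram("f1", np.array(labels), frame_rate_hz=10.0)


@pytest.fixture
def simple_cohort(simple_ethogram) -> Cohort:
    other = Ethogram("f2", simple_ethogram.labels[::-1].copy(), frame_rate_hz=10.0)
    return Cohort([simple_ethogram, other], group_name="toy")


def make_ethogram(labels, fly_id="f1", frame_rate_hz=30.0) -> Ethogram:
    return Ethogram(fly_id, np.array(labels, dtype="U16"), frame_rate_hz)
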