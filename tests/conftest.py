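import numpy as np
import pytest

from pupilhmm.models import BehaviorSession
from pupilhmm.task import generate_schedule, sample_outcomes


def make_session(choices_left, outcomes_left, participant="p1", block="volatile"):
    """Build a BehaviorSession from 0/1 arrays (1 = left)."""
    ch = np.where(np.asarray(choices_left, bool), "left", "right").astype(object)
    oc = np.where(np.asarray(outcomes_left, bool), "left", "right").astype(object)
    return BehaviorSession(participant=participant, block_label=block, choices=ch, outcomes=oc)


@pytest.fixture(scope="session")
def schedule_160():
    return generate_schedule(160, 20, 4, seed=7)


@pytest.fixture(scope="session")
def outcomes_160(schedule_160):
    return sample_outcomes(schedule_160, seed=11)
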