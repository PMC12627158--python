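import numpy as np
import pytest

from patchforage import EnvConfig, EventRecord, SessionLog


@pytest.fixture
def env():
    return EnvConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_log(river_specs, participant_id="p1", session="pre", condition="none"):
    """Build a SessionLog from [(outcomes, left?), ...] river descriptions.

    ``outcomes`` is a list of 0/1 pan results; ``left`` says whether the
    river ends with a leave action (the last river may not).
    """
    events = []
    t = 0
    for ri, (outcomes, left) in enumerate(river_specs, start=1):
        for si, o in enumerate(outcomes, start=1):
            t += 1
            events.append(
                EventRecord(
                    participant_id=participant_id,
                    condition=condition,
                    session=session,
                    river_index=ri,
                    step_in_river=si,
                    global_time_after=t,
                    action="pan",
                    outcome=o,
                )
            )
        if left:
            t += 5
            events.append(
                EventRecord(
                    participant_id=participant_id,
                    condition=condition,
                    session=session,
                    river_index=ri,
                    step_in_river=len(outcomes) + 1,
                    global_time_after=t,
                    action="leave",
                    outcome=None,
                )
            )
    return SessionLog(events=events, metadata={"participant_id": participant_id})


@pytest.fixture
def toy_log():
    """Two completed rivers plus an unfinished final river."""
    return make_log(
        [
            ([0, 0, 1, 0], True),  # 1 nugget, leaves after 1 failure-run
            ([1, 1, 0, 0], True),  # 2 nuggets, leaves after 2 failures
            ([1, 0], False),  # session ended inside this river
        ]
    )
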