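import numpy as np
import pytest

from collmove import (
    IndividualRecord,
    JoinRecord,
    MovementEvent,
    SimulationConfig,
    simulate_study,
    table1_roster,
)


@pytest.fixture(scope="session")
def roster12():
    """The packaged 12-adult roster."""
    return table1_roster()


@pytest.fixture(scope="session")
def roster32():
    """Full 32-member group: packaged adults plus generated non-adults."""
    from collmove import make_roster

    return make_roster(SimulationConfig())


@pytest.fixture(scope="session")
def quorum_study():
    """A small seeded quorum-rule study shared by read-only tests."""
    return simulate_study(SimulationConfig(rule="quorum", n_events=120, seed=11))


@pytest.fixture(scope="session")
def selective_study():
    return simulate_study(SimulationConfig(rule="selective", n_events=171, seed=3))


def make_event(event_id, joiner_ids, join_times, group_size=32, adult_ids=None,
               early_window=300.0, entire_fraction=2.0 / 3.0):
    """Hand-build a MovementEvent for metric tests."""
    import math

    adult_ids = set(adult_ids if adult_ids is not None else joiner_ids)
    joins = [
        JoinRecord(individual_id=i, join_time_s=t, position=p + 1)
        for p, (i, t) in enumerate(zip(joiner_ids, join_times))
    ]
    early = {
        j.individual_id
        for j in joins
        if j.individual_id in adult_ids and j.join_time_s <= early_window
    }
    return MovementEvent(
        event_id=event_id,
        initiator_id=joiner_ids[0],
        start_s=0.0,
        direction_deg=0.0,
        joins=joins,
        termination_s=join_times[-1] + 300.0,
        entire_group=len(joins) >= math.ceil(entire_fraction * group_size - 1e-12),
        early_joiner_ids=early,
    )


@pytest.fixture
def make_event_factory():
    return make_event
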