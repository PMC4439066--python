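import math

import numpy as np
import pandas as pd
import pytest

from collmove import (
    IndividualRecord,
    JoinRecord,
    SegmentationParams,
    SimulationConfig,
    ValidationError,
    apply_termination,
    classify_event,
    detect_initiation,
    detect_joiners,
    presence_filter,
    segment_session,
)
from collmove.segmentation import Initiation, entire_group_quorum, presence_at_start
from collmove.simulate import render_positions, simulate_and_segment, simulate_schedules

PARAMS = SegmentationParams()


def track(ind, points):
    return pd.DataFrame(
        [{"individual_id": ind, "t_s": t, "x_m": x, "y_m": y} for t, x, y in points]
    )


def stationary(ind, t_end, x=0.0, y=0.0, step=5.0):
    return track(ind, [(t, x, y) for t in np.arange(0, t_end + step / 2, step)])


@pytest.fixture
def mini_roster():
    return [
        IndividualRecord("AD1", "male", "adult", 10, 1),
        IndividualRecord("AD2", "female", "adult", 10, 1),
        IndividualRecord("JUV", "male", "juvenile", 2, 2),
    ]


class TestInitiation:
    def test_adult_moving_12m_in_20s_initiates(self, mini_roster):
        fixes = pd.concat([
            track("AD1", [(0, 0, 0), (10, 6, 0), (20, 12, 0), (30, 12, 0)]),
            stationary("AD2", 30, x=2),
            stationary("JUV", 30, y=2),
        ])
        cands = detect_initiation(fixes, mini_roster, PARAMS)
        assert [c.initiator_id for c in cands] == ["AD1"]
        assert cands[0].start_s == 0 and cands[0].direction_deg == 0

    def test_fast_juvenile_never_initiates(self, mini_roster):
        fixes = pd.concat([
            stationary("AD1", 30), stationary("AD2", 30, x=2),
            track("JUV", [(0, 0, 0), (10, 15, 0), (20, 15, 0), (30, 15, 0)]),
        ])
        assert detect_initiation(fixes, mini_roster, PARAMS) == []

    def test_exactly_10m_in_30s_is_not_initiation(self, mini_roster):
        fixes = pd.concat([
            track("AD1", [(0, 0, 0), (30, 10.0, 0), (60, 10.0, 0)]),
            stationary("AD2", 60, x=2), stationary("JUV", 60, y=2),
        ])
        assert detect_initiation(fixes, mini_roster, PARAMS) == []


class TestJoiners:
    def _with_mover(self, mini_roster, bearing_deg, dist=6.0):
        rad = math.radians(bearing_deg)
        fixes = pd.concat([
            track("AD1", [(0, 0, 0), (10, 12, 0), (600, 12, 0)]),
            track("AD2", [(0, 0, 2), (10, 0, 2),
                          (60, dist * math.cos(rad), 2 + dist * math.sin(rad)),
                          (600, dist * math.cos(rad), 2 + dist * math.sin(rad))]),
            stationary("JUV", 600, y=-2),
        ])
        init = detect_initiation(fixes, mini_roster, PARAMS)[0]
        return detect_joiners(fixes, init, mini_roster, PARAMS)

    def test_6m_at_44_degrees_joins(self, mini_roster):
        records = self._with_mover(mini_roster, 44.0)
        assert [r.individual_id for r in records] == ["AD1", "AD2"]
        assert records[1].join_time_s == 60

    def test_6m_at_46_degrees_does_not_join(self, mini_roster):
        records = self._with_mover(mini_roster, 46.0)
        assert [r.individual_id for r in records] == ["AD1"]

    def test_widening_cone_never_removes_candidate_joiners(self):
        config = SimulationConfig(rule="quorum", n_events=5, seed=21)
        roster, _, schedules = simulate_schedules(config)
        for i, s in enumerate(schedules):
            fixes, _ = render_positions(s, roster, config, np.random.default_rng(i))
            init = detect_initiation(fixes, roster, PARAMS)[0]
            narrow = {r.individual_id
                      for r in detect_joiners(fixes, init, roster,
                                              SegmentationParams(join_cone_deg=30))}
            wide = {r.individual_id
                    for r in detect_joiners(fixes, init, roster,
                                            SegmentationParams(join_cone_deg=60))}
            assert narrow <= wide


class TestTermination:
    def _records(self, times):
        return [
            JoinRecord(individual_id=f"I{i}", join_time_s=t, position=i + 1)
            for i, t in enumerate(times)
        ]

    def test_truncates_at_first_long_gap(self):
        kept, term = apply_termination(self._records([0, 100, 250, 600]), PARAMS)
        assert [r.join_time_s for r in kept] == [0, 100, 250]
        assert term == 550

    def test_lone_initiator_terminates_after_gap(self):
        kept, term = apply_termination(self._records([0]), PARAMS)
        assert len(kept) == 1 and term == 300

    def test_gaps_of_exactly_299s_all_kept(self):
        times = [299.0 * i for i in range(10)]
        kept, _ = apply_termination(self._records(times), PARAMS)
        assert len(kept) == 10


class TestClassification:
    def _classify(self, n_joins, roster32, late_adult=None):
        init = Initiation("TG", 0.0, 0.0, 0.0, 0.0, 12.0)
        ids = [r.id for r in roster32]
        ids.remove("TG")
        records = [JoinRecord("TG", 0.0, 1, 12.0, 0.0)]
        for i in range(n_joins - 1):
            t = 301.0 if ids[i] == late_adult else 10.0 * (i + 1)
            records.append(JoinRecord(ids[i], t, i + 2))
        records.sort(key=lambda r: r.join_time_s)
        for p, r in enumerate(records):
            records[p] = JoinRecord(r.individual_id, r.join_time_s, p + 1)
        return classify_event("e1", init, records, 1000.0, roster32, PARAMS)

    def test_two_thirds_of_32_is_22(self, roster32):
        assert entire_group_quorum(32) == 22
        assert self._classify(22, roster32).entire_group
        assert not self._classify(21, roster32).entire_group

    def test_adult_joining_after_early_window_excluded(self, roster32):
        ev = self._classify(5, roster32, late_adult="ZL")
        assert "ZL" in ev.joiner_ids and "ZL" not in ev.early_joiner_ids

    def test_initiator_counts_as_early_joiner(self, roster32):
        assert "TG" in self._classify(3, roster32).early_joiner_ids


class TestPresence:
    def _event_with_positions(self, roster32, n_near):
        ids = [r.id for r in roster32]
        frames = [track(ids[0], [(0, 0, 0), (10, 12, 0), (40, 12, 0)])]
        for i, ind in enumerate(ids[1:], start=1):
            d = 5.0 if i < n_near else 50.0
            frames.append(stationary(ind, 40, x=d, y=float(i) * 1e-3))
        fixes = pd.concat(frames)
        init = detect_initiation(fixes, roster32, PARAMS)[0]
        records = detect_joiners(fixes, init, roster32, PARAMS)
        kept, term = apply_termination(records, PARAMS)
        ev = classify_event("e1", init, kept, term, roster32, PARAMS)
        return ev, fixes

    def test_individual_at_exactly_10m_counts_as_present(self, roster32):
        ev, fixes = self._event_with_positions(roster32, 32)
        fixes.loc[fixes["individual_id"] == "YZ", "x_m"] = 10.0
        fixes.loc[fixes["individual_id"] == "YZ", "y_m"] = 0.0
        assert "YZ" in presence_at_start(ev, fixes, PARAMS)

    def test_21_of_32_near_drops_event_22_keeps(self, roster32):
        ev, fixes = self._event_with_positions(roster32, 22)
        assert presence_filter([ev], fixes, roster32, PARAMS) == [ev]
        ev2, fixes2 = self._event_with_positions(roster32, 21)
        assert presence_filter([ev2], fixes2, roster32, PARAMS) == []


class TestOracleAgreement:
    @pytest.mark.parametrize("rule,seed", [("quorum", 31), ("selective", 32), ("anonymous", 33)])
    def test_rendered_events_recover_latent_schedules(self, rule, seed):
        config = SimulationConfig(rule=rule, n_events=40, seed=seed)
        roster, events, truths = simulate_and_segment(config)
        assert len(events) == len(truths)
        exact = sum(
            ev.initiator_id == tr.initiator_id
            and [(j.individual_id, j.join_time_s) for j in ev.joins] == list(tr.joins)
            for ev, tr in zip(events, truths)
        )
        assert exact >= 0.99 * len(truths)

    def test_resegmenting_an_events_own_fixes_is_idempotent(self):
        config = SimulationConfig(rule="quorum", n_events=1, seed=13)
        roster, _, schedules = simulate_schedules(config)
        fixes, _ = render_positions(schedules[0], roster, config, np.random.default_rng(5))
        first = segment_session(fixes, roster, PARAMS)
        assert len(first) == 1
        ev = first[0]
        window = fixes[(fixes["t_s"] >= ev.start_s - 40) & (fixes["t_s"] <= ev.termination_s)]
        again = segment_session(window.reset_index(drop=True), roster, PARAMS)
        assert len(again) == 1
        assert again[0].initiator_id == ev.initiator_id
        assert [(j.individual_id, j.join_time_s) for j in again[0].joins] == [
            (j.individual_id, j.join_time_s) for j in ev.joins
        ]
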