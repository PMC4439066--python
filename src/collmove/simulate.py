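"""Generative simulator of collective-movement joining processes.

The simulator produces discrete departure events from a feeding site for a
group of 32 macaque-like individuals (4 adult males, 8 adult females and 20
non-adults by default), with join times governed by one of three rules:

``anonymous``
    an unjoined individual's hazard grows linearly with the number of
    individuals already moving, regardless of identity;
``selective``
    an unjoined adult's hazard grows with its summed affiliation to the
    adults already moving, weighted up for higher-ranking movers;
``quorum``
    hazards follow a (possibly mimetic) baseline until the number of moving
    adults reaches a threshold q, after which every remaining group member
    switches to a high constant hazard.

Two ingredients shared by all rules shape realistic event heterogeneity:

* joining impetus decays exponentially with time since the initiation
  (time constant ``decay_tau_s``), so a joining process either cascades
  within a few minutes or dies out — without this, no parameterisation can
  both accumulate many joiners inside the five-minute early window and
  still leave a realistic fraction of events terminated by the
  five-minute-gap rule;
* a lognormal per-event frailty multiplies all baseline hazards,
  capturing between-event context (weather, disturbance, patch quality)
  that makes some departures generally more contagious than others.

The post-quorum hazard is deliberately neither decayed nor
frailty-scaled: a reached quorum commits the group.

Besides latent join schedules, the module renders position fixes at a 5-s
cadence whose geometry guarantees that event segmentation recovers the
(grid-quantized) latent schedule exactly, and simulates focal-sample
proximity bouts whose dyadic rates follow the latent affiliation matrix.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as cmio
from .segmentation import (
    Initiation,
    SegmentationParams,
    apply_termination,
    classify_event,
    segment_session,
)
from .types import (
    IndividualRecord,
    JoinRecord,
    MovementEvent,
    ProximityBout,
    ValidationError,
    adults,
    dominance_score,
    validate_roster,
)

__all__ = [
    "GeometryConfig",
    "SimulationConfig",
    "JoinSchedule",
    "StudyData",
    "make_roster",
    "default_affiliation",
    "simulate_join_schedule",
    "simulate_schedules",
    "events_from_schedule",
    "render_positions",
    "simulate_focal_bouts",
    "simulate_study",
    "simulate_and_segment",
    "table1_roster",
]

RULES = ("anonymous", "selective", "quorum")


@dataclass(frozen=True)
class GeometryConfig:
    """Spatial parameters of the rendered feeding-site scene (metres, m/s)."""

    cadence_s: float = 5.0
    cluster_radius_m: float = 3.5  # rest positions around the initiator
    initiator_speed_mps: float = 0.38
    initiator_walk_s: float = 60.0
    joiner_speed_mps: float = 1.2
    joiner_walk_s: float = 30.0
    heading_margin_deg: float = 5.0  # kept clear of the 45-degree cone edge
    jitter_sd_m: float = 0.05
    pre_roll_s: float = 60.0


@dataclass
class SimulationConfig:
    """Generative rule, group composition and hazard parameters.

    Rates are per second.  ``base_hazard`` (lambda0) is the spontaneous
    joining rate; ``mimetism_gain`` (alpha) the per-already-joined increment
    (anonymous rule, and the pre-threshold baseline of the quorum rule);
    ``selective_gain`` scales the affiliation-weighted sum of the selective
    rule, with ``rank_weight`` (beta) amplifying high-ranking movers;
    ``post_quorum_hazard`` (lambda_q) applies to every remaining individual
    once ``quorum_threshold`` (q) adults are moving.  ``decay_tau_s`` and
    ``frailty_sd`` are described in the module docstring.
    """

    rule: str = "quorum"
    n_adult_males: int = 4
    n_adult_females: int = 8
    n_subadults: int = 6
    n_juveniles: int = 9
    n_infants: int = 5
    base_hazard: float = 4e-4
    mimetism_gain: float = 8e-4
    selective_gain: float = 2e-3
    rank_weight: float = 1.0
    nonadult_gain: float = 4e-4
    nonadult_gate: int = 2
    quorum_threshold: int = 7
    post_quorum_hazard: float = 0.05
    decay_tau_s: float = 150.0
    frailty_sd: float = 0.75
    gap_s: float = 300.0
    affiliation: np.ndarray | None = None
    n_events: int = 200
    seed: int = 0
    use_table1_adults: bool = True
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    n_focal_samples: int = 20
    focal_sample_s: float = 600.0
    bout_rate_per_affiliation: float = 1.0 / 300.0
    mean_bout_s: float = 20.0

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValidationError(f"unknown rule {self.rule!r}; expected one of {RULES}")
        for name in ("base_hazard", "post_quorum_hazard", "gap_s", "decay_tau_s"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("mimetism_gain", "selective_gain", "rank_weight",
                     "nonadult_gain", "frailty_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.quorum_threshold < 1:
            raise ValidationError("quorum_threshold must be >= 1")
        if self.quorum_threshold > self.n_adults:
            raise ValidationError("quorum_threshold cannot exceed the adult count")

    @property
    def n_adults(self) -> int:
        return self.n_adult_males + self.n_adult_females

    @property
    def group_size(self) -> int:
        return self.n_adults + self.n_subadults + self.n_juveniles + self.n_infants


@dataclass
class JoinSchedule:
    """Latent outcome of one simulated joining process.

    ``joins`` is the ordered list of (individual id, join time in seconds
    since the initiator's departure); the initiator is first at time 0.
    """

    initiator_id: str
    direction_deg: float
    joins: list[tuple[str, float]]

    @property
    def joiner_ids(self) -> list[str]:
        return [i for i, _ in self.joins]

    def join_times(self) -> dict[str, float]:
        return dict(self.joins)


@dataclass
class StudyData:
    """Everything one synthetic study produces."""

    config: SimulationConfig
    roster: list[IndividualRecord]
    affiliation: np.ndarray
    adult_ids: list[str]
    schedules: list[JoinSchedule]
    events: list[MovementEvent]
    bouts: list[ProximityBout]


def table1_roster() -> list[IndividualRecord]:
    """The packaged 12-adult roster (ids, sex, rank, age, focal durations)."""
    ref = importlib.resources.files("collmove.data") / "table1_roster.csv"
    with importlib.resources.as_file(ref) as path:
        return cmio.read_roster(path)


def make_roster(config: SimulationConfig) -> list[IndividualRecord]:
    """Roster for the configured composition.

    With the default 4-male/8-female adult block the packaged adult roster
    is used verbatim; otherwise generic adult ids are generated.  Non-adults
    get ids by age class, alternating sexes, with within-sex ranks
    continuing below the adults'.
    """
    roster: list[IndividualRecord] = []
    if (
        config.use_table1_adults
        and config.n_adult_males == 4
        and config.n_adult_females == 8
    ):
        roster.extend(table1_roster())
    else:
        for i in range(config.n_adult_males):
            roster.append(IndividualRecord(f"AM{i+1:02d}", "male", "adult", 10.0, i + 1))
        for i in range(config.n_adult_females):
            roster.append(IndividualRecord(f"AF{i+1:02d}", "female", "adult", 10.0, i + 1))
    next_rank = {
        "male": 1 + sum(1 for r in roster if r.sex == "male"),
        "female": 1 + sum(1 for r in roster if r.sex == "female"),
    }
    blocks = [
        ("SA", "subadult", 4.0, config.n_subadults),
        ("JU", "juvenile", 2.0, config.n_juveniles),
        ("IN", "infant", 0.5, config.n_infants),
    ]
    for prefix, age_class, age, count in blocks:
        for i in range(count):
            sex = "male" if i % 2 == 0 else "female"
            roster.append(
                IndividualRecord(
                    f"{prefix}{i+1:02d}", sex, age_class, age, next_rank[sex]
                )
            )
            next_rank[sex] += 1
    validate_roster(roster)
    return roster


def _dominance(roster: Sequence[IndividualRecord]) -> dict[str, float]:
    n_by_sex = {
        s: sum(1 for r in adults(roster) if r.sex == s) for s in ("male", "female")
    }
    return {r.id: dominance_score(r, n_by_sex[r.sex]) for r in adults(roster)}


def default_affiliation(
    roster: Sequence[IndividualRecord], rng: np.random.Generator
) -> np.ndarray:
    """Dominance-structured latent affiliation matrix over the adults.

    Dyads of two high-ranking animals affiliate most (despotic-style
    hierarchy); small symmetric noise keeps dyads distinct.  Entries are in
    [0.02, 0.95], diagonal 0.
    """
    ad = adults(roster)
    dom = _dominance(roster)
    n = len(ad)
    d = np.array([dom[r.id] for r in ad])
    base = 0.15 + 0.55 * np.outer(d, d)
    noise = rng.normal(0.0, 0.05, size=(n, n))
    noise = (noise + noise.T) / 2.0
    a = np.clip(base + noise, 0.02, 0.95)
    np.fill_diagonal(a, 0.0)
    return a


def _hazard_weights(
    config: SimulationConfig,
    unjoined: list[IndividualRecord],
    joined_ids: list[str],
    adult_ids: list[str],
    affiliation: np.ndarray,
    dom: dict[str, float],
    frailty: float,
    quorum_reached: bool,
) -> np.ndarray:
    """Undecayed hazard for each unjoined individual at the current state.

    Post-quorum hazards are constant (no decay, no frailty); all others are
    multiplied by the event frailty here and by the decay factor at
    sampling time.
    """
    if config.rule == "quorum" and quorum_reached:
        return np.full(len(unjoined), config.post_quorum_hazard)
    k_total = len(joined_ids)
    adult_index = {a: i for i, a in enumerate(adult_ids)}
    joined_adults = [j for j in joined_ids if j in adult_index]
    k_adults = len(joined_adults)
    out = np.zeros(len(unjoined))
    for i, rec in enumerate(unjoined):
        if rec.is_adult:
            if config.rule == "anonymous":
                lam = config.base_hazard + config.mimetism_gain * k_total
            elif config.rule == "selective":
                s = sum(
                    affiliation[adult_index[rec.id], adult_index[j]]
                    * (1.0 + config.rank_weight * dom[j])
                    for j in joined_adults
                )
                lam = config.base_hazard + config.selective_gain * s
            else:  # quorum, pre-threshold: mimetic baseline
                lam = config.base_hazard + config.mimetism_gain * k_adults
        else:
            if config.rule == "quorum":
                lam = 0.0  # non-adults commit only once the quorum is reached
            elif k_adults < config.nonadult_gate:
                lam = 0.0
            else:
                lam = config.base_hazard + config.nonadult_gain * k_adults
        out[i] = frailty * lam
    return out


def simulate_join_schedule(
    config: SimulationConfig,
    roster: Sequence[IndividualRecord],
    affiliation: np.ndarray,
    rng: np.random.Generator,
) -> JoinSchedule:
    """Sample one latent joining process by continuous-time next-event
    simulation with piecewise (between joins) decaying hazards.

    Truncated by the five-minute-gap rule exactly as segmentation applies
    it: if the waiting time to the next join exceeds ``gap_s`` the process
    terminates.
    """
    ad = adults(roster)
    adult_ids = [r.id for r in ad]
    dom = _dominance(roster)
    if config.rule == "selective":
        w = np.array([dom[r.id] for r in ad])
        initiator = ad[rng.choice(len(ad), p=w / w.sum())]
    else:
        initiator = ad[rng.integers(len(ad))]
    direction = float(rng.uniform(0.0, 360.0))
    frailty = (
        float(rng.lognormal(-config.frailty_sd**2 / 2.0, config.frailty_sd))
        if config.frailty_sd > 0
        else 1.0
    )

    joined: list[tuple[str, float]] = [(initiator.id, 0.0)]
    joined_ids = [initiator.id]
    unjoined = [r for r in roster if r.id != initiator.id]
    t = 0.0
    tau = config.decay_tau_s
    while unjoined:
        k_adults = sum(1 for j in joined_ids if j in set(adult_ids))
        quorum_reached = config.rule == "quorum" and k_adults >= config.quorum_threshold
        weights = _hazard_weights(
            config, unjoined, joined_ids, adult_ids, affiliation, dom,
            frailty, quorum_reached,
        )
        total = float(weights.sum())
        if total <= 0.0:
            break
        e = rng.exponential(1.0)
        if config.rule == "quorum" and quorum_reached:
            dt = e / total  # constant post-quorum hazard
        else:
            # integrated decaying hazard from t: total * tau * exp(-t/tau) * (1 - exp(-dt/tau))
            budget = total * tau * math.exp(-t / tau)
            if e >= budget:
                break  # hazard decays away before the next join
            dt = -tau * math.log1p(-e / budget)
        if dt > config.gap_s:
            break
        t += dt
        pick = int(rng.choice(len(unjoined), p=weights / total))
        rec = unjoined.pop(pick)
        joined.append((rec.id, t))
        joined_ids.append(rec.id)
    return JoinSchedule(initiator_id=initiator.id, direction_deg=direction, joins=joined)


def simulate_schedules(
    config: SimulationConfig,
) -> tuple[list[IndividualRecord], np.ndarray, list[JoinSchedule]]:
    """Roster, affiliation matrix and ``n_events`` latent schedules.

    One master seed; the affiliation draw, each event and the bout process
    use deterministic substreams, so identical configs reproduce byte-
    identical outputs.
    """
    roster = make_roster(config)
    master = np.random.SeedSequence(config.seed)
    affil_ss, events_ss, _ = master.spawn(3)
    if config.affiliation is not None:
        affiliation = np.asarray(config.affiliation, dtype=float)
        n = len(adults(roster))
        if affiliation.shape != (n, n) or not np.allclose(affiliation, affiliation.T):
            raise ValidationError("affiliation must be a symmetric n_adults matrix")
    else:
        affiliation = default_affiliation(roster, np.random.default_rng(affil_ss))
    schedules = [
        simulate_join_schedule(config, roster, affiliation, np.random.default_rng(ss))
        for ss in events_ss.spawn(config.n_events)
    ]
    return roster, affiliation, schedules


def events_from_schedule(
    schedule: JoinSchedule,
    roster: Sequence[IndividualRecord],
    params: SegmentationParams = SegmentationParams(),
    event_id: str = "sim0001",
    start_s: float = 0.0,
) -> MovementEvent:
    """Classify a latent schedule into a MovementEvent without rendering."""
    records = [
        JoinRecord(individual_id=i, join_time_s=t, position=p + 1)
        for p, (i, t) in enumerate(schedule.joins)
    ]
    records[0] = replace(records[0], bearing_deg=schedule.direction_deg)
    kept, termination = apply_termination(records, params)
    init = Initiation(
        initiator_id=schedule.initiator_id,
        start_s=start_s,
        x_m=0.0,
        y_m=0.0,
        direction_deg=schedule.direction_deg,
        displacement_m=float("nan"),
    )
    event = classify_event(event_id, init, kept, termination, roster, params)
    event.present_ids = {r.id for r in roster}
    return event


def _quantize_schedule(
    schedule: JoinSchedule, config: SimulationConfig
) -> JoinSchedule:
    """Snap join times to the fix grid, order-preservingly, and re-apply the
    gap rule; the result is the renderable ground truth.

    The minimum join time keeps every joiner's own >10-m-in-30-s window
    strictly later than the initiator's: a joiner walking at speed v covers
    the initiation distance within a window starting up to
    ``init_window - init_dist / v`` seconds before its walk starts, so join
    times are pushed past that lookback (plus one cadence step for the
    walk's head start).
    """
    g = config.geometry
    c = g.cadence_s
    seg = SegmentationParams()
    lookback = seg.init_window_s - seg.init_dist_m / g.joiner_speed_mps
    min_q = c * (math.floor((lookback + c) / c) + 1)
    out: list[tuple[str, float]] = [schedule.joins[0]]
    prev = 0.0
    for ind, t in schedule.joins[1:]:
        q = max(math.ceil(t / c) * c, min_q, prev + c)
        out.append((ind, q))
        prev = q
    # gap rule on the quantized times
    kept = [out[0]]
    prev = 0.0
    for ind, t in out[1:]:
        if t - prev > config.gap_s:
            break
        kept.append((ind, t))
        prev = t
    return JoinSchedule(
        initiator_id=schedule.initiator_id,
        direction_deg=schedule.direction_deg,
        joins=kept,
    )


def render_positions(
    schedule: JoinSchedule,
    roster: Sequence[IndividualRecord],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, JoinSchedule]:
    """Render one event as position fixes at a fixed cadence.

    All individuals rest in a tight cluster around the initiator's starting
    point (so the starting-zone presence filter passes); the initiator
    departs at a speed slow enough that no 30-s window straddling its rest
    phase reaches the 10-m initiation displacement, and each joiner walks
    fast enough to cross the 5-m joining displacement within one cadence
    step, on a heading inside the 45-degree cone by a safety margin.
    Returns the fixes and the quantized ground-truth schedule that
    segmentation recovers exactly.
    """
    g = config.geometry
    truth = _quantize_schedule(schedule, config)
    times = truth.join_times()
    t0 = g.pre_roll_s
    last = max(times.values())
    t_end = t0 + last + 60.0
    grid = np.arange(0.0, t_end + g.cadence_s / 2, g.cadence_s)
    theta = math.radians(truth.direction_deg)

    # rest anchors: initiator at the origin, everyone inside the cluster
    anchors: dict[str, tuple[float, float]] = {}
    for rec in roster:
        if rec.id == truth.initiator_id:
            anchors[rec.id] = (0.0, 0.0)
        else:
            r = g.cluster_radius_m * math.sqrt(rng.uniform())
            phi = rng.uniform(0.0, 2.0 * math.pi)
            anchors[rec.id] = (r * math.cos(phi), r * math.sin(phi))

    frames = []
    for rec in roster:
        ax, ay = anchors[rec.id]
        x = np.full_like(grid, ax)
        y = np.full_like(grid, ay)
        if rec.id == truth.initiator_id:
            walk_start, speed, dur = t0, g.initiator_speed_mps, g.initiator_walk_s
            heading = theta
        elif rec.id in times:
            # start one cadence step before the truth join time so the 5-m
            # crossing is first observed exactly at that fix
            walk_start = t0 + times[rec.id] - g.cadence_s
            speed, dur = g.joiner_speed_mps, g.joiner_walk_s
            offset = rng.uniform(
                -(45.0 - g.heading_margin_deg), 45.0 - g.heading_margin_deg
            )
            heading = theta + math.radians(offset)
        else:
            walk_start = None
        if walk_start is not None:
            dist = np.clip(grid - walk_start, 0.0, dur) * speed
            x = x + dist * math.cos(heading)
            y = y + dist * math.sin(heading)
        x = x + rng.normal(0.0, g.jitter_sd_m, size=len(grid))
        y = y + rng.normal(0.0, g.jitter_sd_m, size=len(grid))
        frames.append(
            pd.DataFrame(
                {"individual_id": rec.id, "t_s": grid, "x_m": x, "y_m": y}
            )
        )
    fixes = pd.concat(frames, ignore_index=True)
    return fixes, truth


def simulate_focal_bouts(
    affiliation: np.ndarray,
    roster: Sequence[IndividualRecord],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[ProximityBout]:
    """Simulate within-1-m proximity bouts over round-robin focal samples.

    Each adult is the focal animal of ``n_focal_samples`` samples of
    ``focal_sample_s`` seconds.  Within a sample, bouts with each adult
    partner arrive as a renewal process at rate
    ``bout_rate_per_affiliation * A[focal, partner]`` with exponential bout
    lengths, bouts of one (sample, partner) pair never overlapping.  The
    roster's adult ``focal_duration_s`` values are set to the simulated
    observation effort.
    """
    ad = adults(roster)
    ids = [r.id for r in ad]
    bouts: list[ProximityBout] = []
    for fi, focal in enumerate(ids):
        for s in range(config.n_focal_samples):
            sample_id = f"{focal}_s{s+1:03d}"
            for pi, partner in enumerate(ids):
                if partner == focal:
                    continue
                rate = config.bout_rate_per_affiliation * affiliation[fi, pi]
                if rate <= 0.0:
                    continue
                t = 0.0
                while True:
                    t += rng.exponential(1.0 / rate)
                    if t >= config.focal_sample_s:
                        break
                    dur = rng.exponential(config.mean_bout_s)
                    end = min(t + dur, config.focal_sample_s)
                    if end > t:
                        bouts.append(
                            ProximityBout(sample_id, focal, partner, t, end)
                        )
                    t = end
    effort = config.n_focal_samples * config.focal_sample_s
    for rec in ad:
        rec.focal_duration_s = effort
    return bouts


def simulate_study(config: SimulationConfig) -> StudyData:
    """Full synthetic study: schedules, classified events and focal bouts."""
    roster, affiliation, schedules = simulate_schedules(config)
    params = SegmentationParams(gap_s=config.gap_s)
    events = [
        events_from_schedule(s, roster, params, event_id=f"sim{i+1:04d}", start_s=float(i))
        for i, s in enumerate(schedules)
    ]
    bouts_rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    bouts = simulate_focal_bouts(affiliation, roster, config, bouts_rng)
    return StudyData(
        config=config,
        roster=roster,
        affiliation=affiliation,
        adult_ids=[r.id for r in adults(roster)],
        schedules=schedules,
        events=events,
        bouts=bouts,
    )


def simulate_and_segment(
    config: SimulationConfig,
    params: SegmentationParams = SegmentationParams(),
) -> tuple[list[IndividualRecord], list[MovementEvent], list[JoinSchedule]]:
    """Render every simulated event to fixes, segment each rendered session,
    and return (roster, segmented events, quantized ground-truth schedules).

    Each event is rendered as its own session; segmented events are
    re-timed so that session offsets do not collide.
    """
    roster, affiliation, schedules = simulate_schedules(config)
    render_ss = np.random.SeedSequence((config.seed, 1)).spawn(len(schedules))
    events: list[MovementEvent] = []
    truths: list[JoinSchedule] = []
    for i, (schedule, ss) in enumerate(zip(schedules, render_ss)):
        fixes, truth = render_positions(
            schedule, roster, config, np.random.default_rng(ss)
        )
        truths.append(truth)
        segmented = segment_session(
            fixes, roster, params, apply_presence=True, event_prefix=f"e{i+1:04d}_"
        )
        for ev in segmented:
            ev.start_s += i * 1e6  # keep session-relative times, unique ordering
            ev.termination_s += i * 1e6
            events.append(ev)
    return roster, events, truths
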