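"""Segment collective-movement events from position fixes.

The operational definitions follow standard macaque collective-movement
field protocols:

* initiation — the first adult whose net displacement exceeds 10 m within a
  window of at most 30 s; non-adults never initiate;
* joiner — any individual whose net displacement since the initiation
  exceeds 5 m with a bearing within 45 degrees of the initiator's departure
  direction, before the joining terminates;
* termination — the joining process ends at the first gap of more than five
  minutes without a new joiner (the first gap is measured from the
  initiator's departure);
* early joiner — an adult joiner (initiator included) whose join falls in
  the first five minutes;
* entire-group movement — at least two-thirds of all group members join;
* starting-zone filter — events are kept only when at least two-thirds of
  the group is within 10 m (inclusive) of the initiator's starting point at
  the moment of departure.

Distance thresholds for movement are strict (``>``); the starting-zone
radius is inclusive (``<=``).  Displacement is net (straight-line), not
path length.  Ties in join time are broken by roster id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    IndividualRecord,
    JoinRecord,
    MovementEvent,
    adults,
)

__all__ = [
    "SegmentationParams",
    "Initiation",
    "detect_initiation",
    "detect_joiners",
    "apply_termination",
    "classify_event",
    "presence_filter",
    "segment_session",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable thresholds of the event definitions (defaults = field protocol)."""

    init_dist_m: float = 10.0
    init_window_s: float = 30.0
    join_dist_m: float = 5.0
    join_cone_deg: float = 45.0
    gap_s: float = 300.0
    early_window_s: float = 300.0
    zone_radius_m: float = 10.0
    presence_fraction: float = 2.0 / 3.0
    entire_fraction: float = 2.0 / 3.0
    presence_fix_tol_s: float = 15.0

    def __post_init__(self) -> None:
        for name in (
            "init_dist_m", "init_window_s", "join_dist_m", "gap_s",
            "early_window_s", "zone_radius_m", "presence_fraction",
            "entire_fraction", "presence_fix_tol_s",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.join_cone_deg < 180:
            raise ValueError("join_cone_deg must lie in (0, 180)")


@dataclass(frozen=True)
class Initiation:
    """A candidate initiation: who departed, when, from where, heading where."""

    initiator_id: str
    start_s: float
    x_m: float
    y_m: float
    direction_deg: float
    displacement_m: float


def _tracks(fixes: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    out = {}
    for ind, grp in fixes.groupby("individual_id", sort=True):
        out[str(ind)] = (
            grp["t_s"].to_numpy(float),
            grp["x_m"].to_numpy(float),
            grp["y_m"].to_numpy(float),
        )
    return out


def _bearing_deg(dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    return np.degrees(np.arctan2(dy, dx)) % 360.0


def _angdiff_deg(a, b) -> np.ndarray:
    d = np.abs(np.asarray(a) - np.asarray(b)) % 360.0
    return np.minimum(d, 360.0 - d)


def detect_initiation(
    fixes: pd.DataFrame,
    roster: Sequence[IndividualRecord],
    params: SegmentationParams = SegmentationParams(),
    t_min: float = -math.inf,
) -> list[Initiation]:
    """Find candidate initiations at or after ``t_min``.

    For every adult, the earliest fix-to-fix window no longer than
    ``init_window_s`` whose net displacement strictly exceeds ``init_dist_m``
    is a candidate; candidates are sorted by start time, ties by id.  The
    departure direction is the bearing of the first qualifying displacement
    of that window start.  An empty list means no initiation was found.
    """
    adult_ids = {r.id for r in adults(roster)}
    tracks = _tracks(fixes)
    candidates: list[Initiation] = []
    for ind in sorted(adult_ids & set(tracks)):
        t, x, y = tracks[ind]
        keep = t >= t_min
        t, x, y = t[keep], x[keep], y[keep]
        n = len(t)
        if n < 2:
            continue
        best_i = None
        best_j = None
        for lag in range(1, n):
            dt = t[lag:] - t[:-lag]
            ok_t = dt <= params.init_window_s
            if not ok_t.any():
                break  # larger lags only increase dt (monotone timestamps)
            disp = np.hypot(x[lag:] - x[:-lag], y[lag:] - y[:-lag])
            hit = np.nonzero(ok_t & (disp > params.init_dist_m))[0]
            if len(hit):
                i = int(hit[0])
                if best_i is None or i < best_i or (i == best_i and lag < best_j - best_i):
                    best_i, best_j = i, i + lag
        if best_i is not None:
            dx, dy = x[best_j] - x[best_i], y[best_j] - y[best_i]
            candidates.append(
                Initiation(
                    initiator_id=ind,
                    start_s=float(t[best_i]),
                    x_m=float(x[best_i]),
                    y_m=float(y[best_i]),
                    direction_deg=float(_bearing_deg(dx, dy)),
                    displacement_m=float(math.hypot(dx, dy)),
                )
            )
    candidates.sort(key=lambda c: (c.start_s, c.initiator_id))
    return candidates


def detect_joiners(
    fixes: pd.DataFrame,
    initiation: Initiation,
    roster: Sequence[IndividualRecord],
    params: SegmentationParams = SegmentationParams(),
) -> list[JoinRecord]:
    """Candidate join records for one initiation, before termination.

    An individual joins at the first fix where its net displacement since
    the initiation strictly exceeds ``join_dist_m`` with a bearing within
    ``join_cone_deg`` of the departure direction.  Records are ordered by
    join time (relative to the initiator's departure), ties by id; the
    initiator occupies position 1 at time 0.  Apply :func:`apply_termination`
    before interpreting the result.
    """
    tracks = _tracks(fixes)
    t0 = initiation.start_s
    records = [
        JoinRecord(
            individual_id=initiation.initiator_id,
            join_time_s=0.0,
            position=1,
            displacement_m=initiation.displacement_m,
            bearing_deg=initiation.direction_deg,
        )
    ]
    others: list[tuple[float, str, float, float]] = []
    for ind in sorted(tracks):
        if ind == initiation.initiator_id:
            continue
        t, x, y = tracks[ind]
        before = np.nonzero(t <= t0)[0]
        if len(before) == 0:
            continue  # no anchor position at initiation time
        a = before[-1]
        after = t >= t0
        if not after.any():
            continue
        dx, dy = x[after] - x[a], y[after] - y[a]
        disp = np.hypot(dx, dy)
        moved = disp > params.join_dist_m
        if not moved.any():
            continue
        bearings = _bearing_deg(dx, dy)
        ok = moved & (_angdiff_deg(bearings, initiation.direction_deg) <= params.join_cone_deg)
        hit = np.nonzero(ok)[0]
        if len(hit) == 0:
            continue
        j = int(hit[0])
        others.append((float(t[after][j] - t0), ind, float(disp[j]), float(bearings[j])))
    others.sort(key=lambda r: (r[0], r[1]))
    for pos, (jt, ind, disp, bearing) in enumerate(others, start=2):
        records.append(
            JoinRecord(
                individual_id=ind,
                join_time_s=jt,
                position=pos,
                displacement_m=disp,
                bearing_deg=bearing,
            )
        )
    return records


def apply_termination(
    records: Sequence[JoinRecord],
    params: SegmentationParams = SegmentationParams(),
) -> tuple[list[JoinRecord], float]:
    """Truncate a time-ordered join list at the first gap exceeding ``gap_s``.

    The first gap is measured from the initiator's departure (time 0).
    Returns the kept records (positions renumbered 1..k) and the
    termination time, ``gap_s`` after the last kept join, both relative to
    the initiator's departure.
    """
    kept: list[JoinRecord] = []
    prev = 0.0
    for rec in records:
        if rec.join_time_s - prev > params.gap_s:
            break
        kept.append(rec)
        prev = rec.join_time_s
    kept = [replace(r, position=i + 1) for i, r in enumerate(kept)]
    termination = (kept[-1].join_time_s if kept else 0.0) + params.gap_s
    return kept, termination


def entire_group_quorum(group_size: int, fraction: float = 2.0 / 3.0) -> int:
    """Minimum joiner count for an entire-group movement: ceil(fraction * N)."""
    return int(math.ceil(fraction * group_size - 1e-12))


def classify_event(
    event_id: str,
    initiation: Initiation,
    kept_records: Sequence[JoinRecord],
    termination_rel_s: float,
    roster: Sequence[IndividualRecord],
    params: SegmentationParams = SegmentationParams(),
) -> MovementEvent:
    """Assemble a :class:`MovementEvent` from termination-applied records.

    ``entire_group`` is true when at least ``entire_fraction`` of the roster
    joined; early joiners are the adult joiners (initiator included) with
    join time at most ``early_window_s`` (inclusive boundary).
    """
    adult_ids = {r.id for r in adults(roster)}
    need = entire_group_quorum(len(roster), params.entire_fraction)
    early = {
        r.individual_id
        for r in kept_records
        if r.individual_id in adult_ids and r.join_time_s <= params.early_window_s
    }
    return MovementEvent(
        event_id=event_id,
        initiator_id=initiation.initiator_id,
        start_s=initiation.start_s,
        direction_deg=initiation.direction_deg,
        joins=list(kept_records),
        termination_s=initiation.start_s + termination_rel_s,
        present_ids=set(),
        entire_group=len(kept_records) >= need,
        early_joiner_ids=early,
    )


def presence_at_start(
    event: MovementEvent,
    fixes: pd.DataFrame,
    params: SegmentationParams = SegmentationParams(),
) -> set[str]:
    """Ids within ``zone_radius_m`` (inclusive) of the initiator's start
    point at the event start, using each individual's nearest fix within
    ``presence_fix_tol_s``; individuals with no such fix count as absent."""
    tracks = _tracks(fixes)
    init_track = tracks.get(event.initiator_id)
    if init_track is None:
        return set()
    t, x, y = init_track
    i0 = int(np.argmin(np.abs(t - event.start_s)))
    x0, y0 = x[i0], y[i0]
    present = set()
    for ind, (t, x, y) in tracks.items():
        i = int(np.argmin(np.abs(t - event.start_s)))
        if abs(t[i] - event.start_s) > params.presence_fix_tol_s:
            continue
        if math.hypot(x[i] - x0, y[i] - y0) <= params.zone_radius_m:
            present.add(ind)
    return present


def presence_filter(
    events: Sequence[MovementEvent],
    fixes: pd.DataFrame,
    roster: Sequence[IndividualRecord],
    params: SegmentationParams = SegmentationParams(),
) -> list[MovementEvent]:
    """Keep events with at least ``presence_fraction`` of the group in the
    starting zone at the moment of initiation; annotates ``present_ids``."""
    need = entire_group_quorum(len(roster), params.presence_fraction)
    kept = []
    for ev in events:
        present = presence_at_start(ev, fixes, params)
        ev.present_ids = present
        if len(present) >= need:
            kept.append(ev)
    return kept


def segment_session(
    fixes: pd.DataFrame,
    roster: Sequence[IndividualRecord],
    params: SegmentationParams = SegmentationParams(),
    apply_presence: bool = True,
    event_prefix: str = "ev",
) -> list[MovementEvent]:
    """Segment a whole session of fixes into movement events.

    Scans for the earliest initiation, extracts and terminates its joining
    process, then resumes the scan after the event's termination.
    """
    events: list[MovementEvent] = []
    t_min = -math.inf
    counter = 1
    while True:
        candidates = detect_initiation(fixes, roster, params, t_min=t_min)
        if not candidates:
            break
        init = candidates[0]
        records = detect_joiners(fixes, init, roster, params)
        kept, termination = apply_termination(records, params)
        event = classify_event(
            f"{event_prefix}{counter:04d}", init, kept, termination, roster, params
        )
        event.present_ids = presence_at_start(event, fixes, params)
        events.append(event)
        counter += 1
        t_min = event.termination_s
    if apply_presence:
        need = entire_group_quorum(len(roster), params.presence_fraction)
        events = [e for e in events if len(e.present_ids) >= need]
    return events
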