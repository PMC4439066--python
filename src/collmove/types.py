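"""Core domain types for collective-movement joining analysis.

The objects here mirror the quantities a field study of group departures
works with: a roster of individually known animals, time-stamped planar
position fixes, focal-sample proximity bouts, and segmented collective
movement events with their ordered join records.

Conventions
-----------
* Times are seconds, non-negative, relative to the start of an observation
  session; join times inside an event are relative to the initiator's
  departure.
* Coordinates are planar metres; bearings are degrees in [0, 360), measured
  counter-clockwise from the +x axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

SEXES = ("male", "female")
AGE_CLASSES = ("adult", "subadult", "juvenile", "infant")


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass
class IndividualRecord:
    """One group member: identity, demography and observation effort.

    ``rank_within_sex`` is the ordinal dominance rank inside the individual's
    sex class, 1 = highest.  ``focal_duration_s`` is the total focal-animal
    observation time for this individual (0 for animals never focal-sampled).
    """

    id: str
    sex: str
    age_class: str
    age_years: float
    rank_within_sex: int
    focal_duration_s: float = 0.0

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("individual id must be a non-empty token")
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r} for {self.id!r}")
        if self.age_class not in AGE_CLASSES:
            raise ValidationError(
                f"unknown age_class {self.age_class!r} for {self.id!r}"
            )
        if not self.age_years > 0:
            raise ValidationError(f"age_years must be positive for {self.id!r}")
        if int(self.rank_within_sex) != self.rank_within_sex or self.rank_within_sex < 1:
            raise ValidationError(
                f"rank_within_sex must be a positive integer for {self.id!r}"
            )
        self.rank_within_sex = int(self.rank_within_sex)
        if self.focal_duration_s < 0:
            raise ValidationError(
                f"focal_duration_s must be non-negative for {self.id!r}"
            )

    @property
    def is_adult(self) -> bool:
        return self.age_class == "adult"


def validate_roster(roster: Sequence[IndividualRecord]) -> None:
    """Check roster-level invariants.

    Ids must be unique, and the within-sex ranks of the *adults* must form a
    gap-free sequence 1..n for each sex.
    """
    seen: set[str] = set()
    for rec in roster:
        if rec.id in seen:
            raise ValidationError(f"duplicate individual id {rec.id!r} in roster")
        seen.add(rec.id)
    for sex in SEXES:
        ranks = sorted(
            r.rank_within_sex for r in roster if r.sex == sex and r.is_adult
        )
        if ranks and ranks != list(range(1, len(ranks) + 1)):
            raise ValidationError(
                f"adult {sex} ranks are not a gap-free 1..n sequence: {ranks}"
            )


def adults(roster: Sequence[IndividualRecord]) -> list[IndividualRecord]:
    return [r for r in roster if r.is_adult]


def dominance_score(rec: IndividualRecord, n_same_sex: int) -> float:
    """Normalized dominance in (0, 1]; 1 = top-ranked within its sex."""
    return (n_same_sex - rec.rank_within_sex + 1) / n_same_sex


@dataclass
class ProximityBout:
    """A within-1-m proximity bout between a focal animal and a partner."""

    sample_id: str
    focal_id: str
    partner_id: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.focal_id == self.partner_id:
            raise ValidationError(
                f"bout of {self.focal_id!r} with itself in sample {self.sample_id!r}"
            )
        if not self.end_s > self.start_s:
            raise ValidationError(
                f"bout end must exceed start in sample {self.sample_id!r}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class JoinRecord:
    """One individual's entry into a collective movement.

    ``position`` is the rank in the order of group progression (1 = the
    initiator); ``join_time_s`` is measured from the initiator's departure,
    so position 1 always has time 0.
    """

    individual_id: str
    join_time_s: float
    position: int
    displacement_m: float = float("nan")
    bearing_deg: float = float("nan")

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError("join position must be >= 1")
        if self.position == 1 and self.join_time_s != 0:
            raise ValidationError("position 1 (the initiator) must have time 0")
        if self.join_time_s < 0:
            raise ValidationError("join_time_s must be non-negative")
        if not math.isnan(self.bearing_deg):
            self.bearing_deg = self.bearing_deg % 360.0


@dataclass
class MovementEvent:
    """A segmented collective movement.

    ``early_joiner_ids`` holds the adult joiners (initiator included) whose
    join time falls within the early window (first five minutes by default);
    ``entire_group`` flags events joined by at least two-thirds of the group.
    """

    event_id: str
    initiator_id: str
    start_s: float
    direction_deg: float
    joins: list[JoinRecord]
    termination_s: float
    present_ids: set[str] = field(default_factory=set)
    entire_group: bool = False
    early_joiner_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.joins:
            raise ValidationError(f"event {self.event_id!r} has no join records")
        if self.joins[0].individual_id != self.initiator_id:
            raise ValidationError(
                f"event {self.event_id!r}: first join record must be the initiator"
            )
        times = [j.join_time_s for j in self.joins]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValidationError(
                f"event {self.event_id!r}: join times must be non-decreasing"
            )
        positions = [j.position for j in self.joins]
        if positions != list(range(1, len(positions) + 1)):
            raise ValidationError(
                f"event {self.event_id!r}: positions must be 1..k in order"
            )
        self.direction_deg = self.direction_deg % 360.0

    @property
    def n_joiners(self) -> int:
        return len(self.joins)

    @property
    def joiner_ids(self) -> list[str]:
        return [j.individual_id for j in self.joins]

    def position_of(self, individual_id: str) -> int | None:
        for j in self.joins:
            if j.individual_id == individual_id:
                return j.position
        return None


@dataclass
class AssociationMatrix:
    """Symmetric dyadic association index matrix with labelled rows/columns.

    ``kind`` distinguishes the half-weight index computed over movement
    events (HWI) from the proximity-based dyadic association index (DAI).
    Entries lie in [0, 1]; the diagonal is fixed at 0 by convention.
    """

    ids: list[str]
    values: np.ndarray
    kind: str  # "HWI" | "DAI"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError("matrix shape does not match id list")
        if self.kind not in ("HWI", "DAI"):
            raise ValidationError(f"unknown association kind {self.kind!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValidationError("association matrix must be symmetric")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValidationError("association entries must lie in [0, 1]")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValidationError("association diagonal must be 0")

    def entry(self, a: str, b: str) -> float:
        ia, ib = self.ids.index(a), self.ids.index(b)
        return float(self.values[ia, ib])


@dataclass
class CentralityVector:
    """Eigenvector centrality scores, non-negative, Euclidean norm 1."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids),):
            raise ValidationError("centrality length does not match id list")
        if np.any(self.values < -1e-12):
            raise ValidationError("centrality entries must be non-negative")
        if abs(np.linalg.norm(self.values) - 1.0) > 1e-9:
            raise ValidationError("centrality vector must have Euclidean norm 1")

    def score_of(self, individual_id: str) -> float:
        return float(self.values[self.ids.index(individual_id)])

    def as_dict(self) -> dict[str, float]:
        return {i: float(v) for i, v in zip(self.ids, self.values)}


@dataclass
class QuorumCurve:
    """Empirical early-joiner-count -> entire-group-probability curve.

    One row per observed early-joiner count k: the number of events with
    that count, how many of them were entire-group movements, and the
    empirical probability (undefined bins are simply absent).
    """

    k: np.ndarray
    n_events: np.ndarray
    n_entire: np.ndarray

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=int)
        self.n_events = np.asarray(self.n_events, dtype=int)
        self.n_entire = np.asarray(self.n_entire, dtype=int)
        if not (len(self.k) == len(self.n_events) == len(self.n_entire)):
            raise ValidationError("curve arrays must have equal length")
        if np.any(self.n_entire > self.n_events):
            raise ValidationError("n_entire cannot exceed n_events")
        if np.any(self.n_events < 1):
            raise ValidationError("curve bins must have at least one event")
        order = np.argsort(self.k)
        self.k = self.k[order]
        self.n_events = self.n_events[order]
        self.n_entire = self.n_entire[order]

    @property
    def probability(self) -> np.ndarray:
        return self.n_entire / self.n_events

    def prob_at(self, k: int) -> float | None:
        idx = np.nonzero(self.k == k)[0]
        if len(idx) == 0:
            return None
        return float(self.probability[idx[0]])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "k": self.k,
                "n_events": self.n_events,
                "n_entire": self.n_entire,
                "probability": self.probability,
            }
        )


def sorted_events(events: Iterable[MovementEvent]) -> list[MovementEvent]:
    """Deterministic event ordering: by start time, then event id."""
    return sorted(events, key=lambda e: (e.start_s, e.event_id))
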