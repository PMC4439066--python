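"""Readers and writers for the pipeline's file formats.

All files are plain UTF-8 CSV (comma separator, ``.`` decimal, mandatory
header) or JSON.  Floats are written with ``repr`` precision so every
write -> read round trip is lossless well below 1e-12.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    AssociationMatrix,
    CentralityVector,
    IndividualRecord,
    JoinRecord,
    MovementEvent,
    ProximityBout,
    ValidationError,
    sorted_events,
    validate_roster,
)

ROSTER_COLUMNS = ["id", "sex", "age_class", "age_years", "rank_within_sex", "focal_duration_s"]
FIX_COLUMNS = ["individual_id", "t_s", "x_m", "y_m"]
BOUT_COLUMNS = ["sample_id", "focal_id", "partner_id", "start_s", "end_s"]


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")


def read_roster(path) -> list[IndividualRecord]:
    """Read and validate a roster CSV (one row per individual)."""
    df = pd.read_csv(path, dtype={"id": str})
    _require_columns(df, ROSTER_COLUMNS, path)
    roster = []
    for i, row in df.iterrows():
        try:
            roster.append(
                IndividualRecord(
                    id=str(row["id"]),
                    sex=str(row["sex"]),
                    age_class=str(row["age_class"]),
                    age_years=float(row["age_years"]),
                    rank_within_sex=int(row["rank_within_sex"]),
                    focal_duration_s=float(row["focal_duration_s"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {i + 2}: {exc}") from exc
    ids = [r.id for r in roster]
    for i, r in enumerate(roster):
        if ids.index(r.id) != i:
            raise ValidationError(f"{path}: row {i + 2}: duplicate id {r.id!r}")
    validate_roster(roster)
    return roster


def write_roster(roster: Sequence[IndividualRecord], path) -> None:
    df = pd.DataFrame(
        [
            [r.id, r.sex, r.age_class, r.age_years, r.rank_within_sex, r.focal_duration_s]
            for r in roster
        ],
        columns=ROSTER_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_fixes(path, roster: Sequence[IndividualRecord] | None = None) -> pd.DataFrame:
    """Read a position-fix CSV into a time-sorted-per-individual frame.

    Timestamps must be strictly increasing within each individual; when a
    roster is supplied, ids not on it are rejected.
    """
    df = pd.read_csv(path, dtype={"individual_id": str})
    _require_columns(df, FIX_COLUMNS, path)
    df = df[FIX_COLUMNS].astype(
        {"t_s": float, "x_m": float, "y_m": float}
    )
    if (df["t_s"] < 0).any():
        line = int(df.index[df["t_s"] < 0][0]) + 2
        raise ValidationError(f"{path}: line {line}: negative timestamp")
    for ind, grp in df.groupby("individual_id", sort=False):
        t = grp["t_s"].to_numpy()
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if len(bad):
            line = int(grp.index[bad[0] + 1]) + 2
            raise ValidationError(
                f"{path}: line {line}: non-increasing timestamps for {ind!r}"
            )
    if roster is not None:
        known = {r.id for r in roster}
        unknown = set(df["individual_id"]) - known
        if unknown:
            raise ValidationError(f"{path}: unknown individual id(s) {sorted(unknown)}")
    return df.reset_index(drop=True)


def write_fixes(fixes: pd.DataFrame, path) -> None:
    fixes[FIX_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_bouts(path, roster: Sequence[IndividualRecord] | None = None) -> list[ProximityBout]:
    """Read proximity bouts; overlapping bouts of one (sample, partner) pair
    are rejected."""
    df = pd.read_csv(path, dtype={"sample_id": str, "focal_id": str, "partner_id": str})
    _require_columns(df, BOUT_COLUMNS, path)
    bouts = []
    for i, row in df.iterrows():
        try:
            bouts.append(
                ProximityBout(
                    sample_id=str(row["sample_id"]),
                    focal_id=str(row["focal_id"]),
                    partner_id=str(row["partner_id"]),
                    start_s=float(row["start_s"]),
                    end_s=float(row["end_s"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {i + 2}: {exc}") from exc
    by_pair: dict[tuple[str, str], list[ProximityBout]] = {}
    for b in bouts:
        by_pair.setdefault((b.sample_id, b.partner_id), []).append(b)
    for (sample, partner), group in by_pair.items():
        group = sorted(group, key=lambda b: b.start_s)
        for a, b in zip(group, group[1:]):
            if b.start_s < a.end_s:
                raise ValidationError(
                    f"{path}: overlapping bouts for sample {sample!r}, "
                    f"partner {partner!r} at {b.start_s} s"
                )
    if roster is not None:
        known = {r.id for r in roster}
        for i, b in enumerate(bouts):
            for who in (b.focal_id, b.partner_id):
                if who not in known:
                    raise ValidationError(f"{path}: row {i + 2}: unknown id {who!r}")
    return bouts


def write_bouts(bouts: Sequence[ProximityBout], path) -> None:
    df = pd.DataFrame(
        [[b.sample_id, b.focal_id, b.partner_id, b.start_s, b.end_s] for b in bouts],
        columns=BOUT_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.17g")


def write_matrix(matrix, path) -> None:
    """Write an association matrix or centrality vector as a labelled CSV."""
    if isinstance(matrix, CentralityVector):
        df = pd.DataFrame({"id": matrix.ids, "centrality": matrix.values})
        df.to_csv(path, index=False, float_format="%.17g")
        return
    df = pd.DataFrame(matrix.values, index=matrix.ids, columns=matrix.ids)
    df.index.name = "id"
    df.to_csv(path, float_format="%.17g")


def read_matrix(path, kind: str = "HWI") -> AssociationMatrix:
    df = pd.read_csv(path, index_col=0)
    ids = [str(c) for c in df.columns]
    return AssociationMatrix(ids=ids, values=df.to_numpy(dtype=float), kind=kind)


def _event_to_record(event: MovementEvent) -> dict:
    return {
        "event_id": event.event_id,
        "initiator_id": event.initiator_id,
        "start_s": event.start_s,
        "direction_deg": event.direction_deg,
        "joins": [
            {
                "individual_id": j.individual_id,
                "join_time_s": j.join_time_s,
                "position": j.position,
                "displacement_m": None if math.isnan(j.displacement_m) else j.displacement_m,
                "bearing_deg": None if math.isnan(j.bearing_deg) else j.bearing_deg,
            }
            for j in event.joins
        ],
        "termination_s": event.termination_s,
        "present_ids": sorted(event.present_ids),
        "entire_group": event.entire_group,
        "early_joiner_ids": sorted(event.early_joiner_ids),
    }


def write_events(events: Sequence[MovementEvent], path) -> None:
    """Serialize events as JSON, deterministically ordered by (start_s, id)."""
    records = [_event_to_record(e) for e in sorted_events(events)]
    Path(path).write_text(json.dumps(records, indent=1), encoding="utf-8")


def read_events(path) -> list[MovementEvent]:
    records = json.loads(Path(path).read_text(encoding="utf-8"))
    events = []
    for rec in records:
        joins = [
            JoinRecord(
                individual_id=j["individual_id"],
                join_time_s=j["join_time_s"],
                position=j["position"],
                displacement_m=float("nan") if j.get("displacement_m") is None else j["displacement_m"],
                bearing_deg=float("nan") if j.get("bearing_deg") is None else j["bearing_deg"],
            )
            for j in rec["joins"]
        ]
        events.append(
            MovementEvent(
                event_id=rec["event_id"],
                initiator_id=rec["initiator_id"],
                start_s=rec["start_s"],
                direction_deg=rec["direction_deg"],
                joins=joins,
                termination_s=rec["termination_s"],
                present_ids=set(rec.get("present_ids", [])),
                entire_group=rec["entire_group"],
                early_joiner_ids=set(rec.get("early_joiner_ids", [])),
            )
        )
    return events
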