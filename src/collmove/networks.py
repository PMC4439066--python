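"""Association indices, eigenvector centrality and joining-order indices.

Two dyadic association matrices are computed over a roster of adults:

* **HWI** — a co-occurrence ratio over movement events: the number of
  events in which both members of a dyad appear in the early-joiner set,
  divided by the total number of events.  (The classical half-weight
  variant with joint-absence terms, x / (x + y_ab + (y_a + y_b)/2), is
  available behind ``variant="whitehead"``.)
* **DAI** — a proximity-time index from focal samples:
  D_ab / (D_a + D_b - D_ab), where D_ab is the summed duration the dyad is
  seen within one metre and D_a, D_b are the focal observation durations.

Eigenvector centrality is the Perron eigenvector of the association
matrix, computed by shifted power iteration and cross-checkable against a
dense eigendecomposition.  The joining-order index scores progression
position I out of N as 1 - (I - 1)/(N - 1), from 1 (first) to 0 (last).
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .types import (
    AssociationMatrix,
    CentralityVector,
    IndividualRecord,
    MovementEvent,
    ProximityBout,
    ValidationError,
    adults,
)

__all__ = [
    "compute_hwi",
    "compute_dai",
    "eigenvector_centrality",
    "joining_order_index",
    "mean_joining_order",
]


def compute_hwi(
    events: Sequence[MovementEvent],
    ids: Sequence[str],
    use_all_joiners: bool = False,
    variant: str = "ratio",
) -> AssociationMatrix:
    """Half-weight association matrix over movement events.

    By default a dyad counts as "seen together" when both are in the
    event's early-joiner set; ``use_all_joiners=True`` uses the full joiner
    list instead.  ``variant="ratio"`` (default) divides joint counts by
    the total number of events; ``variant="whitehead"`` applies the
    classical half-weight denominator x + y_ab + (y_a + y_b) / 2.
    """
    if len(events) == 0:
        raise ValidationError("HWI requires at least one event")
    if variant not in ("ratio", "whitehead"):
        raise ValidationError(f"unknown HWI variant {variant!r}")
    ids = list(ids)
    index = {ind: i for i, ind in enumerate(ids)}
    n = len(ids)
    together = np.zeros((n, n))
    seen = np.zeros(n)
    for ev in events:
        members = set(ev.joiner_ids) if use_all_joiners else ev.early_joiner_ids
        present = [index[m] for m in members if m in index]
        for a in present:
            seen[a] += 1
        for i, a in enumerate(present):
            for b in present[i + 1:]:
                together[a, b] += 1
                together[b, a] += 1
    if variant == "ratio":
        values = together / len(events)
    else:
        x = together
        # y_a: events with a but not b; joint absences do not enter.
        y_a = seen[:, None] - x
        y_b = seen[None, :] - x
        denom = x + (y_a + y_b) / 2.0
        with np.errstate(invalid="ignore"):
            values = np.where(denom > 0, x / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(values, 0.0)
    return AssociationMatrix(ids=ids, values=values, kind="HWI")


def compute_dai(
    bouts: Sequence[ProximityBout],
    roster: Sequence[IndividualRecord],
    ids: Sequence[str] | None = None,
) -> AssociationMatrix:
    """Dyadic association index D_ab / (D_a + D_b - D_ab) from focal bouts.

    D_a is the focal observation duration of individual a taken from the
    roster; D_ab sums the durations of within-1-m bouts between a and b
    with either as the focal animal.
    """
    roster_by_id = {r.id: r for r in roster}
    if ids is None:
        ids = [r.id for r in adults(roster)]
    ids = list(ids)
    for ind in ids:
        if roster_by_id[ind].focal_duration_s <= 0:
            raise ValidationError(
                f"DAI requires a positive focal duration for {ind!r}"
            )
    index = {ind: i for i, ind in enumerate(ids)}
    n = len(ids)
    d_ab = np.zeros((n, n))
    for b in bouts:
        if b.focal_id in index and b.partner_id in index:
            i, j = index[b.focal_id], index[b.partner_id]
            d_ab[i, j] += b.duration_s
            d_ab[j, i] += b.duration_s
    d = np.array([roster_by_id[ind].focal_duration_s for ind in ids])
    denom = d[:, None] + d[None, :] - d_ab
    off = ~np.eye(n, dtype=bool)
    if np.any(denom[off] <= 0):
        bad = np.argwhere((denom <= 0) & off)[0]
        raise ValidationError(
            f"inconsistent durations for dyad ({ids[bad[0]]!r}, {ids[bad[1]]!r}): "
            "D_a + D_b - D_ab <= 0"
        )
    values = np.where(off, d_ab / np.where(off, denom, 1.0), 0.0)
    return AssociationMatrix(ids=ids, values=values, kind="DAI")


def _components(values: np.ndarray, ids: Sequence[str]) -> list[set[str]]:
    g = nx.Graph()
    g.add_nodes_from(range(len(ids)))
    for i, j in zip(*np.nonzero(values > 0)):
        if i < j:
            g.add_edge(int(i), int(j))
    return [{ids[i] for i in comp} for comp in nx.connected_components(g)]


def eigenvector_centrality(
    matrix: AssociationMatrix,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> CentralityVector:
    """Leading eigenvector of a connected association matrix.

    Power iteration on the spectrally shifted matrix A + cI (c = the
    maximum row sum, which dominates the spectral radius), so convergence
    is guaranteed even for bipartite-like structures whose smallest
    eigenvalue is -lambda_1.  The result is sign-fixed non-negative with
    Euclidean norm 1.  A zero or disconnected matrix is an error.
    """
    a = matrix.values
    n = len(matrix.ids)
    if not np.any(a > 0):
        raise ValidationError("cannot compute centrality of an all-zero matrix")
    comps = _components(a, matrix.ids)
    if len(comps) > 1:
        named = ", ".join("{" + ", ".join(sorted(c)) + "}" for c in comps)
        raise ValidationError(f"association matrix is disconnected: {named}")
    shift = float(a.sum(axis=1).max())
    b = a + shift * np.eye(n)
    v = np.full(n, 1.0 / math.sqrt(n))
    for _ in range(max_iter):
        w = b @ v
        w /= np.linalg.norm(w)
        if np.linalg.norm(w - v) <= tol * np.linalg.norm(w):
            v = w
            break
        v = w
    v = np.abs(v)  # Perron vector of a connected non-negative matrix
    v /= np.linalg.norm(v)
    return CentralityVector(ids=list(matrix.ids), values=v)


def joining_order_index(position: int, n: int) -> float:
    """1 - (I - 1)/(N - 1): 1 for the first position, 0 for the last."""
    if n < 2:
        raise ValidationError("joining order index requires N >= 2")
    if not 1 <= position <= n:
        raise ValidationError(f"position {position} outside 1..{n}")
    return 1.0 - (position - 1) / (n - 1)


def mean_joining_order(
    events: Iterable[MovementEvent],
    individual_id: str,
    n_convention: str = "joiners",
    group_size: int | None = None,
) -> float | None:
    """Mean joining-order index of one individual across the events it joined.

    ``n_convention`` fixes the N of the formula: ``"joiners"`` (default)
    uses the number of joiners of each event, ``"group"`` uses a fixed
    group size (required argument then).  Returns ``None`` when the
    individual joined no event (missing, never coerced to 0); events with a
    single joiner carry no order information and are skipped.
    """
    if n_convention not in ("joiners", "group"):
        raise ValidationError(f"unknown N convention {n_convention!r}")
    if n_convention == "group" and (group_size is None or group_size < 2):
        raise ValidationError("group convention requires group_size >= 2")
    values = []
    for ev in events:
        pos = ev.position_of(individual_id)
        if pos is None:
            continue
        n = ev.n_joiners if n_convention == "joiners" else group_size
        if n < 2:
            continue
        values.append(joining_order_index(pos, n))
    if not values:
        return None
    return float(np.mean(values))
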