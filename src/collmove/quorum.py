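"""Quorum-curve construction and threshold detection.

The curve bins movement events by their early-joiner count k and reports
the empirical probability that an event with that count became an
entire-group movement.  A quorum signature is an upper threshold k* above
which the probability pins at exactly 1; the complementary lower threshold
is a count below which entire-group movements never occur.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Sequence

from .types import MovementEvent, QuorumCurve, ValidationError

__all__ = [
    "build_curve",
    "detect_upper_threshold",
    "detect_lower_threshold",
    "simple_majority",
]


def build_curve(events: Sequence[MovementEvent]) -> QuorumCurve:
    """Bin events by early-joiner count; empty bins are skipped, not
    interpolated."""
    if len(events) == 0:
        raise ValidationError("cannot build a quorum curve from zero events")
    n_events: Counter[int] = Counter()
    n_entire: Counter[int] = Counter()
    for ev in events:
        k = len(ev.early_joiner_ids)
        if k < 1:
            continue
        n_events[k] += 1
        if ev.entire_group:
            n_entire[k] += 1
    ks = sorted(n_events)
    return QuorumCurve(
        k=ks,
        n_events=[n_events[k] for k in ks],
        n_entire=[n_entire[k] for k in ks],
    )


def detect_upper_threshold(curve: QuorumCurve, min_support: int = 5) -> int | None:
    """Smallest k* such that every observed bin k >= k* has probability
    exactly 1 and those bins together hold at least ``min_support`` events.

    Returns ``None`` when no tail of the curve pins at probability 1 with
    enough support.
    """
    prob = curve.probability
    best = None
    for i in range(len(curve.k)):
        if all(prob[j] == 1.0 for j in range(i, len(curve.k))):
            if int(curve.n_events[i:].sum()) >= min_support:
                # smallest k* covering this all-ones tail: one past the
                # previous (non-1) bin, or the first observed k.
                best = int(curve.k[i - 1]) + 1 if i > 0 else int(curve.k[0])
            break
    return best


def detect_lower_threshold(curve: QuorumCurve, min_support: int = 5) -> int | None:
    """Largest k0 such that every observed bin k < k0 has probability 0 and
    those bins together hold at least ``min_support`` events."""
    prob = curve.probability
    i = 0
    while i < len(curve.k) and prob[i] == 0.0:
        i += 1
    if i == 0:
        return None
    if int(curve.n_events[:i].sum()) < min_support:
        return None
    # all observed bins strictly below curve.k[i] are zero
    return int(curve.k[i]) if i < len(curve.k) else int(curve.k[i - 1]) + 1


def simple_majority(n_adults: int) -> int:
    """Smallest integer strictly exceeding half of the adults."""
    if n_adults < 1:
        raise ValidationError("n_adults must be >= 1")
    return n_adults // 2 + 1


def pooled_tail_probability(curve: QuorumCurve, k_min: int) -> tuple[float, int]:
    """Pooled entire-group probability over all bins with k >= k_min.

    Returns (probability, pooled event count); probability is ``nan`` when
    no events fall at or above ``k_min``.
    """
    mask = curve.k >= k_min
    n = int(curve.n_events[mask].sum())
    if n == 0:
        return math.nan, 0
    return float(curve.n_entire[mask].sum() / n), n
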