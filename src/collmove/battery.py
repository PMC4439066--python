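"""The study's full test battery over pipeline outputs.

Given a roster of adults, segmented events and the two centrality vectors
(HWI- and DAI-based), this runs, in one deterministic report:

* mean joining-order index vs HWI centrality (Spearman, all adults);
* dominance vs centrality within each sex (Spearman; rank 1 = highest, so
  the correlation is computed on the *dominance score*, the inverse of the
  rank number — a positive rho means higher-ranking animals are more
  central);
* age vs centrality (Spearman);
* male vs female centrality (pooled-variance t, with a KS normality check);
* centrality heterogeneity across individuals (Kruskal-Wallis on
  per-individual replicate sets across events);
* HWI centrality vs DAI centrality (Spearman).

The Kruskal-Wallis replicate unit is configurable: ``"jackknife"``
(default) uses each individual's centrality recomputed with one event left
out at a time, so every event contributes one replicate per individual;
``"joining_order"`` uses the individual's per-event joining-order indices.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .networks import (
    compute_hwi,
    eigenvector_centrality,
    joining_order_index,
    mean_joining_order,
)
from .stats import TestResult, kruskal_wallis, ks_normality, spearman, t_test_independent
from .types import (
    CentralityVector,
    IndividualRecord,
    MovementEvent,
    ValidationError,
    adults,
    dominance_score,
)

__all__ = ["run_test_battery", "centrality_replicates"]


def centrality_replicates(
    events: Sequence[MovementEvent],
    ids: Sequence[str],
    unit: str = "jackknife",
) -> dict[str, list[float]]:
    """Per-individual replicate observations for the heterogeneity test."""
    if unit == "jackknife":
        reps: dict[str, list[float]] = {i: [] for i in ids}
        for left_out in range(len(events)):
            subset = [e for i, e in enumerate(events) if i != left_out]
            if not subset:
                continue
            try:
                cent = eigenvector_centrality(compute_hwi(subset, ids))
            except ValidationError:
                continue  # leave-one-out matrix disconnected; skip replicate
            for ind, v in cent.as_dict().items():
                reps[ind].append(v)
        return reps
    if unit == "joining_order":
        reps = {i: [] for i in ids}
        for ev in events:
            for ind in ids:
                pos = ev.position_of(ind)
                if pos is not None and ev.n_joiners >= 2:
                    reps[ind].append(joining_order_index(pos, ev.n_joiners))
        return reps
    raise ValidationError(f"unknown replicate unit {unit!r}")


def run_test_battery(
    roster: Sequence[IndividualRecord],
    events: Sequence[MovementEvent],
    centrality_hwi: CentralityVector,
    centrality_dai: CentralityVector | None = None,
    kw_replicate_unit: str = "jackknife",
    n_convention: str = "joiners",
) -> dict[str, dict]:
    """Run the full battery; returns a JSON-serializable report.

    Raises a stage-naming error when a required input is missing.
    """
    adult_recs = adults(roster)
    ids = [r.id for r in adult_recs]
    if not events:
        raise ValidationError("test battery: missing input at stage 'events'")
    if centrality_hwi is None:
        raise ValidationError("test battery: missing input at stage 'centrality_hwi'")
    missing = [i for i in ids if i not in centrality_hwi.ids]
    if missing:
        raise ValidationError(
            f"test battery: centrality_hwi lacks adults {missing} (stage 'metrics')"
        )

    cent = np.array([centrality_hwi.score_of(i) for i in ids])
    n_by_sex = {s: sum(1 for r in adult_recs if r.sex == s) for s in ("male", "female")}
    dom = np.array([dominance_score(r, n_by_sex[r.sex]) for r in adult_recs])
    age = np.array([r.age_years for r in adult_recs])

    results: list[TestResult] = []

    mjo = [
        mean_joining_order(events, i, n_convention=n_convention, group_size=len(roster))
        for i in ids
    ]
    pairs = [(m, c) for m, c in zip(mjo, cent) if m is not None]
    if len(pairs) >= 3:
        results.append(
            spearman([p[0] for p in pairs], [p[1] for p in pairs],
                     name="joining_order_vs_centrality")
        )

    for sex in ("male", "female"):
        sel = [i for i, r in enumerate(adult_recs) if r.sex == sex]
        if len(sel) >= 3:
            results.append(
                spearman(dom[sel], cent[sel], name=f"rank_vs_centrality_{sex}")
            )

    results.append(spearman(age, cent, name="age_vs_centrality"))

    males = cent[[i for i, r in enumerate(adult_recs) if r.sex == "male"]]
    females = cent[[i for i, r in enumerate(adult_recs) if r.sex == "female"]]
    if len(males) >= 2 and len(females) >= 2:
        try:
            results.append(ks_normality(cent, name="centrality_normality"))
        except ValidationError:
            pass
        results.append(t_test_independent(males, females, name="sex_centrality_t"))

    reps = centrality_replicates(events, ids, unit=kw_replicate_unit)
    groups = [reps[i] for i in ids if reps[i]]
    if len(groups) >= 2 and all(len(g) >= 1 for g in groups):
        results.append(
            kruskal_wallis(groups, name="centrality_heterogeneity_kw")
        )

    if centrality_dai is not None:
        dai = np.array([centrality_dai.score_of(i) for i in ids])
        results.append(spearman(cent, dai, name="hwi_vs_dai_centrality"))

    return {r.name: r.as_dict() for r in results}
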