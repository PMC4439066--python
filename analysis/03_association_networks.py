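#!/usr/bin/env python
"""Association networks of the selective-mimetism study.

Computes the movement-based half-weight index (HWI) over early-joiner
co-occurrence, the proximity-based dyadic association index (DAI) from
focal bouts, eigenvector centralities on both, and each adult's mean
joining-order index; writes the tables under results/networks/.
"""

from pathlib import Path

import pandas as pd

from collmove import (
    compute_dai,
    compute_hwi,
    eigenvector_centrality,
    mean_joining_order,
    read_bouts,
    read_events,
    read_roster,
    write_matrix,
)
from collmove.types import adults

BASE = Path(__file__).resolve().parent.parent / "results"
DATA = BASE / "synthetic" / "selective"
OUT = BASE / "networks"
OUT.mkdir(parents=True, exist_ok=True)

roster = read_roster(DATA / "roster.csv")
events = read_events(DATA / "events.json")
bouts = read_bouts(DATA / "bouts.csv", roster)
ids = [r.id for r in adults(roster)]

hwi = compute_hwi(events, ids)
dai = compute_dai(bouts, roster, ids)
cent_hwi = eigenvector_centrality(hwi)
cent_dai = eigenvector_centrality(dai)
orders = {i: mean_joining_order(events, i) for i in ids}

write_matrix(hwi, OUT / "hwi.csv")
write_matrix(dai, OUT / "dai.csv")
write_matrix(cent_hwi, OUT / "centrality_hwi.csv")
write_matrix(cent_dai, OUT / "centrality_dai.csv")
pd.DataFrame({"id": list(orders), "mean_joining_order": list(orders.values())}).to_csv(
    OUT / "joining_order.csv", index=False
)

summary = pd.DataFrame(
    {
        "id": ids,
        "sex": [next(r.sex for r in roster if r.id == i) for i in ids],
        "rank": [next(r.rank_within_sex for r in roster if r.id == i) for i in ids],
        "centrality_hwi": [cent_hwi.score_of(i) for i in ids],
        "centrality_dai": [cent_dai.score_of(i) for i in ids],
        "mean_joining_order": [orders[i] for i in ids],
    }
)
print(summary.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"\ntables -> {OUT}")
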