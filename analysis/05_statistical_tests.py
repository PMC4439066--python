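#!/usr/bin/env python
"""The full statistical test battery on the selective-mimetism study.

Runs Spearman correlations (joining order vs centrality, dominance vs
centrality within each sex, age vs centrality, HWI vs DAI centrality),
the male-female pooled-variance t test with its normality check, and the
Kruskal-Wallis centrality-heterogeneity test; writes the JSON report.
"""

import json
from pathlib import Path

from collmove import (
    compute_dai,
    compute_hwi,
    eigenvector_centrality,
    read_bouts,
    read_events,
    read_roster,
    run_test_battery,
)
from collmove.types import adults

BASE = Path(__file__).resolve().parent.parent / "results"
DATA = BASE / "synthetic" / "selective"

roster = read_roster(DATA / "roster.csv")
events = read_events(DATA / "events.json")
bouts = read_bouts(DATA / "bouts.csv", roster)
ids = [r.id for r in adults(roster)]

cent_hwi = eigenvector_centrality(compute_hwi(events, ids))
cent_dai = eigenvector_centrality(compute_dai(bouts, roster, ids))
report = run_test_battery(roster, events, cent_hwi, cent_dai)

(BASE / "stats_selective.json").write_text(json.dumps(report, indent=1))
for name, r in report.items():
    df = f" df={r['df']}" if r["df"] is not None else ""
    print(f"{name:32s} {r['statistic_name']}={r['statistic']:+.3f}"
          f" p={r['p_value']:.4f} n={r['n']}{df}")
print(f"\nreport -> {BASE / 'stats_selective.json'}")
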