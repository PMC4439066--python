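#!/usr/bin/env python
"""Quorum curves and thresholds for all three synthetic studies.

Bins each study's events by early-joiner count, estimates the probability
of entire-group movement per bin, and applies upper/lower threshold
detection.  Under the quorum rule the curve should pin at probability 1
from the generating threshold onwards; under either mimetism rule it
should rise smoothly without a pinned tail.
"""

import json
from pathlib import Path

from collmove import (
    build_curve,
    detect_lower_threshold,
    detect_upper_threshold,
    read_events,
    simple_majority,
)

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "quorum"
OUT.mkdir(parents=True, exist_ok=True)

report = {}
for rule in ("anonymous", "selective", "quorum"):
    events = read_events(BASE / "synthetic" / rule / "events.json")
    curve = build_curve(events)
    curve.to_frame().to_csv(OUT / f"curve_{rule}.csv", index=False)
    upper = detect_upper_threshold(curve)
    lower = detect_lower_threshold(curve)
    report[rule] = {"upper_threshold": upper, "lower_threshold": lower}
    print(f"{rule:10s}: upper threshold = {upper}, lower threshold = {lower}")
    for k, n, p in zip(curve.k, curve.n_events, curve.probability):
        print(f"    k={k:2d}  n={n:3d}  P(entire)={p:.2f}")

report["simple_majority_of_12_adults"] = simple_majority(12)
(OUT / "thresholds.json").write_text(json.dumps(report, indent=1))
print(f"\nsimple majority of 12 adults = {report['simple_majority_of_12_adults']}")
print(f"curves -> {OUT}")
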