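# collmove

Tools for studying **how group-living animals decide to join collective
movements** — the joining process that turns one departing individual into a
whole group on the move. The package targets the classic field design used
with macaques at provisioned sites: a known group rests at a feeding site,
an adult initiates a departure, and observers record who joins, when, and in
which order, alongside focal-animal proximity sampling of everyday
affiliation. It is written for behavioural ecologists who want the whole
chain — event segmentation, social-network metrics, quorum analysis,
inferential statistics — as tested, scriptable code, together with a
generative simulator that provides ground truth for every stage.

## What it computes

**Event segmentation** from time-stamped 2-D position fixes, using the
standard operational definitions: an *initiation* is the first adult walking
more than 10 m in under 30 s; a *joiner* is any individual walking more than
5 m within 45° of the initiator's departure direction before the joining
terminates; joining *terminates* after a five-minute gap with no new joiner;
an *early joiner* is an adult (initiator included) joining within the first
five minutes; an *entire-group movement* is one joined by at least
two-thirds of the group; events are kept only when two-thirds of the group
was within 10 m of the initiator's starting point.

**Association networks** over the adults:

- half-weight index over movement events,
  `HWI(a,b) = (# events with a and b both early joiners) / (# events)`;
- dyadic association index from within-1-m focal bouts,
  `DAI(a,b) = D_ab / (D_a + D_b − D_ab)`;
- eigenvector centrality (leading eigenvector of either matrix, power
  iteration, Euclidean norm 1);
- joining-order index `1 − (I − 1)/(N − 1)` for progression position *I*
  of *N* (1 = first, 0 = last), and its per-individual mean.

**Quorum analysis**: the empirical curve of entire-group probability against
early-joiner count *k*, with detection of an upper threshold *k\** (smallest
*k* above which the probability pins at exactly 1) and a lower threshold
(largest *k* below which it is exactly 0), plus the simple majority of the
adults (`⌊n/2⌋ + 1`).

**Statistics**: Spearman rank correlation (exact permutation p for n ≤ 10),
tie-corrected Kruskal–Wallis, pooled-variance two-sample t, and the
one-sample Kolmogorov–Smirnov normality check — bundled into the study's
full test battery (`run_test_battery`).

**Simulation**: continuous-time next-event generation of joining processes
under three rules — *anonymous mimetism* (hazard grows with the number
already moving), *selective mimetism* (hazard grows with affiliation to the
movers, weighted by their dominance), and *quorum* (a high constant hazard
for everyone once a threshold number of adults is moving) — plus rendering
to position fixes that segmentation provably recovers, and focal-bout
simulation from a latent affiliation matrix. `rule_signature` /
`classify_rule` discriminate the generating rule from pipeline outputs
alone.

## Worked example

Simulate a 171-event study under the quorum rule (threshold 7, group of 32
with 12 adults), segment the rendered position fixes, and ask where the
quorum sits:

```python
from collmove import (SimulationConfig, simulate_and_segment, build_curve,
                      detect_upper_threshold, simple_majority)

config = SimulationConfig(rule="quorum", quorum_threshold=7, n_events=171, seed=103)
roster, events, truths = simulate_and_segment(config)
curve = build_curve(events)
print(curve.to_frame().tail(6).to_string(index=False))
print("upper threshold:", detect_upper_threshold(curve))
print("simple majority of 12 adults:", simple_majority(12))
```

```
 k  n_events  n_entire  probability
 7         2         2          1.0
 8         1         1          1.0
 9         2         2          1.0
10         1         1          1.0
11         3         3          1.0
12        14        14          1.0
upper threshold: 7
simple majority of 12 adults: 7
```

Every bin with seven or more early joiners has entire-group probability 1,
so the detected quorum (7) is recovered — and it coincides with the simple
majority of the adults. Below the threshold the probability falls away
(0.33 at k = 6, 0.18 at k = 5, 0 below), which is what distinguishes a
quorum from mimetic joining: under the mimetism rules the same analysis
yields a smoothly rising curve whose tail does not pin at 1.

The numbered scripts under `analysis/` run the full study in order:

```bash
python analysis/01_simulate_study.py        # three synthetic studies -> results/synthetic/
python analysis/02_segment_rendered_events.py
python analysis/03_association_networks.py  # HWI/DAI/centrality tables
python analysis/04_quorum_curve.py          # curves + thresholds
python analysis/05_statistical_tests.py     # the full test battery
python analysis/06_rule_discrimination.py   # 60-study confusion table
```

On the selective-mimetism study, for instance, the battery prints a strong
positive dominance–centrality correlation in both sexes
(`rank_vs_centrality_female rho=+0.952 p=0.0011`), a positive correlation
between movement-network and proximity-network centralities
(`hwi_vs_dai_centrality rho=+0.937`), no age effect, and no sex difference
(`t=+0.453, df=10`) — the signature that separates socially selective
joining from anonymous contagion. The same pipeline classifies the
generating rule correctly in 59 of 60 simulated studies
(`06_rule_discrimination.py`).

A `collmove` CLI wraps the same stages (`simulate`, `segment`, `metrics`,
`quorum`, `stats`, and `run` for a config-driven end-to-end pass); see
`collmove --help`.

## Layout

```
src/collmove/        library: types, io, segmentation, networks, quorum,
                     stats, battery, simulate, discrimination, pipeline, cli
analysis/            numbered study drivers (write under results/)
tests/               pytest suite, including end-to-end acceptance checks
docs/methods.md      models, parameters, design choices, limitations
```
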