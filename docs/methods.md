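# Methods

This note records the models and conventions behind `collmove`: what each
stage computes, the parameters that matter, what the simulator does and
does not emulate, and the choices made where the design was genuinely open.

## 1. Event segmentation

Segmentation turns per-individual position fixes `(t, x, y)` into discrete
collective-movement events using the operational definitions standard in
macaque collective-movement fieldwork.

**Initiation.** The earliest adult whose net (straight-line) displacement
over any fix-to-fix window of at most `init_window_s` (30 s) strictly
exceeds `init_dist_m` (10 m). Non-adults never initiate. The event start is
the *beginning* of the qualifying window; the departure direction is the
bearing of its displacement vector. Displacement is net, not path length:
positions on a grid of reference points measure where an animal is, not how
far it wandered.

**Joining.** For every other individual, the join time is the first fix at
which its net displacement since the event start strictly exceeds
`join_dist_m` (5 m) with a bearing within `join_cone_deg` (45°, absolute
angular difference, i.e. a 90° cone) of the departure direction. No time
limit applies to the displacement itself beyond event termination. Records
are ordered by join time; exact ties are broken by roster id so output is
deterministic.

**Termination.** The join list is truncated at the first gap longer than
`gap_s` (300 s) between consecutive joins, the first gap being measured
from the initiator's departure; termination time is the last kept join plus
`gap_s`.

**Classification.** Early joiners are the adult joiners (initiator
included) with join time ≤ `early_window_s` (300 s, boundary inclusive —
"within the first five minutes"). An event is an entire-group movement when
at least `⌈entire_fraction · N⌉` of the `N` roster members joined
(two-thirds by default; `⌈2/3 · 32⌉ = 22`).

**Presence filter.** An event is retained only when at least
`⌈presence_fraction · N⌉` individuals are within `zone_radius_m` of the
initiator's starting point (≤ 10 m, boundary inclusive) at the event start,
judged from each individual's nearest fix within ±`presence_fix_tol_s`
(15 s; the fix cadence of real data is study-specific, so the tolerance is
a parameter). Individuals without such a fix count as absent.

Boundary conventions follow the field wording: movement thresholds are
strict (*more than* 10 m, *more than* 5 m), the starting zone is inclusive
(*less than or equal to* 10 m).

## 2. Association networks

**HWI.** The half-weight index here is the plain co-occurrence ratio used
in the joining literature: joint early-joiner appearances divided by the
total number of movements. It equals 1 for an always-together dyad and 0
for a never-together one. The classical half-weight estimator with
joint-absence handling, `x / (x + y_ab + (y_a + y_b)/2)`, is available as
`variant="whitehead"`; a flag also allows counting all joiners rather than
early joiners.

**DAI.** `D_ab / (D_a + D_b − D_ab)`, with `D_a` an individual's total
focal observation time (from the roster) and `D_ab` the summed within-1-m
bout durations of the dyad with either member as focal. A non-positive
denominator indicates inconsistent inputs and is an error, not a clamp.

**Eigenvector centrality.** The Perron eigenvector of the association
matrix, normalized to Euclidean norm 1 (conventions differ across network
packages — SOCPROG reports different scalings — but every correlation
computed downstream is invariant to the choice). Power iteration runs on
the shifted matrix `A + cI` with `c` = maximum row sum: the shift dominates
the spectral radius, so iteration converges even for bipartite-like
matrices whose smallest eigenvalue is `−λ₁` (a star graph, for example),
without changing the eigenvector. Relative tolerance 1e-10, at most 10 000
iterations; the test suite checks agreement with a dense eigendecomposition
to 1e-8. A matrix with more than one connected component has no
well-defined global centrality and is rejected with the components named.

**Joining order.** `1 − (I − 1)/(N − 1)` for position `I` of `N`. The
field formula leaves `N` ambiguous between "group size" and "number of
joiners of that event"; positions are only defined for joiners, so the
package defaults to the per-event joiner count and exposes
`n_convention="group"` for the fixed-group-size reading. Individuals that
joined no event are reported as missing, never as 0 (0 means "always
last"). Single-joiner events carry no order information and are skipped.

## 3. Quorum analysis

The quorum curve bins events by early-joiner count `k` and reports the
empirical probability of entire-group movement per bin; empty bins are
skipped, not interpolated. The **upper threshold** is the smallest `k*`
such that every observed bin at `k ≥ k*` has probability exactly 1 and
those bins jointly contain at least `min_support` events (default 5 — a
threshold claimed from one or two events is meaningless); the **lower
threshold** is the symmetric construction over an all-zero head of the
curve. `simple_majority(n)` is the smallest integer strictly exceeding
`n/2`, so 7 for 12 adults.

## 4. Statistical tests

Implemented from first principles so the small-sample behaviour is fully
specified, and cross-checked against independent reference implementations
in the test suite (agreement to 1e-8):

- **Spearman**: Pearson correlation of midranks. For `n ≤ 10` the
  two-sided p-value is exact, by full enumeration of all `n!` permutations
  of one rank vector (counting `|ρ_perm| ≥ |ρ_obs|` with a 1e-12 guard
  against float ties); above that, the usual `t = ρ√((n−2)/(1−ρ²))`
  approximation on `n − 2` df.
- **Kruskal–Wallis**: `H` with the standard tie correction, chi-square
  p on `g − 1` df.
- **t test**: pooled-variance Student t with integer df
  `n_a + n_b − 2` (for 4 males vs 8 females, df = 10); Welch is
  deliberately not used, as the analysis convention here reports integer
  df.
- **KS normality**: one-sample Kolmogorov–Smirnov distance against a
  normal with the sample's own moments, asymptotic Kolmogorov p. (With
  estimated parameters this is the common SPSS-style usage; it is
  conservative relative to Lilliefors.)

**The battery** (`run_test_battery`) assembles the study's analyses:
joining order vs movement-network centrality, dominance vs centrality
within each sex, age vs centrality, the male–female t test with a
normality check, centrality heterogeneity across individuals
(Kruskal–Wallis), and movement-network vs proximity-network centrality.
Dominance enters correlations as a *dominance score*
`(n_sex − rank + 1)/n_sex` (rank 1 = highest), so a positive rho means
higher-ranking individuals are more central — avoiding the sign confusion
of correlating against raw rank numbers. What constitutes the replicate
observations behind a per-individual centrality heterogeneity test is
genuinely open; the default uses leave-one-event-out (jackknife)
centralities, so every event contributes one replicate per individual, with
per-event joining-order indices available as an alternative unit.

## 5. The simulator

The generator emulates the study system: a 32-member group (4 adult males,
8 adult females, 6 subadults, 9 juveniles, 5 infants; the packaged
12-adult roster carries the real ids, ranks, ages and focal durations)
resting at a feeding site and producing discrete departure events.

**Joining hazards.** After an adult initiates (chosen uniformly, or
dominance-proportionally under the selective rule), each unjoined
individual `i` carries a hazard

- anonymous: `λ_i = F · (λ₀ + α·k(t)) · e^(−t/τ)` with `k(t)` the number
  already moving;
- selective (adults): `λ_i = F · (λ₀ + α_s · Σ_j A[i,j](1 + β·dom_j)) ·
  e^(−t/τ)` over joined adults `j`;
- quorum: the anonymous form while fewer than `q` adults are moving, then
  a constant `λ_q` for every remaining individual (neither decayed nor
  frailty-scaled: a reached quorum commits the group).

`F` is a lognormal per-event frailty (mean 1, log-sd `frailty_sd` = 0.75)
capturing between-event context; `e^(−t/τ)` (τ = 150 s) is the decay of
joining impetus as the front walks away. The decay is load-bearing: with
any constant rate, accumulating seven joiners inside the five-minute early
window makes a subsequent five-minute silence (the termination criterion)
essentially impossible, so entire-group probability would pin at 1 in
every bin and no threshold structure could exist. With decay, a joining
process either cascades within ~2τ or dies out, which is exactly the
empirical phenomenology the analysis stages are built to detect. Setting
`τ = ∞`, `frailty_sd = 0`, `α = 0` recovers the bare textbook forms.

Non-adults follow rather than decide: under the mimetism rules they are
inactive until `nonadult_gate` (2) adults are moving and then join at
`F · (λ₀ + α_na · k_adults) · e^(−t/τ)`; under the quorum rule they join
only post-quorum. Entire-group outcomes therefore hinge on adult dynamics,
and under the quorum rule "entire group" coincides with quorum attainment.

Defaults (`λ₀ = 4e-4 /s`, `α = 8e-4`, `α_s = 2e-3`, `β = 1`,
`α_na = 4e-4`, `λ_q = 0.05`, 171–300 events per study) were chosen to
place a 171-event study in the regime the analysis addresses: early-joiner
counts spread over 1–12, intermediate entire-group probabilities in the
middle bins, and — under the quorum rule — a tail pinned at exactly 1 from
the generating threshold.

**Sampling.** Next-event simulation: between joins the hazards are
constant up to the common decay factor, so the waiting time solves
`Total·τ·e^(−t/τ)(1 − e^(−Δ/τ)) = E`, `E ~ Exp(1)`, in closed form (no
event if `E` exceeds the remaining integrated hazard); the joiner is drawn
proportionally to the individual hazards. A waiting time beyond `gap_s`
terminates the schedule — the same five-minute rule segmentation applies.
One master seed; the affiliation draw, every event and the bout process use
deterministic substreams, so identical configs give byte-identical outputs.

**Affiliation.** `A[i,j] = clip(0.15 + 0.55·dom_i·dom_j + ε, 0.02, 0.95)`
with small symmetric noise: dyads of high-ranking animals affiliate most, a
despotic-hierarchy pattern that makes selective joining produce the
positive dominance-centrality correlation the battery tests for.

**Rendering.** Each event is rendered as one session of fixes at a 5-s
cadence: everyone rests in a 3.5-m cluster around the initiator (inside the
10-m starting zone), with 5-cm Gaussian measurement jitter. The initiator
walks at 0.38 m/s — slow enough that no 30-s window straddling its rest
phase reaches 10 m, so the detected start time and direction are exact —
and joiners walk at 1.2 m/s on headings drawn inside the 45° cone with a 5°
safety margin, starting one cadence step before their scheduled join so the
5-m crossing is first observed exactly at the scheduled fix. Latent join
times are quantized to the grid order-preservingly (minimum separation one
cadence step; minimum join time late enough that a joiner's own >10-m
window cannot precede the initiator's) and the gap rule is re-applied after
quantization; that quantized schedule is the recorded ground truth, and
segmentation recovers it exactly (the suite checks ≥ 99% over 500 rendered
events; observed 100%).

**Focal bouts.** Round-robin 10-minute focal samples per adult (20 by
default); within a sample, bouts with each partner arrive as a renewal
process at rate `A[focal, partner]/300 s⁻¹` with exponential 20-s bout
lengths, never overlapping within a (sample, partner) pair. DAI-based
centrality recovers the row sums of `A` (Spearman > 0.8 across seeds).

**What the simulator does not emulate.** No spatial foraging or terrain,
no learning or memory across events, no inter-group dynamics, no drift in
ranks or affiliation, no observation loss or mis-identification, and
rendered geometry is deliberately clean (a tight resting cluster,
straight-line walks). Passing tests therefore demonstrate that the
pipeline's inferences are correct *when the data satisfy the operational
definitions*, not that real field data are this well behaved; with real
fixes, the cadence tolerance, heading noise and presence filter do real
work and results will degrade gracefully rather than exactly.

## 6. Rule discrimination

A study is classified from three statistics: the quorum-curve upper
threshold (with its pooled tail support), the dominance-centrality
Spearman rho, and the movement-vs-proximity centrality rho. Decision list:

1. **quorum** if an upper threshold exists *strictly below the number of
   adults* with tail support ≥ 10 events — a "threshold" consisting only of
   the all-adults bin is the tautology that fully joined groups moved;
2. else **selective** if either rho exceeds 0.5 (≈ the 95th percentile of
   the Spearman null at n = 12; socially structured joining yields ≈ 0.9);
3. else **anonymous**.

At 300 events per study this classifies ≥ 90% of studies correctly across
seeds (observed 59/60).

## 7. Numerical and I/O conventions

Times are seconds from session start (join times: from the initiator's
departure); coordinates planar metres; bearings degrees in [0, 360)
counter-clockwise from +x. CSV is comma-separated, `.`-decimal, UTF-8,
header mandatory; floats are written at `repr` precision so write→read
round trips are lossless below 1e-12. Events serialize to JSON ordered by
(start time, event id) with id sets sorted, so outputs diff stably. All
readers reject malformed input with row-addressed errors.

## 8. Known limitations

- Segmentation assumes one joining process at a time; simultaneous
  opposite-direction initiations and mid-movement direction changes are out
  of scope.
- The HWI here is the plain ratio used in the joining literature, not an
  association-index estimator with sampling corrections; permutation null
  models for network significance are out of scope.
- Threshold detection is empirical (exact 0/1 tails with support), not a
  parametric quorum-response fit; with few high-k events the upper
  threshold is reported as absent rather than extrapolated.
- The exact Spearman permutation p enumerates up to 10! permutations;
  beyond n = 10 the t approximation is used.
- Analyses at n = 4 (males) have almost no power; the exact permutation
  p-value floor at n = 4 is 1/12 ≈ 0.083.
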