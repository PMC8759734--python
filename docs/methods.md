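# Methods

## Decision model

The engine solves a discrete multiobjective selection problem: choose one
therapy from a finite list of alternatives, each scored on m objectives
f₁…f_m with per-objective optimization directions (the canonical knee-OA
problem has m = 5: minimize cost, maximize net pain improvement, maximize
net function improvement, minimize supervised sessions, minimize treatment
length). Because the decision space is a finite list, "optimization" is
dominance filtering plus preference-guided ranking — there is no numerical
search and no convergence machinery anywhere in the package.

Alternative a *dominates* b when a is at least as good on every objective
(directions respected) and strictly better on at least one. The
nondominated subset is the Pareto front; its members are the *compromise*
therapies, and by default only they are eligible for display, so every
therapy the decision-maker sees embodies a genuine trade-off. The
`restrict_to_front=False` escape hatch ranks dominated alternatives too,
for exploratory use.

## Preferred ranges, group I/II, closeness

The decision-maker's preferences are per-objective intervals
[lower, upper]. The two bounds are not symmetric:

* the **reservation bound** is the bound on the objective's *bad* side
  (upper for a minimized objective, lower for a maximized one). Violating
  it disqualifies an alternative from group I.
* the **aspiration bound** is the bound on the good side. Values beyond it
  are *better than asked for* and still satisfy the range — an alternative
  cheaper than the requested minimum budget is not penalized.

This asymmetry is forced by the classification rule that better-than-desired
values still count as fully satisfying: a per-objective status is `within`
(inside the interval, endpoints included), `better` (strictly beyond the
aspiration bound), or `worse` (strictly beyond the reservation bound), and
**group I** = no objective `worse`; everything else is **group II**.

Group II alternatives are ranked by a closeness score

    closeness(x) = Σ_j  max(0, violation_j(x)) / span_j

where violation_j is the distance from x's value to the nearest
group-I-eligible value on objective j (zero for `within`/`better`) and
span_j = |nadir_j − ideal_j| is the observed range of objective j over the
full alternative set. Normalizing by the ideal–nadir span makes violations
on € and % scales commensurable; closeness is zero exactly on group I. The
ideal/nadir point is computed over the *full* set, before Pareto
filtering, because it doubles as the "best and worst attainable" overview
shown to the decision-maker at session start, and because a full-set
normalizer is stable under changes to the candidate pool.

The L1 (sum) aggregation was a genuinely open design choice; it was picked
for simplicity and monotonicity in each violation, and the aggregator is a
pluggable argument (`agg=max` gives the Chebyshev/worst-violation variant)
so the choice can be revisited without touching the selection logic.

Within group I, alternatives are ranked by ascending normalized L1 distance
to the *aspiration corner* (the vector of good-side bounds). This ordering
only matters when more than k alternatives satisfy every range — a case the
reference worked example never reaches — so it is likewise a package-level
convention: it surfaces the "most preferred-looking" range-satisfiers
first.

Selection returns the top k: group I (by aspiration distance) first, then
group II (by closeness). All orderings tie-break lexicographically by
record id, which makes every selection deterministic and invariant under
row permutation of the input table — a property the replay machinery and
the tests rely on.

Degenerate objectives (all alternatives share one value) get a normalizer
fallback of 1; such an objective contributes the same (possibly nonzero)
violation to every alternative and therefore never changes their relative
order.

## Interactive loop

A session fixes the dataset and k (the number of compromises shown per
round; elicited once, at the start — changing k means a new session). Each
iteration takes a complete preference set, runs selection, and appends an
immutable result snapshot (preferences, classified selection, ideal/nadir,
1-based index, timestamp) to the history. The final prescription must come
from the *latest* shown selection — group II members included, since a
decision-maker may knowingly accept a range violation — and closes the
session. An optional include/exclude filter on exercise-type tags is
applied at session start, for pre-filtering modality families a patient
cannot perform.

Sessions serialize to JSON-lines transcripts (header with a SHA-256 digest
of the canonical CSV serialization of the dataset, then one line per
iteration). Replay re-runs the logged preferences against a dataset and
verifies digest and per-iteration selections; timestamps are excluded from
all determinism checks.

The scripted decision-maker (`simulated_dm`) drives this loop from a policy
(preference sequence + stop rule + choice rule), which is how the
end-to-end behaviour is tested; it raises after policy exhaustion if the
stop rule never fires.

## Cost model

Therapy cost is Σ (session count × unit fee) + contacts × contact fee +
equipment fee, priced against a fee schedule. The packaged default is the
early-2021 Finnish schedule: individual supervised sessions 100/75/50 € for
60/45/30 min, group-of-five sessions 20/15/10 € per head, unsupervised
facility sessions 10 €, home sessions 0 €, checkpoint contacts (phone/SMS,
one flat fee regardless of medium) 10 €, equipment 0 €. Durations match
schedule entries exactly — the schedule lists discrete price points, so
in-between durations are rejected rather than interpolated, and callers
round explicitly. Costs cover baseline to outcome end-point only; a plan's
`window` field is documentation, not computation. Users supply their own
schedule JSON to re-price for another time or country.

## WOMAC arithmetic

Outcome objectives are built from arm-level summaries only (no
individual-level data, hence no variance propagation):
`standardize_womac` linearly maps a reported subscale range onto the
standard 0–20 (pain) / 0–68 (function) ranges with exact endpoint mapping;
`mean_change` is pre − post (positive = improvement, lower WOMAC being
better); `net_change` is exercise-arm change − control-arm change. The
percent improvements used in preferences are net change divided by a
positive reference; the package convention takes the exercise arm's
baseline (pre-intervention) mean on the standardized scale as the
reference — the most common convention for relative improvement — since
only the percentages, not their denominators, are fixed upstream.

## Packaged fixtures and the synthetic generator

The real extracted trial table behind the reference worked example is not
distributed with the package. In its place:

* `scenario_dataset()` — eight hand-built, explicitly **synthetic** records
  (study names echo the trials cited in the worked example; every numeric
  value is invented). The eight rows are mutually nondominated, and they
  are engineered so the two packaged preference sets reproduce the
  reference iteration pattern exactly: round 1 yields exactly one
  all-ranges-met therapy; round 2 (cost cap lowered to 500 €, function
  aspiration raised to +40 %, up to 30 sessions tolerated) yields exactly
  three, with the mixed resistance+aerobic record carrying the largest
  function improvement and hence being the scripted final choice after two
  iterations.
* `published_preferences()` — the two published preference sets (iteration 1:
  cost 300–600 €, pain +15–30 %, function +15–25 %, 0–15 sessions, 8–26
  weeks; iteration 2: 200–500 €, +15–25 %, +15–40 %, 0–30 sessions, 12–26
  weeks).
* `default_fee_schedule()` — the nine-entry fee table above.

`generate_alternatives(SynthConfig(...))` draws arbitrary-size synthetic
problems. A latent intensity u ~ U(0,1) per alternative drives cost and
supervised sessions directly; each efficacy objective follows
`tradeoff_strength·u + (1−tradeoff_strength)·v` (independent v ~ U(0,1))
scaled to its range, plus Gaussian noise, clipped; sessions are rounded to
integers; treatment period is drawn independently. Defaults mirror the
reference problem's shape: n = 31 alternatives attributed to 21 distinct
study labels (the published ratio), costs 0–1500 €, efficacy −5…45 %,
0–36 sessions, 8–48 weeks, tradeoff_strength 0.7, per-objective noise SDs
of 60 € / 4 % / 4 % / 2 sessions. The coupling guarantees genuine
cost↔efficacy conflict, so Pareto fronts are nontrivial
(tradeoff_strength = 1 with zero noise degenerates to identical cost and
efficacy orderings, which the tests use as a closed-form check).

What the generator does *not* emulate: between-trial clinical
heterogeneity, correlated pain/function effects beyond the shared latent
intensity, reporting quirks of real extracted tables (missing arm sizes,
heterogeneous instrument ranges), or any dependence of period on efficacy.
Tests passing on synthetic data therefore validate the *machinery*
(classification, ranking, determinism, I/O) at realistic scales and value
ranges — not clinical conclusions about real therapies. Substituting a
user-supplied copy of the real extracted table upgrades the worked-example
checks from pattern-level to exact.

## Visualization

One vertical axis per objective; each shown alternative is a polyline.
Axis coordinates are (value − nadir)/(ideal − nadir), so by default every
axis puts *better* at the top (minimized objectives are inverted — a
configurable convention) and the axis endpoints are exactly the dataset's
ideal/nadir values. Group I polylines get full-opacity distinct colors;
group II are low-opacity gray; the preferred range is a band on each axis.
The renderer returns a draw manifest (axis endpoints, band positions,
polyline coordinates and styles) that tests assert on — no pixel
comparisons — and writes SVG or PNG.

## Numerical and testing choices

Everything is exact float arithmetic on small data; there are no
tolerances in the engine itself. Boundary semantics: values exactly on a
preferred-range endpoint are `within`; `better` requires strictly passing
the aspiration bound. The Pareto filter is a vectorized all-pairs
dominance check (n ≤ a few hundred in practice, so O(n²m) broadcasting is
instantaneous); tests verify it against an independently-coded row-sweep
oracle on 100 random problems up to n = 500, and verify classification
properties (reservation-bound relaxation never shrinks group I;
closeness = 0 ⇔ group I; affine rescaling invariance) on seeded random
ensembles of ~1000 draws — sizes chosen to exercise the combinatorics
thoroughly while keeping the default suite in the tens of seconds.

## Known limitations

* Arm-level means only: no variance/covariance propagation, no
  individual-level personalization.
* The closeness scalarization and group-I ranking are package conventions
  (see above), not externally fixed quantities.
* Costs are deterministic unit-fee sums; no discounting, no stochastic
  attendance.
* The interactive loop offers the latest selection only for the final
  choice; earlier iterations' selections are in the history but not
  re-offerable without re-running their preferences.
* Group decision-making (multiple decision-makers) and clinical-guideline
  pre-filtering are out of scope; the exercise-type tag filter is the only
  pre-filtering hook.
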