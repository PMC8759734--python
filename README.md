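# premio

Preferred-range interactive multiobjective optimization for choosing among
discrete treatment alternatives.

## The problem

Clinicians choosing an exercise therapy modality for a patient with knee
osteoarthritis face genuinely conflicting objectives: supervised programmes
tend to reduce pain and improve function more, but cost more, demand more
supervised sessions and often run longer. No single therapy is best on all
counts — there are only *compromises*, and which compromise is right depends
on the patient (budget, travel distance, urgency, severity).

`premio` is a decision-support engine for exactly this situation. Each
alternative is a row in a table, scored on five objectives:

| objective | f | direction | units |
|---|---|---|---|
| cost of therapy | f₁ | minimize | € |
| net WOMAC pain improvement | f₂ | maximize | % |
| net WOMAC function improvement | f₃ | maximize | % |
| supervised training sessions | f₄ | minimize | count |
| treatment period | f₅ | minimize | weeks |

subject to choosing one therapy from the list. "Net" change means
(exercise-arm mean change) − (control-arm mean change), with WOMAC
subscales first standardized onto 0–20 (pain) and 0–68 (function).

## The method

The interactive loop works with a *decision-maker* (a clinician) who states,
for each objective, a **preferred range** [lower, upper] of desirable
outcomes:

1. The per-objective best (ideal) and worst (nadir) observed values are
   shown, so the decision-maker knows what is attainable.
2. Among the Pareto-optimal (nondominated) alternatives, those meeting
   *every* preferred range form **group I** — where out-performing a range
   on its good side still counts as meeting it (only the *reservation*
   bound, the one on the objective's bad side, is binding). The rest form
   **group II** and are ranked by a closeness score: the sum over
   objectives of each reservation violation divided by that objective's
   ideal–nadir span.
3. The k best compromises (group I first, then the closest group II) are
   shown as a parallel-coordinate plot — group I highlighted, group II
   shaded, the preferred ranges drawn as bands.
4. The decision-maker revises the ranges and repeats, or
5. prescribes one of the displayed therapies. Done.

A cost model prices each modality from its session composition (individual
vs group-of-five supervised sessions of 30/45/60 min, unsupervised facility
or home sessions, checkpoint contacts) against a unit-fee schedule; the
packaged default reflects early-2021 Finnish physiotherapy fees.

## Worked example

The package ships a small synthetic eight-alternative dataset
(`premio.scenario_dataset()`) plus the two preference sets of the published
worked example (`premio.published_preferences()`). Round one — a patient with
a ~300 € budget, stretchable to 600 €, wanting ≥15 % improvement, few
supervised sessions, results within 26 weeks:

```sh
premio iterate src/premio/data/scenario_knee_oa.csv \
       --prefs src/premio/data/preferences_iter1.json -k 4
```

prints

```
* [ I] cheung-yoga          closeness=0.0000  cost_eur=520  pain=22  function=18  sessions=12  weeks=12
  [II] lin-proprioception   closeness=0.0833  cost_eur=300  pain=17  function=22  sessions=18  weeks=20
  [II] wang-aquatic         closeness=0.1111  cost_eur=600  pain=18  function=11  sessions=15  weeks=8
  [II] fransen-taichi       closeness=0.1250  cost_eur=220  pain=12  function=20  sessions=6   weeks=10
```

Exactly one therapy (a yoga programme) satisfies every preferred range and
is highlighted (`*`, group I); the other three slots are filled with the
nearest-miss compromises — e.g. the proprioceptive programme misses only on
supervised sessions (18 vs the ≤15 asked for; closeness (18−15)/36 ≈ 0.083).

In round two the decision-maker asks for more function improvement
(+15–40 %) and tolerates up to 30 supervised sessions; now three therapies
(mixed resistance+aerobic, strengthening, proprioceptive) meet every range,
and the scripted decision-maker

```python
import premio as p

scenario = p.scenario_dataset()
prefs1, prefs2 = p.published_preferences()
policy = p.DecisionMakerPolicy(
    preferences=[prefs1, prefs2],
    stop_rule=p.stop_when_group_i_at_least(3),
    choice_rule=p.choose_best("function_net_change_pct"),
)
session = p.simulated_dm(policy, p.start_session(scenario, k=4))
print(len(session.history), session.chosen)   # -> 2 krasilshchikov-mixed
```

finishes in two iterations, prescribing the shown therapy with the largest
function improvement (+38 %).

Other entry points: `premio ranges` (best/worst table), `premio session`
(interactive prompt loop with JSON-lines transcript), `premio replay`
(verify a transcript reproduces), `premio cost` (itemized plan pricing),
`premio synth` (synthetic alternative tables).

## Data interchange

Alternative sets are plain UTF-8 CSV with canonical columns (`id`, `study`,
`exercise_type`, the five objective columns, optional arm sizes); a JSON
*dialect* map lets you ingest tables with different headers without
rewriting them. Preference sets and fee schedules are small JSON files;
session transcripts are JSON lines. Substituting a real extracted trial
table for the synthetic scenario upgrades the worked-example checks from
pattern-level to exact.
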