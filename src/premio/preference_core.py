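"""Optimization core: dominance, preferred ranges, and compromise selection.

The decision problem is discrete: one therapy must be chosen from a finite
list of alternatives scored on several conflicting objectives.  The engine
implements

* Pareto dominance and nondominated (compromise) filtering,
* per-objective ideal (best observed) and nadir (worst observed) values,
* classification of alternatives against a decision-maker's *preferred
  ranges* — per-objective [lower, upper] bounds — into group I (meets every
  range, where out-performing a range on its good side still counts) and
  group II (violates at least one range),
* a closeness score ranking group II alternatives by how little they
  violate the ranges, and
* deterministic top-k selection: group I first, then the closest group II.

Preferred-range semantics
-------------------------
For each objective the *reservation* bound is the bound on the objective's
bad side — the upper bound of a minimized objective, the lower bound of a
maximized one.  Violating the reservation bound excludes group I
membership.  The opposite (*aspiration*) bound is non-binding: values
beyond it are simply better than asked for.  This asymmetry is forced by
the rule that better-than-desired values still count as group I.

Closeness aggregation
---------------------
``closeness_score`` sums, over the objectives, each reservation violation
divided by the objective's observed ideal–nadir span, so violations on
differently-scaled objectives are commensurable.  The aggregation is a
single pluggable function (``agg``), so an alternative scalarization such
as the Chebyshev/max rule can be swapped in.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .therapy_data import (
    AlternativeSet,
    ObjectiveSpec,
    TherapyRecord,
    ValidationError,
)

__all__ = [
    "Status",
    "PreferredRange",
    "PreferenceSet",
    "IdealNadir",
    "ClassifiedAlternative",
    "IterationResult",
    "dominates",
    "pareto_front",
    "ideal_nadir",
    "reservation_bound",
    "aspiration_bound",
    "status",
    "classify",
    "closeness_score",
    "aspiration_distance",
    "select",
]


class Status(str, enum.Enum):
    """How one objective value sits relative to its preferred range."""

    BETTER = "better"   # beyond the range on the objective's good side
    WITHIN = "within"   # inside [lower, upper]
    WORSE = "worse"     # beyond the reservation bound (bad side)


@dataclass(frozen=True)
class PreferredRange:
    """Decision-maker's desirable [lower, upper] bounds for one objective."""

    objective_key: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise ValidationError(
                f"preferred range for {self.objective_key!r}: "
                f"lower ({self.lower}) must be <= upper ({self.upper})"
            )


@dataclass
class PreferenceSet:
    """One preferred range per objective."""

    ranges: Mapping[str, PreferredRange]

    def __post_init__(self) -> None:
        self.ranges = dict(self.ranges)
        for key, rng in self.ranges.items():
            if rng.objective_key != key:
                raise ValidationError(
                    f"range key mismatch: {key!r} vs {rng.objective_key!r}"
                )

    def validate_against(self, specs: Sequence[ObjectiveSpec]) -> None:
        keys = {s.key for s in specs}
        missing = sorted(keys - set(self.ranges))
        extra = sorted(set(self.ranges) - keys)
        if missing or extra:
            parts = []
            if missing:
                parts.append(f"missing objectives: {missing}")
            if extra:
                parts.append(f"unknown objectives: {extra}")
            raise ValidationError("; ".join(parts))

    def to_json(self) -> dict:
        return {
            k: {"lower": r.lower, "upper": r.upper} for k, r in self.ranges.items()
        }

    @classmethod
    def from_json(cls, obj: Mapping[str, Mapping[str, float]]) -> "PreferenceSet":
        return cls(
            {
                k: PreferredRange(k, float(v["lower"]), float(v["upper"]))
                for k, v in obj.items()
            }
        )


@dataclass(frozen=True)
class IdealNadir:
    """Best (ideal) and worst (nadir) observed value per objective."""

    ideal: Mapping[str, float]
    nadir: Mapping[str, float]

    def span(self, key: str) -> float:
        """Normalizer |nadir - ideal|; falls back to 1 for degenerate
        objectives on which all alternatives coincide."""
        width = abs(self.nadir[key] - self.ideal[key])
        return width if width > 0 else 1.0

    def to_json(self) -> dict:
        return {"ideal": dict(self.ideal), "nadir": dict(self.nadir)}


@dataclass(frozen=True)
class ClassifiedAlternative:
    """A record labelled against a preference set."""

    record: TherapyRecord
    group: str  # "I" or "II"
    statuses: Mapping[str, Status]
    closeness: float
    aspiration_dist: float

    def to_json(self) -> dict:
        return {
            "id": self.record.id,
            "group": self.group,
            "statuses": {k: s.value for k, s in self.statuses.items()},
            "closeness": self.closeness,
            "aspiration_dist": self.aspiration_dist,
        }


@dataclass
class IterationResult:
    """Outcome of one selection round: the k compromises shown to the DM."""

    prefs: PreferenceSet
    selection: list[ClassifiedAlternative]
    ideal_nadir: IdealNadir
    index: int = 0
    timestamp: str | None = None

    @property
    def group_i(self) -> list[ClassifiedAlternative]:
        return [c for c in self.selection if c.group == "I"]

    @property
    def group_ii(self) -> list[ClassifiedAlternative]:
        return [c for c in self.selection if c.group == "II"]

    def to_json(self) -> dict:
        return {
            "index": self.index,
            "timestamp": self.timestamp,
            "prefs": self.prefs.to_json(),
            "selection": [c.to_json() for c in self.selection],
            "ideal_nadir": self.ideal_nadir.to_json(),
        }


# ---------------------------------------------------------------------------
# Dominance and ranges
# ---------------------------------------------------------------------------

def _sign(direction: str) -> float:
    # map both directions onto minimization
    return 1.0 if direction == "minimize" else -1.0


def dominates(
    a: TherapyRecord, b: TherapyRecord, specs: Sequence[ObjectiveSpec]
) -> bool:
    """True iff ``a`` is at least as good as ``b`` on every objective and
    strictly better on at least one (directions respected)."""
    for rec in (a, b):
        missing = [s.key for s in specs if s.key not in rec.objectives]
        if missing:
            raise ValidationError(f"record {rec.id!r} missing objectives {missing}")
    at_least_as_good = True
    strictly_better = False
    for spec in specs:
        va = _sign(spec.direction) * a.objectives[spec.key]
        vb = _sign(spec.direction) * b.objectives[spec.key]
        if va > vb:
            at_least_as_good = False
            break
        if va < vb:
            strictly_better = True
    return at_least_as_good and strictly_better


def _minimization_matrix(altset: AlternativeSet) -> np.ndarray:
    signs = np.array([_sign(s.direction) for s in altset.specs])
    values = np.array(
        [[r.objectives[s.key] for s in altset.specs] for r in altset.records],
        dtype=float,
    )
    return values * signs


def pareto_front(altset: AlternativeSet) -> list[str]:
    """Ids of the nondominated records, in input order.

    Vectorized all-pairs check: record j is dominated iff some i is <= on
    every (sign-adjusted) objective and < on at least one.
    """
    if len(altset) == 0:
        raise ValidationError("alternative set is empty")
    a = _minimization_matrix(altset)
    le = (a[:, None, :] <= a[None, :, :]).all(axis=2)
    lt = (a[:, None, :] < a[None, :, :]).any(axis=2)
    dominated = (le & lt).any(axis=0)
    return [r.id for r, d in zip(altset.records, dominated) if not d]


def ideal_nadir(altset: AlternativeSet) -> IdealNadir:
    """Best and worst observed values per objective over the full set.

    Computed before any Pareto filtering, so the decision-maker sees the
    true range of available therapies.
    """
    if len(altset) == 0:
        raise ValidationError("alternative set is empty")
    ideal: dict[str, float] = {}
    nadir: dict[str, float] = {}
    for spec in altset.specs:
        values = [r.objectives[spec.key] for r in altset.records]
        if spec.direction == "minimize":
            ideal[spec.key], nadir[spec.key] = min(values), max(values)
        else:
            ideal[spec.key], nadir[spec.key] = max(values), min(values)
    return IdealNadir(ideal=ideal, nadir=nadir)


def reservation_bound(rng: PreferredRange, direction: str) -> float:
    """The binding bound, on the objective's bad side."""
    return rng.upper if direction == "minimize" else rng.lower


def aspiration_bound(rng: PreferredRange, direction: str) -> float:
    """The non-binding bound, on the objective's good side."""
    return rng.lower if direction == "minimize" else rng.upper


def status(value: float, rng: PreferredRange, direction: str) -> Status:
    """Classify one objective value against its preferred range."""
    if rng.lower <= value <= rng.upper:
        return Status.WITHIN
    if direction == "minimize":
        return Status.BETTER if value < rng.lower else Status.WORSE
    return Status.BETTER if value > rng.upper else Status.WORSE


def _reservation_violation(value: float, rng: PreferredRange, direction: str) -> float:
    """Distance from the value to the nearest group-I-eligible value; zero
    for status better/within."""
    if direction == "minimize":
        return max(0.0, value - rng.upper)
    return max(0.0, rng.lower - value)


def closeness_score(
    record: TherapyRecord,
    prefs: PreferenceSet,
    specs: Sequence[ObjectiveSpec],
    norm: IdealNadir,
    agg: Callable[[Iterable[float]], float] = sum,
) -> float:
    """Aggregate ideal–nadir-normalized reservation violations.

    Zero iff the record is group I.  ``agg`` defaults to the L1 sum; pass
    ``max`` for a Chebyshev-style worst-violation score.
    """
    violations = []
    for spec in specs:
        rng = prefs.ranges[spec.key]
        v = _reservation_violation(record.objectives[spec.key], rng, spec.direction)
        violations.append(v / norm.span(spec.key))
    return float(agg(violations))


def aspiration_distance(
    record: TherapyRecord,
    prefs: PreferenceSet,
    specs: Sequence[ObjectiveSpec],
    norm: IdealNadir,
) -> float:
    """Normalized L1 distance to the aspiration corner (the vector of
    good-side bounds); used to rank within group I."""
    total = 0.0
    for spec in specs:
        asp = aspiration_bound(prefs.ranges[spec.key], spec.direction)
        total += abs(record.objectives[spec.key] - asp) / norm.span(spec.key)
    return total


def classify(
    record: TherapyRecord,
    prefs: PreferenceSet,
    specs: Sequence[ObjectiveSpec],
    norm: IdealNadir,
    agg: Callable[[Iterable[float]], float] = sum,
) -> ClassifiedAlternative:
    """Label a record group I (all ranges met, better-than-desired values
    included) or group II, with per-objective statuses and scores."""
    prefs.validate_against(specs)
    statuses = {
        s.key: status(record.objectives[s.key], prefs.ranges[s.key], s.direction)
        for s in specs
    }
    group = "I" if all(st is not Status.WORSE for st in statuses.values()) else "II"
    closeness = closeness_score(record, prefs, specs, norm, agg=agg)
    asp = aspiration_distance(record, prefs, specs, norm)
    return ClassifiedAlternative(
        record=record,
        group=group,
        statuses=statuses,
        closeness=closeness,
        aspiration_dist=asp,
    )


def select(
    altset: AlternativeSet,
    prefs: PreferenceSet,
    k: int,
    restrict_to_front: bool = True,
    agg: Callable[[Iterable[float]], float] = sum,
) -> IterationResult:
    """Pick the k compromise alternatives best reflecting the preferences.

    The candidate pool is the Pareto front by default (every shown therapy
    is then a genuine compromise); set ``restrict_to_front=False`` to rank
    dominated alternatives as well.  All group I candidates come first,
    ordered by ascending aspiration distance; remaining slots are filled by
    group II candidates in ascending closeness.  Ties break
    lexicographically by record id, so the output is deterministic and
    invariant under row permutation of the input.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(altset) == 0:
        raise ValidationError("alternative set is empty")
    prefs.validate_against(altset.specs)

    norm = ideal_nadir(altset)
    if restrict_to_front:
        front = set(pareto_front(altset))
        pool = [r for r in altset.records if r.id in front]
    else:
        pool = list(altset.records)

    classified = [classify(r, prefs, altset.specs, norm, agg=agg) for r in pool]
    group_i = sorted(
        (c for c in classified if c.group == "I"),
        key=lambda c: (c.aspiration_dist, c.record.id),
    )
    group_ii = sorted(
        (c for c in classified if c.group == "II"),
        key=lambda c: (c.closeness, c.record.id),
    )
    selection = (group_i + group_ii)[:k]
    return IterationResult(prefs=prefs, selection=selection, ideal_nadir=norm)
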