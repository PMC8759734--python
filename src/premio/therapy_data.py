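"""Data model and I/O for discrete therapy alternatives.

An :class:`AlternativeSet` holds one row per intervention (an exercise
therapy modality extracted from a randomized controlled trial arm) together
with the ordered list of objectives on which the alternatives are compared.
The canonical problem uses five objectives:

* ``cost_eur`` — patient-facing cost of the therapy, € (minimize)
* ``pain_net_change_pct`` — net WOMAC pain improvement, % (maximize)
* ``function_net_change_pct`` — net WOMAC function improvement, % (maximize)
* ``supervised_sessions`` — number of supervised training sessions (minimize)
* ``period_weeks`` — length of the treatment period, weeks (minimize)

The module also provides the WOMAC pre/post arithmetic that turns trial arm
summaries into objective values: linear rescaling of WOMAC subscales onto
the standard ranges (0–20 pain, 0–68 function), pre-minus-post mean change,
exercise-minus-control net change, and percent net change relative to a
baseline reference.
"""

from __future__ import annotations

import math
import re
import unicodedata
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import pandas as pd

__all__ = [
    "SchemaError",
    "ParseError",
    "ValidationError",
    "ObjectiveSpec",
    "TherapyRecord",
    "AlternativeSet",
    "WomacArmSummary",
    "WOMAC_PAIN_SCALE",
    "WOMAC_FUNCTION_SCALE",
    "canonical_objectives",
    "read_alternatives",
    "write_alternatives",
    "standardize_womac",
    "mean_change",
    "net_change",
    "percent_net_change",
    "slugify",
]

Direction = Literal["minimize", "maximize"]

#: Standardized WOMAC subscale ranges used across the dataset.
WOMAC_PAIN_SCALE: tuple[float, float] = (0.0, 20.0)
WOMAC_FUNCTION_SCALE: tuple[float, float] = (0.0, 68.0)

#: Canonical column order of the delimited interchange format.
CANONICAL_COLUMNS: tuple[str, ...] = (
    "id",
    "study",
    "exercise_type",
    "cost_eur",
    "pain_net_change_pct",
    "function_net_change_pct",
    "supervised_sessions",
    "period_weeks",
    "n_exercise",
    "n_control",
)

_OPTIONAL_COLUMNS = frozenset({"id", "n_exercise", "n_control"})


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class ParseError(ValueError):
    """A cell could not be parsed as the expected type."""


class ValidationError(ValueError):
    """A record or alternative set violates a structural invariant."""


@dataclass(frozen=True)
class ObjectiveSpec:
    """One objective: identifier, optimization direction and units.

    ``standard_scale`` is only meaningful for outcome objectives whose raw
    trial values may arrive on heterogeneous instrument ranges and need
    rescaling (the WOMAC subscales).
    """

    key: str
    label: str
    direction: Direction
    units: str = ""
    standard_scale: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("minimize", "maximize"):
            raise ValidationError(
                f"objective {self.key!r}: direction must be 'minimize' or "
                f"'maximize', got {self.direction!r}"
            )
        if self.standard_scale is not None:
            lo, hi = self.standard_scale
            if not lo < hi:
                raise ValidationError(
                    f"objective {self.key!r}: standard_scale min must be < max"
                )


def canonical_objectives() -> list[ObjectiveSpec]:
    """The five canonical objectives of the therapy-selection problem."""
    return [
        ObjectiveSpec("cost_eur", "Costs", "minimize", "€"),
        ObjectiveSpec(
            "pain_net_change_pct",
            "Pain change",
            "maximize",
            "%",
            standard_scale=WOMAC_PAIN_SCALE,
        ),
        ObjectiveSpec(
            "function_net_change_pct",
            "Function change",
            "maximize",
            "%",
            standard_scale=WOMAC_FUNCTION_SCALE,
        ),
        ObjectiveSpec("supervised_sessions", "Supervised sessions", "minimize", "sessions"),
        ObjectiveSpec("period_weeks", "Period", "minimize", "weeks"),
    ]


@dataclass(frozen=True)
class TherapyRecord:
    """One intervention with its objective values and provenance."""

    id: str
    study: str
    exercise_type: str
    objectives: Mapping[str, float]
    n_exercise: int | None = None
    n_control: int | None = None

    def value(self, key: str) -> float:
        return self.objectives[key]


@dataclass
class AlternativeSet:
    """An ordered collection of therapy alternatives sharing objectives."""

    specs: Sequence[ObjectiveSpec]
    records: Sequence[TherapyRecord]

    def __post_init__(self) -> None:
        self.specs = list(self.specs)
        self.records = list(self.records)
        self.validate()

    @property
    def objective_keys(self) -> list[str]:
        return [s.key for s in self.specs]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, record_id: str) -> TherapyRecord:
        for r in self.records:
            if r.id == record_id:
                return r
        raise KeyError(record_id)

    def validate(self) -> None:
        keys = self.objective_keys
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate objective keys in specs")
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValidationError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
            missing = [k for k in keys if k not in rec.objectives]
            if missing:
                raise ValidationError(
                    f"record {rec.id!r} is missing objective value(s): {missing}"
                )
            for k in keys:
                v = rec.objectives[k]
                if not math.isfinite(v):
                    raise ValidationError(
                        f"record {rec.id!r}: objective {k!r} is not finite"
                    )
            self._check_domain(rec)
            for n in (rec.n_exercise, rec.n_control):
                if n is not None and n <= 0:
                    raise ValidationError(
                        f"record {rec.id!r}: arm sizes must be positive"
                    )

    @staticmethod
    def _check_domain(rec: TherapyRecord) -> None:
        obj = rec.objectives
        if "supervised_sessions" in obj:
            s = obj["supervised_sessions"]
            if s < 0 or s != round(s):
                raise ValidationError(
                    f"record {rec.id!r}: supervised_sessions must be a "
                    f"nonnegative integer, got {s}"
                )
        if "period_weeks" in obj and obj["period_weeks"] <= 0:
            raise ValidationError(f"record {rec.id!r}: period_weeks must be > 0")
        if "cost_eur" in obj and obj["cost_eur"] < 0:
            raise ValidationError(f"record {rec.id!r}: cost_eur must be >= 0")

    def subset(self, ids: Sequence[str]) -> "AlternativeSet":
        wanted = set(ids)
        return AlternativeSet(self.specs, [r for r in self.records if r.id in wanted])


@dataclass(frozen=True)
class WomacArmSummary:
    """Pre/post mean WOMAC scores of one trial arm, on its reported scale."""

    pre_mean: float
    post_mean: float
    scale: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.scale
        if not lo < hi:
            raise ValidationError("WOMAC scale min must be < max")
        for name, v in (("pre_mean", self.pre_mean), ("post_mean", self.post_mean)):
            if not lo <= v <= hi:
                raise ValidationError(
                    f"{name}={v} outside the reported scale ({lo}, {hi})"
                )


# ---------------------------------------------------------------------------
# WOMAC arithmetic
# ---------------------------------------------------------------------------

def standardize_womac(
    score: float,
    source_scale: tuple[float, float],
    target_scale: tuple[float, float],
) -> float:
    """Linearly map ``score`` from ``source_scale`` onto ``target_scale``.

    Endpoints map exactly to endpoints; scores outside the source scale are
    rejected.  Used to bring heterogeneous WOMAC subscale ranges onto the
    standard 0–20 (pain) and 0–68 (function) ranges.
    """
    s_lo, s_hi = source_scale
    t_lo, t_hi = target_scale
    if not (s_lo < s_hi and t_lo < t_hi):
        raise ValidationError("scale min must be < max")
    if not s_lo <= score <= s_hi:
        raise ValidationError(
            f"score {score} outside source scale ({s_lo}, {s_hi})"
        )
    if score == s_hi:  # exact endpoint mapping regardless of rounding
        return t_hi
    return t_lo + (score - s_lo) * (t_hi - t_lo) / (s_hi - s_lo)


def mean_change(arm: WomacArmSummary) -> float:
    """Pre-minus-post mean change; positive means improvement (lower WOMAC
    scores are better)."""
    return arm.pre_mean - arm.post_mean


def net_change(exercise_change: float, control_change: float) -> float:
    """Exercise-arm change minus control-arm change.

    Positive values mean the exercise arm improved more than the usual-care
    control arm; antisymmetric under swapping the arms.
    """
    for v in (exercise_change, control_change):
        if not math.isfinite(v):
            raise ValidationError("arm changes must be finite")
    return exercise_change - control_change


def percent_net_change(net: float, reference: float) -> float:
    """Net change as a percentage of a positive reference value.

    The conventional reference is the exercise arm's baseline mean on the
    standardized scale, giving relative improvement versus where the arm
    started.
    """
    if not reference > 0:
        raise ValidationError(f"reference must be > 0, got {reference}")
    return 100.0 * net / reference


# ---------------------------------------------------------------------------
# Delimited I/O
# ---------------------------------------------------------------------------

def slugify(text: str) -> str:
    """ASCII-fold and kebab-case a label for use as a deterministic id."""
    folded = (
        unicodedata.normalize("NFKD", text).encode("ascii", "ignore").decode("ascii")
    )
    slug = re.sub(r"[^a-z0-9]+", "-", folded.lower()).strip("-")
    return slug or "record"


def _apply_dialect(canonical: str, dialect: Mapping[str, str] | None) -> str:
    if dialect and canonical in dialect:
        return dialect[canonical]
    return canonical


def read_alternatives(
    path,
    dialect: Mapping[str, str] | None = None,
    specs: Sequence[ObjectiveSpec] | None = None,
) -> AlternativeSet:
    """Load an :class:`AlternativeSet` from a delimited (CSV) file.

    Parameters
    ----------
    path:
        CSV file with a header row, UTF-8 encoded.
    dialect:
        Optional mapping of canonical column names to the actual column
        names used in the file, so user-supplied tables with different
        headers can be ingested without rewriting them.
    specs:
        Objective specs; defaults to the five canonical objectives.

    Row order is preserved.  When the ``id`` column is absent, ids are
    generated deterministically as ``slug(study)-slug(exercise_type)`` with
    a numeric suffix on collision.
    """
    specs = list(specs) if specs is not None else canonical_objectives()
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")

    required = ["study", "exercise_type"] + [s.key for s in specs]
    colmap: dict[str, str] = {}
    for canonical in required:
        actual = _apply_dialect(canonical, dialect)
        if actual not in df.columns:
            raise SchemaError(
                f"missing required column {actual!r} (canonical {canonical!r})"
            )
        colmap[canonical] = actual
    for canonical in _OPTIONAL_COLUMNS:
        actual = _apply_dialect(canonical, dialect)
        if actual in df.columns:
            colmap[canonical] = actual

    records: list[TherapyRecord] = []
    used_ids: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        study = row_d[colmap["study"]].strip()
        exercise_type = row_d[colmap["exercise_type"]].strip()

        objectives: dict[str, float] = {}
        for spec in specs:
            cell = row_d[colmap[spec.key]].strip()
            try:
                objectives[spec.key] = float(cell)
            except ValueError:
                raise ParseError(
                    f"row {i}: column {colmap[spec.key]!r}: "
                    f"cannot parse {cell!r} as a number"
                ) from None

        arm_sizes: dict[str, int | None] = {}
        for key in ("n_exercise", "n_control"):
            cell = row_d.get(colmap.get(key, ""), "").strip()
            if cell == "":
                arm_sizes[key] = None
            else:
                try:
                    arm_sizes[key] = int(float(cell))
                except ValueError:
                    raise ParseError(
                        f"row {i}: column {colmap[key]!r}: "
                        f"cannot parse {cell!r} as an integer"
                    ) from None

        if "id" in colmap and row_d[colmap["id"]].strip():
            rec_id = row_d[colmap["id"]].strip()
            if rec_id in used_ids:
                raise ValidationError(f"row {i}: duplicate record id {rec_id!r}")
        else:
            base = f"{slugify(study)}-{slugify(exercise_type)}"
            rec_id, suffix = base, 2
            while rec_id in used_ids:
                rec_id = f"{base}-{suffix}"
                suffix += 1
        used_ids.add(rec_id)

        records.append(
            TherapyRecord(
                id=rec_id,
                study=study,
                exercise_type=exercise_type,
                objectives=objectives,
                n_exercise=arm_sizes["n_exercise"],
                n_control=arm_sizes["n_control"],
            )
        )

    return AlternativeSet(specs, records)


def write_alternatives(altset: AlternativeSet, path) -> None:
    """Write an :class:`AlternativeSet` as canonical CSV (UTF-8).

    Round-trips exactly: ``read_alternatives(write_alternatives(s))``
    reproduces ``s`` field for field (floats are serialized at full
    precision).
    """
    rows = []
    for rec in altset.records:
        row: dict[str, object] = {
            "id": rec.id,
            "study": rec.study,
            "exercise_type": rec.exercise_type,
        }
        for spec in altset.specs:
            row[spec.key] = repr(rec.objectives[spec.key])
        row["n_exercise"] = "" if rec.n_exercise is None else rec.n_exercise
        row["n_control"] = "" if rec.n_control is None else rec.n_control
        rows.append(row)
    columns = ["id", "study", "exercise_type"] + [s.key for s in altset.specs] + [
        "n_exercise",
        "n_control",
    ]
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, index=False, encoding="utf-8")
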