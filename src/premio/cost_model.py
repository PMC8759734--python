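"""Patient-facing cost estimation for exercise therapy modalities.

Cost is estimated from the session composition of an intervention — how
many supervised sessions (individual or in groups of five), of what
duration, how many unsupervised facility or home sessions, and how many
checkpoint contacts (phone call / SMS) — priced against a fee schedule of
unit fees.  The packaged default schedule reflects early-2021 Finnish
physiotherapy prices; users can supply their own schedule to adapt the
estimates to another time or country.

Durations are matched exactly against the listed entries (30/45/60 min);
fees for in-between durations are not interpolated because the schedule
lists discrete price points only — callers round to the nearest listed
duration explicitly.  Costs cover the window from baseline to the outcome
end-point; later follow-ups are excluded, so a plan's ``window`` field is
documentation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

__all__ = [
    "Setting",
    "FeeEntry",
    "FeeSchedule",
    "PlanItem",
    "InterventionPlan",
    "FeeLookupError",
    "unit_fee",
    "estimate_cost",
    "itemize_cost",
]


class Setting(str, Enum):
    """Where/how a session takes place, for fee lookup."""

    SUPERVISED_INDIVIDUAL = "supervised_individual"
    SUPERVISED_GROUP5 = "supervised_group5"
    UNSUPERVISED_FACILITY = "unsupervised_facility"
    UNSUPERVISED_HOME = "unsupervised_home"
    CONTACT = "contact"


@dataclass(frozen=True)
class FeeEntry:
    """One line of a fee schedule.

    ``duration_min`` is ``None`` for per-session/per-event fees that do not
    depend on duration (facility and home sessions, contacts); such entries
    match any requested duration.
    """

    setting: Setting
    duration_min: int | None
    unit_fee_eur: float

    def __post_init__(self) -> None:
        if self.unit_fee_eur < 0:
            raise ValueError("unit fees must be nonnegative")


@dataclass(frozen=True)
class FeeSchedule:
    entries: tuple[FeeEntry, ...]
    equipment_fee_eur: float = 0.0

    def __post_init__(self) -> None:
        if self.equipment_fee_eur < 0:
            raise ValueError("equipment fee must be nonnegative")

    def to_json(self) -> dict:
        return {
            "entries": [
                {
                    "setting": e.setting.value,
                    "duration_min": e.duration_min,
                    "unit_fee_eur": e.unit_fee_eur,
                }
                for e in self.entries
            ],
            "equipment_fee_eur": self.equipment_fee_eur,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "FeeSchedule":
        entries = tuple(
            FeeEntry(Setting(e["setting"]), e["duration_min"], float(e["unit_fee_eur"]))
            for e in obj["entries"]
        )
        return cls(entries=entries, equipment_fee_eur=float(obj.get("equipment_fee_eur", 0.0)))


@dataclass(frozen=True)
class PlanItem:
    setting: Setting
    duration_min: int | None
    count: int

    def __post_init__(self) -> None:
        if self.count < 0 or self.count != int(self.count):
            raise ValueError("item counts must be nonnegative integers")


@dataclass(frozen=True)
class InterventionPlan:
    """Session composition of one intervention over its measurement window."""

    items: tuple[PlanItem, ...] = ()
    contacts: int = 0
    window: str = ""

    def __post_init__(self) -> None:
        if self.contacts < 0:
            raise ValueError("contact count must be nonnegative")

    @classmethod
    def from_json(cls, obj: dict) -> "InterventionPlan":
        items = tuple(
            PlanItem(Setting(it["setting"]), it.get("duration_min"), int(it["count"]))
            for it in obj.get("items", [])
        )
        return cls(items=items, contacts=int(obj.get("contacts", 0)), window=obj.get("window", ""))


class FeeLookupError(LookupError):
    """No fee schedule entry matches a requested (setting, duration)."""


def unit_fee(
    schedule: FeeSchedule, setting: Setting, duration_min: int | None = None
) -> float:
    """Return the unit fee for a session of the given setting and duration.

    Entries with a duration match only that exact duration; duration-free
    entries (home/facility/contact) match any requested duration.
    """
    setting = Setting(setting)
    for entry in schedule.entries:
        if entry.setting != setting:
            continue
        if entry.duration_min is None or entry.duration_min == duration_min:
            return entry.unit_fee_eur
    raise FeeLookupError(
        f"no fee entry for setting={setting.value!r}, duration_min={duration_min!r}"
    )


def itemize_cost(
    plan: InterventionPlan, schedule: FeeSchedule
) -> list[tuple[str, int, float, float]]:
    """Breakdown as (description, count, unit fee €, subtotal €) lines."""
    lines: list[tuple[str, int, float, float]] = []
    for item in plan.items:
        fee = unit_fee(schedule, item.setting, item.duration_min)
        dur = f" {item.duration_min} min" if item.duration_min is not None else ""
        lines.append(
            (f"{item.setting.value}{dur}", item.count, fee, item.count * fee)
        )
    if plan.contacts:
        fee = unit_fee(schedule, Setting.CONTACT)
        lines.append(("contact", plan.contacts, fee, plan.contacts * fee))
    if schedule.equipment_fee_eur:
        lines.append(("equipment", 1, schedule.equipment_fee_eur, schedule.equipment_fee_eur))
    return lines


def estimate_cost(plan: InterventionPlan, schedule: FeeSchedule) -> float:
    """Total patient-facing cost of a plan under a fee schedule, in €.

    Sum of session counts times unit fees, plus contact fees, plus the
    (one-off) equipment fee.  Additive over plans and monotone in every
    count.
    """
    total = sum(
        item.count * unit_fee(schedule, item.setting, item.duration_min)
        for item in plan.items
    )
    if plan.contacts:
        total += plan.contacts * unit_fee(schedule, Setting.CONTACT)
    total += schedule.equipment_fee_eur
    return total
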