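"""Packaged reference inputs and a synthetic alternative-set generator.

Three kinds of inputs ship with the package:

* the published fee schedule (early-2021 Finnish physiotherapy unit fees)
  used to cost exercise therapy modalities,
* the two published preference sets of the worked knee-OA example
  (a patient with a ~300 € budget, stretchable to 600 € for ≥25 %
  improvement, preferring few supervised sessions), and
* ``scenario_dataset`` — a small, hand-built, **synthetic** set of eight
  mutually nondominated therapy alternatives engineered so that those two
  preference sets reproduce the published two-iteration pattern: first
  exactly one alternative meets every range, then — after relaxing cost
  downwards and asking for more function improvement while tolerating more
  supervised sessions — exactly three do (the Krasilshchikov, Braghin and
  Lin records).  The study names echo the trials cited in the worked
  example but the numeric values are invented; substituting a user-supplied
  copy of the real extracted table upgrades pattern-level checks to exact
  ones.

:func:`generate_alternatives` draws larger synthetic problems with a
controllable cost/effort ↔ efficacy trade-off, for property testing and
benchmarking at arbitrary n.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

from .cost_model import FeeSchedule
from .preference_core import PreferenceSet
from .therapy_data import (
    AlternativeSet,
    TherapyRecord,
    ValidationError,
    canonical_objectives,
)

__all__ = [
    "SynthConfig",
    "published_preferences",
    "default_fee_schedule",
    "generate_alternatives",
    "scenario_dataset",
]

_EXERCISE_TYPES = (
    "yoga",
    "resistance+aerobic",
    "strengthening",
    "proprioceptive",
    "tai chi",
    "home exercise",
    "aquatic",
    "walking",
    "cycling",
    "stretching",
)


def _load_json(name: str) -> dict:
    with resources.files("premio.data").joinpath(name).open(encoding="utf-8") as fh:
        return json.load(fh)


def published_preferences() -> tuple[PreferenceSet, PreferenceSet]:
    """The two published preference sets of the worked example.

    Iteration 1: cost 300–600 €, pain +15–30 %, function +15–25 %,
    0–15 supervised sessions, 8–26 weeks.  Iteration 2: cost 200–500 €,
    pain +15–25 %, function +15–40 %, 0–30 sessions, 12–26 weeks.
    """
    return (
        PreferenceSet.from_json(_load_json("preferences_iter1.json")),
        PreferenceSet.from_json(_load_json("preferences_iter2.json")),
    )


def default_fee_schedule() -> FeeSchedule:
    """The published unit-fee table: 100/75/50 € for individual supervised
    sessions of 60/45/30 min, 20/15/10 € per head in groups of five,
    10 € per unsupervised facility session, 0 € at home, 10 € per
    checkpoint contact, 0 € equipment."""
    return FeeSchedule.from_json(_load_json("fees_table.json"))


def scenario_dataset() -> AlternativeSet:
    """The packaged eight-record synthetic worked-example dataset.

    All eight records are mutually nondominated; see the module docstring
    for how the values were engineered.
    """
    from .therapy_data import read_alternatives

    with resources.files("premio.data").joinpath("scenario_knee_oa.csv").open(
        encoding="utf-8"
    ) as fh:
        return read_alternatives(fh)


@dataclass
class SynthConfig:
    """Parameters of the synthetic alternative-set generator.

    The generator emulates the structure of an extracted trial table: five
    mixed min/max objectives where efficacy (net pain and function
    improvement) is positively coupled — with strength
    ``tradeoff_strength`` — to the effort objectives (cost, supervised
    sessions), so cheap *and* highly effective therapies are rare and the
    Pareto front is nontrivial.  Defaults mirror the published problem:
    31 alternatives from 21 studies, costs up to ~1 500 €, efficacy in the
    −5…45 % band, up to 36 supervised sessions, 8–48-week programmes.
    """

    n: int = 31
    seed: int = 42
    cost_range: tuple[float, float] = (0.0, 1500.0)
    pain_range: tuple[float, float] = (-5.0, 45.0)
    function_range: tuple[float, float] = (-5.0, 45.0)
    sessions_range: tuple[int, int] = (0, 36)
    period_range: tuple[int, int] = (8, 48)
    tradeoff_strength: float = 0.7
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "cost_eur": 60.0,
            "pain_net_change_pct": 4.0,
            "function_net_change_pct": 4.0,
            "supervised_sessions": 2.0,
        }
    )
    n_studies: int | None = None  # default: round(n * 21 / 31)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if not 0.0 <= self.tradeoff_strength <= 1.0:
            raise ValidationError("tradeoff_strength must be in [0, 1]")
        for name in ("cost_range", "pain_range", "function_range",
                     "sessions_range", "period_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"{name}: min must be < max")


def generate_alternatives(config: SynthConfig) -> AlternativeSet:
    """Draw a seeded synthetic :class:`AlternativeSet`.

    A latent per-alternative intensity u ~ U(0,1) drives cost and session
    count directly; each efficacy objective follows
    ``tradeoff_strength * u + (1 - tradeoff_strength) * v`` for an
    independent v ~ U(0,1), plus Gaussian noise, clipped to its range.
    With ``tradeoff_strength=1`` and zero noise the cost order equals the
    efficacy order exactly; with intermediate values the extremes conflict
    and the expected Pareto front holds several records.  The treatment
    period is drawn independently.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    sd = dict(config.noise_sd)

    u = rng.uniform(0.0, 1.0, n)

    def couple(lo: float, hi: float, key: str) -> np.ndarray:
        v = rng.uniform(0.0, 1.0, n)
        mix = config.tradeoff_strength * u + (1.0 - config.tradeoff_strength) * v
        vals = lo + mix * (hi - lo) + rng.normal(0.0, sd.get(key, 0.0), n)
        return np.clip(vals, lo, hi)

    c_lo, c_hi = config.cost_range
    cost = np.clip(
        c_lo + u * (c_hi - c_lo) + rng.normal(0.0, sd.get("cost_eur", 0.0), n),
        c_lo, c_hi,
    )
    s_lo, s_hi = config.sessions_range
    sessions = np.clip(
        np.round(
            s_lo + u * (s_hi - s_lo)
            + rng.normal(0.0, sd.get("supervised_sessions", 0.0), n)
        ),
        s_lo, s_hi,
    )
    pain = couple(*config.pain_range, "pain_net_change_pct")
    func = couple(*config.function_range, "function_net_change_pct")
    w_lo, w_hi = config.period_range
    period = rng.integers(w_lo, w_hi + 1, n)

    n_studies = (
        config.n_studies
        if config.n_studies is not None
        else max(1, round(n * 21 / 31))
    )
    n_studies = min(n_studies, n)

    records = []
    for i in range(n):
        records.append(
            TherapyRecord(
                id=f"synth-{i + 1:03d}",
                study=f"Synthetic study {(i % n_studies) + 1:02d}",
                exercise_type=_EXERCISE_TYPES[i % len(_EXERCISE_TYPES)],
                objectives={
                    "cost_eur": float(cost[i]),
                    "pain_net_change_pct": float(pain[i]),
                    "function_net_change_pct": float(func[i]),
                    "supervised_sessions": float(sessions[i]),
                    "period_weeks": float(period[i]),
                },
            )
        )
    return AlternativeSet(canonical_objectives(), records)
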