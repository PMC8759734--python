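"""Interactive solution loop for preferred-range therapy selection.

A :class:`Session` wraps one decision process: the alternative set is
fixed, the decision-maker states how many compromises to see per round
(``k``, elicited once at the start), and then iterates — provide preferred
ranges, inspect the k returned compromises (group I highlighted, group II
shaded), optionally revise the ranges, and finally prescribe one of the
therapies shown in the latest round.

The loop is fully deterministic given the dataset and the sequence of
preference sets, which makes sessions replayable: :func:`export_log`
writes a JSON-lines transcript and :func:`replay` re-runs it against a
dataset, verifying that every selection is reproduced exactly.

:func:`simulated_dm` drives a session from a scripted
:class:`DecisionMakerPolicy` — a sequence of preference sets plus stop and
choice rules — so end-to-end behaviour can be exercised without a human.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Callable, Sequence

import pandas as pd

from .preference_core import (
    IdealNadir,
    IterationResult,
    PreferenceSet,
    ideal_nadir,
    select,
)
from .therapy_data import AlternativeSet, ValidationError, write_alternatives

__all__ = [
    "Session",
    "SessionError",
    "ReplayError",
    "PolicyExhaustedError",
    "DecisionMakerPolicy",
    "start_session",
    "run_iteration",
    "finish",
    "simulated_dm",
    "stop_when_group_i_at_least",
    "choose_best",
    "export_log",
    "replay",
    "dataset_digest",
]


class SessionError(RuntimeError):
    """Invalid state transition in the interactive loop."""


class ReplayError(RuntimeError):
    """A logged session does not reproduce against the given dataset."""


class PolicyExhaustedError(RuntimeError):
    """A scripted decision-maker ran out of preference sets before its
    stop rule fired."""


@dataclass
class Session:
    dataset: AlternativeSet
    k: int
    restrict_to_front: bool = True
    history: list[IterationResult] = field(default_factory=list)
    state: str = "awaiting_preferences"  # or "finished"
    chosen: str | None = None

    @property
    def ideal_nadir(self) -> IdealNadir:
        return ideal_nadir(self.dataset)

    def ranges_table(self) -> pd.DataFrame:
        """Best/worst value per objective — the overview shown to the
        decision-maker before the first preferences are elicited."""
        inad = self.ideal_nadir
        rows = [
            {
                "objective": s.label,
                "key": s.key,
                "direction": s.direction,
                "units": s.units,
                "best": inad.ideal[s.key],
                "worst": inad.nadir[s.key],
            }
            for s in self.dataset.specs
        ]
        return pd.DataFrame(rows)

    @property
    def latest(self) -> IterationResult:
        if not self.history:
            raise SessionError("no iterations have been run yet")
        return self.history[-1]


def start_session(
    dataset: AlternativeSet,
    k: int,
    include_types: Sequence[str] | None = None,
    exclude_types: Sequence[str] | None = None,
    restrict_to_front: bool = True,
) -> Session:
    """Open a session on a dataset, optionally pre-filtered by exercise type.

    ``include_types`` / ``exclude_types`` match against each record's
    ``exercise_type`` tag, letting a clinician exclude modality families a
    patient cannot perform before any preferences are stated.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    records = list(dataset.records)
    if include_types is not None:
        wanted = {t.lower() for t in include_types}
        records = [r for r in records if r.exercise_type.lower() in wanted]
    if exclude_types is not None:
        banned = {t.lower() for t in exclude_types}
        records = [r for r in records if r.exercise_type.lower() not in banned]
    if not records:
        raise ValidationError("no alternatives available (empty dataset after filtering)")
    filtered = AlternativeSet(dataset.specs, records)
    return Session(dataset=filtered, k=k, restrict_to_front=restrict_to_front)


def run_iteration(session: Session, prefs: PreferenceSet) -> IterationResult:
    """Solve one round: classify, rank and return the k best compromises.

    Appends the result to the session history; the session stays open for
    further preference revisions.
    """
    if session.state != "awaiting_preferences":
        raise SessionError(f"session is {session.state}; cannot iterate")
    prefs.validate_against(session.dataset.specs)
    result = select(
        session.dataset, prefs, session.k, restrict_to_front=session.restrict_to_front
    )
    result.index = len(session.history) + 1
    result.timestamp = datetime.now(timezone.utc).isoformat()
    session.history.append(result)
    return result


def finish(session: Session, chosen_id: str) -> Session:
    """Close the session by prescribing one of the latest shown therapies.

    The final choice must come from the compromises displayed in the most
    recent iteration (group II members included — a decision-maker may
    knowingly accept a range violation).
    """
    if session.state == "finished":
        raise SessionError("session already finished")
    latest = session.latest
    shown = {c.record.id for c in latest.selection}
    if chosen_id not in shown:
        raise SessionError(
            f"chosen id {chosen_id!r} was not among the latest shown "
            f"compromises {sorted(shown)}"
        )
    session.chosen = chosen_id
    session.state = "finished"
    return session


# ---------------------------------------------------------------------------
# Scripted decision-maker
# ---------------------------------------------------------------------------

@dataclass
class DecisionMakerPolicy:
    """Scripted preferences plus stop and choice rules for automated runs."""

    preferences: Sequence[PreferenceSet]
    stop_rule: Callable[[IterationResult], bool]
    choice_rule: Callable[[IterationResult], str]

    def __post_init__(self) -> None:
        if not self.preferences:
            raise ValueError("policy needs at least one preference set")


def stop_when_group_i_at_least(n: int) -> Callable[[IterationResult], bool]:
    """Stop once at least ``n`` of the shown compromises meet every range."""
    return lambda result: len(result.group_i) >= n


def choose_best(
    objective_key: str, direction: str = "maximize"
) -> Callable[[IterationResult], str]:
    """Choose the shown alternative with the best value on one objective
    (ties broken by record id)."""
    sign = -1.0 if direction == "maximize" else 1.0

    def rule(result: IterationResult) -> str:
        ranked = sorted(
            result.selection,
            key=lambda c: (sign * c.record.objectives[objective_key], c.record.id),
        )
        return ranked[0].record.id

    return rule


def simulated_dm(policy: DecisionMakerPolicy, session: Session) -> Session:
    """Replay a scripted decision-maker through the interactive loop.

    Runs the policy's preference sets in order; after each iteration the
    stop rule decides whether to prescribe (via the choice rule) or revise.
    Raises :class:`PolicyExhaustedError` if the script runs out before the
    stop rule fires.
    """
    for prefs in policy.preferences:
        result = run_iteration(session, prefs)
        if policy.stop_rule(result):
            finish(session, policy.choice_rule(result))
            return session
    raise PolicyExhaustedError(
        f"stop rule never fired within {len(policy.preferences)} scripted iterations"
    )


# ---------------------------------------------------------------------------
# Logging and replay
# ---------------------------------------------------------------------------

def dataset_digest(altset: AlternativeSet) -> str:
    """SHA-256 of the canonical CSV serialization — identifies the dataset
    a session log belongs to."""
    buf = io.StringIO()
    write_alternatives(altset, buf)
    return hashlib.sha256(buf.getvalue().encode("utf-8")).hexdigest()


def export_log(session: Session, path) -> None:
    """Write a JSON-lines transcript: one header object, then one object
    per iteration (preferences, selection with groups and scores, and the
    ideal/nadir snapshot)."""
    header = {
        "type": "header",
        "dataset_digest": dataset_digest(session.dataset),
        "n_records": len(session.dataset),
        "k": session.k,
        "restrict_to_front": session.restrict_to_front,
        "state": session.state,
        "chosen": session.chosen,
    }
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps(header) + "\n")
        for result in session.history:
            line = {"type": "iteration", **result.to_json()}
            fh.write(json.dumps(line) + "\n")


def replay(log_path, dataset: AlternativeSet, verify: bool = True) -> Session:
    """Re-run a logged session against a dataset.

    With ``verify=True`` (default) every re-computed selection is compared
    id-for-id and group-for-group with the log; any difference — including
    a dataset digest mismatch — raises :class:`ReplayError`.
    """
    with open(log_path, encoding="utf-8") as fh:
        lines = [json.loads(line) for line in fh if line.strip()]
    if not lines or lines[0].get("type") != "header":
        raise ReplayError("log has no header line")
    header, iterations = lines[0], lines[1:]

    if verify and header["dataset_digest"] != dataset_digest(dataset):
        raise ReplayError("dataset digest does not match the log header")

    session = Session(
        dataset=dataset,
        k=int(header["k"]),
        restrict_to_front=bool(header.get("restrict_to_front", True)),
    )
    for entry in iterations:
        prefs = PreferenceSet.from_json(entry["prefs"])
        result = run_iteration(session, prefs)
        if verify:
            got = [(c.record.id, c.group) for c in result.selection]
            want = [(c["id"], c["group"]) for c in entry["selection"]]
            if got != want:
                raise ReplayError(
                    f"iteration {entry['index']}: selection mismatch "
                    f"(replayed {got}, logged {want})"
                )
    if header.get("state") == "finished" and header.get("chosen"):
        finish(session, header["chosen"])
    return session
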