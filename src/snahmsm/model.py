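"""Ten-state arthroplasty multi-state model: state paths and long-format data.

The shipped model follows a cohort of patients from their first recorded
arthroplasty — a unilateral total hip — through up to two further procedures
and death:

====  =============================================  =========
state  label                                          kind
====  =============================================  =========
1     1st arthroplasty hip                            initial
2     Revision of 1st arthroplasty                    transient
3     2nd arthroplasty hip                            transient
4     2nd arthroplasty knee                           transient
5     2nd arthroplasty hip / revision of 1st hip      transient
6     2nd arthroplasty knee / revision of 1st hip     transient
7     Revision of 2nd arthroplasty hip                transient
8     Revision of 2nd arthroplasty knee               transient
9     Revision of 1st or 2nd arthroplasty             transient
10    Dead                                            absorbing
====  =============================================  =========

Allowed moves: 1→{2,3,4,10}, 2→{5,6,10}, 3→{5,7,10}, 4→{6,8,10},
5..8→{9,10}, 9→{10}.  The graph is acyclic, so a path never revisits a
state.  Patients are right-censored at a fixed administrative date after
their last event if death has not occurred.  Events the model does not
represent (a third arthroplasty, a re-revision beyond state 9) truncate the
path: follow-up is censored at the date of the unrepresentable event.

Analysis-ready data are produced in the long ("counting-process") format
used by multi-state packages such as R's mstate: one row per patient, per
visited transient state, per allowed outgoing transition, with entry/exit
times on the time-since-first-arthroplasty scale, the sojourn duration
(clock-reset scale), and a status flag marking the transition that actually
happened.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .snah import SnahHistory, history_from_records, validate_history

__all__ = [
    "StateModelSpec",
    "PatientRecord",
    "ArthroEvent",
    "StatePath",
    "EligibilityError",
    "InconsistentRecordError",
    "DEFAULT_MODEL",
    "default_model",
    "load_model_spec",
    "dump_model_spec",
    "assign_state_path",
    "to_transition_rows",
    "transition_count_table",
    "read_event_table",
    "write_event_table",
    "records_from_event_table",
]

DAYS_PER_YEAR = 365.25

AGE_GROUPS = ("55-64", "65-74", "75-84")


class EligibilityError(ValueError):
    """Record does not satisfy the cohort-entry rule (first event = hip primary)."""


class InconsistentRecordError(ValueError):
    """Internally contradictory record, e.g. an arthroplasty after death."""


@dataclass(frozen=True)
class StateModelSpec:
    """Structure of a multi-state model: states, allowed moves, entry rule."""

    states: tuple[tuple[int, str], ...]
    transitions: frozenset[tuple[int, int]]
    absorbing: frozenset[int]
    initial_state: int
    eligibility: str = "first arthroplasty is a primary total hip"

    def __post_init__(self) -> None:
        ids = {s for s, _ in self.states}
        for q, r in self.transitions:
            if q not in ids or r not in ids:
                raise ValueError(f"transition {q}->{r} uses unknown state")
            if q in self.absorbing:
                raise ValueError(f"absorbing state {q} has outgoing transition")
            if r == self.initial_state:
                raise ValueError("initial state cannot be entered")

    @property
    def state_ids(self) -> tuple[int, ...]:
        return tuple(s for s, _ in self.states)

    @property
    def labels(self) -> dict[int, str]:
        return dict(self.states)

    def targets(self, state: int) -> tuple[int, ...]:
        """Allowed destinations out of ``state``, in ascending order."""
        return tuple(sorted(r for q, r in self.transitions if q == state))

    def is_transient(self, state: int) -> bool:
        return state not in self.absorbing


def default_model() -> StateModelSpec:
    """The shipped 10-state hip-first model."""
    states = (
        (1, "1st arthroplasty hip"),
        (2, "Revision of 1st arthroplasty"),
        (3, "2nd arthroplasty hip"),
        (4, "2nd arthroplasty knee"),
        (5, "2nd arthroplasty hip / revision of 1st hip"),
        (6, "2nd arthroplasty knee / revision of 1st hip"),
        (7, "Revision of 2nd arthroplasty hip"),
        (8, "Revision of 2nd arthroplasty knee"),
        (9, "Revision of 1st or 2nd arthroplasty"),
        (10, "Dead"),
    )
    transitions = frozenset(
        [(1, 2), (1, 3), (1, 4), (1, 10),
         (2, 5), (2, 6), (2, 10),
         (3, 5), (3, 7), (3, 10),
         (4, 6), (4, 8), (4, 10),
         (5, 9), (5, 10), (6, 9), (6, 10),
         (7, 9), (7, 10), (8, 9), (8, 10),
         (9, 10)]
    )
    return StateModelSpec(
        states=states,
        transitions=transitions,
        absorbing=frozenset({10}),
        initial_state=1,
    )


DEFAULT_MODEL = default_model()


def load_model_spec(path) -> StateModelSpec:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return StateModelSpec(
        states=tuple((int(s["id"]), str(s["label"])) for s in doc["states"]),
        transitions=frozenset((int(q), int(r)) for q, r in doc["transitions"]),
        absorbing=frozenset(int(s) for s in doc["absorbing"]),
        initial_state=int(doc["initial_state"]),
        eligibility=str(doc.get("eligibility", "")),
    )


def dump_model_spec(spec: StateModelSpec, path) -> None:
    doc = {
        "states": [{"id": s, "label": lab} for s, lab in spec.states],
        "transitions": sorted([list(t) for t in spec.transitions]),
        "absorbing": sorted(spec.absorbing),
        "initial_state": spec.initial_state,
        "eligibility": spec.eligibility,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass(frozen=True)
class ArthroEvent:
    joint: str  # "hip" | "knee"
    side: str  # "right" | "left"
    kind: str  # "primary" | "revision"
    date: _dt.date


@dataclass(frozen=True)
class PatientRecord:
    """One registry patient: covariates, dated procedures, death/censoring."""

    patient_id: str
    sex: str  # "M" | "F"
    age_at_entry: float  # years at first arthroplasty
    events: tuple[ArthroEvent, ...]
    censor_date: _dt.date
    death_date: _dt.date | None = None

    @property
    def age_group(self) -> str:
        a = self.age_at_entry
        if a < 65:
            return AGE_GROUPS[0]
        if a < 75:
            return AGE_GROUPS[1]
        return AGE_GROUPS[2]

    @property
    def entry_date(self) -> _dt.date:
        return min(e.date for e in self.events)

    def snah_history(self) -> SnahHistory:
        return history_from_records(
            [(e.joint, e.side, e.kind, e.date) for e in self.events]
        )


@dataclass(frozen=True)
class StatePath:
    """States visited with entry times (days since first arthroplasty)."""

    patient_id: str
    states: tuple[tuple[int, float], ...]  # (state id, entry day)
    end_time: float  # day of absorption or censoring
    absorbed: bool  # True if the path ends in an absorbing state

    @property
    def censored(self) -> bool:
        return not self.absorbed


def _hip_first_next_state(
    current: int,
    event: ArthroEvent,
    first_js: tuple[str, str],
    second_js: tuple[str, str] | None,
) -> int | None:
    """State reached from ``current`` when ``event`` occurs, or None if the
    event is outside the model (path is then censored at the event date).

    ``first_js``/``second_js`` identify which joint+side were the first and
    second arthroplasties, needed to tell a revision of the 1st from a
    revision of the 2nd.
    """
    js = (event.joint, event.side)
    if event.kind == "primary":
        if current == 1:
            return 3 if event.joint == "hip" else 4
        if current == 2:
            return 5 if event.joint == "hip" else 6
        return None  # third arthroplasty: not represented
    # revision
    if js == first_js:
        which = 1
    elif second_js is not None and js == second_js:
        which = 2
    else:
        return None
    if current == 1:
        return 2 if which == 1 else None
    if current == 3:
        return 5 if which == 1 else 7
    if current == 4:
        return 6 if which == 1 else 8
    if current in (5, 6, 7, 8):
        return 9  # any further revision of 1st or 2nd arthroplasty
    return None  # re-revision from 2 or 9: not represented


def assign_state_path(
    record: PatientRecord, spec: StateModelSpec = DEFAULT_MODEL
) -> StatePath:
    """Map a patient's dated events to their path through the state model.

    The path starts in the initial state on the day of the first
    arthroplasty (day 0).  Each later procedure moves the patient along an
    allowed arrow; a procedure the model cannot represent censors follow-up
    at its date.  Death (on or before the administrative censoring date)
    absorbs the path; otherwise the patient is censored at the
    administrative date.
    """
    if not record.events:
        raise EligibilityError(f"{record.patient_id}: no arthroplasty events")
    events = sorted(record.events, key=lambda e: (e.date, 0 if e.kind == "primary" else 1))
    first = events[0]
    if not (first.kind == "primary" and first.joint == "hip"):
        raise EligibilityError(
            f"{record.patient_id}: cohort entry requires a primary hip as first "
            f"event, got {first.kind} {first.joint}"
        )
    report = validate_history(record.snah_history())
    if not report.ok:
        raise InconsistentRecordError(
            f"{record.patient_id}: event history invalid: "
            + "; ".join(str(v) for v in report.violations)
        )
    origin = first.date
    last_event_date = events[-1].date
    if record.death_date is not None and record.death_date < last_event_date:
        raise InconsistentRecordError(
            f"{record.patient_id}: death date {record.death_date} precedes an "
            f"arthroplasty on {last_event_date}"
        )

    def day(d: _dt.date) -> float:
        return float((d - origin).days)

    first_js = (first.joint, first.side)
    second_js: tuple[str, str] | None = None
    path: list[tuple[int, float]] = [(spec.initial_state, 0.0)]
    current = spec.initial_state
    truncated_at: float | None = None

    for ev in events[1:]:
        if ev.kind == "primary" and second_js is None:
            second_js_candidate = (ev.joint, ev.side)
        else:
            second_js_candidate = second_js
        nxt = _hip_first_next_state(current, ev, first_js, second_js)
        if nxt is None or (current, nxt) not in spec.transitions:
            truncated_at = day(ev.date)
            break
        path.append((nxt, day(ev.date)))
        current = nxt
        second_js = second_js_candidate

    if truncated_at is not None:
        return StatePath(record.patient_id, tuple(path), truncated_at, absorbed=False)

    died = (
        record.death_date is not None and record.death_date <= record.censor_date
    )
    if died:
        t_death = day(record.death_date)
        dead_state = 10
        if (current, dead_state) in spec.transitions:
            path.append((dead_state, t_death))
            return StatePath(record.patient_id, tuple(path), t_death, absorbed=True)
        return StatePath(record.patient_id, tuple(path), t_death, absorbed=False)
    return StatePath(
        record.patient_id, tuple(path), day(record.censor_date), absorbed=False
    )


#: long-format column order (mstate-compatible semantics)
ROW_COLUMNS = [
    "id", "from", "to", "Tstart", "Tstop", "duration",
    "status", "sex", "age", "age_group",
]


def to_transition_rows(
    cohort: Iterable[PatientRecord], spec: StateModelSpec = DEFAULT_MODEL
) -> pd.DataFrame:
    """Long-format transition data for a cohort.

    For each visited transient state, one row per allowed outgoing
    transition; the realized transition (if any) has ``status = 1``, the
    rest 0.  ``Tstart``/``Tstop`` are days since the first arthroplasty;
    ``duration = Tstop - Tstart`` is the clock-reset time at risk.  A
    same-day state change would give a zero-length sojourn, which no
    risk-set based estimator can use, so ``Tstop`` is nudged by +0.5 day.
    """
    recs: list[tuple] = []
    for record in cohort:
        path = assign_state_path(record, spec)
        sex01 = 1 if record.sex == "M" else 0
        age = record.age_at_entry
        grp = record.age_group
        states = path.states
        for k, (state, t_in) in enumerate(states):
            if not spec.is_transient(state):
                continue
            if k + 1 < len(states):
                next_state, t_out = states[k + 1]
            else:
                next_state, t_out = None, path.end_time
            if t_out <= t_in:
                t_out = t_in + 0.5  # same-day tie adjustment
            dur = t_out - t_in
            for dest in spec.targets(state):
                recs.append(
                    (record.patient_id, state, dest, t_in, t_out, dur,
                     1 if dest == next_state else 0, sex01, age, grp)
                )
    df = pd.DataFrame(recs, columns=ROW_COLUMNS)
    return df


def transition_count_table(
    rows: pd.DataFrame, spec: StateModelSpec = DEFAULT_MODEL
) -> pd.DataFrame:
    """Counts and row-percentages of events by origin state.

    One row per transient state: how many patients entered it, how many
    moved to each destination, how many had no further event (censored
    there), and the corresponding integer percentages of the number
    entering.
    """
    out = {}
    for state in spec.state_ids:
        if not spec.is_transient(state):
            continue
        sub = rows[rows["from"] == state]
        if sub.empty:
            continue
        # one visit per (id, Tstart); each visit emits len(targets) rows
        n_targets = len(spec.targets(state))
        entering = len(sub) // n_targets
        dest_counts = {
            r: int(((sub["to"] == r) & (sub["status"] == 1)).sum())
            for r in spec.targets(state)
        }
        moved = sum(dest_counts.values())
        row = {"entering": entering, "no_further_event": entering - moved}
        row.update({f"to_{r}": c for r, c in dest_counts.items()})
        for r, c in dest_counts.items():
            row[f"pct_to_{r}"] = int(round(100.0 * c / entering))
        row["pct_no_further_event"] = int(
            round(100.0 * (entering - moved) / entering)
        )
        out[state] = row
    table = pd.DataFrame.from_dict(out, orient="index")
    table.index.name = "from"
    count_cols = [c for c in table.columns if c.startswith("to_")]
    table[count_cols] = table[count_cols].fillna(0).astype(int)
    pct_cols = [c for c in table.columns if c.startswith("pct_")]
    table[pct_cols] = table[pct_cols].astype("Int64")  # NA = not a target
    return table


# ---------------------------------------------------------------------------
# Event-table I/O (delimited text)

EVENT_COLUMNS = ["patient_id", "joint", "side", "event_type", "date"]


def write_event_table(cohort: Iterable[PatientRecord], path) -> None:
    """Write a cohort as the canonical CSV pair of tables in one file:
    per-event rows plus per-patient metadata columns repeated on each row."""
    rows = []
    for rec in cohort:
        for ev in sorted(rec.events, key=lambda e: e.date):
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "joint": ev.joint,
                    "side": ev.side,
                    "event_type": ev.kind,
                    "date": ev.date.isoformat(),
                    "sex": rec.sex,
                    "age_at_entry": rec.age_at_entry,
                    "death_date": rec.death_date.isoformat() if rec.death_date else "",
                    "censor_date": rec.censor_date.isoformat(),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_event_table(path) -> list[PatientRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return records_from_event_table(df)


def records_from_event_table(df: pd.DataFrame) -> list[PatientRecord]:
    """Build PatientRecords from an event table with the canonical columns."""
    records = []
    for pid, grp in df.groupby("patient_id", sort=False):
        events = tuple(
            ArthroEvent(
                joint=str(r.joint),
                side=str(r.side),
                kind=str(r.event_type),
                date=_dt.date.fromisoformat(str(r.date)),
            )
            for r in grp.itertuples()
        )
        meta = grp.iloc[0]
        death = str(meta.get("death_date", "") or "")
        records.append(
            PatientRecord(
                patient_id=str(pid),
                sex=str(meta["sex"]),
                age_at_entry=float(meta["age_at_entry"]),
                events=events,
                censor_date=_dt.date.fromisoformat(str(meta["censor_date"])),
                death_date=_dt.date.fromisoformat(death) if death else None,
            )
        )
    return records
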