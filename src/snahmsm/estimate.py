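"""Nonparametric transition-hazard and state-occupation estimation.

Cumulative transition hazards are estimated by the Nelson-Aalen estimator:
at each observed time of a q→r transition the hazard increments by
``d_qr(t) / n_q(t)``, the number of q→r transitions at t over the number of
patients occupying state q just before t.

State occupation probabilities — the estimated proportion of the cohort in
each state at time t since the first arthroplasty — come from the
Aalen-Johansen estimator, the product integral of the increment matrices:

    P(0, t) = prod_{u <= t} (I + dA(u)),

where ``dA(u)`` has off-diagonal entries ``d_qr(u)/n_q(u)`` and diagonal
entries making each row of ``I + dA(u)`` sum to one.  In the two-state
alive→dead reduction this is exactly 1 − Kaplan-Meier; in the competing-risks
reduction it is the classical cumulative-incidence-function estimator.  The
estimator is consistent for state occupation probabilities even when the
process is semi-Markov, provided censoring is independent of the states
occupied, so it is computed here on the clock-forward scale (time since
first arthroplasty) regardless of the time scale used for regression.

Ties between a transition and a censoring at the same time are resolved
events-first: the censored patients are still in the risk set at that time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import DEFAULT_MODEL, StateModelSpec

__all__ = [
    "CumulativeHazard",
    "OccupationProbabilityPath",
    "nelson_aalen",
    "aalen_johansen",
    "occupation_by_group",
    "visits_from_rows",
    "cumulative_hazards_frame",
]


@dataclass(frozen=True)
class CumulativeHazard:
    """Right-continuous nondecreasing step function A(t) for one transition."""

    transition: tuple[int, int]
    times: np.ndarray  # sorted distinct event times
    n_events: np.ndarray  # d(t) at each time
    n_at_risk: np.ndarray  # n(t-) at each time
    increments: np.ndarray  # d/n
    cumulative: np.ndarray  # cumsum of increments

    def at(self, t: float) -> float:
        """A(t), right-continuous."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.cumulative[idx])


@dataclass(frozen=True)
class OccupationProbabilityPath:
    """Matrix-valued step function P(0, t) over the state space."""

    state_ids: tuple[int, ...]
    times: np.ndarray  # includes t = 0 first
    matrices: np.ndarray  # shape (len(times), S, S); matrices[0] = I

    def at(self, t: float) -> np.ndarray:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return self.matrices[max(idx, 0)]

    def occupation(self, initial_state: int | None = None) -> pd.DataFrame:
        """Occupation probabilities over time for one starting state."""
        if initial_state is None:
            initial_state = self.state_ids[0]
        i = self.state_ids.index(initial_state)
        df = pd.DataFrame(
            self.matrices[:, i, :], columns=list(self.state_ids)
        )
        df.insert(0, "time", self.times)
        return df


def visits_from_rows(rows: pd.DataFrame) -> pd.DataFrame:
    """Collapse long-format rows to one row per state visit.

    The long format carries one row per allowed outgoing transition of each
    visit; they share (id, from, Tstart, Tstop) and differ only in the
    candidate destination.  For risk-set counting we need each visit once,
    with its realized destination (or none).
    """
    realized = rows[rows["status"] == 1][["id", "from", "Tstart", "to"]]
    visits = rows.drop_duplicates(["id", "from", "Tstart"])[
        ["id", "from", "Tstart", "Tstop"]
    ].merge(realized, on=["id", "from", "Tstart"], how="left")
    return visits


def nelson_aalen(
    rows: pd.DataFrame,
    transition: tuple[int, int],
    timescale: str = "clock_forward",
) -> CumulativeHazard:
    """Nelson-Aalen cumulative hazard for one transition.

    ``timescale="clock_forward"`` uses (Tstart, Tstop] at-risk intervals on
    time since first arthroplasty; ``"clock_reset"`` uses (0, duration] on
    time since entry into the origin state.
    """
    q, r = transition
    sub = rows[(rows["from"] == q) & (rows["to"] == r)]
    if timescale == "clock_forward":
        entry = sub["Tstart"].to_numpy(float)
        exit_ = sub["Tstop"].to_numpy(float)
    elif timescale == "clock_reset":
        entry = np.zeros(len(sub))
        exit_ = sub["duration"].to_numpy(float)
    else:
        raise ValueError(f"unknown timescale {timescale!r}")
    status = sub["status"].to_numpy(int)

    event_times = np.unique(exit_[status == 1])
    if event_times.size == 0:
        z = np.array([])
        return CumulativeHazard((q, r), z, z, z, z, z)
    entry_sorted = np.sort(entry)
    exit_sorted = np.sort(exit_)
    # n(t-) = #{entry < t} - #{exit < t}; rows with exit == t (event or
    # censoring) are still at risk at t (events-first convention)
    n_at_risk = (
        np.searchsorted(entry_sorted, event_times, side="left")
        - np.searchsorted(exit_sorted, event_times, side="left")
    ).astype(float)
    order = np.argsort(exit_)
    d = np.zeros_like(event_times)
    ev_exit = exit_[status == 1]
    for i, t in enumerate(event_times):
        d[i] = np.sum(ev_exit == t)
    assert np.all(n_at_risk >= d), "risk set smaller than event count"
    increments = d / n_at_risk
    return CumulativeHazard(
        (q, r), event_times, d, n_at_risk, increments, np.cumsum(increments)
    )


def aalen_johansen(
    rows: pd.DataFrame, spec: StateModelSpec = DEFAULT_MODEL
) -> OccupationProbabilityPath:
    """Aalen-Johansen transition-probability matrices P(0, t).

    Clock-forward time scale.  Each factor I + dA(u) is row-stochastic, so
    every P(0, t) row sums to one and absorbing-state columns are
    nondecreasing.
    """
    state_ids = spec.state_ids
    idx = {s: i for i, s in enumerate(state_ids)}
    S = len(state_ids)

    visits = visits_from_rows(rows)
    entry = visits["Tstart"].to_numpy(float)
    exit_ = visits["Tstop"].to_numpy(float)
    from_state = visits["from"].to_numpy()
    to_state = visits["to"].to_numpy()  # NaN where censored
    moved = ~pd.isna(to_state)

    event_times = np.unique(exit_[moved])
    times = np.concatenate([[0.0], event_times])
    mats = np.empty((len(times), S, S))
    mats[0] = np.eye(S)

    # per-origin-state sorted entry/exit arrays for O(log n) risk counts
    per_state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for q in state_ids:
        mask = from_state == q
        per_state[q] = (np.sort(entry[mask]), np.sort(exit_[mask]))

    # group realized transitions by exit time
    ev = pd.DataFrame(
        {
            "t": exit_[moved],
            "q": from_state[moved],
            "r": to_state[moved].astype(int),
        }
    )
    counts = ev.groupby(["t", "q", "r"]).size()

    P = np.eye(S)
    time_to_row = {t: k for k, t in enumerate(event_times)}
    factor = np.eye(S)
    current_t = None
    k = 1
    for (t, q, r), d in counts.items():
        if current_t is None:
            current_t, factor = t, np.eye(S)
        if t != current_t:
            P = P @ factor
            mats[k] = P
            k += 1
            current_t, factor = t, np.eye(S)
        ent_s, ex_s = per_state[q]
        n_q = np.searchsorted(ent_s, t, side="left") - np.searchsorted(
            ex_s, t, side="left"
        )
        if n_q < d:
            raise ValueError(
                f"more {q}->{r} transitions ({d}) than patients at risk "
                f"({n_q}) at t={t}: inconsistent data"
            )
        iq, ir = idx[q], idx[r]
        factor[iq, ir] += d / n_q
        factor[iq, iq] -= d / n_q
    if current_t is not None:
        P = P @ factor
        mats[k] = P
        k += 1
    assert k == len(times)
    return OccupationProbabilityPath(state_ids, times, mats)


def occupation_by_group(
    rows: pd.DataFrame,
    spec: StateModelSpec = DEFAULT_MODEL,
    grouping: str = "age_group",
    combine: tuple[int, ...] = (5, 6, 7, 8, 9),
    combined_label: str = "other",
) -> pd.DataFrame:
    """Tidy per-group state occupation probabilities from the initial state.

    Runs the Aalen-Johansen estimator within each subgroup.  States with few
    occupants (by default 5-9, the beyond-second-event states) are reported
    combined under one label; remaining states keep their ids as labels.
    Returns a tidy frame (time, group, state, probability).
    """
    frames = []
    for g, sub in rows.groupby(grouping):
        if sub.empty or not (sub["status"] == 1).any():
            warnings.warn(f"group {g!r} has no observed transitions; omitted")
            continue
        path = aalen_johansen(sub, spec)
        occ = path.occupation(spec.initial_state)
        tidy = {"time": occ["time"]}
        for s in spec.state_ids:
            if s not in combine:
                tidy[str(s)] = occ[s]
        if combine:
            present = [s for s in combine if s in occ.columns]
            tidy[combined_label] = occ[present].sum(axis=1)
        f = pd.DataFrame(tidy).melt(
            id_vars="time", var_name="state", value_name="probability"
        )
        f.insert(1, "group", g)
        frames.append(f)
    if not frames:
        return pd.DataFrame(columns=["time", "group", "state", "probability"])
    return pd.concat(frames, ignore_index=True)


def cumulative_hazards_frame(
    rows: pd.DataFrame,
    spec: StateModelSpec = DEFAULT_MODEL,
    timescale: str = "clock_forward",
) -> pd.DataFrame:
    """All transitions' Nelson-Aalen estimates as one tidy frame."""
    frames = []
    for q, r in sorted(spec.transitions):
        ch = nelson_aalen(rows, (q, r), timescale)
        if ch.times.size == 0:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "time": ch.times,
                    "from": q,
                    "to": r,
                    "n_events": ch.n_events,
                    "n_at_risk": ch.n_at_risk,
                    "increment": ch.increments,
                    "cumulative": ch.cumulative,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["time", "from", "to", "n_events", "n_at_risk",
                     "increment", "cumulative"]
        )
    return pd.concat(frames, ignore_index=True)
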