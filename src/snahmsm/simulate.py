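"""Synthetic arthroplasty-registry cohorts with semi-Markov dynamics.

The simulator emulates a registry cohort of unilateral first-THA patients
aged 55-84: patients accrue uniformly over a calendar window (default
2002-01-01 to 2008-12-31), carry sex and entry-age covariates, and then move
through the 10-state model by a clock-reset (semi-Markov) mechanism.  On
entering each transient state, one latent sojourn time per allowed outgoing
transition is drawn from its cause-specific hazard — exponential by default,
optionally Weibull — multiplied by exp(covariate effects); the earliest
latent clock wins.  For independent cause-specific hazards this latent-clocks
construction is distributionally identical to sampling the total exit hazard
and then the destination.  Follow-up is administratively censored at a fixed
calendar date (default 2008-12-31).

Each winning transition is emitted as a dated registry event (the
contralateral hip for a second hip arthroplasty, a random side for a knee,
revisions of whichever prosthesis the destination state implies), so that a
simulated cohort round-trips through the SNAH codec and the state-path
assignment and lands back in the states it was generated from.

Baseline rates (events per person-year) default to magnitudes that make a
seven-year run resemble a hip-first registry cohort: roughly 12% of patients
acquiring a contralateral hip, 4% a knee, 2% a first-hip revision and 5%
dying out of the initial state, with correspondingly sparse later states.
Default sex effects (male vs female) are of the magnitude reported for such
cohorts — males slower to a second arthroplasty, faster to death — and an
age gradient acts on mortality.

Randomness is reproducible: every patient has an independent substream
derived from ``(seed, patient index)``, so the same configuration produces
byte-identical cohorts regardless of generation order.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np

from .model import DAYS_PER_YEAR, ArthroEvent, PatientRecord
from .snah import write_snah_lines

__all__ = [
    "SimulationConfig",
    "DEFAULT_BASELINE_RATES",
    "DEFAULT_SEX_LOGHR",
    "DEFAULT_AGE_LOGHR",
    "simulate_cohort",
    "emit_snah",
    "cohort_from_transition_counts",
]

#: baseline cause-specific rates, events per person-year, by transition
DEFAULT_BASELINE_RATES: dict[tuple[int, int], float] = {
    (1, 2): 0.006, (1, 3): 0.037, (1, 4): 0.012, (1, 10): 0.016,
    (2, 5): 0.028, (2, 6): 0.019, (2, 10): 0.033,
    (3, 5): 0.004, (3, 7): 0.009, (3, 10): 0.015,
    (4, 6): 0.004, (4, 8): 0.009, (4, 10): 0.015,
    (5, 9): 0.013, (5, 10): 0.018,
    (6, 9): 0.006, (6, 10): 0.015,
    (7, 9): 0.010, (7, 10): 0.024,
    (8, 9): 0.010, (8, 10): 0.024,
    (9, 10): 0.030,
}

#: log hazard ratios, male vs female, per transition (0 where omitted)
DEFAULT_SEX_LOGHR: dict[tuple[int, int], float] = {
    (1, 2): math.log(1.04), (1, 3): math.log(0.86),
    (1, 4): math.log(0.78), (1, 10): math.log(1.59),
    (2, 5): math.log(1.33), (2, 6): math.log(0.72), (2, 10): math.log(1.15),
    (3, 5): math.log(0.74), (3, 7): math.log(1.18), (3, 10): math.log(1.71),
    (4, 6): math.log(1.52), (4, 8): math.log(1.78), (4, 10): math.log(1.64),
}

#: log hazard ratios per year of age (centred at 70), per transition
DEFAULT_AGE_LOGHR: dict[tuple[int, int], float] = {
    (1, 3): -0.02, (1, 4): -0.02, (1, 10): 0.085,
    (2, 10): 0.085, (3, 10): 0.085, (4, 10): 0.085,
    (5, 10): 0.085, (6, 10): 0.085, (7, 10): 0.085, (8, 10): 0.085,
    (9, 10): 0.085,
}

AGE_CENTER = 70.0

#: which registry event a transition emits: (joint, which-prosthesis, kind)
#: "first"/"second" pick the joint+side of the 1st/2nd arthroplasty;
#: "contra_hip" is a new primary hip on the opposite side; "new_knee" a new
#: primary knee (random side); None emits no arthroplasty event (death)
_TRANSITION_EVENT: dict[tuple[int, int], tuple[str, str] | None] = {
    (1, 2): ("first", "revision"),
    (1, 3): ("contra_hip", "primary"),
    (1, 4): ("new_knee", "primary"),
    (2, 5): ("contra_hip", "primary"),
    (2, 6): ("new_knee", "primary"),
    (3, 5): ("first", "revision"),
    (3, 7): ("second", "revision"),
    (4, 6): ("first", "revision"),
    (4, 8): ("second", "revision"),
    (5, 9): ("second", "revision"),
    (6, 9): ("second", "revision"),
    (7, 9): ("first", "revision"),
    (8, 9): ("first", "revision"),
    (9, 10): None,
}

# number of uniforms pre-drawn per patient; a shipped-model path needs at most:
# 4 covariate/entry draws + 2 side draws + 4 visits x 4 latent clocks
_DRAWS_PER_PATIENT = 26


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 10_000
    seed: int = 0
    accrual_start: _dt.date = _dt.date(2002, 1, 1)
    accrual_end: _dt.date = _dt.date(2008, 12, 31)
    censor_date: _dt.date = _dt.date(2008, 12, 31)
    male_prop: float = 0.45
    #: probability of entry age falling in 55-64 / 65-74 / 75-84
    age_group_probs: tuple[float, float, float] = (0.27, 0.41, 0.32)
    hazard_family: str = "exponential"  # or "weibull"
    weibull_shape: float = 1.0
    baseline_rates: dict[tuple[int, int], float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_RATES)
    )
    sex_loghr: dict[tuple[int, int], float] = field(
        default_factory=lambda: dict(DEFAULT_SEX_LOGHR)
    )
    age_loghr: dict[tuple[int, int], float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_LOGHR)
    )

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if self.accrual_start >= self.censor_date:
            raise ValueError("accrual must start before the censoring date")
        if self.accrual_end < self.accrual_start:
            raise ValueError("accrual window is empty")
        if not 0.0 <= self.male_prop <= 1.0:
            raise ValueError("male_prop must be a probability")
        if abs(sum(self.age_group_probs) - 1.0) > 1e-9:
            raise ValueError("age_group_probs must sum to 1")
        if any(v < 0 for v in self.baseline_rates.values()):
            raise ValueError("hazard rates must be nonnegative")
        if self.hazard_family not in ("exponential", "weibull"):
            raise ValueError(f"unknown hazard family {self.hazard_family!r}")

    def with_(self, **kwargs) -> "SimulationConfig":
        return _dc_replace(self, **kwargs)


_AGE_BOUNDS = ((55.0, 65.0), (65.0, 75.0), (75.0, 85.0))


def _sojourn_days(u: float, rate: float, mult: float, family: str, shape: float) -> float:
    """Invert the sojourn survivor function at u; returns days (inf if rate 0)."""
    if rate <= 0.0:
        return math.inf
    e = -math.log1p(-u)  # unit exponential; u in [0, 1) keeps it finite
    if family == "exponential" or shape == 1.0:
        t_years = e / (rate * mult)
    else:
        # Weibull with proportional-hazards multiplier on the rate scale:
        # H(t) = mult * (rate * t)^shape
        t_years = (e / mult) ** (1.0 / shape) / rate
    return t_years * DAYS_PER_YEAR


def _simulate_patient(index: int, config: SimulationConfig) -> PatientRecord:
    rng = np.random.default_rng((config.seed, index))
    u = rng.random(_DRAWS_PER_PATIENT)
    ptr = 0

    def draw() -> float:
        nonlocal ptr
        v = u[ptr]
        ptr += 1
        return v

    # covariates and entry
    accrual_days = (config.accrual_end - config.accrual_start).days
    entry = config.accrual_start + _dt.timedelta(days=int(draw() * (accrual_days + 1)))
    sex = "M" if draw() < config.male_prop else "F"
    g = draw()
    cum = np.cumsum(config.age_group_probs)
    group = int(np.searchsorted(cum, g, side="right"))
    group = min(group, 2)
    lo, hi = _AGE_BOUNDS[group]
    age = lo + draw() * (hi - lo)

    first_side = "right" if draw() < 0.5 else "left"
    knee_side = "right" if draw() < 0.5 else "left"
    first_js = ("hip", first_side)
    contra_js = ("hip", "left" if first_side == "right" else "right")
    knee_js = ("knee", knee_side)

    events: list[ArthroEvent] = [
        ArthroEvent("hip", first_side, "primary", entry)
    ]
    second_js: tuple[str, str] | None = None

    horizon = float((config.censor_date - entry).days)
    cov_mult = {}

    def multiplier(tr: tuple[int, int]) -> float:
        if tr not in cov_mult:
            lhr = 0.0
            if sex == "M":
                lhr += config.sex_loghr.get(tr, 0.0)
            lhr += config.age_loghr.get(tr, 0.0) * (age - AGE_CENTER)
            cov_mult[tr] = math.exp(lhr)
        return cov_mult[tr]

    targets = {
        1: (2, 3, 4, 10), 2: (5, 6, 10), 3: (5, 7, 10), 4: (6, 8, 10),
        5: (9, 10), 6: (9, 10), 7: (9, 10), 8: (9, 10), 9: (10,),
    }

    state = 1
    t_now = 0.0  # days since entry
    death_date: _dt.date | None = None
    while True:
        best_t, best_r = math.inf, None
        for r in targets[state]:
            tr = (state, r)
            soj = _sojourn_days(
                draw(), config.baseline_rates.get(tr, 0.0), multiplier(tr),
                config.hazard_family, config.weibull_shape,
            )
            if soj < best_t:
                best_t, best_r = soj, r
        t_next = t_now + best_t
        if best_r is None or t_next > horizon:
            break  # administratively censored in the current state
        t_now = t_next
        when = entry + _dt.timedelta(days=int(round(t_now)))
        if best_r == 10:
            death_date = when
            break
        spec = _TRANSITION_EVENT[(state, best_r)]
        which, kind = spec
        if which == "first":
            joint, side = first_js
        elif which == "second":
            joint, side = second_js  # set when the 2nd arthroplasty happened
        elif which == "contra_hip":
            joint, side = contra_js
        else:  # new_knee
            joint, side = knee_js
        events.append(ArthroEvent(joint, side, kind, when))
        if kind == "primary":
            second_js = (joint, side)
        state = best_r
        if state == 9:
            # only death remains; loop once more for the 9 -> 10 clock
            continue

    return PatientRecord(
        patient_id=f"P{index:06d}",
        sex=sex,
        age_at_entry=age,
        events=tuple(events),
        censor_date=config.censor_date,
        death_date=death_date,
    )


def simulate_cohort(config: SimulationConfig) -> list[PatientRecord]:
    """Generate a cohort; deterministic for a fixed config (incl. seed)."""
    return [_simulate_patient(i, config) for i in range(config.n_patients)]


def cohort_from_transition_counts(
    branching: dict[int, dict[int | None, int]],
    entry_date: _dt.date = _dt.date(2002, 1, 1),
    censor_date: _dt.date = _dt.date(2008, 12, 31),
    gap_days: int = 200,
) -> list[PatientRecord]:
    """Deterministic cohort realizing specified per-state transition counts.

    ``branching[q]`` maps each destination state to the number of patients
    who move there from ``q``, with key ``None`` counting patients who stop
    in ``q`` (no further event, administratively censored).  States absent
    from ``branching`` retain everyone who enters them.  The per-state
    outflows must sum to the inflow.  Useful for reproducing published
    count/percentage tables exactly and for worked examples.

    Events are spaced ``gap_days`` apart starting at ``entry_date``; sides
    are fixed (first hip left, second hip right, knee right), which pins
    down the emitted SNAH histories.
    """
    paths: list[tuple[tuple[int, ...], int]] = []

    def expand(path: tuple[int, ...], n: int) -> None:
        state = path[-1]
        b = branching.get(state)
        if b is None or state == 10:
            paths.append((path, n))
            return
        total = sum(b.values())
        if total != n:
            raise ValueError(
                f"outflow from state {state} sums to {total}, but {n} enter"
            )
        stop = b.get(None, 0)
        if stop:
            paths.append((path, stop))
        for dest, cnt in b.items():
            if dest is None or cnt == 0:
                continue
            expand(path + (dest,), cnt)

    n_initial = sum(branching[1].values())
    expand((1,), n_initial)

    first_js = ("hip", "left")
    contra_js = ("hip", "right")
    knee_js = ("knee", "right")
    cohort: list[PatientRecord] = []
    serial = 0
    for path, count in paths:
        # one prototype event list per path, replicated `count` times
        events = [ArthroEvent("hip", "left", "primary", entry_date)]
        death: _dt.date | None = None
        second_js: tuple[str, str] | None = None
        for k, (q, r) in enumerate(zip(path, path[1:]), start=1):
            when = entry_date + _dt.timedelta(days=k * gap_days)
            if r == 10:
                death = when
                continue
            which, kind = _TRANSITION_EVENT[(q, r)]
            if which == "first":
                joint, side = first_js
            elif which == "second":
                joint, side = second_js
            elif which == "contra_hip":
                joint, side = contra_js
            else:
                joint, side = knee_js
            events.append(ArthroEvent(joint, side, kind, when))
            if kind == "primary":
                second_js = (joint, side)
        for _ in range(count):
            cohort.append(
                PatientRecord(
                    patient_id=f"C{serial:06d}",
                    sex="F",
                    age_at_entry=70.0,
                    events=tuple(events),
                    censor_date=censor_date,
                    death_date=death,
                )
            )
            serial += 1
    return cohort


def emit_snah(cohort, path=None) -> list[str]:
    """SNAH history lines (``id<TAB>history``) for a simulated cohort."""
    histories = [rec.snah_history() for rec in cohort]
    ids = [rec.patient_id for rec in cohort]
    if path is not None:
        write_snah_lines(path, histories, ids=ids)
    from .snah import format_history

    return [f"{pid}\t{format_history(h)}" for pid, h in zip(ids, histories)]
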