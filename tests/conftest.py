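"""Shared fixtures and generators for the test suite.

All fixture data is generated programmatically; small cohorts are built by
hand where an example needs exact dates, larger ones come from the
simulator with fixed seeds.
"""

from __future__ import annotations

import datetime as dt
import random

import pytest
from hypothesis import HealthCheck, settings

from snahmsm.model import ArthroEvent, PatientRecord
from snahmsm.snah import SnahHistory, append_event

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

CENSOR = dt.date(2008, 12, 31)
D0 = dt.date(2002, 1, 1)


def day(n: int) -> dt.date:
    """Calendar date n days after the reference cohort entry date."""
    return D0 + dt.timedelta(days=n)


def patient(
    pid: str,
    events: list[tuple[str, str, str, int]],
    sex: str = "F",
    age: float = 70.0,
    death_day: int | None = None,
    censor: dt.date = CENSOR,
) -> PatientRecord:
    """Compact patient builder: events as (joint, side, kind, day-offset)."""
    return PatientRecord(
        patient_id=pid,
        sex=sex,
        age_at_entry=age,
        events=tuple(
            ArthroEvent(j, s, k, day(d)) for j, s, k, d in events
        ),
        censor_date=censor,
        death_date=day(death_day) if death_day is not None else None,
    )


def random_valid_history(rng: random.Random, max_len: int = 6) -> SnahHistory:
    """A structurally valid history built by a random legal-move walk."""
    h = SnahHistory()
    length = rng.randint(1, max_len)
    joints = [("hip", "right"), ("hip", "left"), ("knee", "right"), ("knee", "left")]
    for _ in range(length):
        primaries = {e.joint_side for e in h if e.is_primary}
        moves = [(j, s, False) for j, s in joints if (j, s) not in primaries]
        moves += [(j, s, True) for j, s in primaries]
        j, s, rev = rng.choice(moves)
        h = append_event(h, j, s, is_revision=rev)
    return h


@pytest.fixture
def make_patient():
    return patient


@pytest.fixture
def rng():
    return random.Random(20140604)
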