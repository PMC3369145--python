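"""Summary Notation for Arthroplasty Histories (SNAH): parse, validate, construct.

A patient's arthroplasty history is an alphanumeric string of 4-character
elements ``JSnm`` separated by a delimiter (usually ``/``):

* ``J`` — anatomical location of the arthroplasty (``H`` hip, ``K`` knee),
* ``S`` — side (``R`` right, ``L`` left),
* ``n`` — cumulative number of arthroplasties for the patient to date,
* ``m`` — cumulative number of revisions of this joint+side to date
  (``0`` for a primary procedure).

``HR10`` is a first-ever arthroplasty, a primary right hip; ``HR21`` says the
patient's second arthroplasty was the first revision of the right hip.
Elements concatenate in time order, e.g. ``KR10/KL20/HR30/KL41/KL52/`` —
primary right knee, primary left knee, primary right hip, then two successive
revisions of the left knee.  Because ``n`` encodes the time sequence, an
unordered bag of elements can be re-assembled into the original history.

The codec is deliberately strict: the shipped grammar covers hips and knees
with single-digit counters (histories of ten or more procedures are outside
it), which is sufficient for joint-registry cohorts over study-length
follow-up.  The joint alphabet and separator are configurable for other
dialects.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "JOINTS",
    "SIDES",
    "SnahElement",
    "SnahHistory",
    "SnahParseError",
    "SnahValidationError",
    "Violation",
    "ValidationReport",
    "parse_element",
    "format_element",
    "parse_history",
    "format_history",
    "validate_history",
    "reconstruct_order",
    "append_event",
    "history_from_records",
    "read_snah_lines",
    "write_snah_lines",
]

#: canonical joint-letter -> name map of the shipped grammar
JOINTS = {"H": "hip", "K": "knee"}
SIDES = {"R": "right", "L": "left"}

_JOINT_CODE = {v: k for k, v in JOINTS.items()}
_SIDE_CODE = {v: k for k, v in SIDES.items()}


class SnahParseError(ValueError):
    """Raised when a SNAH element or history string cannot be decoded."""


class SnahValidationError(ValueError):
    """Raised when a structurally impossible history is constructed."""


@dataclass(frozen=True, order=True)
class SnahElement:
    """One arthroplasty event: joint, side, cumulative counters ``n`` and ``m``."""

    seq_n: int  # cumulative number of arthroplasties to date (>= 1)
    joint: str  # "hip" | "knee" (or a configured extension)
    side: str  # "right" | "left"
    rev_m: int = 0  # cumulative revisions of this joint+side (0 = primary)

    def __post_init__(self) -> None:
        if self.seq_n < 1:
            raise SnahValidationError(f"seq_n must be >= 1, got {self.seq_n}")
        if self.rev_m < 0:
            raise SnahValidationError(f"rev_m must be >= 0, got {self.rev_m}")
        if self.rev_m >= self.seq_n:
            raise SnahValidationError(
                f"rev_m ({self.rev_m}) must be < seq_n ({self.seq_n}): a joint "
                "cannot have more revisions than the patient has arthroplasties"
            )

    @property
    def is_primary(self) -> bool:
        return self.rev_m == 0

    @property
    def is_revision(self) -> bool:
        return self.rev_m > 0

    @property
    def joint_side(self) -> tuple[str, str]:
        return (self.joint, self.side)

    def code(self, joints: dict[str, str] = JOINTS) -> str:
        """4-character canonical code, e.g. ``HR21``."""
        inv = {v: k for k, v in joints.items()}
        if self.joint not in inv:
            raise SnahValidationError(f"joint {self.joint!r} not in grammar alphabet")
        if self.seq_n > 9 or self.rev_m > 9:
            raise SnahValidationError(
                "shipped grammar uses single-digit counters; "
                f"cannot format n={self.seq_n}, m={self.rev_m}"
            )
        return f"{inv[self.joint]}{_SIDE_CODE[self.side]}{self.seq_n}{self.rev_m}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.code()


@dataclass(frozen=True)
class SnahHistory:
    """An ordered sequence of SNAH elements for one patient."""

    elements: tuple[SnahElement, ...] = ()
    separator: str = "/"

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", tuple(self.elements))
        if len(self.separator) != 1:
            raise SnahValidationError("separator must be a single character")

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    def __getitem__(self, i):
        return self.elements[i]

    def __str__(self) -> str:
        return format_history(self)


@dataclass(frozen=True)
class Violation:
    """One validation failure: which rule, at which element (0-based)."""

    rule: str
    index: int
    message: str

    def __str__(self) -> str:  # pragma: no cover
        return f"element {self.index}: [{self.rule}] {self.message}"


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    violations: tuple[Violation, ...] = ()

    def __bool__(self) -> bool:
        return self.ok


def parse_element(text: str, joints: dict[str, str] = JOINTS) -> SnahElement:
    """Decode a single 4-character SNAH code such as ``HR10``.

    Parsing is case-insensitive; the inverse of :meth:`SnahElement.code`.
    """
    code = text.strip().upper()
    if len(code) != 4:
        raise SnahParseError(f"SNAH element must be 4 characters, got {text!r}")
    j, s, n, m = code
    if j not in joints:
        raise SnahParseError(f"unknown joint letter {j!r} at position 0 in {text!r}")
    if s not in SIDES:
        raise SnahParseError(f"unknown side letter {s!r} at position 1 in {text!r}")
    if not n.isdigit():
        raise SnahParseError(f"non-digit {n!r} at position 2 (seq_n) in {text!r}")
    if not m.isdigit():
        raise SnahParseError(f"non-digit {m!r} at position 3 (rev_m) in {text!r}")
    seq_n, rev_m = int(n), int(m)
    if seq_n < 1:
        raise SnahParseError(f"seq_n must be >= 1 at position 2 in {text!r}")
    if rev_m >= seq_n:
        raise SnahParseError(
            f"rev_m ({rev_m}) >= seq_n ({seq_n}) at position 3 in {text!r}"
        )
    return SnahElement(seq_n=seq_n, joint=joints[j], side=SIDES[s], rev_m=rev_m)


def format_element(element: SnahElement, joints: dict[str, str] = JOINTS) -> str:
    return element.code(joints)


def parse_history(
    text: str, separator: str = "/", joints: dict[str, str] = JOINTS
) -> SnahHistory:
    """Parse a SNAH history string into its elements, in string order.

    A trailing separator is tolerated (the canonical printed form ends with
    one); surrounding whitespace is trimmed.  No sequence validation is
    applied here — use :func:`validate_history` for that — so corrupted or
    partial histories remain inspectable.
    """
    stripped = text.strip()
    if not stripped:
        return SnahHistory((), separator)
    parts = stripped.split(separator)
    if parts and parts[-1] == "":
        parts = parts[:-1]
    elements = []
    for i, part in enumerate(parts):
        try:
            elements.append(parse_element(part, joints))
        except SnahParseError as exc:
            raise SnahParseError(f"element {i} of history {text!r}: {exc}") from exc
    return SnahHistory(tuple(elements), separator)


def format_history(history: SnahHistory, joints: dict[str, str] = JOINTS) -> str:
    """Render a history as text; non-empty histories end with the separator."""
    if not history.elements:
        return ""
    sep = history.separator
    return sep.join(e.code(joints) for e in history.elements) + sep


def _scan(elements: Sequence[SnahElement]):
    """Replay a history, yielding (index, element, violations-at-index).

    Maintains per-(joint, side) counters of primaries and revisions, the
    ground-truth bookkeeping the counters in the notation summarize.
    """
    primaries: set[tuple[str, str]] = set()
    revisions: dict[tuple[str, str], int] = {}
    for i, el in enumerate(elements):
        problems: list[Violation] = []
        if el.seq_n != i + 1:
            problems.append(
                Violation(
                    "sequence",
                    i,
                    f"seq_n is {el.seq_n}, expected {i + 1}: 'n' must count "
                    "events 1, 2, ... in time order",
                )
            )
        js = el.joint_side
        if el.is_primary:
            if js in primaries:
                problems.append(
                    Violation(
                        "duplicate-primary",
                        i,
                        f"second primary of {el.joint} {el.side}: a joint+side "
                        "gets one primary; later procedures are revisions",
                    )
                )
            primaries.add(js)
        else:
            if js not in primaries:
                problems.append(
                    Violation(
                        "revision-without-primary",
                        i,
                        f"revision of never-replaced {el.joint} {el.side}",
                    )
                )
            expected_m = revisions.get(js, 0) + 1
            if el.rev_m != expected_m:
                problems.append(
                    Violation(
                        "revision-count",
                        i,
                        f"rev_m is {el.rev_m}, expected {expected_m} "
                        f"(cumulative revisions of {el.joint} {el.side})",
                    )
                )
            revisions[js] = revisions.get(js, 0) + 1
        yield i, el, problems


def validate_history(history: SnahHistory | Sequence[SnahElement]) -> ValidationReport:
    """Check the sequence invariants of a history; violations are data, not errors."""
    elements = history.elements if isinstance(history, SnahHistory) else tuple(history)
    violations: list[Violation] = []
    for _, _, problems in _scan(elements):
        violations.extend(problems)
    return ValidationReport(ok=not violations, violations=tuple(violations))


def reconstruct_order(
    elements: Iterable[SnahElement], separator: str = "/"
) -> SnahHistory:
    """Rebuild the time-ordered history from an unordered bag of elements.

    The ``n`` counter carries the sequence, so corruption of element order is
    recoverable as long as all elements survive.  Duplicate or missing ``n``
    values, and reconstructions that fail validation, are errors.
    """
    els = sorted(elements, key=lambda e: e.seq_n)
    if not els:
        raise SnahValidationError("cannot reconstruct an empty element set")
    seen = [e.seq_n for e in els]
    for k in range(1, len(els) + 1):
        count = seen.count(k)
        if count > 1:
            raise SnahValidationError(f"duplicate seq_n={k}: order is ambiguous")
        if count == 0:
            raise SnahValidationError(f"missing seq_n={k}: history has a gap")
    history = SnahHistory(tuple(els), separator)
    report = validate_history(history)
    if not report.ok:
        raise SnahValidationError(
            "reconstructed history is invalid: "
            + "; ".join(str(v) for v in report.violations)
        )
    return history


def append_event(
    history: SnahHistory, joint: str, side: str, is_revision: bool = False
) -> SnahHistory:
    """Append a new arthroplasty to a valid history, updating the counters.

    A primary gets ``m = 0``; a revision gets one more than the prior revision
    count of that joint+side.  A second primary of an already-replaced
    joint+side and a revision of a never-replaced one are rejected.
    """
    if joint not in _JOINT_CODE and joint not in JOINTS.values():
        raise SnahValidationError(f"unknown joint {joint!r}")
    if side not in _SIDE_CODE:
        raise SnahValidationError(f"unknown side {side!r}")
    js = (joint, side)
    primaries = {e.joint_side for e in history if e.is_primary}
    n_revisions = sum(1 for e in history if e.is_revision and e.joint_side == js)
    if is_revision:
        if js not in primaries:
            raise SnahValidationError(
                f"cannot record a revision of never-replaced {joint} {side}"
            )
        rev_m = n_revisions + 1
    else:
        if js in primaries:
            raise SnahValidationError(
                f"{joint} {side} already has a primary; record a revision instead"
            )
        rev_m = 0
    new = SnahElement(seq_n=len(history) + 1, joint=joint, side=side, rev_m=rev_m)
    return replace(history, elements=history.elements + (new,))


# deterministic same-day ordering: primaries before revisions, hips before
# knees, right before left — reproducible encoding of simultaneous procedures
_TIE_JOINT = {"hip": 0, "knee": 1}
_TIE_SIDE = {"right": 0, "left": 1}


def history_from_records(
    events: Iterable[tuple[str, str, str, _dt.date]], separator: str = "/"
) -> SnahHistory:
    """Encode dated registry records as a SNAH history.

    ``events`` are ``(joint, side, event_type, date)`` tuples with
    ``event_type`` in ``{"primary", "revision"}``.  Records are sorted by
    date (ties broken deterministically) and folded through
    :func:`append_event`, so the result always validates.
    """
    recs = list(events)
    if not recs:
        raise SnahValidationError("no events to encode")
    for joint, side, kind, date in recs:
        if kind not in ("primary", "revision"):
            raise SnahValidationError(f"event_type must be primary|revision, got {kind!r}")
    recs.sort(key=lambda r: (r[3], 0 if r[2] == "primary" else 1,
                             _TIE_JOINT.get(r[0], 9), _TIE_SIDE.get(r[1], 9)))
    history = SnahHistory((), separator)
    for joint, side, kind, date in recs:
        try:
            history = append_event(history, joint, side, is_revision=(kind == "revision"))
        except SnahValidationError as exc:
            raise SnahValidationError(f"record dated {date}: {exc}") from exc
    return history


def read_snah_lines(path, separator: str = "/") -> list[tuple[str | None, SnahHistory]]:
    """Read a SNAH text file: one history per line, optionally ``id<TAB>history``."""
    out: list[tuple[str | None, SnahHistory]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if "\t" in line:
                pid, text = line.split("\t", 1)
                out.append((pid, parse_history(text, separator)))
            else:
                out.append((None, parse_history(line, separator)))
    return out


def write_snah_lines(path, histories, ids=None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if ids is None:
            for h in histories:
                fh.write(format_history(h) + "\n")
        else:
            for pid, h in zip(ids, histories):
                fh.write(f"{pid}\t{format_history(h)}\n")
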