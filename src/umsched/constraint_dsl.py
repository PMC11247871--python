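"""Symbolic medication-time constraint language.

Prescribing instructions like "take 1 h before a meal or 2 h after a meal"
are encoded in a compact symbolic notation: an anchor letter names a
patient-profile reference time (``C`` any meal, ``ZC`` breakfast, ``ZHC``
lunch, ``WC`` dinner, ``S`` sleep), a leading ``-`` means *before* the
anchor (after is the default), a number gives the offset in hours on a
0.25 h grid, ``~`` joins the two ends of an offset range, and ``;``
separates alternative instructions ("or").  Two degenerate forms exist:
the literal ``prn`` (as-needed dosing, never scheduled) and a bare number
(a duration constant such as the 0.5 h default meal length).

This module parses the notation into an AST (:class:`TimeConstraintExpr`),
renders it back canonically, and resolves it against a patient's anchor
times (:class:`AnchorSet`) into absolute clock-time windows on the 0.25 h
day grid.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

GRID = 0.25  #: scheduling resolution, hours


class Anchor(enum.Enum):
    """Reference times a symbolic constraint can attach to."""

    MEAL_GENERIC = "C"
    BREAKFAST = "ZC"
    LUNCH = "ZHC"
    DINNER = "WC"
    SLEEP = "S"


class Sign(enum.Enum):
    BEFORE = "-"
    AFTER = "+"


class Meal(enum.Enum):
    """Concrete meal instance a generic meal anchor can bind to."""

    BREAKFAST = "breakfast"
    LUNCH = "lunch"
    DINNER = "dinner"


class ParseError(ValueError):
    """Malformed constraint text; carries the offending token and position."""

    def __init__(self, message: str, token: str = "", pos: int = -1):
        self.token = token
        self.pos = pos
        if token:
            message = f"{message}: {token!r} at position {pos}"
        super().__init__(message)


def _on_grid(x: float) -> bool:
    return abs(x / GRID - round(x / GRID)) < 1e-9


def snap(x: float) -> float:
    """Snap a time/duration to the 0.25 h grid (nearest)."""
    return round(x / GRID) * GRID


@dataclass(frozen=True)
class AnchorSet:
    """A patient's daily anchor times, 24-h clock, hours.

    Defaults are the system conventions: breakfast 07:00, lunch 12:00,
    dinner 18:00, sleep 22:00, meals lasting 30 minutes.
    """

    breakfast_start: float = 7.0
    lunch_start: float = 12.0
    dinner_start: float = 18.0
    sleep_time: float = 22.0
    meal_duration: float = 0.5

    def __post_init__(self):
        for name in ("breakfast_start", "lunch_start", "dinner_start", "sleep_time"):
            v = getattr(self, name)
            if not (0 <= v < 24):
                raise ValueError(f"{name}={v} outside [0, 24)")
            if not _on_grid(v):
                raise ValueError(f"{name}={v} not a multiple of {GRID} h")
        if self.meal_duration <= 0 or not _on_grid(self.meal_duration):
            raise ValueError(f"meal_duration={self.meal_duration} must be a positive multiple of {GRID} h")
        if not self.breakfast_start < self.lunch_start < self.dinner_start:
            raise ValueError("meal times must be ordered breakfast < lunch < dinner")

    def meal_start(self, meal: Meal) -> float:
        return {
            Meal.BREAKFAST: self.breakfast_start,
            Meal.LUNCH: self.lunch_start,
            Meal.DINNER: self.dinner_start,
        }[meal]

    def shifted(self, delta: float) -> "AnchorSet":
        """All anchors shifted by ``delta`` hours (must stay in-day)."""
        return AnchorSet(
            self.breakfast_start + delta,
            self.lunch_start + delta,
            self.dinner_start + delta,
            self.sleep_time + delta,
            self.meal_duration,
        )


@dataclass(frozen=True)
class ConstraintAtom:
    """One anchored offset (or offset range), e.g. ``-S0.25~-S0.5``.

    ``anchor is None`` marks a bare duration literal (the dining-time row
    of the symbol table); it has no schedulable window.
    """

    anchor: Anchor | None
    sign: Sign = Sign.AFTER
    offset_lo: float = 0.0
    offset_hi: float = 0.0

    def __post_init__(self):
        if self.offset_lo < 0 or self.offset_hi < self.offset_lo:
            raise ValueError(f"offsets must satisfy 0 <= lo <= hi, got {self.offset_lo}, {self.offset_hi}")
        for off in (self.offset_lo, self.offset_hi):
            if not _on_grid(off):
                raise ValueError(f"offset {off} not a multiple of {GRID} h")

    @property
    def is_point(self) -> bool:
        return self.offset_lo == self.offset_hi

    @property
    def is_duration_literal(self) -> bool:
        return self.anchor is None


@dataclass(frozen=True)
class TimeConstraintExpr:
    """Disjunction of constraint atoms, or the prn marker."""

    alternatives: tuple[ConstraintAtom, ...] = ()
    prn: bool = False

    def __post_init__(self):
        if self.prn and self.alternatives:
            raise ValueError("prn expression cannot carry alternatives")
        if not self.prn and not self.alternatives:
            raise ValueError("non-prn expression needs at least one alternative")


@dataclass(frozen=True)
class TimeWindow:
    """Absolute clock-time window [start, end] on the 0.25 h grid."""

    start: float
    end: float

    def __post_init__(self):
        if not (0 <= self.start <= self.end < 24):
            raise ValueError(f"window [{self.start}, {self.end}] not within the day")
        if not (_on_grid(self.start) and _on_grid(self.end)):
            raise ValueError(f"window [{self.start}, {self.end}] off the {GRID} h grid")

    def contains(self, t: float) -> bool:
        return self.start - 1e-9 <= t <= self.end + 1e-9

    def grid_times(self) -> list[float]:
        n = int(round((self.end - self.start) / GRID))
        return [snap(self.start + i * GRID) for i in range(n + 1)]


# Longest anchor letters first so "ZHC" wins over "ZC".
_ANCHOR_LETTERS = sorted((a.value for a in Anchor), key=len, reverse=True)
_ATOM_RE = re.compile(
    r"(?P<sign>[-+]?)(?P<anchor>" + "|".join(_ANCHOR_LETTERS) + r")?(?P<num>\d+(?:\.\d+)?)?"
)


def _parse_half(text: str, base_pos: int) -> ConstraintAtom:
    """Parse one side of a ``~`` range into a single-offset atom."""
    s = text.strip()
    pos = base_pos + (len(text) - len(text.lstrip()))
    m = _ATOM_RE.fullmatch(s)
    if not m or (m.group("anchor") is None and m.group("num") is None):
        raise ParseError("unrecognised constraint atom", s, pos)
    sign = Sign.BEFORE if m.group("sign") == "-" else Sign.AFTER
    anchor = Anchor(m.group("anchor")) if m.group("anchor") else None
    if anchor is None and m.group("sign"):
        raise ParseError("sign without anchor letter", s, pos)
    off = float(m.group("num")) if m.group("num") is not None else 0.0
    if not _on_grid(off):
        raise ParseError(f"offset not a multiple of {GRID} h", m.group("num"), pos)
    return ConstraintAtom(anchor=anchor, sign=sign, offset_lo=off, offset_hi=off)


def _parse_alternative(text: str, base_pos: int) -> ConstraintAtom:
    parts = text.split("~")
    if len(parts) == 1:
        return _parse_half(parts[0], base_pos)
    if len(parts) != 2:
        raise ParseError("more than one '~' in a range", text.strip(), base_pos)
    lo_pos = base_pos
    hi_pos = base_pos + len(parts[0]) + 1
    a = _parse_half(parts[0], lo_pos)
    b = _parse_half(parts[1], hi_pos)
    if a.anchor is not b.anchor or a.sign is not b.sign:
        raise ParseError("range ends must share anchor and sign", text.strip(), base_pos)
    if a.is_duration_literal:
        raise ParseError("duration literal cannot form a range", text.strip(), base_pos)
    lo, hi = a.offset_lo, b.offset_lo
    if lo > hi:
        lo, hi = hi, lo  # "-S0.25~-S0.5" is printed lower magnitude first
    return ConstraintAtom(anchor=a.anchor, sign=a.sign, offset_lo=lo, offset_hi=hi)


def parse_time_expr(text: str) -> TimeConstraintExpr:
    """Parse a symbolic constraint string into a :class:`TimeConstraintExpr`.

    Grammar (case-sensitive): ``[-]ANCHOR NUMBER [~ [-]ANCHOR NUMBER]``,
    alternatives joined by ``;``; the literal ``prn``; or a bare number
    (duration constant).  A missing number means offset 0.

    Raises :class:`ParseError` naming the offending token and position.
    """
    if not isinstance(text, str) or not text.strip():
        raise ParseError("empty constraint text")
    s = text.strip()
    if s == "prn":
        return TimeConstraintExpr(prn=True)
    alts: list[ConstraintAtom] = []
    pos = 0
    for chunk in s.split(";"):
        if not chunk.strip():
            raise ParseError("empty alternative", ";", pos)
        alts.append(_parse_alternative(chunk, pos))
        pos += len(chunk) + 1
    return TimeConstraintExpr(alternatives=tuple(alts))


def _fmt_num(x: float) -> str:
    return f"{x:g}"


def _render_atom(a: ConstraintAtom) -> str:
    if a.is_duration_literal:
        return _fmt_num(a.offset_lo)
    sign = "-" if a.sign is Sign.BEFORE else ""
    lo = f"{sign}{a.anchor.value}{_fmt_num(a.offset_lo)}"
    if a.is_point:
        return lo
    return f"{lo}~{sign}{a.anchor.value}{_fmt_num(a.offset_hi)}"


def render_time_expr(expr: TimeConstraintExpr) -> str:
    """Canonical string form: no spaces, explicit offsets, lower bound first.

    ``parse_time_expr(render_time_expr(e))`` structurally equals ``e``.
    """
    if expr.prn:
        return "prn"
    return ";".join(_render_atom(a) for a in expr.alternatives)


def resolve_atom(atom: ConstraintAtom, anchors: AnchorSet, meal: Meal | None = None) -> TimeWindow:
    """Resolve one atom to an absolute window.

    BEFORE offsets subtract from the anchor's *start*; AFTER offsets add to
    the anchor's *end* (meal end = start + meal_duration, sleep has zero
    duration).  The zero-offset AFTER atom on a meal anchor denotes the
    with-meal window [meal_start, meal_start + meal_duration].  Windows
    poking out of the day are clipped; a fully out-of-day window is an
    error.
    """
    if atom.is_duration_literal:
        raise ValueError("duration literal has no schedulable window")
    if atom.anchor is Anchor.SLEEP:
        start = end = anchors.sleep_time
    else:
        if atom.anchor is Anchor.MEAL_GENERIC:
            if meal is None:
                raise ValueError("generic meal anchor needs a concrete meal to bind to")
            start = anchors.meal_start(meal)
        else:
            start = anchors.meal_start(
                {Anchor.BREAKFAST: Meal.BREAKFAST, Anchor.LUNCH: Meal.LUNCH, Anchor.DINNER: Meal.DINNER}[atom.anchor]
            )
        end = start + anchors.meal_duration

    if atom.sign is Sign.BEFORE:
        lo, hi = start - atom.offset_hi, start - atom.offset_lo
    elif atom.offset_lo == atom.offset_hi == 0.0 and atom.anchor is not Anchor.SLEEP:
        lo, hi = start, end  # with-meal window
    else:
        lo, hi = end + atom.offset_lo, end + atom.offset_hi

    # clip to the day grid [0, 24 - GRID]
    lo_c, hi_c = max(lo, 0.0), min(hi, 24.0 - GRID)
    if lo_c > hi_c:
        raise ValueError(f"resolved window [{lo}, {hi}] lies entirely outside the day")
    return TimeWindow(snap(lo_c), snap(hi_c))


def resolve_windows(
    expr: TimeConstraintExpr, anchors: AnchorSet, meal: Meal | None = None
) -> list[TimeWindow]:
    """Resolve every alternative of ``expr`` to an absolute window.

    ``meal`` names the concrete meal a generic meal anchor binds to; atoms
    with a specific anchor ignore it.  prn expressions have no windows and
    raise.
    """
    if expr.prn:
        raise ValueError("prn has no schedulable window")
    return [resolve_atom(a, anchors, meal) for a in expr.alternatives]


#: The 13 symbol-table rows: (symbol, meaning) — used by tests and docs.
SYMBOL_TABLE_ROWS: tuple[tuple[str, str], ...] = (
    ("-C1;C2", "fasting: 1 h before a meal or 2 h after a meal"),
    ("C0", "with meals"),
    ("-C0.5", "half an hour before meals"),
    ("-C3", "3 h before meals"),
    ("C0.5~C1", "30 min to 1 h after meals"),
    ("C3", "3 h after meals"),
    ("-S0.25~-S0.5", "15-30 min before bedtime"),
    ("0.5", "dining time: meals last 30 min"),
    ("ZC0", "breakfast (default 07:00)"),
    ("ZHC0", "lunch (default 12:00)"),
    ("WC0", "dinner (default 18:00)"),
    ("S", "sleep (default 22:00)"),
    ("prn", "as needed"),
)
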