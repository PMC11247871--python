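"""Universal Medication Schedule (UMS) projection and reminder export.

The UMS describes a regimen with four standardized times of day —
morning, noon, evening, bedtime — which patients find far easier to follow
than per-drug clock times.  Slot boundaries are derived from the patient's
own anchors so the view stays meaningful for unusual routines:

* MORNING  = [wake, breakfast + 3 h)
* NOON     = [breakfast + 3 h, dinner - 2 h)
* EVENING  = [dinner - 2 h, sleep - 1 h)
* BEDTIME  = [sleep - 1 h, sleep]

Boundaries are clamped to be monotone, so the four slots always partition
[wake, sleep]; doses outside the waking span are flagged as unslotted.

Reminders are exported as RFC 5545 iCalendar text (one VEVENT per timed
dose, floating local times, plus one VTODO per as-needed product) and as a
JSON mirror.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass, field
from pathlib import Path

from .interaction_check import PatientProfile
from .knowledge_base import KnowledgeBase
from .scheduler import Schedule, fmt_time


class Slot(enum.Enum):
    MORNING = "morning"
    NOON = "noon"
    EVENING = "evening"
    BEDTIME = "bedtime"


@dataclass
class UMSView:
    slots: dict[Slot, list[tuple[str, float]]]
    unslotted: list[tuple[str, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            **{s.value: [{"product_id": p, "time": fmt_time(t)} for p, t in self.slots[s]] for s in Slot},
            "unslotted": [{"product_id": p, "time": fmt_time(t)} for p, t in self.unslotted],
        }


def slot_boundaries(profile: PatientProfile) -> list[tuple[Slot, float, float]]:
    """Monotone slot boundaries [start, end) over the waking span."""
    a = profile.anchors
    wake, sleep = profile.wake, profile.sleep
    b1 = min(max(wake, a.breakfast_start + 3.0), sleep)
    b2 = min(max(b1, a.dinner_start - 2.0), sleep)
    b3 = min(max(b2, sleep - 1.0), sleep)
    return [
        (Slot.MORNING, wake, b1),
        (Slot.NOON, b1, b2),
        (Slot.EVENING, b2, b3),
        (Slot.BEDTIME, b3, sleep),
    ]


def to_ums(schedule: Schedule, profile: PatientProfile) -> UMSView:
    """Project a feasible schedule onto the four UMS slots.

    Every scheduled dose lands in exactly one slot, or in ``unslotted``
    when it falls outside [wake, sleep] (e.g. a night-time
    chronopharmacology window).
    """
    bounds = slot_boundaries(profile)
    view = UMSView(slots={s: [] for s in Slot})
    for (pid, _idx), t in sorted(schedule.assignments.items(), key=lambda kv: (kv[1], kv[0])):
        placed = False
        for slot, lo, hi in bounds:
            # the last slot is end-inclusive so the sleep time itself belongs to BEDTIME
            if lo <= t < hi or (slot is Slot.BEDTIME and t == hi):
                view.slots[slot].append((pid, t))
                placed = True
                break
        if not placed:
            view.unslotted.append((pid, t))
    return view


@dataclass(frozen=True)
class ReminderEvent:
    product_id: str
    date: _dt.date
    time: float | None  # None for as-needed products
    label: str
    action_required: bool = True


def to_reminders(schedule: Schedule, kb: KnowledgeBase, date: _dt.date) -> list[ReminderEvent]:
    """One timed reminder per scheduled dose, plus an untimed entry per
    as-needed (prn) product."""
    events = []
    for (pid, idx), t in sorted(schedule.assignments.items()):
        name = kb.products[pid].name if pid in kb.products else pid
        events.append(
            ReminderEvent(pid, date, t, f"Take {name} (dose {idx + 1}) at {fmt_time(t)}")
        )
    for pid in sorted(schedule.prn_products):
        name = kb.products[pid].name if pid in kb.products else pid
        events.append(
            ReminderEvent(pid, date, None, f"{name}: take as needed (prn)", action_required=False)
        )
    return events


def _ics_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace(";", "\\;").replace(",", "\\,").replace("\n", "\\n")


def render_ics(events: list[ReminderEvent]) -> str:
    """RFC 5545 calendar text: timed doses as VEVENTs with floating local
    DTSTART, prn products as VTODOs."""
    lines = [
        "BEGIN:VCALENDAR",
        "VERSION:2.0",
        "PRODID:-//umsched//medication reminders//EN",
    ]
    for i, ev in enumerate(events):
        day = ev.date.strftime("%Y%m%d")
        if ev.time is not None:
            hh = int(ev.time)
            mm = int(round((ev.time - hh) * 60))
            lines += [
                "BEGIN:VEVENT",
                f"UID:umsched-{day}-{i}@local",
                f"DTSTART:{day}T{hh:02d}{mm:02d}00",
                f"SUMMARY:{_ics_escape(ev.label)}",
                f"DESCRIPTION:{_ics_escape(ev.product_id)}",
                "END:VEVENT",
            ]
        else:
            lines += [
                "BEGIN:VTODO",
                f"UID:umsched-{day}-{i}@local",
                f"SUMMARY:{_ics_escape(ev.label)}",
                f"DESCRIPTION:{_ics_escape(ev.product_id)}",
                "END:VTODO",
            ]
    lines.append("END:VCALENDAR")
    return "\r\n".join(lines) + "\r\n"


def export_ics(events: list[ReminderEvent], path: str | Path) -> None:
    Path(path).write_text(render_ics(events), encoding="utf-8")


def reminders_to_json(events: list[ReminderEvent]) -> list[dict]:
    return [
        {
            "product_id": ev.product_id,
            "date": ev.date.isoformat(),
            "time": None if ev.time is None else fmt_time(ev.time),
            "label": ev.label,
            "action_required": ev.action_required,
        }
        for ev in events
    ]


def timeline_text(schedule: Schedule, kb: KnowledgeBase, profile: PatientProfile) -> str:
    """Plain-text daily timeline grouped by UMS slot."""
    view = to_ums(schedule, profile)
    out = []
    for slot in Slot:
        out.append(slot.value.upper())
        for pid, t in view.slots[slot]:
            name = kb.products[pid].name if pid in kb.products else pid
            out.append(f"  {fmt_time(t)}  {name}")
        if not view.slots[slot]:
            out.append("  -")
    if view.unslotted:
        out.append("OUTSIDE WAKING HOURS")
        for pid, t in view.unslotted:
            name = kb.products[pid].name if pid in kb.products else pid
            out.append(f"  {fmt_time(t)}  {name}")
    if schedule.prn_products:
        out.append("AS NEEDED")
        for pid in sorted(schedule.prn_products):
            name = kb.products[pid].name if pid in kb.products else pid
            out.append(f"  {name} (prn)")
    return "\n".join(out) + "\n"
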