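"""Prescription-level drug-drug interaction screening.

Prescriptions name pharmaceutical *products*, but interactions are curated
between *ingredients*; a finding therefore expands each product pair into
its ingredient pairs, looks those up in the de-duplicated DDI table,
aggregates severity (most severe wins) and attaches the direction-specific
interval constraints (MTCMD) when the KB has them.

The policy action attached to each finding follows the standard severity
ladder: major interactions are to be avoided outright; moderate ones are
separated in time when interval data exist (otherwise monitored); minor
ones are monitored; unknown pairs trigger nothing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .constraint_dsl import AnchorSet
from .knowledge_base import (
    DDIRecord,
    KnowledgeBase,
    MTCMDRecord,
    Severity,
)


class Action(enum.Enum):
    AVOID = "avoid"
    SEPARATE = "separate"
    MONITOR = "monitor"
    NONE = "none"


@dataclass(frozen=True)
class PrescriptionItem:
    product_id: str
    doses_per_day: int | None = None  # None = use the MTCOD value


@dataclass(frozen=True)
class PatientProfile:
    """Anchor times plus the waking window start used by the scheduler."""

    anchors: AnchorSet = field(default_factory=AnchorSet)
    wake_time: float | None = None  # None = breakfast start

    @property
    def wake(self) -> float:
        return self.anchors.breakfast_start if self.wake_time is None else self.wake_time

    @property
    def sleep(self) -> float:
        return self.anchors.sleep_time


@dataclass(frozen=True)
class Prescription:
    items: tuple[PrescriptionItem, ...]
    profile: PatientProfile = field(default_factory=PatientProfile)

    def __post_init__(self):
        ids = [it.product_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("prescription product_ids must be distinct")

    @property
    def product_ids(self) -> tuple[str, ...]:
        return tuple(it.product_id for it in self.items)


@dataclass(frozen=True)
class DDIFinding:
    """One interacting product pair with its evidence and policy action."""

    product_a: str
    product_b: str  # canonical: product_a < product_b
    ingredient_pairs: tuple[DDIRecord, ...]
    overall_severity: Severity
    action: Action
    intervals: tuple[MTCMDRecord, ...] = ()  # directional records, 0-2

    @property
    def product_pair(self) -> tuple[str, str]:
        return (self.product_a, self.product_b)

    def interval(self, first: str, second: str) -> MTCMDRecord | None:
        for r in self.intervals:
            if (r.first_product_id, r.second_product_id) == (first, second):
                return r
        return None


def action_for(severity: Severity, has_intervals: bool) -> Action:
    """Map a severity class (and interval-data availability) to an action."""
    if severity is Severity.MAJOR:
        return Action.AVOID
    if severity is Severity.MODERATE:
        return Action.SEPARATE if has_intervals else Action.MONITOR
    if severity is Severity.MINOR:
        return Action.MONITOR
    return Action.NONE


def find_interactions(rx: Prescription, kb: KnowledgeBase) -> list[DDIFinding]:
    """Screen every unordered product pair of the prescription.

    Returns one finding per pair sharing at least one DDI ingredient pair,
    ordered by severity (descending) then product-id pair; the output is
    invariant under permutation of the prescription items.
    """
    for pid in rx.product_ids:
        if pid not in kb.products:
            raise KeyError(f"unknown product_id {pid!r} in prescription")

    ddi = {}
    for rec in kb.ddi:
        key = rec.canonical_pair
        prev = ddi.get(key)
        if prev is None or rec.severity.rank > prev.severity.rank:
            ddi[key] = rec

    findings: list[DDIFinding] = []
    ids = sorted(rx.product_ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            pairs = []
            for ia in kb.products[a].ingredients:
                for ib in kb.products[b].ingredients:
                    if ia == ib:
                        continue
                    rec = ddi.get(tuple(sorted((ia, ib))))
                    if rec is not None:
                        pairs.append(rec)
            if not pairs:
                continue
            severity = max((p.severity for p in pairs), key=lambda s: s.rank)
            intervals = tuple(
                kb.mtcmd[key]
                for key in ((a, b), (b, a))
                if key in kb.mtcmd
            )
            findings.append(
                DDIFinding(
                    product_a=a,
                    product_b=b,
                    ingredient_pairs=tuple(pairs),
                    overall_severity=severity,
                    action=action_for(severity, bool(intervals)),
                    intervals=intervals,
                )
            )
    findings.sort(key=lambda f: (-f.overall_severity.rank, f.product_pair))
    return findings


def finding_to_dict(f: DDIFinding) -> dict:
    """JSON-ready view of a finding (CLI output schema)."""
    return {
        "product_pair": list(f.product_pair),
        "overall_severity": f.overall_severity.value,
        "action": f.action.value,
        "ingredient_pairs": [
            {
                "ingredient_a": p.ingredient_a,
                "ingredient_b": p.ingredient_b,
                "severity": p.severity.value,
                "mechanism_note": p.mechanism_note,
            }
            for p in f.ingredient_pairs
        ],
        "intervals": [
            {
                "first_product_id": r.first_product_id,
                "second_product_id": r.second_product_id,
                "min_itd": r.min_itd,
                "max_itd": r.max_itd,
            }
            for r in f.intervals
        ],
    }
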