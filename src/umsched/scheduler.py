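"""Daily dose-time assignment on the 0.25 h grid.

Each dose of each prescribed product is a variable over the 96-slot day
grid.  Constraints:

* consecutive doses of one product are separated by a gap in
  [Min-ISD, Max-ISD];
* each dose sits inside its resolved meal/chronopharmacology windows when
  the product has any, otherwise inside the patient's waking window;
* for every ordered product pair with a directional interval record
  (MTCMD), any dose of the first product that precedes a dose of the
  second must be at least Min-ITD hours earlier, and the first dose of the
  second product following the first dose of the first must come within
  Max-ITD hours.

The solver is an exact, fully deterministic backtracking search with
forward checking and admissible branch-and-bound pruning; it returns the
feasible assignment maximising a lexicographic preference (fewest distinct
administration events, most even intra-product spacing, most doses while
awake, earliest first dose), or an :class:`InfeasibilityReport` naming the
constraints that could not be met.  All grid times are exact binary
fractions, so float equality is safe throughout.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field

from .constraint_dsl import (
    GRID,
    Anchor,
    Meal,
    TimeWindow,
    render_time_expr,
    resolve_windows,
    snap,
)
from .interaction_check import (
    Action,
    DDIFinding,
    PatientProfile,
    Prescription,
    finding_to_dict,
)
from .knowledge_base import KnowledgeBase

DoseVar = tuple[str, int]  # (product_id, dose_index)

_MEAL_ORDER = (Meal.BREAKFAST, Meal.LUNCH, Meal.DINNER)


class ViolationKind(enum.Enum):
    MIN_ISD = "min_isd"
    MAX_ISD = "max_isd"
    MIN_ITD = "min_itd"
    MAX_ITD = "max_itd"
    WINDOW = "window"
    ORDER = "order"
    GRID = "grid"


@dataclass(frozen=True)
class Violation:
    kind: ViolationKind
    message: str
    variables: tuple[DoseVar, ...] = ()


class InteractionBlockedError(RuntimeError):
    """A MAJOR (avoid-combination) finding blocks scheduling."""

    def __init__(self, finding: DDIFinding):
        self.finding = finding
        super().__init__(
            f"prescription blocked: {finding.product_a} + {finding.product_b} is a "
            f"{finding.overall_severity.value} interaction (avoid combination); "
            "pass override_major=True to schedule anyway"
        )


@dataclass
class ScheduleProblem:
    """Materialised constraint problem over dose variables."""

    variables: list[DoseVar] = field(default_factory=list)
    domains: dict[DoseVar, tuple[float, ...]] = field(default_factory=dict)
    #: union-of-windows per variable (empty tuple = waking-window fallback)
    windows: dict[DoseVar, tuple[TimeWindow, ...]] = field(default_factory=dict)
    window_labels: dict[DoseVar, str] = field(default_factory=dict)
    #: (earlier dose var, later dose var, min gap, max gap)
    gap_constraints: list[tuple[DoseVar, DoseVar, float, float]] = field(default_factory=list)
    #: ordered product pair -> (min_itd, max_itd)
    itd: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    max_isd: dict[str, float] = field(default_factory=dict)
    wake: float = 7.0
    sleep: float = 22.0
    prn_products: list[str] = field(default_factory=list)
    #: causes recorded when initial window pruning emptied a domain
    pruning_failures: list[str] = field(default_factory=list)

    def product_vars(self, pid: str) -> list[DoseVar]:
        return [v for v in self.variables if v[0] == pid]

    @property
    def product_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for pid, _ in self.variables:
            seen.setdefault(pid)
        return list(seen)


@dataclass
class Schedule:
    assignments: dict[DoseVar, float]
    preference_score: float = 0.0
    prn_products: list[str] = field(default_factory=list)

    def times_for(self, pid: str) -> list[float]:
        return sorted(t for (p, _), t in self.assignments.items() if p == pid)

    def to_dict(self) -> dict:
        return {
            "assignments": [
                {"product_id": pid, "dose_index": idx, "time": fmt_time(t)}
                for (pid, idx), t in sorted(self.assignments.items())
            ],
            "prn": sorted(self.prn_products),
            "score": self.preference_score,
        }


@dataclass
class InfeasibilityReport:
    status: str = "CONFLICT"
    constraints: list[str] = field(default_factory=list)
    suggestions: list[str] = field(default_factory=list)


def fmt_time(t: float) -> str:
    h = int(t)
    m = int(round((t - h) * 60))
    return f"{h:02d}:{m:02d}"


# ---------------------------------------------------------------------------
# problem construction

def _dose_windows(
    rec, profile: PatientProfile, dose_index: int, doses: int
) -> tuple[tuple[TimeWindow, ...], str]:
    """Window union for one dose, with a human-readable label."""
    meal_ws: list[TimeWindow] = []
    labels: list[str] = []
    if rec.meal_constraint is not None:
        uses_generic = any(a.anchor is Anchor.MEAL_GENERIC for a in rec.meal_constraint.alternatives)
        meal = None
        if uses_generic:
            if doses > len(_MEAL_ORDER):
                raise ValueError(
                    f"{rec.product_id}: {doses} doses/day cannot bind to the three daily meals"
                )
            meal = _MEAL_ORDER[dose_index]
        meal_ws = resolve_windows(rec.meal_constraint, profile.anchors, meal)
        labels.append(f"meal constraint '{render_time_expr(rec.meal_constraint)}'")
    chrono = list(rec.chrono_windows)
    if chrono:
        labels.append(
            "chrono windows " + ";".join(f"{fmt_time(w.start)}-{fmt_time(w.end)}" for w in chrono)
        )

    if meal_ws and chrono:
        out = []
        for mw in meal_ws:
            for cw in chrono:
                lo, hi = max(mw.start, cw.start), min(mw.end, cw.end)
                if lo <= hi:
                    out.append(TimeWindow(lo, hi))
        windows = tuple(out)
    else:
        windows = tuple(meal_ws or chrono)
    return windows, " AND ".join(labels)


def build_problem(
    rx: Prescription,
    profile: PatientProfile,
    kb: KnowledgeBase,
    findings: list[DDIFinding] | None = None,
    override_major: bool = False,
) -> ScheduleProblem:
    """Materialise all constraint classes for a prescription.

    prn products are excluded from the variables and listed separately.
    Raises :class:`InteractionBlockedError` on an un-overridden AVOID
    finding.
    """
    if findings is not None and not override_major:
        for f in findings:
            if f.action is Action.AVOID:
                raise InteractionBlockedError(f)

    prob = ScheduleProblem(wake=profile.wake, sleep=profile.sleep)
    waking = TimeWindow(snap(profile.wake), snap(profile.sleep))

    for item in rx.items:
        rec = kb.mtcod[item.product_id]
        if rec.prn or (rec.meal_constraint is not None and rec.meal_constraint.prn):
            prob.prn_products.append(item.product_id)
            continue
        doses = item.doses_per_day if item.doses_per_day is not None else rec.doses_per_day
        prob.max_isd[item.product_id] = rec.max_isd
        dose_vars = []
        for k in range(doses):
            var: DoseVar = (item.product_id, k)
            windows, label = _dose_windows(rec, profile, k, doses)
            if not label:
                domain_src: tuple[TimeWindow, ...] = (waking,)
                label = f"waking window {fmt_time(waking.start)}-{fmt_time(waking.end)}"
            elif windows:
                domain_src = windows
            else:
                domain_src = ()
            domain = sorted({t for w in domain_src for t in w.grid_times()})
            prob.variables.append(var)
            prob.domains[var] = tuple(domain)
            prob.windows[var] = windows
            prob.window_labels[var] = label
            dose_vars.append(var)
            if not domain:
                prob.pruning_failures.append(
                    f"dose {var} has no feasible time: {label} resolves to an empty window set"
                )
        for a, b in zip(dose_vars, dose_vars[1:]):
            prob.gap_constraints.append((a, b, rec.min_isd, rec.max_isd))

    scheduled = set(pid for pid, _ in prob.variables)
    for (a, b), rec in kb.mtcmd.items():
        if a in scheduled and b in scheduled:
            prob.itd[(a, b)] = (rec.min_itd, rec.max_itd)
    return prob


# ---------------------------------------------------------------------------
# validation

def validate_schedule(schedule: Schedule, problem: ScheduleProblem) -> list[Violation]:
    """Pure check of every materialised constraint; empty list == feasible."""
    out: list[Violation] = []
    for var in schedule.assignments:
        if var not in problem.domains:
            raise KeyError(f"assignment references unknown variable {var}")
    for var in problem.variables:
        if var not in schedule.assignments:
            out.append(Violation(ViolationKind.WINDOW, f"{var} unassigned", (var,)))
            continue
        t = schedule.assignments[var]
        if abs(t / GRID - round(t / GRID)) > 1e-9 or not (0 <= t < 24):
            out.append(Violation(ViolationKind.GRID, f"{var} at {t} off the day grid", (var,)))
            continue
        ws = problem.windows[var]
        if ws:
            if not any(w.contains(t) for w in ws):
                out.append(
                    Violation(
                        ViolationKind.WINDOW,
                        f"{var} at {fmt_time(t)} outside {problem.window_labels[var]}",
                        (var,),
                    )
                )
        elif not (problem.wake <= t <= problem.sleep):
            out.append(
                Violation(ViolationKind.WINDOW, f"{var} at {fmt_time(t)} outside the waking window", (var,))
            )

    asg = schedule.assignments
    for a, b, lo, hi in problem.gap_constraints:
        if a not in asg or b not in asg:
            continue
        gap = asg[b] - asg[a]
        if gap <= 0:
            out.append(Violation(ViolationKind.ORDER, f"doses {a}, {b} out of order", (a, b)))
        elif gap < lo:
            out.append(
                Violation(ViolationKind.MIN_ISD, f"gap {a}->{b} is {gap} h < Min-ISD {lo} h", (a, b))
            )
        elif gap > hi:
            out.append(
                Violation(ViolationKind.MAX_ISD, f"gap {a}->{b} is {gap} h > Max-ISD {hi} h", (a, b))
            )

    for (pa, pb), (min_itd, max_itd) in problem.itd.items():
        a_times = sorted(t for (p, _), t in asg.items() if p == pa)
        b_times = sorted(t for (p, _), t in asg.items() if p == pb)
        if not a_times or not b_times:
            continue
        for ta in a_times:
            for tb in b_times:
                if ta <= tb and tb - ta < min_itd:
                    out.append(
                        Violation(
                            ViolationKind.MIN_ITD,
                            f"{pb} at {fmt_time(tb)} only {tb - ta} h after {pa} at "
                            f"{fmt_time(ta)} (Min-ITD {min_itd} h)",
                        )
                    )
        first_a = a_times[0]
        later_b = [tb for tb in b_times if tb >= first_a]
        if later_b and later_b[0] - first_a > max_itd:
            out.append(
                Violation(
                    ViolationKind.MAX_ITD,
                    f"first {pb} dose {later_b[0] - first_a} h after first {pa} dose "
                    f"(Max-ITD {max_itd} h)",
                )
            )
    return out


# ---------------------------------------------------------------------------
# preference objective

def _score_tuple(asg: dict[DoseVar, float], problem: ScheduleProblem) -> tuple:
    """Exact lexicographic objective, larger is better."""
    if not asg:
        return (0, 0.0, 0, 0.0)
    events = len(set(asg.values()))
    ss = 0.0
    for pid in problem.product_ids:
        times = sorted(t for (p, _), t in asg.items() if p == pid)
        if len(times) < 2:
            continue
        mx = problem.max_isd.get(pid, 24.0)
        gaps = [b - a for a, b in zip(times, times[1:])]
        gaps.append(24.0 - (times[-1] - times[0]))  # wrap-around to the next day
        ss += sum((g - mx) ** 2 for g in gaps)
    waking = sum(1 for t in asg.values() if problem.wake <= t <= problem.sleep)
    first = min(asg.values())
    return (-events, -ss, waking, -first)


def preference_score(schedule: Schedule, problem: ScheduleProblem) -> float:
    """Flatten the lexicographic preference into one real (larger = better).

    Clauses, in strict priority order: (1) fewest distinct administration
    events (compatible drugs grouped); (2) most even intra-product spacing,
    measured against Max-ISD over circular day gaps; (3) most doses inside
    the waking window; (4) earliest first dose.
    """
    if validate_schedule(schedule, problem):
        raise ValueError("preference_score requires a feasible schedule")
    ne, nss, waking, nfirst = _score_tuple(schedule.assignments, problem)
    ss_q = int(round(-nss * 16))  # grid squares are multiples of 1/16
    first_q = int(round(-nfirst / GRID))
    events = -ne
    # nested base encoding keeps the order strictly lexicographic
    return -float(((events * 400_000 + ss_q) * 64 + (63 - waking)) * 96 + first_q)


# ---------------------------------------------------------------------------
# solving

def _binary_ok(problem: ScheduleProblem, va: DoseVar, ta: float, vb: DoseVar, tb: float) -> bool:
    """All binary constraints between two assigned dose variables."""
    for a, b, lo, hi in problem.gap_constraints:
        if (a, b) == (va, vb) and not (lo <= tb - ta <= hi):
            return False
        if (a, b) == (vb, va) and not (lo <= ta - tb <= hi):
            return False
    pa, pb = va[0], vb[0]
    if pa != pb:
        r = problem.itd.get((pa, pb))
        if r and ta <= tb and tb - ta < r[0]:
            return False
        r = problem.itd.get((pb, pa))
        if r and tb <= ta and ta - tb < r[0]:
            return False
    return True


def _constraint_labels(problem: ScheduleProblem, va: DoseVar, vb: DoseVar) -> list[str]:
    labels = []
    for a, b, lo, hi in problem.gap_constraints:
        if {a, b} == {va, vb}:
            labels.append(f"dose gap of {a[0]} must lie in [{lo}, {hi}] h")
    pa, pb = va[0], vb[0]
    for key in ((pa, pb), (pb, pa)):
        if key in problem.itd:
            labels.append(f"Min-ITD {key[0]}->{key[1]} = {problem.itd[key][0]} h")
    return labels


def solve(problem: ScheduleProblem) -> Schedule | InfeasibilityReport:
    """Exact deterministic search for the best feasible schedule.

    Backtracking with forward checking; variables picked by fewest
    remaining values (ties: product id, dose index); values tried earliest
    first; the optimum under :func:`preference_score` is returned, keeping
    the first-found schedule among equal optima.
    """
    if problem.pruning_failures:
        return InfeasibilityReport(
            constraints=list(problem.pruning_failures),
            suggestions=["widen the constraint windows or review the product's dosing constraints"],
        )
    if not problem.variables:
        return Schedule(assignments={}, preference_score=0.0, prn_products=list(problem.prn_products))

    variables = list(problem.variables)
    domains: dict[DoseVar, tuple[float, ...]] = {v: problem.domains[v] for v in variables}
    best: dict | None = None
    failure_counts: dict[str, int] = {}
    product_doses = {pid: problem.product_vars(pid) for pid in problem.product_ids}
    # doses of one product occupy distinct, strictly increasing times
    min_events = max((len(vs) for vs in product_doses.values()), default=0)

    def bound(asg: dict[DoseVar, float], doms: dict[DoseVar, tuple[float, ...]]) -> tuple:
        """Optimistic (admissible) score bound for any completion of ``asg``."""
        events = max(len(set(asg.values())), min_events) if asg else min_events
        ss = 0.0
        for pid, pvars in product_doses.items():
            if len(pvars) < 2:
                continue
            mx = problem.max_isd.get(pid, 24.0)
            # dose index order is time order, so a gap between adjacent
            # assigned indices is final even while other doses are open
            for a, b in zip(pvars, pvars[1:]):
                if a in asg and b in asg:
                    ss += (asg[b] - asg[a] - mx) ** 2
            first, last = pvars[0], pvars[-1]
            if first in asg and last in asg:
                ss += (24.0 - (asg[last] - asg[first]) - mx) ** 2
        unassigned = [v for v in variables if v not in asg]
        waking_ub = sum(1 for t in asg.values() if problem.wake <= t <= problem.sleep) + len(unassigned)
        lows = [asg[v] for v in asg] + [doms[v][0] for v in unassigned if doms[v]]
        first_lb = min(lows) if lows else 0.0
        return (-events, -ss, waking_ub, -first_lb)

    def dfs(asg: dict[DoseVar, float], doms: dict[DoseVar, tuple[float, ...]]):
        nonlocal best
        if len(asg) == len(variables):
            sched = Schedule(assignments=dict(asg))
            if validate_schedule(sched, problem):  # Max-ITD is checked here
                return
            score = _score_tuple(asg, problem)
            if best is None or score > best["score"]:
                best = {"score": score, "assignments": dict(asg)}
            return
        if best is not None and bound(asg, doms) <= best["score"]:
            return
        # fewest remaining values, then product id, dose index
        var = min((v for v in variables if v not in asg), key=lambda v: (len(doms[v]), v))
        for t in doms[var]:
            new_doms = dict(doms)
            new_doms[var] = (t,)
            dead = False
            for other in variables:
                if other in asg or other == var:
                    continue
                filtered = tuple(u for u in doms[other] if _binary_ok(problem, var, t, other, u))
                if not filtered:
                    for lab in _constraint_labels(problem, var, other) or [
                        f"no joint time for {var} and {other}"
                    ]:
                        failure_counts[lab] = failure_counts.get(lab, 0) + 1
                    dead = True
                    break
                new_doms[other] = filtered
            if dead:
                continue
            asg[var] = t
            dfs(asg, new_doms)
            del asg[var]

    dfs({}, domains)

    if best is None:
        constraints = sorted(failure_counts, key=lambda k: (-failure_counts[k], k)) or [
            "no assignment satisfies the combined window and interval constraints"
        ]
        suggestions = []
        if problem.itd:
            suggestions.append("relax or override a drug-pair interval (Min-ITD) constraint")
        suggestions.append("widen the waking window or the constraint windows")
        return InfeasibilityReport(constraints=constraints, suggestions=suggestions)

    sched = Schedule(assignments=best["assignments"], prn_products=list(problem.prn_products))
    sched.preference_score = preference_score(sched, problem)
    return sched


def enumerate_feasible(
    problem: ScheduleProblem, coarse_grid: float = GRID
) -> list[dict[DoseVar, float]]:
    """All feasible full assignments on a (possibly coarsened) grid.

    Exhaustive; intended for small problems (testing oracle).
    """
    if coarse_grid not in (0.25, 0.5, 1.0):
        raise ValueError("coarse_grid must be one of 0.25, 0.5, 1.0")
    if len(problem.variables) > 6:
        raise ValueError("brute force limited to 6 dose variables")
    if problem.pruning_failures:
        return []
    variables = sorted(problem.variables)
    doms = [
        tuple(t for t in problem.domains[v] if abs(t / coarse_grid - round(t / coarse_grid)) < 1e-9)
        for v in variables
    ]
    feasible = []
    for combo in itertools.product(*doms):
        asg = dict(zip(variables, combo))
        if not validate_schedule(Schedule(assignments=asg), problem):
            feasible.append(asg)
    return feasible


def brute_force_solve(
    problem: ScheduleProblem, coarse_grid: float = GRID
) -> Schedule | InfeasibilityReport:
    """Exhaustive-enumeration reference solver (same contract as :func:`solve`)."""
    if not problem.variables and not problem.pruning_failures:
        return Schedule(assignments={}, preference_score=0.0, prn_products=list(problem.prn_products))
    feasible = enumerate_feasible(problem, coarse_grid)
    if not feasible:
        return InfeasibilityReport(constraints=["exhaustive enumeration found no feasible assignment"])
    best = max(feasible, key=lambda a: _score_tuple(a, problem))
    sched = Schedule(assignments=best, prn_products=list(problem.prn_products))
    sched.preference_score = preference_score(sched, problem)
    return sched
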