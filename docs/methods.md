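# Methods

## Problem setting

A day is discretised into 96 slots of 0.25 h; every dose of every
prescribed product is a decision variable over that grid.  The package
schedules a *single* day: medication regimens for chronic conditions are
overwhelmingly daily-periodic, so the day is treated as the repeating
unit and windows or intervals that would cross midnight are clipped to
the day rather than wrapped.  Multi-day titration, missed-dose
rescheduling and adherence modelling are out of scope.

All grid times are exact binary fractions (multiples of 1/4), so float
arithmetic and equality on them are exact; no tolerance machinery is
needed anywhere in the solver.

## The symbolic constraint language

Meal- and sleep-anchored instructions are encoded as strings over five
anchor letters (`C` any meal, `ZC` breakfast, `ZHC` lunch, `WC` dinner,
`S` sleep), a `-` prefix for *before* (after is the default and its `+`
is omitted), decimal offsets in hours accurate to 0.25 h, `~` for offset
ranges and `;` for alternatives; `prn` marks as-needed dosing and a bare
number is a duration constant (the 0.5 h default meal length).  The
grammar is case-sensitive and total over the thirteen symbol-table rows
the notation defines.

Resolution against a patient's anchors uses one convention decided here,
since the notation itself does not say whether "2 h after a meal" counts
from the start or the end of eating: **before-offsets subtract from the
anchor's start; after-offsets add to the anchor's end** (meal end =
start + meal duration; sleep has zero duration).  This uses the meal
duration the profile explicitly carries and matches the clinical intent
of fasting instructions (an empty stomach is reached only after eating
ends).  The zero-offset form `C0` denotes the whole with-meal window
[start, start + duration].  Single offsets resolve to zero-width windows
("at that grid time"): the notation writes `~` whenever a range is
meant, so a bare offset is read as a point.  Range endpoints are
inclusive.

Two degenerate rows are handled for totality: a bare anchor letter
(`S`) parses as offset 0, and the bare number parses as a duration
literal with no schedulable window (like `prn`).  Canonical rendering
always writes the offset (`S` renders as `S0`), so round-tripping is
defined at the AST level: `parse(render(e)) == e` for every valid
expression, verified property-based.

When a product with a generic meal constraint is taken *n* times a day,
dose *k* binds to the *k*-th meal in order breakfast, lunch, dinner;
*n* > 3 with a meal constraint is rejected.  This mirrors everyday
"with meals" dosing.

Default anchors: breakfast 07:00, lunch 12:00, dinner 18:00, sleep
22:00, meals 30 min; the waking window defaults to [07:00, 22:00].

## Knowledge-base conventions

* Max-ISD = 24/n floored to the grid (n = 7 gives 3.25 h) so every
  derived quantity stays on the scheduling grid.
* DDI records are deduplicated to one per canonical unordered ingredient
  pair; on conflicting severities the more severe wins
  (major > moderate > minor > unknown) — conservative alerting.
* Composition summaries report percentages at two decimals, half-up.
  One published count table this package ships as fixture input contains
  small internal rounding slips (its counts give 96.22 and 43.02 where
  it prints 96.21 and 43.04); the summaries always report the value
  computed from the counts.
* Tabular I/O is CSV (UTF-8, header row); a JSON bundle (`kb.json`,
  schema in `docs/kb.schema.json`) is the single-file alternative.
  Symbolic constraints are stored as DSL strings, chronopharmacology
  windows as `start~end;…` hour pairs.  Loading validates every foreign
  key and record invariant and reports all offending rows at once.

## Interaction policy

Severity definitions translate to machine actions as: MAJOR → AVOID
(the scheduler refuses the prescription unless explicitly overridden),
MODERATE → SEPARATE when directional interval data exist, otherwise
MONITOR (non-blocking: absent interval data there is nothing actionable
to schedule), MINOR → MONITOR, UNKNOWN → no action.  Findings are
reported at product level with the contributing ingredient pairs
attached, because prescriptions name products while interaction evidence
lives at ingredient level.

## Constraint semantics

* Min-ISD/Max-ISD bound the gap between *consecutive* doses of one
  product (dose index order is time order).
* Min-ITD is a safety floor: for an ordered pair (A, B) with a record,
  **every** dose of B that does not precede a dose of A must come at
  least Min-ITD hours after it.  Max-ITD is a permissive ceiling whose
  operational meaning is not pinned down by the data model; here it
  upper-bounds the gap between the *first* dose of A and the *first*
  subsequent dose of B.  Doses of B earlier than every dose of A are
  governed solely by the reverse-direction record.
* Meal windows and chronopharmacology windows are hard constraints and
  intersect when both are present; window-less doses are confined to the
  waking window.  Windows deliberately override the waking window (a
  before-bed drug may sit at 21:30 even if the patient sleeps at 22:00,
  and a 3 a.m. chronotherapy window is honoured).
* prn products are never assigned times; they pass through to the
  reminder export as untimed to-dos.

## Solver

Exact backtracking search with forward checking over the grid domains.
Variable order: fewest remaining values, ties by (product id, dose
index).  Value order: earliest time first.  The search enumerates
complete feasible assignments, keeps the best under the lexicographic
objective, and prunes with an admissible bound; the first-found optimum
is kept on ties, which realises the earliest-time tie-break and makes
the output bit-for-bit deterministic (no randomness anywhere).

Objective, in strict priority order:

1. fewest distinct administration events — schedules that let the
   patient act fewer times a day are strongly preferred;
2. most even intra-product spacing: minimise Σ(gap − Max-ISD)² over the
   *circular* day gaps (including the wrap to the next morning), so a
   q12h drug at gaps (12, 12) is optimal;
3. most doses inside the waking window;
4. earliest first dose.

The flattened score is a nested base encoding of the exact tuple
(spacing terms are multiples of 1/16, times of 1/4, so the encoding is
integral and exact in double precision).  The objective is isolated in
`preference_score` and can be swapped without touching the search.

The admissible bound exploits two structural facts: gaps between
adjacent-index assigned doses are final even while other variables are
open, and the doses of a single product always occupy distinct times, so
the event count is at least the largest per-product dose count.  Max-ITD
(a non-binary constraint) is enforced at complete assignments.

`brute_force_solve` is the reference implementation: exhaustive
enumeration over (optionally coarsened) domains, capped at six dose
variables, scored by the same objective.  The test suite checks solver /
oracle agreement on feasibility and optimal objective value over 240
seeded random problems with compact window domains on a 0.5 h grid —
sizes chosen so exhaustive enumeration stays a genuine oracle while the
whole suite runs in well under a minute.

Infeasibility is reported, not silently absorbed: an empty initial
domain names the window constraints that emptied it, and an exhausted
search lists the constraints that most often wiped domains during
forward checking, with coarse relaxation suggestions.

## UMS slot view

The four-slot boundaries are derived from the profile rather than fixed
clock times, so the view stays meaningful for shift-work routines:
morning = [wake, breakfast + 3 h), noon = [breakfast + 3 h,
dinner − 2 h), evening = [dinner − 2 h, sleep − 1 h), bedtime =
[sleep − 1 h, sleep].  Boundaries are clamped monotone, so the slots
always partition [wake, sleep]; doses outside the waking span are
flagged unslotted rather than forced into a slot.  Reminder export
writes RFC 5545 text directly (VEVENTs with floating local DTSTART — a
single patient-local day needs no TZID — and VTODOs for prn products).

## Synthetic data

The generator emits seed-deterministic knowledge bases: ingredient
classes drawn at 55/43/2 % (chemical / TCM extract / natural product,
matching the composition large product registries report), DDIs sampled
per canonical ingredient pair at a configurable density with a
configurable severity mix (default 19/61/10/10 %, echoing the published
major/moderate share), doses per day uniform on the configured range,
Min-ISD uniform on the grid below a feasibility cap, Max-ISD always
24/n.  Each non-prn product carries recommended-time windows (±0.75 h
around an even in-day layout), reflecting how real systems store a
per-product recommended medication time; 40 % of once-daily products are
left window-free.

Feasibility by construction: the generator lays out a schedule for its
embedded 2–3-product seed prescription first and derives the directional
Min-ITD values from the gaps that layout actually realises, so the seed
prescription is solvable for every seed (regression-tested across 25
seeds spanning 0–96).

What the generator does *not* emulate: real label heterogeneity (free-
text instructions, dose-strength variants), food/disease interactions,
ingredient-count distributions of combination products, and the scale of
production databases (10⁵ products, 10⁶ pairwise records).  Passing
tests therefore demonstrate correctness of the constraint semantics and
solver on realistic problem *shapes*, not coverage of any real
formulary.

## Known limitations

* Exact optimisation is exponential in the worst case; with window-rich
  KBs at prescription scale (≤ ~10 products) it is interactive, but a
  prescription of many window-free multi-dose products can be slow.
* Max-ITD semantics beyond the first-dose reading are unspecified in the
  data model and may need revisiting against clinical practice.
* Single-day periodicity cannot express every-other-day or weekly
  regimens, nor night-shift days crossing midnight.
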