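# umsched

Drug-interaction-aware daily medication scheduling.

Patients with several chronic conditions routinely juggle five or more
products a day, each with its own instructions ("with meals", "on an empty
stomach", "every 12 h", "not within 2 h of ...").  `umsched` turns those
instructions into a constraint-satisfaction problem on a 15-minute day
grid and solves it, producing per-dose clock times, a four-slot
**Universal Medication Schedule** view (morning / noon / evening /
bedtime), and iCalendar reminders.  It is a library plus a small CLI
(`ums`) aimed at clinical-pharmacy decision-support prototyping.

## The model

Per product (an *MTCOD* record — medication time constraint, one drug):

* `doses_per_day` *n*, and the interval between successive doses bounded
  by **Min-ISD** and **Max-ISD**, where Max-ISD = 24 h / *n* (floored to
  the 0.25 h grid) so the drug is spread evenly over the day;
* an optional symbolic meal/sleep constraint, e.g. `-C1;C2` ("1 h before
  a meal **or** 2 h after it"), `C0` (with meals), `-S0.25~-S0.5`
  (15–30 min before bedtime), `prn` (as needed — never scheduled);
* optional absolute chronopharmacology windows (preferred dosing times).

Per ordered product pair (an *MTCMD* record — medication time constraint,
multi drug): **Min-ITD** / **Max-ITD**, the minimum/maximum interval
between the two drugs in a day.  The records are directional because safe
separation depends on administration order — ibuprofen is harmless from
2 h after aspirin, while aspirin needs a 24 h gap after ibuprofen.

Drug–drug interactions are stored per unordered *ingredient* pair with a
severity class (major / moderate / minor / unknown) and mapped onto
prescriptions (which name products) by expanding each product into its
ingredients.  Policy: major → avoid (scheduling refuses unless
overridden), moderate → separate in time when interval data exist
(monitor otherwise), minor → monitor.

The solver is an exact, deterministic backtracking search with forward
checking over the 96-slot grid.  Among feasible schedules it maximises,
lexicographically: fewest distinct administration events (compatible
drugs are grouped), most even intra-product spacing (circular day gaps
vs. Max-ISD), most doses inside the patient's waking window, earliest
first dose.

## Worked example

```bash
ums build-kb --worked-example --out kb
echo '{"items":[{"product_id":"ASP"},{"product_id":"IBU"},
       {"product_id":"OXY"},{"product_id":"PRN"}]}' > rx.json
ums check --kb kb --rx rx.json
ums schedule --kb kb --rx rx.json --ics day.ics
```

prints

```
ASP + IBU: MODERATE -> separate
  ASP first, then IBU: separate by 2.0-22.0 h
  IBU first, then ASP: separate by 24.0-24.0 h
OXY + PRN: MINOR -> monitor

MORNING
  07:00  aspirin enteric-coated tablets
  07:00  oxycodone hydrochloride extended-release tablets
NOON
  -
EVENING
  19:00  ibuprofen tablets
  19:00  oxycodone hydrochloride extended-release tablets
BEDTIME
  -
AS NEEDED
  rescue analgesic tablets (synthetic) (prn)
```

Reading: the aspirin/ibuprofen pair is moderate, so the solver separates
them — aspirin first, ibuprofen 12 h later (≥ the 2 h floor).  The q12h
extended-release product lands at 07:00 and 19:00 (exactly 12 h apart),
and each of its doses shares an administration event with another drug,
so the patient acts only twice a day.  The as-needed product is listed,
never timed.  `day.ics` holds one VEVENT per dose (plus a VTODO for the
prn product) and imports into any RFC 5545 calendar.

The same pipeline is available as a library:

```python
from umsched import (worked_example_kb, Prescription, PrescriptionItem,
                     PatientProfile, find_interactions, build_problem, solve)

kb = worked_example_kb()
rx = Prescription(items=(PrescriptionItem("ASP"), PrescriptionItem("IBU")))
profile = PatientProfile()
schedule = solve(build_problem(rx, profile, kb, find_interactions(rx, kb)))
print(schedule.to_dict())
```

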