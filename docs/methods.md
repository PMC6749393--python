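# Methods

`wardflow` simulates the patient flow of a Brazilian polyclinic on a discrete
10-second clock and compares three staffing regimes over a simulated week:

* **S1 — static staffing**: eleven professionals on duty around the clock,
  one per staffed post, relieved on a 12 h-on / 36 h-off roster.
* **S2 — reactive elasticity**: every monitoring cycle (10 min), each room's
  estimated wait is compared against an upper and a lower threshold; rooms
  above the band receive attendants, rooms below it release them.
* **S3 — proactive elasticity**: the same orchestration, but triggered by
  ARIMA forecasts of each room's demand so that staff movements begin before
  the overload materializes.

## Patient flow and service model

Patients enter at reception, are triaged, and see a doctor; afterwards 24%
go to X-ray, 37% to laboratory collection, 8% to ECG and 31% continue
without exams.  The no-exam group follows the medication split (1% released
with a prescription, 50% intravenous, 30% intramuscular, 19% inhalation); a
configuration switch (`first_care_no_exam_to="exit"`) instead releases them
directly, since the source data leave this ambiguous.  After exams, 60%
return to the doctor and 40% leave; after a return consultation 78% leave,
2% need new exams (renormalized 24/37/8 split) and 20% new medication
(renormalized 50/30/19 split).  Care durations are triangular (minimum,
mode, maximum in minutes), e.g. record preparation (2, 3, 5), triage
(5, 8, 10), first consultation (5, 11, 16), intravenous medication
(40, 70, 120) preceded by a short preparation.  An intravenous or inhalation
service occupies the attendant for preparation plus administration; this is
the literal reading of the published care times and makes the medication
room the heaviest in the hospital.

Queues are FIFO per room.  Care time is sampled at service start.  A room
serves at most `min(active attendants, station_limit)` patients at once;
`station_limit` defaults to 4 care stations per room (a modelling default —
the source does not state it).

**Shift changes.** At a rostered handover the relieving professional takes
over any service in progress, so static staffing shows exactly 11 active
professionals at every tick and no professional works past their shift.  A
professional serving away from their home post (after a reallocation) has no
designated reliever, so they simply never start a service that would outlast
their permitted window; the patient at the head of the queue waits for the
relief instead.  The same rule bounds overtime staff by their deallocation
deadline, which is how the 12-hour cap holds exactly at every instant.

## Workloads and calibration

Arrival profiles are daily shapes in patients per tick: constant, ascending
(0 to peak), descending, and a wave `A/2·(1 + sin 2πt/T)` with period one
day, starting at mid-amplitude rising.  Fractional offered load is
converted to whole admissions by a carry accumulator (two ticks of 0.6
patients admit one patient and carry 0.2), which conserves offered load
exactly.  Arrivals are therefore deterministic given the profile; all
stochasticity lives in care times and routing.

The published experiments do not print arrival magnitudes, so the wave
amplitude is a calibration parameter: `calibrate_wave_amplitude` bisects the
amplitude until a 7-day static week reaches a stated average of hourly
maximum waits (384.18 min for the wave workload).  The calibrated hospital
sits close to its critical load — the triage nurse (capacity ≈ 7.8
patients/h) and the medication nurses saturate during the daily peak — so
small amplitude changes move the static waiting times a lot; replicate seeds
at a fixed amplitude are the honest way to read the elastic results.

## Elasticity mathematics

For a room *r* over a window, `ACT` is the mean completed care duration,
`ANA` the mean attendant count, `ENP` the waiting patients at the window
start plus incoming patients, `ECT = ACT·ENP` the time one attendant would
need to clear the queue, and `HRES = ECT/ANA` the estimated wait with
parallel attendants (infinite when the room is unstaffed).  The proactive
counterpart `PHRES = (ACT′·ENP′)/a` uses forecast quantities and a
hypothetical attendant count *a*.

The room-level rules search the smallest signed attendant delta that brings
the (predicted) wait back inside `[lower, upper]`, bounded by the station
limit above and one attendant below.  Hospital-wide, deltas are reconciled
in a fixed order: overtime staff are released only when every room has been
below its lower threshold for a full cycle; needy rooms then draw from
surplus rooms by an adapted dynamic list-scheduling greedy (take one
attendant from the donor room with most spare attendants holding the needed
specialty, re-sort, repeat — ties favour the most recent donor, then the
room latest in the list, reproducing the published walkthrough); only unmet
need summons off-shift staff, which is the expensive action.  Reallocations
take 10 min, external allocations 60 min; attendants already in transit
count as supply so orders are not duplicated while help is on the way.

**Thresholds.**  100% load is 30 min of waiting (a statutory maximum).  The
reactive controller is evaluated at the four combinations 90/50, 70/50,
90/30, 70/30 (percent of 30 min); the proactive controller uses 30 min
upper and 9 min lower.

## Forecasting

Per room and cycle the store keeps average care time, incoming patients and
queue length (zero-filled, no gaps).  Forecasts use ARIMA(1,1,1) fitted on a
trailing 24 h window, re-optimized every 6 cycles with Kalman-filter updates
in between, and fall back to a trailing 12-cycle mean for short or
degenerate series; predictions are clipped at zero.  Two details matter in
practice:

* An idle cycle stores a zero in the care-time series, but that zero is
  missing data, not a measurement; the controller forward-fills idle cycles
  before fitting.  Without this, rooms with long, sparse services (ECG,
  intravenous medication) forecast near-zero care times and are starved of
  staff.
* `ENP′` is taken as the worse of two estimates: a *near* one at the
  reallocation lead (current queue plus two cycles of forecast arrivals) and
  a *far* one at the allocation lead (forecast queue length 60 min ahead
  plus the following cycle's arrivals).  Summing forecast arrivals over the
  whole 10–70 min horizon with no outflow — the obvious alternative —
  overestimates load roughly by the horizon-to-cycle ratio, pins every room
  at its station limit and makes the proactive hospital *worse* than the
  reactive one while costing more; the two-horizon form restores the
  expected ordering (proactive waits below reactive, at slightly higher
  cost).

## Labor rules

Off-shift staff may be summoned as overtime (paid 1.5×) only if: they have
rested ≥ 11 h (Rule 1); the stint, capped at 12 h of continuous work
(Rule 2), can end ≥ 11 h before their next rostered shift (Rule 3, enforced
by fixing the deallocation deadline at allocation time); and a full 36 h
rest gap remains feasible somewhere in the current week given all known
commitments (Rule 4, a feasibility check).  A deallocated professional is
not summoned again within the same 12 h shift window, and a cooldown
prevents any resource from returning to the room it left on the immediately
preceding cycle (the hysteresis guard).

Because the roster's natural rest gaps are exactly 36 h, *any* overtime
stint inside a gap consumes it: each professional supports roughly two
stints per week before Rule 4 refuses further summons.  The external pool
is therefore ordered by marginal Rule-4 cost, preferring staff whose stint
would land in an already-broken gap.

## What the comparison shows — and its limits

At the calibrated wave amplitude the reactive controller (70/30) cuts the
weekly average of hourly maximum waits by ~80–90% (means of 84–87% over
five seeds, depending on the calibration seed), and the proactive
controller consistently beats it on matched seeds at a slightly higher
cost.  The reduction does not reach the published
93.4% for this workload.  The residual is structural under this package's
declared defaults, not a controller defect: (i) with 4 care stations per
room, the doctor and medication rooms run at ≈ 0.9 utilization during the
calibrated peak even when fully staffed, so queues built during the 60 min
allocation lead drain slowly; and (ii) the weekly Rule-4 rest budget
(~2 overtime stints per professional) is exhausted by days 5–6, leaving
occasional morning hours with no summonable doctor and waits of 2–3 hours
that dominate the weekly average.  Larger station limits or a lighter
calibrated load would close the gap; both are configuration choices, not
algorithm changes.

The synthetic workloads emulate daily demand shapes only: no day-of-week
effects, no triage priority classes, no balking or abandonment, total
compliance with movement notifications, and deterministic admission counts.
Passing tests therefore validate the control algorithms and the labor-rule
bookkeeping under these idealized conditions, not the magnitude of benefits
in any real hospital.

## Numerical and reproducibility choices

One tick is 10 s; durations are rounded to ticks (minimum one tick).  All
randomness flows from a single seeded generator; equal seeds give
bit-identical logs.  Weekly metrics: the hourly maximum realized wait
(service start minus queue entry) is averaged over hours in which care
started; cost is the time average of on-shift headcount plus 1.5× overtime
headcount; elastic staffing is the hourly mean of professionals present in
rooms (transit time excluded).  Simulated horizons are 7 days for scenario
comparisons and 12 h–1 day for unit-level checks.
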