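# Model and methods

`rtflowsim` is a discrete-event simulation of the pre-treatment workflow
of a large radiotherapy (RT) department: consultation → CT (and possibly
MRI / PET-CT) → image post-processing (IPP) → contouring with peer review
→ treatment planning → first irradiation.  Its purpose is to compare
workflow-control strategies — *pull* (the first-fraction date is fixed
right after consultation and pre-treatment must beat it) versus *push*
(the date is set only once treatment planning starts) — and to test
capacity/scheduling interventions on top of a fixed baseline.

## Event engine

Time is integer minutes from a configurable origin Monday 00:00, so every
duration in the model (25/45/60/90/120/150–960 min, whole days, whole
weeks) is exact and schedules cannot drift.  Events are processed in
strict `(time, priority, sequence)` order; resource-release events carry a
lower priority tier than requests so capacity freed at an instant is
visible to work arriving at the same instant.  Each stochastic component
(arrivals, care content, start-date draws, IPP lags, service variation,
staff agendas) owns a named RNG substream seeded from
`(base_seed, stream, replication)`.  Replications are therefore
independent, re-runs are bit-identical, and a scenario edit perturbs only
the streams of the components it touches — common random numbers across
scenario comparisons.

## Patient generation

Arrivals are weekday-dependent Poisson processes per tumor site (no
weekend or holiday arrivals); per-site daily counts are drawn at 00:00
and consultation instants spread uniformly over 08:00–17:00.  Each
patient then draws a care trajectory from the catalogue of their site,
which fixes urgency (acute / subacute / regular), imaging needs (MRI,
PET-CT), post-processing needs (warping, image registration), a possible
beam set-up, the planning type (P2 = beam set-up only, P3 = automated
planning — forced for the automated-planning sites, P4 = conventional),
an optional planned delay of 1–8 weeks before pre-treatment, and, for
regular patients, whether the treatment is combined with another modality
(which makes them pull-scheduled at baseline).

The bundled preset defines two trajectories ("complex"/"standard") per
site.  Trajectory-level probabilities are solved so the mixture
reproduces, exactly in expectation, the department-level marginals the
preset is calibrated to: urgency 1.3 / 30.8 / 67.9 %, MRI 18.5 %, PET-CT
3.9 %, warping 12.4 %, image registration 29.7 %, beam set-up 34.7 %,
planned-delay fraction 13 %, pull share 40.8 % and a 93 % P2 share for
bone metastasis.  Per-site values are modelling choices; one residual
site absorbs rounding so the totals are exact.  The per-site weekday
consultation profiles (e.g. lung clinics clustering midweek) are fitted
by iterative proportional fitting so the weekday totals
(17.5/20.9/23.2/21.7/15.5 per day, Mon–Fri) and the site mix both hold
exactly.

## Resources

* **Machines** — 2 CT scanners with 13 × 25-min slots each per day (26
  total), 37 weekly 45-min MRI slots and 5 weekly 45-min PET-CT slots,
  booked first-come-first-planned.  The first two morning CT slots per
  scanner exclude IV-contrast patients; one CT slot per day is reserved
  for acute patients and expires unused (a deliberately conservative
  reading of an exclusive reservation).
* **Doctors** — 44 across seven specialty teams (lung 7, head-and-neck 9,
  breast 9, CNS 3, gynecology 4, GI 5, urology 7).  A doctor is free for
  contouring outside consultations/meetings; the preset gives each doctor
  14 h/week of contouring availability, distributed over weekdays
  inversely to the team's consultation load (the same doctors hold the
  clinics), as one end-of-shift block per day.  Absences are ~5 one-week
  vacation blocks per year plus a 4 % incidental daily rate — clustered
  leave is what produces the multi-day capacity dips of real agendas.
* **Planning RTTs** — 24 planners: 3 at P2 level, 7 at P3, 14 at P4
  (skill counts as enumerated sum to 20 against a stated total of 24; the
  preset honours the total by enlarging the P4 group, and an alternate
  3/7/10 roster is one config edit away).  Skills are
  downward-compatible (P4 ⊇ P3 ⊇ P2) and P3/P4 planners run up to two
  plans concurrently.

## Pathway execution

Imaging occupies the booked slots; scans are sequenced CT → MRI → PET-CT.
IPP lags (CT→warping and last-scan→registration) are lognormal elapsed
times moment-matched to means (SD) of 0.4 (0.6) and 0.1 (1.0) days; they
consume no staff.  Contouring takes 30 min (acute/subacute) or 60 min
(regular) plus a flat 60-min peer review, needs one contiguous free
interval of the assigned specialty doctor — any doctor for palliative
(acute or bone-metastasis) patients, load-balanced — and does not split
across days.  Treatment planning takes the per-trajectory minutes (beam
set-up 60–120; planning 150–960), goes to the least-skilled capable
planner with a free concurrency token, and, being software-driven,
resumes next morning when it outruns the workday.  Both queues serve
earliest-due-date first: the due date is the scheduled start (pull) or
arrival plus the national target (push), so urgent work overtakes
far-dated work automatically.

## Scheduling moments, rebooks, KPIs

Pull patients draw a time-to-treatment at consultation from per-urgency,
per-weekday tables over the empirically observed supports (acute 0–1,
subacute and bone metastasis 1–8, regular 3–21 days); push patients draw
a 1–7 day gap at planning start.  Defaults are two-sided truncated
geometric masses peaked inside the support (acute {0: .2, 1: .8};
subacute mode 4; regular mode 8; push gap mode 2) — empirical tables
reflect dates schedulers actually met, so mass concentrates on feasible
offsets; every table is config-overridable.  Start-weekday constraints
(head-and-neck starts Mondays) bind regular patients; urgent patients
start as soon as possible.  A pull patient found without a finished plan
at the 17:30 checkpoint the day before their start, or at the start
instant itself, is postponed to the next admissible day, one rebook per
postponement; the first fraction is deliverable until 17:00 of the start
day, which keeps same-day acute starts feasible.  Push starts are
adjusted (not rebooked) if planning finishes after the provisional date.

Waiting time is calendar days from consultation to first fraction,
excluding the planned delay (including it would let the 13 % of patients
with 1–8-week intended delays dominate the breach counts; a config switch
restores the inclusive definition).  A breach is a waiting time strictly
above the national target (1 / 10 / 28 days — "within" is inclusive).
KPIs cover patients *arriving* in the measured window; warm-up truncation
is post-hoc on the records and never changes an event time.

## Experiments

Default experiment: 130 warm-up days, a 365-day measured horizon, 60
drain days so work in progress completes, 15 replications; the
cumulative-average warm-up curve and the t-based relative-error rule
(α = 0.05, γ′ = 0.05) that motivated those defaults are implemented in
`kpi`.  The workflow-control sweep promotes tumor sites to pull
cumulatively, simplest pre-treatment first (bone metastasis → breast →
prostate → chest wall → brain → lung → others → head-and-neck), ending at
100 % pull.  Scenarios are pure config transforms: S1 equalises each
trajectory's weekday arrival rates (weekly mass preserved); S2 drops the
CT slot labels; S3 flattens contouring availability to equal hours every
day (≥ 2 h/day, weekly hours preserved); S4 lets P3 planners serve lung
and chest-wall plans (16.4 % of the case mix by construction); S5 adds
one full-time P4 planner.

## Calibration of the preset

Printed facts (machine slots, staff counts, weekday arrival rates,
processing times, target days, the input marginals above) are taken as
is.  The remaining free knobs — per-site step probabilities, weekly
contouring hours, the coupling floor, vacation structure, TTT shapes —
were set once so the baseline operates in the regime the published
department reports (mean waiting time ≈ 8½ days with pull ≈ 6½ < push
≈ 10, roughly 100–200 target breaches per year) and then frozen.  In
this regime the model reproduces the qualitative comparative statics:
waiting times rise and breaches fall as the pull share grows, rebooks
grow with it, and spreading consultations is the single most effective
intervention.  Absolute sweep/scenario magnitudes (e.g. yearly rebook
counts) depend on unpublished per-trajectory empirical distributions and
real 2017 agendas, and are not calibration targets.

## Numerical and design notes

* Contouring is non-preemptive; a task that does not fit today's largest
  remaining free block waits for the next opportunity.  Planning splits
  across days because 960-min plans cannot fit one 10-h day.
* "Up to 30 min" urgent contouring is a fixed 30 min by default.
* Beam set-up alongside P3/P4 planning is modelled as additional planning
  minutes on the same task.
* Doctor assignment within a team is uniform at random at consultation.
* The IV-contrast restriction applies per scanner (config-switchable).
* MRI/PET-CT weekly slots are spread uniformly over weekdays (8/7/8/7/7
  and 1/day) since their placement is not specified.
* The unused acute-reserved CT slot is not released to other patients.
* An imaging-booking horizon of 120 days raises a capacity error when
  exhausted, signalling a misconfigured department rather than looping.
* Holidays default to a generic 8-day closure calendar, not any specific
  national calendar.

## What the synthetic preset does and does not show

The generator emulates a department's statistical behaviour — arrival
seasonality-free weekday structure, care-mix marginals, service-time
scale, leave patterns — not any particular hospital's micro-data: the 62
real care trajectories are collapsed to 16, agendas are synthetic, and
service times are deterministic per trajectory.  Green tests therefore
demonstrate that the machinery (engine, booking rules, queues, KPIs,
replication statistics) is correct and that the comparative directions
are robust in a realistic operating regime; they do not validate absolute
performance numbers for a real department.  Runs at other operating
points (slacker or tighter staffing) can and do change scenario rankings,
which is itself a finding the tool is designed to expose.
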