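# Methods

## Posture epochs and the sedentary definition

All analyses run on a contiguous grid of fixed-length epochs (default 60 s),
each carrying a posture in {SITTING, LYING, STANDING, STEPPING}, a step
count, and a device status in {WORN, NOT_WORN, OFF, CHARGING, BATTERY_DEAD}.
Sedentary means *worn and sitting or lying*: standing breaks sedentary time
even without steps, consistent with the posture-based definition of
sedentary behaviour (≤1.5 METs in a sitting, reclining or lying posture).
Steps may only accrue on STEPPING epochs, and posture is only meaningful
while WORN; both are enforced at construction and at parse time. Gaps in
input files are filled with NOT_WORN epochs and never alter epochs that were
present. Epoch timestamps are timezone-naive local clock time; the study day
index of a date is its offset from the discharge date (day 0), with the
monitored period spanning days 1–14.

The four-state posture vocabulary is an abstraction: the source device also
emits stand-up transition events, which are recovered here as derived
quantities (a worn sedentary epoch followed by a worn standing/stepping
epoch) rather than stored.

## Prompt detection

A vibration prompt is reconstructed by a streaming counter over the epoch
grid. The counter increments on every worn sedentary epoch and resets to
zero on any non-sedentary posture, any non-worn status (NOT_WORN, OFF,
CHARGING, BATTERY_DEAD — a body-worn vibrator cannot prompt off the body),
at midnight, and on prompt emission. A prompt is stamped the instant the
counter reaches the interval, i.e. at the *end* of the interval-th sedentary
epoch, so unbroken sitting from 09:00 with a 30-min setting prompts at
09:30, 10:00, 10:30. Emission resetting the counter is forced by the
observed behaviour of consecutive prompts exactly one interval apart during
unbroken sitting. A single non-sedentary epoch breaks the bout; no minimum
break length is imposed. The midnight reset reflects day-level analysis;
overnight non-wear makes cross-day bouts unobservable in practice anyway.

Two consequences are exact and are tested as identities: no two prompts are
closer than the interval, and a fully sedentary worn span of T minutes
yields ⌊T/interval⌋ prompts. A quadratic-time re-scan
(`detect_prompts_oracle`) checks, for every epoch, whether the trailing
window of one interval is entirely worn-sedentary, within one calendar day,
and free of already-emitted prompts; it exists purely as an independent test
oracle and is held equivalent to the streaming detector on randomized
series.

## Response adjudication

Each prompt opens a 15-minute analysis window starting at the prompt
timestamp, truncated at the next prompt's timestamp and at the first
non-worn epoch. A response is any worn STANDING or STEPPING epoch in-window
— no minimum magnitude is demanded, since "physical activity within 5 min"
is the criterion of record. Latency is the ordinal position of the first
active epoch in minutes, so an immediate stand has latency 1 and latencies
lie in (0, 15]; "within 5 min" means latency ≤ 5, i.e. activity in the first
five post-prompt epochs. Behavioural magnitudes — minutes standing, minutes
walking, steps — are accumulated over the first 5 minutes only, the frame in
which such trials report them; responders with latency in (5, 15] count as
responses but contribute nothing to magnitude means.

A window containing no worn epoch at all is a non-response with
`window_worn_epochs = 0` and `window_truncated = True`; cohort summaries can
either keep such prompts in the denominator (default, an
intention-to-treat-style read) or drop them (`exclude_nonwear_windows`),
since it is ambiguous which denominator a given report used.

Percentages are reported to 2 decimals with ties rounded away from zero
(106/325 → 32.62); trial-flow percentages use 1 decimal with the same tie
rule. Empty inputs produce explicit `None` rates, never a division by zero.

## Wear validation and intensity

Non-wear on the count series uses the plainest standard rule: any run of ≥
60 consecutive zero-count minutes is off-body, with no artifactual-spike
tolerance; the window is configurable. The rule is idempotent, and a longer
window can only flag fewer epochs. A day is valid with ≥ 480 worn minutes
(≥ 8 h, inclusive), and a patient enters cohort analyses only with ≥ 4 valid
days in each of week 1 (days 1–7) and week 2 (days 8–14). Intensity bands on
counts·min⁻¹ are: stationary < 100; MVPA ≥ 1952 (a widely used vertical-axis
ambulation threshold, configurable — trial reports of this design do not
print their light/MVPA cuts); light in between. Day-level percentages are of
worn time and sum to 100 up to rounding. "Waking" wear is approximated by
the wear flags themselves; no sleep diary is modelled.

## Adherence

A 14-day period has 13 overnight charging opportunities. The overnight
window is defined as 18:00 of day d to 12:00 of day d+1 (the notion of
"overnight" needs clock bounds; these are configurable), and a window is
compliant when it contains at least one CHARGING epoch — charging is
device-detected, not self-reported. Compliance is charged windows / 13 × 100
(pro-rated with a warning on shorter series). A day with any worn epoch
counts as worn (no minimum worn duration is imposed, since none is defined);
a day with none is attributed SWITCHED_OFF or BATTERY_DEAD by majority
status, with ties going to BATTERY_DEAD — conservative toward device fault —
and NOT_WORN when neither status appears.

## Trial metrics

Flow percentages use the stage-specific denominators of CONSORT reporting:
eligible/screened, approached/eligible, consented/approached (uptake),
completed/enrolled (retention), each computed only after the monotone funnel
invariant is validated record by record. Categorical comparisons select
Fisher's exact test when any cell is below 5 and Pearson chi-square (no
continuity correction, matching common SPSS-style reporting) otherwise. The
small-cell rule reads *observed* cells by default because that is the
natural reading of "n < 5"; an `expected`-cell mode is provided since the
textbook rule concerns expected counts. Fisher is implemented for 2×2 tables
(scipy); a larger table triggering the rule raises rather than silently
degrading. Continuous comparisons use the independent t test for two groups
and one-way ANOVA beyond, two-sided, with α = 0.05 reported alongside; two
identical constant groups return t = 0, p = 1 rather than NaN.

Questionnaire bands: HADS 0–7 normal, 8–10 borderline, 11–21 abnormal;
FACIT-Fatigue < 30 severe (range 0–52); SPPB < 10 mobility limitation (range
0–12); BMI < 18.5 underweight, [18.5, 25) normal, [25, 30] overweight, > 30
obese. Published BMI bands of this design overlap at exactly 30.0
(overweight ≤ 30, obese ≥ 30); the partition here resolves 30.0 to
overweight so the bands are disjoint.

## The synthetic cohort generator

The generator emulates a 14-day post-discharge monitoring period per
patient on the 1-min grid, emitting the posture series, a matching count
series, a trial manifest, and a ground-truth log of every prompt, response
and device-state day. Two contracts make the pipeline testable end to end:

1. the generator runs the *same* consecutive-sedentary counter as the
   detector, so ground-truth prompt times equal detector output exactly;
2. the log records what was actually emitted into the stream (a drawn
   response that could not be rendered before the day ended is logged as a
   non-response), so classifier verdicts and latencies agree with the log
   event-by-event.

**Daily structure.** Waking hours (default 08:00–22:30) alternate sedentary
bouts and short activity breaks. Bout lengths are exponential: active breaks
with mean 5 min, sedentary bouts with mean f/(1−f) × 5 min where f is the
target sedentary fraction (default 0.75, in the middle of the 63–77%
stationary range typical of this population). Sedentary bouts are sitting
(90%) or lying (10%); active-break epochs are standing (60%) or stepping
(40%). Nights are NOT_WORN.

**Responses.** A prompt elicits a response with probability `p_respond`.
Latency is a two-part mixture: with probability `p_within5` (default 0.41,
the observed share of responses inside 5 min) uniform on {1..5} minutes,
else uniform on {6..15}. A response is rendered as a stand of drawn duration
followed by a walk with steps, then resumed sitting; the ordering is a
modelling choice (the stand-then-walk decomposition is how such responses
are reported, but the true ordering is unreported). Stand and walk durations
are truncated normals on (0, ∞) with defaults 1.4 (SD 0.8) and 0.4 (SD 0.3)
min. Two numerical choices keep the configured means exact: the truncated
normal is parametrized by its *post-truncation* mean (the latent location is
root-solved), and continuous durations are rendered onto the epoch grid by
stochastic rounding (floor + Bernoulli on the fraction), whose expectation
equals the drawn value. The rendered stand is at least one epoch so that
every logged response is visible to the classifier. Steps per response are
`round(step_rate × walk_draw)` with `step_rate` = 53 steps per walking
minute, putting the mean at 53 × 0.4 ≈ 21.2 steps. A non-responded prompt
holds the patient sedentary for the full 15-min window; without that hold a
chance activity break inside the window would contradict the logged
non-response. Prompt intervals must therefore exceed the 15-min window,
which every preset (30/45/60) does.

**Device behaviour.** The battery lasts 2.5 days (middle of the quoted 2–3
day range) of powered operation; each night is charged with probability 0.8,
rendered as CHARGING epochs 02:00–06:00 which refill the battery. A missed
pair of nights therefore produces BATTERY_DEAD spells. Whole days are
manually switched off with probability 0.03 per day — roughly the rate
implied by a few patients turning the device off for one to several days.
There are 13 charging opportunities (nights after days 1–13), matching the
adherence module's denominator.

**Counts.** Sitting, lying and *standing* epochs draw counts uniformly in
[0, 100): quiet standing on a hip accelerometer falls below the stationary
cut-point, which intentionally reproduces the known limitation that counts
measure stationary time, not posture. Stepping epochs draw counts in
[1952, 3952); non-worn, off, charging and dead epochs emit zero.

**Interval assignment.** Patients all sit in the feedback arm (the only arm
the prompt/adherence analytics apply to) and receive intervals by
largest-remainder apportionment of the configured mix, so the default
6:1:5 mix over 30/45/60 min reproduces that split exactly at n = 12.

**Determinism.** A single seed drives a `numpy` `SeedSequence` spawn tree
(one behaviour stream and one counts stream per patient); identical
configurations produce byte-identical outputs, including through the CLI
and the orchestrated pipeline.

**What the generator does not emulate** — and hence what passing tests do
not certify about real data: circadian and day-of-week structure,
heavy-tailed bout-length distributions (real sitting is burstier than
exponential; the generator's prompts-per-day contrast across intervals is
steeper than observed in practice), physiologic count waveforms (every
stepping minute clears the ambulation cut, so synthetic MVPA share equals
walking share, far above the <1% typical of this population), context
effects on responses (car journeys, television), posture-classification
error, and within-patient behavioural drift across the fortnight. Parameter
recovery on synthetic cohorts demonstrates the estimators are faithful to
the stated generating process, not that the process matches any particular
cohort.

## Problem sizes and tolerances in the test suite

Property suites run on deliberately small inputs: detector/oracle
equivalence on 1000 random series of up to 120 epochs (plus a derandomized
hypothesis suite); response-rate recovery on 12-patient × 14-day cohorts
(≈600 prompts) at p ∈ {0.2, 0.33, 0.5} against exact central 99% binomial
intervals; magnitude recovery within 3 standard errors of the configured
means; Fisher-p equivalence against exhaustive hypergeometric enumeration on
every 2×2 table with all margins ≤ 12. The full demo pipeline (12 × 14 days,
1-min epochs) runs end to end in well under two minutes on one CPU. The
worked-example day is deterministic and is checked at exact equality.

## Known limitations

The real device's firmware counter is unobservable; what is implemented is
the published identification procedure (standing-only breaks reset the
bout), not the firmware. The non-wear rule and MVPA cut stand in for
unpublished supplementary protocols and are explicitly configurable.
Cohort-level behavioural numbers from any specific trial (days worn, step
trajectories, prompts per day) are not reproduction targets: the raw data
are unavailable, and those numbers enter only as generator defaults.
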