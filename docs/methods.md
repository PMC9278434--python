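# Methods

This note documents the models behind `somnoresp`: what the synthetic
generator simulates, how each scoring stage works, the numerical choices
that matter, and what the package deliberately does not model.

## Synthetic recordings

The generator produces a plausible 3 h rodent plethysmography session —
airflow, EEG and EMG at a common sample rate (default 100 Hz) — with a
complete record of everything injected, so detectors can be validated by
recovery instead of by eye.

**Sleep architecture** is a semi-Markov chain over WAKE/NREM/REM with
exponentially distributed bout dwell times, REM reachable only from NREM
(the standard rodent constraint).  The user specifies long-run state
fractions and mean dwell times; the two free transition probabilities
(NREM→REM and REM→WAKE) are solved in closed form from the balance of
bout visit rates `π_i = fraction_i / dwell_i`, so scripted fractions
converge to the requested ones.  Not every fraction/dwell combination is
feasible under this topology (the WAKE bout rate cannot exceed NREM's);
infeasible protocols raise immediately with a hint to adjust dwell times.
The recording opens with a quiet-WAKE bout of at least 120 s, mirroring
the experimental practice of reading resting respiratory parameters at
the start of the session; later WAKE bouts are quiet or active with equal
probability, which drives the EMG level.

**Breathing** is synthesised breath by breath: each cycle is one period
of a sine (single inspiration peak, single expiration trough — the
minimal waveform consistent with peak-to-trough tidal volume), with
period and amplitude drawn around the state-modulated resting values
(NREM: slower and slightly deeper; REM: faster, shallower and more
variable).  Breath-to-breath jitter has CV 3 % (doubled in REM).
Additive Gaussian noise (default SD 10 % of resting amplitude) and an
optional 50 Hz line artifact exercise the filtering stages.

**Respiratory events** are injected only inside sleep bouts, never
straddling a wake boundary.  The number of events is the requested
rate times scripted sleep hours; depths are drawn clear of the 0.9
apnoea boundary (apnoeas 0.92–1.0, hypopnoeas 0.55–0.88) so injected
labels are unambiguous, and an event of depth *d* scales the amplitude of
the breaths it covers by (1 − *d*), reducing minute ventilation by the
same factor.  Durations are uniform on 1.9–2.7 s (mean 2.3 s) in NREM
and 25 % longer in REM (mean ≈ 2.9 s), matching the per-state event
durations reported for this preparation; 30 % of events are placed in
REM.  A configurable fraction of REM events is "arousal-linked": placed
at the tail of a REM bout that the architecture already terminates into
WAKE, followed by 5.5 s of hyperpnoea (amplitude × 1.5) before the
awakening — the recovery-overshoot pattern the arousal classifier looks
for.  Sighs are single breaths at 2.5 × amplitude, Poisson-placed in
sleep and quiet wakefulness.

**EEG/EMG** are sums of band-limited Gaussian noise with state-dependent
gains (µV RMS): delta/theta/broadband of 20/22/25 in WAKE, 70/18/18 in
NREM, 12/45/12 in REM; EMG RMS 40 (active wake), 18 (quiet wake),
7 (NREM), 1.5 (REM atonia).  The contrasts are typical of rodent screw
electrode recordings and guarantee the label–signal invariants (delta
dominates NREM; theta:delta > 1 with atonia in REM).

**Presets.**  `sham_protocol()`: f 95 breaths/min, V_T 3.6 mL/kg,
fractions 46/48/6 % (WAKE/NREM/REM), 9 events/h of sleep, 13 sighs/h.
`dta_protocol()`: f 105, V_T 2.3 mL/kg, fractions 52/44/4 %, 30
events/h, 14 sighs/h, and a longer mean WAKE dwell (185 s vs 150 s) —
needed for fraction/dwell feasibility and consistent with the more
consolidated wakefulness of the apnoeic phenotype.

**What the generator does not emulate:** SpO₂ or CO₂ dynamics, thoracic
effort (so obstructive vs central events are indistinguishable, as in
the plethysmograph itself), genuine EEG oscillations (band-limited noise
has the right power distribution but no phase structure), circadian or
ultradian drift, movement artifacts, and sniffing/grooming bouts.
Passing recovery tests therefore shows the pipeline is correct *given*
signals whose band content and amplitudes behave as scripted; it does
not certify performance on artifact-laden real recordings.

## Breath analysis

Airflow is zero-phase low-pass filtered (4th-order Butterworth, default
5 Hz — rodent breathing lives below ~3 Hz) before peak picking.
Inspiration peaks closer than `min_ibi_s` (default 0.25 s) are
suppressed; each peak pairs with the deepest trough before the next
peak; breaths below `min_amplitude_fraction` (default 0.2) of the 10 s
rolling median amplitude are discarded as noise.  Ties in peak location
resolve to the earliest sample (scipy's convention).  A flat trace
yields zero breaths, not an error.

The 0.2 amplitude gate means breaths inside deep (>90 %) events are
usually rejected at realistic noise; the event then appears as a long
inter-breath interval whose per-breath V_E is correspondingly low, so
detection is unaffected, though the *measured* depth of a very deep
event saturates around 0.8 rather than reaching its true value.
Validation helpers that need true depths (`recomputed_event_depth`)
lower the gate to 0.02 on noise-free traces.

Sighs: V_T above `k_sigh` (default 2.0) times the 60-breath rolling
median.  The threshold is a convention — the underlying definition of an
augmented breath — and is configurable.

Quiet wakefulness is operationalised as the earliest run of ≥ 60 s of
contiguous WAKE epochs whose EMG RMS sits below the WAKE median; resting
f, V_T and V_E are means over that interval, with V_E the product of
mean V_T and mean f (products are formed per animal before any group
averaging).

## Sleep staging

Band powers are squared outputs of 4th-order zero-phase Butterworth
band-passes, smoothed by a causal first-order exponential filter with
τ = 5 s, sampled at epoch midpoints; EMG RMS is the square root of the
same smoother applied to the squared signal.  The delta band is
specified as 0–4 Hz but filtered as 0.5–4 Hz: a true 0 Hz edge would
admit DC and movement drift, and 0.5 Hz is the conventional lower edge.
The causal smoother implies the first epoch after a state transition
still carries ~20 % of the previous state's power — the reason
recovery metrics exclude transition-adjacent epochs.

Thresholds adapt per recording.  A single fixed percentile would pin
each threshold to a fixed *rank* and so misclassify a fixed mass of
epochs whenever the true state fractions differ from that rank.
Instead, the delta and EMG thresholds are found by scanning the
feature's quantile ladder (2.5-point steps over the 35th–85th and
30th–85th percentiles respectively) for jumps in log-value and taking
the geometric midpoint of the first jump at least half as large as the
biggest one.  "First substantial" rather than "largest" matters for
EMG, where the quiet/active wakefulness split can open a second, higher
gap: the boundary wanted is the lowest one — sleep versus any
wakefulness.  The theta:delta threshold, whose REM cluster (2–6 % of
epochs) is too small to register in a quantile ladder, is the midpoint
of the 50th and 98th percentiles; the REM rule additionally requires
EMG below the 10th percentile (atonia).  All thresholds are ratios or
quantiles of the recording's own features, so staging is exactly
invariant to channel gain.  Constant (degenerate) features raise an
error rather than fitting meaningless thresholds.

Rules apply in fixed order — EMG first, so a high-tone epoch is WAKE
regardless of EEG; then delta for NREM; then theta:delta with atonia for
REM; DOUBT otherwise.  No post-hoc label smoothing is applied by
default.  DOUBT epochs are excluded from state-fraction denominators and
from total sleep (sleep = NREM + REM only).

## Event detection

Ventilation is evaluated breath by breath (`ve_i = vt_i × 60/ibi_i`), so
events a few breaths long are resolvable.  The baseline is a rolling
median of per-breath V_E over the preceding 60 s, computed twice: a
provisional pass flags candidate event breaths, which are masked out of
the final pass so deep events cannot drag their own reference down.
The first 60 s fall back to the median of the opening window.

Maximal runs of breaths below (1 − 0.5) × baseline become events if they
span ≥ 1.8 s; runs separated by less than one typical breath are merged
first (a hand-scorer would not split an event on one noisy breath).  An
event is an apnoea iff ventilation stays below (1 − 0.9) × baseline for
≥ 1.8 s somewhere inside it; depth is 1 − min(ve)/baseline.  Each event
belongs to exactly one state — its onset epoch's label; a DOUBT onset
inherits the nearest scored epoch's state (DOUBT means unclassifiable,
not awake); events whose resolved onset state is WAKE are discarded.
Because event intervals are breath-quantised (they run from the first
low breath to the first recovered breath), measured durations exceed the
underlying dip by a fraction of a breath, which inflates summed dyspnoea
time by roughly 10 % at 30 events/h; counts and AHI are unaffected.

The minimum duration default is exactly 1.8 s.  The desaturation
calibration utility (`calibrate_min_event_duration`) fits a least-squares
line to (apnoea duration, SpO₂) points and returns the duration at which
saturation would fall a criterion amount (default 4 %) below resting —
the procedure that motivates a ~1.9 s minimum in the rat; it requires a
negative slope and warns when the fitted intercept disagrees with the
stated resting saturation by more than one point.

Arousals are transitions into WAKE from sleep, skipping intervening
DOUBT epochs.  An event is arousal-associated when an arousal falls
within 15 s of its end; the arousal is classified "hyperpnoea" when mean
V_E exceeds 1.2 × baseline either in the 5 s before the awakening or in
the 5 s after event end (the second window covers awakenings the stager
registers one epoch late), and "coincident" when the awakening epoch
contains the event end.

All AHI and dyspnoea rates — total and per state — divide by total sleep
hours, so per-state figures add up exactly to the totals; this identity
is asserted on every run.

## Maze scoring

Barnes: hole visits are entries of the tracked point into a hole's
4.5 cm radius from outside it.  Exit errors are visits to the escape
hole other than the terminal one.  Strategy rules, applied with
precedence spatial > serial > random (most specific first, since the
three field rules are not mutually exclusive): *spatial* — first hole
within two of the exit (inclusive, modulo 20) and the whole path inside
the 90° quadrant centred on the exit (evaluated for points outside a
quarter-radius core, where angles are meaningful); *serial* — any run of
three hole visits stepping ±1 consistently; *random* — at least two
open-field crossings, where a crossing enters the half-radius inner disc
and exits on the opposite side (entry/exit points subtending > 90°).  A
trial matching no rule falls back to random and is flagged as such in
the detailed output, since the field rules are not exhaustive.

Y-maze: the two-paw entry rule is approximated by penetration of the
tracked point ≥ 10 cm into an arm, with exit hysteresis at 5 cm —
a single tracked point cannot resolve paws, and 10 cm is a body-length
fraction for a rat.  Preference is novel/(novel + open) × 100 per
metric; the discrimination ratio is novel over all three arms.  Zero
denominators yield NaN and are flagged, never silently zero.
Occupancy heatmaps assign each inter-sample interval to its sample's
cell, so cell mass sums exactly to trial duration at any grid size.

## Group statistics

R70 is the 85th minus the 15th percentile under the nearest-rank
(inverted-CDF) percentile convention — the order statistic at rank
⌈q·n⌉ — so R70 of the integers 1..100 is exactly 70.  The convention is
recorded in every result object.  The normality gate runs Shapiro–Wilk
on the *control* group only (matching the reporting convention this
package reproduces; a strict mode gating on both groups is available):
Gaussian → unpaired t-test with mean ± SD, otherwise Kruskal–Wallis with
median + R70.  Both tests delegate to scipy.  The optional
Iglewicz–Hoaglin outlier filter (modified Z ≥ 3.5) is off by default.

## Problem sizes and tolerances

The test suite validates recovery on twenty full-length (3 h, 100 Hz)
recordings of the lesioned preset: mean absolute AHI error ≤ max(2/h,
10 %), mean event sensitivity and precision ≥ 0.9, median staging
accuracy ≥ 0.9 with transition-adjacent epochs excluded, and mean REM
fraction error ≤ 0.02.  The acceptance script uses six lesioned and four
sham recordings plus 150 maze trajectories.  Unit tests use 10–20 min
recordings, which are the shortest that still contain several sleep
bouts and enough epochs (≥ 60) to fit staging thresholds.

## Known limitations

- Event kind (apnoea vs hypopnoea) saturates for very deep events at
  realistic noise, because sub-noise breaths cannot be measured; counts
  and AHI are unaffected.
- The stager is threshold-based; it assumes the recording contains a
  substantial amount of both sleep and wake (wake share roughly
  30–70 %).  Recordings that are nearly all one state will fit
  meaningless thresholds.
- Staging registers quiet-wake onsets up to one epoch late (causal
  smoothing), which the arousal classifier compensates for but which
  shortens measured wake bouts slightly.
- Barnes strategy rules are evaluated on the tracked centre point; paths
  that skirt rule boundaries (e.g. quadrant edges) are classified by the
  stated precedence, not by judgement.
- The EDF writer covers the subset of EDF needed here: one data record
  per second, 16-bit samples, integer per-record sample counts.
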