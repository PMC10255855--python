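# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limitations of `fieldtriage`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Triage cascade

Each vital sign *s* carries a reference interval [ref_lo, ref_hi] and
critical thresholds (crit_lo, crit_hi); the severity of a measurement *v*
is

- **in-reference** iff ref_lo ≤ v ≤ ref_hi (bounds inclusive),
- **critical** iff v ≤ crit_lo or v ≥ crit_hi (bounds inclusive, either
  side may be absent — SpO2 has no upper critical threshold),
- **out-of-reference** otherwise.

The published pseudocode walks the signs in priority order RR, HR, SBP,
SpO2 with an explicit no-downgrade state machine; since a later stage can
only hold or raise the tag, the cascade is equivalent to the maximum
severity over signs. We implement the maximum and keep a line-by-line
transliteration of the sequential state machine in the test suite as an
independent oracle, checked for exact agreement on an exhaustive 20⁴
grid spanning below-critical to above-critical values on every axis.

The comparison operators in the pseudocode ("== RRref", "!= RRcritical")
are read as interval membership, since the printed reference values are
ranges, not scalars. The personalized critical values are not published;
the defaults (RR ≤5/≥30, HR ≤40/≥140, SBP ≤80/≥220, SpO2 ≤85 one-sided)
follow START/NEWS2-style extreme bands and are per-soldier configurable.

Missing non-HR signs skip their cascade stage; the tag is computed from
the available signs and annotated with the published reliability score
for that sensor subset. A missing HR forces black regardless of the other
sensors. MPA and body position are carried in snapshots and logged but do
not influence the color.

Evacuation ordering: standard mode sorts red < yellow < green, ascending
survival chance within a color (the "most red" red first), unknown
chances after known ones, black after the color queue (it needs on-scene
confirmation before it can be prioritized), blue strictly last; ties
break by earlier timestamp. Reverse (tactical) mode sorts by descending
survival chance with color rank as fallback, blue still last.

## Chance-of-survival function

**Training data.** A full factorial grid over (RR, HR, SBP, SpO2) with
10×12×12×5 = 7200 cases, labeled by the triage cascade itself. Axis
levels are placed on a uniform ladder of the *normalized band deviation*

  z = 0 at the centre of the reference interval, |z| = 1 at the
  reference bounds, |z| = 2 at the critical thresholds,

piecewise-linearly interpolated and extrapolated. Each pair of adjacent
levels that straddles a clinical threshold is symmetric around it, so the
decision boundary a margin classifier learns between those two grid
planes falls on the threshold itself. SpO2 gets the fewest levels because
its scale is one-sided (no upper critical region).

**Classifiers.** Two binary soft-margin SVMs with RBF kernel compose the
ordinal decision: stage A separates red from {yellow, green}; stage B
separates yellow from green and is consulted only when stage A votes
not-red. Both operate on the z-features (which also serve as the feature
scaling — no additional standardisation). Defaults C = 500, γ = 3.0:
the grid labels are a deterministic function of the thresholds and carry
no noise, so the machines are *meant* to interpolate them; C and γ are
chosen large enough for zero training error while keeping the boundary
smooth across the wider inter-level gaps. Training shuffles case order
with the mandatory seed; the fitted model is reduced to its kernel
expansion (support vectors, dual coefficients, intercept) and persisted
as versioned, binary-free JSON.

**Calibration.** The percentage shown inside a band is

  S = lo + σ(m/s + 2·(edge − d_max)) · 2·(hi − lo), clamped to [lo, hi],

where [lo, hi] is the band of the predicted class (red [1, 50], yellow
[51, 99]), σ the logistic, m the deciding stage's decision value, s the
median absolute training margin of that stage (so σ stays responsive
across the training cloud), d_max = max_s |z_s| the case's worst band
deviation and edge the class edge in z (2 for red, 1 for yellow). The
band-deviation term is needed because an RBF decision value saturates far
outside the training cloud and drifts back toward its intercept, which
would let the displayed chance *rise* again as vitals keep deteriorating;
the deviation gradient is monotone by construction and dominates that far
field (weight 2 on the deviation term is the smallest integer weight that
also suppresses ±1 rounding wobble on fine sweeps). Cases the machines
deem green return exactly 100. The survival function is only defined at
100 % reliability; the triage layer enforces this by consulting it only
when all four signs are present.

The class prediction itself never uses the deviation term — it comes
from the machines alone, and the test suite audits it against the triage
oracle both on the training grid (exact agreement required) and on 1000
random off-grid cases (≥ 95 % agreement required).

**What is out of reach.** The published worked example (yellow tag, 74 %
chance) depends on the authors' unpublished fitted model and their
injured-patient simulator; it cannot be reproduced numerically. The
package asserts the reproducible properties instead: band membership of
every output, exact 100 for green, and monotone decay of the chance along
worsening single-sign sweeps.

## Vital-sign extraction

All windows are half-open [start, end) in ms UTC; defaults 10 s for HR,
SBP, SpO2 and activity, 60 s for RR (spectral estimation needs the longer
support; at least 30 s must be available). Extraction is deterministic
for fixed input frames.

- **R-peaks**: band-pass 5–15 Hz (2nd-order Butterworth, zero-phase),
  squared energy with an adaptive threshold at 0.3 of the window maximum,
  250 ms refractory period, peak refinement to the raw-signal extremum
  within ±50 ms. HR = 60000 / mean inter-beat interval; absent with
  fewer than 2 beats in the window.
- **Pulse feet**: the PPG is low-passed at 15 Hz (zero-phase), systolic
  peaks located, and the preceding minimum refined by intersecting
  tangents — a line fit to the late diastolic decay (150–50 ms before
  the minimum) intersected with a line fit to the early upstroke
  (30–90 ms after). The refinement exists because smoothing rounds the
  foot's V-shape and biases a plain argmin toward the shallower
  (diastolic) flank by tens of ms, which a 0.4 mmHg/ms calibration would
  turn into a 5–15 mmHg SBP error.
- **PAT**: for each R-peak, the first foot in (R, R+600 ms]; unmatched
  peaks are skipped. SBP = a·median(PAT) + b with per-soldier (a, b),
  a < 0; absent with fewer than 3 PAT values.
- **SpO2**: R = (AC/DC)_red / (AC/DC)_ir with AC as the standard
  deviation and DC as the mean over the window (any consistent AC
  estimator cancels in the ratio); SpO2 = c0 − c1·R clamped to [0, 100],
  defaults c0 = 110, c1 = 25; absent when a DC vanishes.
- **RR**: periodogram dominant frequency in the 4–60 /min band, absent
  for flat signals or when the band peak is under 10 % of the global
  spectral maximum.
- **MPA / posture**: MPA is the mean magnitude of the per-axis
  mean-removed acceleration over the window. Below 0.1 g the gravity
  direction resolves posture with the declared chest-unit convention
  x = longitudinal (head-ward), y = lateral, z = anterior: dominant ±x ⇒
  upright, +z ⇒ prone, −z ⇒ supine, ±y ⇒ lateral; otherwise "moving".

## Synthetic physiology

The generator emulates the study conditions: a resting soldier at HR 72,
RR 14, SBP 120, SpO2 97, with scenario states ramping linearly to
exertion (115/24/140/96), hemorrhage (150/28/75/88), respiratory failure
(75/34/115/80) or cardiac arrest (flatline ECG). Sampling rates: ECG
250 Hz, PPG 100 Hz, respiration 25 Hz, accelerometer 50 Hz. Default
additive Gaussian noise at 20 dB SNR per channel; different seeds change
the noise, never the truth trajectories.

Waveforms are template-based, chosen for verifiability over
physiological realism:

- ECG: Gaussian R bump (σ = 20 ms) with a small S undershoot, beats
  placed by integrating the instantaneous rate (a beat per integer phase
  crossing, sub-sample interpolated — so encoded beat times are
  continuous, not grid-locked).
- PPG: one pulse per cardiac cycle, quarter-sine systolic rise over the
  first 30 % of the cycle and linear diastolic decay back to zero, so the
  foot is a sharp V both flanks reach with nonzero slope. Feet trail the
  beat train by PAT = (SBP − b)/a and the red/IR AC-to-DC ratio encodes
  R = (c0 − SpO2)/c1, making extraction under the same calibration an
  exact round trip up to noise.
- Respiration: sinusoid at the integrated target rate; accelerometer:
  posture gravity vector plus 2 Hz bursts (0.35 g walk, 0.7 g run) and a
  0.01 g noise floor.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: heart-rate variability and arrhythmia, PPG
morphology changes under vasoconstriction, motion artefacts coupling into
ECG/PPG, baseline wander, electrode contact loss other than hard dropout,
and any hemodynamic coupling between the four vitals beyond the scripted
trajectories. The parameter-recovery tolerances (HR ±2 bpm, RR ±1 /min,
SpO2 ±2 points, SBP ±5 mmHg on clean 60 s streams) are claims about this
synthetic model, not about field performance.

Sensor dropout removes samples in an interval and never alters surviving
samples. Losing one PPG wavelength removes SpO2 but PAT-based SBP
survives on the other; losing both removes SpO2 *and* SBP (the 70 %
reliability variant) — a physical consequence of the PAT design.

## Telemetry and records

Wire format: 0xAA55 sync, version byte, 8-byte soldier id, message type,
16-bit wrapping sequence number, 16-bit payload length, payload,
CRC-16/CCITT-FALSE (poly 0x1021, init 0xFFFF) over header + payload,
big-endian throughout. Decoding rejects short buffers, bad sync,
truncation and any CRC mismatch; the suite checks every single-bit
corruption of a reference frame is detected. The receiver tags a soldier
black after 3 missed reporting periods (configurable) — the black tag
covers communication loss, and some timeout had to be declared.

The TCCC card is an append-only, time-ordered ledger (vitals, automatic
and manual decisions, free-text interventions) with a lossless JSON
round-trip. Decision *events* are emitted downstream only when the color
changes.

## Problem sizes and seeds

The default test and acceptance runs use: the 7200-case grid (training
seed 42 per the model's protocol), 70–300 s scenarios at the default
rates, 1000 Monte-Carlo off-grid cases (seed 7), a 20⁴ oracle grid, and
derandomized property-based tests. The oracle grid and Monte-Carlo sizes
were chosen to exercise every threshold combination while keeping a full
run in the low minutes on a single core.

## Known limitations

- Thresholds are configuration, not clinically validated values; no
  consciousness scoring (ACVPU) or composite early-warning scores.
- The SBP–PAT relation is linear with static per-soldier calibration;
  real PAT–pressure coupling drifts with vasomotor tone.
- The survival percentages are a calibrated ranking device, not
  probabilities estimated from outcomes.
- Transport is emulated in-process; no radio, encryption or real device
  drivers.
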