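# fieldtriage

Decision core for battlefield casualty monitoring: continuous vital-sign
extraction from body-worn biosignals, START-style rule-cascade triage with
degraded-mode reliability scoring, and a calibrated chance-of-survival
function — testable end to end against a built-in casualty simulator with
known ground truth.

It is written for engineers building medical decision-support tooling for
pre-hospital and tactical-evacuation settings, and for researchers who
need a reproducible sandbox in which triage logic, sensor dropout and
score calibration can be audited against exact ground truth rather than
unverifiable field recordings.

## The model

Four vital signs drive the decision, evaluated in fixed priority order —
respiratory rate (RR), heart rate (HR), systolic blood pressure (SBP),
oxygen saturation (SpO2) — against per-soldier reference intervals and
critical thresholds (defaults: RR 9–20/min, HR 50–110/min, SBP
100–180 mmHg, SpO2 ≥ 94 %; critical at RR ≤5/≥30, HR ≤40/≥140,
SBP ≤80/≥220, SpO2 ≤85). Each sign scores a severity

&nbsp;&nbsp;in-reference &lt; out-of-reference &lt; critical,

and because a later sign can never downgrade the tag, the cascade is
exactly the maximum severity over the available signs, mapped to
**green** / **yellow** / **red**. No heart-rate signal at all means
**black** (presumed dead or link lost — must be confirmed on scene);
**blue** (expectant, evacuated last) can only be assigned manually by a
medic or rescuer. When sensors drop out, the tag is computed from the
surviving signs and annotated with a fixed reliability score: 100 % with
all four, 90 % without SpO2, 80 % without SBP or without RR, 70 % with
HR+RR or HR+SBP, 60 % with HR+SpO2, 50 % with HR alone.

The **chance of survival** S ∈ [1, 100] % refines the tag so casualties
sharing a color can be ranked: red spans 1–50 %, yellow 51–99 %, green is
exactly 100 %. Two RBF-kernel support-vector machines are composed
ordinally (red vs not-red, then yellow vs green) and trained on a
7200-case grid (10×12×12×5 over RR×HR×SBP×SpO2) labeled by the cascade
itself; the signed margin of the deciding machine, blended with the
case's normalized band deviation, is squashed into the band of the
predicted class. S is computed only at 100 % reliability.

Upstream, the signal layer recovers the vitals a wearable would measure:
HR from ECG R-peaks, RR from the respiration spectrum, SpO2 from the
red/infrared ratio-of-ratios, and cuffless SBP from pulse arrival time
(PAT) — the delay between each R-peak and the PPG pulse foot — via a
per-soldier linear calibration SBP = a·PAT + b (a &lt; 0). The simulator
synthesizes all channels from scenario timelines (baseline, exertion,
hemorrhage, respiratory failure, cardiac arrest) with the inverse
encodings, so extraction can be audited against exact truth.

## Worked example

`examples/01_triage_basics.py` tags four casualties and orders them:

```
       healthy: green  reliability=100 survival=100 confirm=False
    tachypneic: yellow reliability=100 survival=None confirm=False
         shock: red    reliability=100 survival=None confirm=False
 no ECG signal: black  reliability=None survival=None confirm=True

reliability when only HR+RR survive: 70
after medic override: blue | source: manual
standard evacuation order: ['yellow', 'green', 'blue']
```

The healthy soldier (RR 14, HR 72, SBP 120, SpO2 97) is green with a
100 % survival chance; a single out-of-reference sign (RR 25) yields
yellow; critical HR/SBP yield red; a missing ECG yields black pending
confirmation. The medic's blue override is recorded as manual and sorts
last in the evacuation queue.

`examples/02_survival_model.py` trains the survival function and sweeps
one axis:

```
training grid: 7200 cases
per-color case counts: {'red': 5408, 'yellow': 1696, 'green': 96}
fraction inside label band: 1.0
raw classifier agreement with triage labels: 1.0

chance of survival as RR rises (HR 72, SBP 120, SpO2 97):
  RR 14/min -> 100 %
  RR 22/min ->  74 %
  RR 25/min ->  58 %
  RR 28/min ->  56 %
  RR 31/min ->  34 %
  RR 34/min ->  10 %
```

Every grid case lands inside the band of its triage label, and the
percentage falls monotonically as the derangement deepens — through the
yellow band, then dropping into the red band once RR crosses the critical
threshold at 30/min.

The remaining examples cover signal round-trips (`03`), sensor dropout
(`04`), the telemetry codec and the electronic TCCC casualty card (`05`),
and the full multi-soldier pipeline with the medical board (`06`). A thin
CLI wraps the same functions: `fieldtriage simulate | extract | triage |
train-survival | run-pipeline | report`.

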