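"""Degrade a stream with sensor dropout and watch reliability fall.

Cuts channels out of a clean baseline stream and shows how the triage
decision degrades: one PPG wavelength lost -> SpO2 gone, 90 % reliability;
ECG lost -> no heart rate -> black tag pending confirmation.
"""

from fieldtriage import (
    Channel,
    ReferenceProfile,
    ScenarioSpec,
    Segment,
    generate_scenario,
    inject_dropout,
    snapshot_from_signals,
    triage,
)

spec = ScenarioSpec(soldier_id="s1", seed=7, segments=(Segment(duration_s=90.0),))
stream = generate_scenario(spec)
profile = ReferenceProfile.default("s1")
window = (70_000, 80_000)


def show(label, frames):
    snap = snapshot_from_signals(frames, spec.calibration, window)
    d = triage(snap, profile)
    present = [s for s in ("rr", "hr", "sbp", "spo2") if getattr(snap, s) is not None]
    print(f"{label:>22}: signs={','.join(present) or 'none':<17}"
          f" color={d.color.value:<6} reliability={d.reliability}"
          f" confirm={d.needs_confirmation}")


show("all sensors up", stream.frames)
show("red PPG lost", inject_dropout(stream, [Channel.PPG_RED], (60_000, 90_000)).frames)
show("both PPG lost", inject_dropout(
    stream, [Channel.PPG_RED, Channel.PPG_IR], (60_000, 90_000)).frames)
show("ECG lost", inject_dropout(stream, [Channel.ECG], (60_000, 90_000)).frames)
# Reliability: 100 with all sensors, 90 without SpO2, 70 with HR+RR only,
# and a black tag (needs on-scene confirmation) once the ECG is silent.
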