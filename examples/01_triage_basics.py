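"""Tag casualties with the rule cascade and order them for evacuation.

Builds a few vital-sign snapshots, runs the triage cascade against the
default reference profile, shows the degraded-mode reliability scores and
a manual blue override, then prints both evacuation orders.
"""

from fieldtriage import (
    ReferenceProfile,
    TriageColor,
    VitalSnapshot,
    apply_override,
    evacuation_order,
    reliability_of,
    triage,
)
from fieldtriage.triage import Sign

profile = ReferenceProfile.default("demo")

cases = {
    "healthy": dict(rr=14, hr=72, sbp=120, spo2=97),
    "tachypneic": dict(rr=25, hr=72, sbp=120, spo2=97),  # RR above 9-20 range
    "shock": dict(rr=28, hr=145, sbp=75, spo2=88),  # HR and SBP critical
    "no ECG signal": dict(rr=14, sbp=120, spo2=97),  # HR sensor cut off
}

decisions = []
for name, vitals in cases.items():
    snap = VitalSnapshot(soldier_id="demo", timestamp=len(decisions) * 1000, **vitals)
    d = triage(snap, profile)
    decisions.append(d)
    print(f"{name:>14}: {d.color.value:<6} reliability={d.reliability}"
          f" survival={d.survival_chance} confirm={d.needs_confirmation}")

# Each sensor subset has a fixed published confidence score; without HR
# the system cannot work at all and the soldier is tagged black.
print("\nreliability when only HR+RR survive:", reliability_of({Sign.HR, Sign.RR}))

# Blue (expectant, evacuate last) can only be assigned by medical personnel.
blue = apply_override(decisions[2], TriageColor.BLUE, actor="medic")
print("after medic override:", blue.color.value, "| source:", blue.source)

queue = evacuation_order([decisions[0], decisions[1], blue], mode="standard")
print("standard evacuation order:", [d.color.value for d in queue])
# Expected: yellow before green, blue always last.
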