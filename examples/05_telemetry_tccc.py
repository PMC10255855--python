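"""Frame vitals for the radio link and keep the electronic casualty card.

Encodes snapshots into CRC-protected binary frames, demonstrates
corruption detection and the silence watchdog (black after three missed
reporting periods), and builds a TCCC card with an intervention note and
a manual override in its history.
"""

import json

from fieldtriage import (
    MdtpFrame,
    MessageType,
    SnapshotReceiver,
    TcccCard,
    TriageColor,
    VitalSnapshot,
    apply_override,
    decode_frame,
    encode_frame,
    export_tccc,
    stream_snapshots,
    update_tccc,
)
from fieldtriage.telemetry import IntegrityError
from fieldtriage.triage import ReferenceProfile, triage

snap = VitalSnapshot(soldier_id="s1", timestamp=10_000, rr=14, hr=72, sbp=120, spo2=97)

frames = stream_snapshots([snap])
wire = encode_frame(frames[0])
print(f"vitals frame: {len(wire)} bytes, round-trip ok ->",
      decode_frame(wire) == frames[0])

corrupted = bytearray(wire)
corrupted[-5] ^= 0x01
try:
    decode_frame(bytes(corrupted))
except IntegrityError as e:
    print("single-bit corruption detected:", e)

rx = SnapshotReceiver(period_s=10.0, silence_periods=3)
rx.receive(frames[0])
print("silent for 45 s ->",
      [d.color.value for d in rx.check_silence(now_ms=55_000)])

# TCCC card: append-only ledger of vitals, decisions and interventions.
card = TcccCard(casualty_id="s1", sex="m", birth_date="1995-04-01", weight_kg=82.0)
card = update_tccc(card, snap)
auto = triage(snap, ReferenceProfile.default("s1"))
card = update_tccc(card, auto)
card = update_tccc(card, apply_override(auto, TriageColor.BLUE, "medic"))
card = update_tccc(card, (12_000, "IV access, right arm"))
doc = export_tccc(card)
print("TCCC export:", json.dumps(doc["triage_history"], indent=2))
# History shows the automatic tag first, then the medic's manual blue.
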