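"""Framed telemetry codec, periodic snapshot streaming, and the TCCC ledger.

The wire format is a compact binary frame suitable for a low-rate personal
radio link: a fixed sync marker, version, soldier id, message type, a
wrapping 16-bit sequence number, payload length, payload bytes, and a
CRC-16/CCITT-FALSE over header and payload.  ``decode_frame`` rejects
truncated buffers and any CRC mismatch, so single-bit (and single-byte)
corruption never yields a frame.

:func:`stream_snapshots` emits one vitals frame per reporting period per
soldier and a loss model can drop frames (jamming, terrain masking); the
:class:`SnapshotReceiver` tags a soldier black once the link has been
silent for a configurable number of periods, mirroring the triage rule
that no heart-rate signal means a black tag pending confirmation.

The :class:`TcccCard` is the electronic casualty card: an append-only,
time-ordered ledger of vital snapshots, automatic and manual triage
decisions and free-text intervention notes, exportable as JSON with a
lossless round-trip.
"""

from __future__ import annotations

import enum
import json
import struct
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping

import numpy as np

from fieldtriage.triage import (
    BodyPosition,
    TriageColor,
    TriageDecision,
    VitalSnapshot,
)

__all__ = [
    "MessageType",
    "MdtpFrame",
    "IntegrityError",
    "FramingError",
    "crc16_ccitt",
    "encode_frame",
    "decode_frame",
    "stream_snapshots",
    "SnapshotReceiver",
    "TcccCard",
    "update_tccc",
    "export_tccc",
    "import_tccc",
]

SYNC = b"\xaa\x55"
VERSION = 1
MAX_PAYLOAD = 65535
SOLDIER_ID_BYTES = 8


class MessageType(enum.IntEnum):
    VITALS = 1
    BIOSIGNAL_CHUNK = 2
    TRIAGE = 3
    REQUEST = 4
    ACK = 5


class IntegrityError(ValueError):
    """CRC mismatch: the frame was corrupted in transit."""


class FramingError(ValueError):
    """Buffer too short, bad sync marker, or inconsistent length."""


def crc16_ccitt(data: bytes, crc: int = 0xFFFF) -> int:
    """CRC-16/CCITT-FALSE (poly 0x1021, init 0xFFFF, no reflection)."""
    for byte in data:
        crc ^= byte << 8
        for _ in range(8):
            if crc & 0x8000:
                crc = ((crc << 1) ^ 0x1021) & 0xFFFF
            else:
                crc = (crc << 1) & 0xFFFF
    return crc


@dataclass(frozen=True)
class MdtpFrame:
    """One telemetry message between the body unit and the terminal."""

    soldier_id: str
    message_type: MessageType
    sequence: int  # 16-bit, wraps
    payload: bytes = b""
    version: int = VERSION

    def __post_init__(self) -> None:
        if len(self.payload) > MAX_PAYLOAD:
            raise ValueError("payload exceeds 65535 bytes")
        if not 0 <= self.sequence <= 0xFFFF:
            raise ValueError("sequence must fit in 16 bits")
        if len(self.soldier_id.encode()) > SOLDIER_ID_BYTES:
            raise ValueError(f"soldier_id longer than {SOLDIER_ID_BYTES} bytes")


def encode_frame(frame: MdtpFrame) -> bytes:
    """Serialise a frame: sync | ver | id | type | seq | len | payload | crc."""
    sid = frame.soldier_id.encode().ljust(SOLDIER_ID_BYTES, b"\x00")
    header = SYNC + struct.pack(
        ">B8sBHH",
        frame.version,
        sid,
        int(frame.message_type),
        frame.sequence,
        len(frame.payload),
    )
    body = header + frame.payload
    return body + struct.pack(">H", crc16_ccitt(body))


_HEADER_LEN = 2 + 1 + SOLDIER_ID_BYTES + 1 + 2 + 2
_CRC_LEN = 2


def decode_frame(buf: bytes) -> MdtpFrame:
    """Parse and verify one frame; raises on truncation or corruption."""
    if len(buf) < _HEADER_LEN + _CRC_LEN:
        raise FramingError(f"buffer too short ({len(buf)} bytes)")
    if buf[:2] != SYNC:
        raise FramingError("bad sync marker")
    version, sid, mtype, seq, plen = struct.unpack(">B8sBHH", buf[2:_HEADER_LEN])
    total = _HEADER_LEN + plen + _CRC_LEN
    if len(buf) < total:
        raise FramingError(
            f"truncated frame: need {total} bytes, got {len(buf)}"
        )
    body = buf[:_HEADER_LEN + plen]
    (crc,) = struct.unpack(">H", buf[_HEADER_LEN + plen:total])
    if crc16_ccitt(body) != crc:
        raise IntegrityError("CRC mismatch")
    try:
        message_type = MessageType(mtype)
    except ValueError:
        raise FramingError(f"unknown message type {mtype}") from None
    return MdtpFrame(
        soldier_id=sid.rstrip(b"\x00").decode(),
        message_type=message_type,
        sequence=seq,
        payload=bytes(buf[_HEADER_LEN:_HEADER_LEN + plen]),
        version=version,
    )


# -- snapshot payloads ----------------------------------------------------

def snapshot_to_payload(snap: VitalSnapshot) -> bytes:
    doc = {
        "soldier_id": snap.soldier_id,
        "timestamp": snap.timestamp,
        "rr": snap.rr,
        "hr": snap.hr,
        "sbp": snap.sbp,
        "spo2": snap.spo2,
        "mpa": snap.mpa,
        "body_position": snap.body_position.value if snap.body_position else None,
    }
    return json.dumps(doc, separators=(",", ":")).encode()


def payload_to_snapshot(payload: bytes) -> VitalSnapshot:
    doc = json.loads(payload.decode())
    pos = doc.get("body_position")
    return VitalSnapshot(
        soldier_id=doc["soldier_id"],
        timestamp=int(doc["timestamp"]),
        rr=doc.get("rr"),
        hr=doc.get("hr"),
        sbp=doc.get("sbp"),
        spo2=doc.get("spo2"),
        mpa=doc.get("mpa"),
        body_position=BodyPosition(pos) if pos else None,
    )


def stream_snapshots(
    snapshots: Iterable[VitalSnapshot],
    loss_model: Callable[[int], bool] | None = None,
    loss_rate: float = 0.0,
    loss_seed: int = 0,
) -> list[MdtpFrame]:
    """Frame a sequence of periodic snapshots, dropping lost ones.

    ``loss_model(i)`` returns True when frame i is lost; alternatively an
    i.i.d. Bernoulli ``loss_rate`` with ``loss_seed`` is applied.  Sequence
    numbers count every *sent* frame (so the receiver can observe gaps) and
    wrap at 16 bits.
    """
    if loss_model is None:
        rng = np.random.default_rng(loss_seed)

        def loss_model(i: int, _rng=rng) -> bool:
            return bool(_rng.random() < loss_rate)

    out = []
    for i, snap in enumerate(snapshots):
        if loss_model(i):
            continue
        out.append(
            MdtpFrame(
                soldier_id=snap.soldier_id,
                message_type=MessageType.VITALS,
                sequence=i & 0xFFFF,
                payload=snapshot_to_payload(snap),
            )
        )
    return out


class SnapshotReceiver:
    """Terminal-side state: latest snapshot per soldier + silence watchdog.

    After ``silence_periods`` reporting periods without a frame from a
    soldier, :meth:`check_silence` emits a black decision (no heart-rate
    signal reaching the terminal), pending confirmation on scene.
    """

    def __init__(self, period_s: float, silence_periods: int = 3) -> None:
        if period_s <= 0:
            raise ValueError("period must be > 0")
        self.period_ms = period_s * 1000.0
        self.silence_periods = silence_periods
        self.last_seen_ms: dict[str, float] = {}
        self.latest: dict[str, VitalSnapshot] = {}

    def receive(self, frame: MdtpFrame) -> VitalSnapshot | None:
        if frame.message_type is not MessageType.VITALS:
            return None
        snap = payload_to_snapshot(frame.payload)
        self.last_seen_ms[snap.soldier_id] = float(snap.timestamp)
        self.latest[snap.soldier_id] = snap
        return snap

    def check_silence(self, now_ms: float) -> list[TriageDecision]:
        """Black decisions for every soldier silent beyond the timeout."""
        out = []
        timeout = self.silence_periods * self.period_ms
        for sid, last in self.last_seen_ms.items():
            if now_ms - last > timeout:
                out.append(
                    TriageDecision(
                        soldier_id=sid,
                        timestamp=int(now_ms),
                        color=TriageColor.BLACK,
                        needs_confirmation=True,
                    )
                )
        return out


# -- TCCC electronic casualty card ----------------------------------------

@dataclass(frozen=True)
class TcccCard:
    """Append-only electronic casualty record.

    Entries are kept time-ordered; triage history never shrinks; the
    current tag is the latest history entry.
    """

    casualty_id: str
    sex: str | None = None
    birth_date: str | None = None
    weight_kg: float | None = None
    vitals: tuple[VitalSnapshot, ...] = ()
    triage_history: tuple[TriageDecision, ...] = ()
    notes: tuple[tuple[int, str], ...] = ()  # (timestamp ms, text)

    @property
    def latest_triage(self) -> TriageDecision | None:
        return self.triage_history[-1] if self.triage_history else None

    def _last_timestamp(self) -> int:
        ts = [v.timestamp for v in self.vitals]
        ts += [d.timestamp for d in self.triage_history]
        ts += [t for t, _ in self.notes]
        return max(ts) if ts else -1


class StaleEventError(ValueError):
    """Event timestamp precedes the last ledger entry."""


def update_tccc(
    card: TcccCard, event: VitalSnapshot | TriageDecision | tuple[int, str]
) -> TcccCard:
    """Append one event to the casualty card (pure: returns a new card).

    Accepts a vital snapshot, a triage decision, or a ``(timestamp, text)``
    intervention note.  Out-of-order events are rejected: the ledger is
    append-only and time-ordered.
    """
    if isinstance(event, VitalSnapshot):
        ts = event.timestamp
    elif isinstance(event, TriageDecision):
        ts = event.timestamp
    elif isinstance(event, tuple):
        ts = event[0]
    else:
        raise TypeError(f"unsupported event type {type(event).__name__}")
    if ts < card._last_timestamp():
        raise StaleEventError(
            f"event at {ts} ms is older than the last ledger entry"
        )
    if isinstance(event, VitalSnapshot):
        return replace(card, vitals=card.vitals + (event,))
    if isinstance(event, TriageDecision):
        return replace(card, triage_history=card.triage_history + (event,))
    return replace(card, notes=card.notes + (event,))


def export_tccc(card: TcccCard) -> dict:
    """Serialise the card to a JSON-ready document (lossless round-trip)."""
    return {
        "format": "tccc-card",
        "version": 1,
        "casualty_id": card.casualty_id,
        "demographics": {
            "sex": card.sex,
            "birth_date": card.birth_date,
            "weight_kg": card.weight_kg,
        },
        "vitals": [json.loads(snapshot_to_payload(v)) for v in card.vitals],
        "triage_history": [d.to_event() for d in card.triage_history],
        "notes": [{"timestamp": t, "text": s} for t, s in card.notes],
    }


def import_tccc(doc: Mapping) -> TcccCard:
    if doc.get("format") != "tccc-card":
        raise ValueError("not a TCCC card document")
    demo = doc.get("demographics", {})
    return TcccCard(
        casualty_id=doc["casualty_id"],
        sex=demo.get("sex"),
        birth_date=demo.get("birth_date"),
        weight_kg=demo.get("weight_kg"),
        vitals=tuple(
            payload_to_snapshot(json.dumps(v).encode()) for v in doc.get("vitals", [])
        ),
        triage_history=tuple(
            TriageDecision.from_event(d) for d in doc.get("triage_history", [])
        ),
        notes=tuple((n["timestamp"], n["text"]) for n in doc.get("notes", [])),
    )
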