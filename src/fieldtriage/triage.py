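"""START-style triage cascade with degraded-mode reliability scores.

The decision core tags each casualty with a color computed from four vital
signs — respiratory rate (RR), heart rate (HR), systolic blood pressure
(SBP) and oxygen saturation (SpO2) — compared against per-soldier reference
intervals and critical thresholds:

* **green** — every available sign inside its reference interval; no
  assistance needed, chance of survival 100 %;
* **yellow** — at least one sign outside its reference interval but none in
  the critical region; second evacuation priority;
* **red** — at least one sign at or beyond a critical threshold; immediate
  evacuation;
* **black** — no heart-rate signal at all (sensor cut-off or death); must be
  confirmed by a medic on scene;
* **blue** — assigned *manually only*, for casualties with minimal chance of
  survival; evacuated last (reverse-triage doctrine).

Signs are evaluated in the fixed priority order RR, HR, SBP, SpO2 and the
color can never be downgraded by a later sign, which makes the cascade
exactly the maximum per-sign severity.  When sensors drop out the color is
computed from the surviving signs and annotated with a reliability
percentage from a fixed table; the chance-of-survival function is attached
only at 100 % reliability.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "Sign",
    "Severity",
    "TriageColor",
    "BodyPosition",
    "SignRange",
    "VitalSnapshot",
    "ReferenceProfile",
    "TriageDecision",
    "severity_of",
    "triage",
    "reliability_of",
    "apply_override",
    "evacuation_order",
    "BLACK_SIGNAL",
    "RELIABILITY_TABLE",
]


class Sign(str, enum.Enum):
    """The four vital signs used by the cascade, in priority order."""

    RR = "rr"
    HR = "hr"
    SBP = "sbp"
    SPO2 = "spo2"


#: Cascade evaluation order: RR first (fastest responder), SpO2 last
#: (least credible).
SIGN_PRIORITY: tuple[Sign, ...] = (Sign.RR, Sign.HR, Sign.SBP, Sign.SPO2)


class Severity(enum.IntEnum):
    """Per-sign severity; the triage color is the maximum over signs."""

    IN_REFERENCE = 0
    OUT_OF_REFERENCE = 1
    CRITICAL = 2


class TriageColor(str, enum.Enum):
    GREEN = "green"
    YELLOW = "yellow"
    RED = "red"
    BLACK = "black"
    BLUE = "blue"


_SEVERITY_TO_COLOR = {
    Severity.IN_REFERENCE: TriageColor.GREEN,
    Severity.OUT_OF_REFERENCE: TriageColor.YELLOW,
    Severity.CRITICAL: TriageColor.RED,
}


class BodyPosition(str, enum.Enum):
    UPRIGHT = "upright"
    SUPINE = "supine"
    PRONE = "prone"
    LATERAL = "lateral"
    MOVING = "moving"


class ConfigurationError(ValueError):
    """Unknown sign or inconsistent threshold configuration."""


class PermissionError_(PermissionError):
    """Actor lacks the medical role required for a manual override."""


@dataclass(frozen=True)
class SignRange:
    """Reference interval plus critical thresholds for one vital sign.

    ``crit_lo < ref_lo <= ref_hi < crit_hi``; either critical bound may be
    ``None`` for one-sided signs (SpO2 has no upper critical threshold).
    """

    ref_lo: float
    ref_hi: float
    crit_lo: float | None = None
    crit_hi: float | None = None

    def __post_init__(self) -> None:
        if not self.ref_lo <= self.ref_hi:
            raise ConfigurationError(
                f"reference interval inverted: [{self.ref_lo}, {self.ref_hi}]"
            )
        if self.crit_lo is not None and not self.crit_lo < self.ref_lo:
            raise ConfigurationError("crit_lo must lie below ref_lo")
        if self.crit_hi is not None and not self.ref_hi < self.crit_hi:
            raise ConfigurationError("crit_hi must lie above ref_hi")


# Typical reference intervals (printed defaults) plus critical thresholds.
# Reference: RR 9–20/min, HR 50–110/min, SBP 100–180 mmHg, SpO2 >= 94 %.
# Critical bands follow START/NEWS2-style extremes and are per-soldier
# configurable; SpO2 is one-sided low.
DEFAULT_RANGES: Mapping[Sign, SignRange] = {
    Sign.RR: SignRange(ref_lo=9.0, ref_hi=20.0, crit_lo=5.0, crit_hi=30.0),
    Sign.HR: SignRange(ref_lo=50.0, ref_hi=110.0, crit_lo=40.0, crit_hi=140.0),
    Sign.SBP: SignRange(ref_lo=100.0, ref_hi=180.0, crit_lo=80.0, crit_hi=220.0),
    Sign.SPO2: SignRange(ref_lo=94.0, ref_hi=100.0, crit_lo=85.0, crit_hi=None),
}


@dataclass(frozen=True)
class ReferenceProfile:
    """Per-soldier reference intervals and critical thresholds."""

    soldier_id: str
    ranges: Mapping[Sign, SignRange] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )

    def range_for(self, sign: Sign) -> SignRange:
        try:
            return self.ranges[sign]
        except KeyError:
            raise ConfigurationError(f"no reference range configured for {sign}")

    @classmethod
    def default(cls, soldier_id: str = "anonymous") -> "ReferenceProfile":
        return cls(soldier_id=soldier_id)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ReferenceProfile":
        """Build from a plain mapping (YAML/JSON config)."""
        ranges = {}
        for key, rng in d.get("ranges", {}).items():
            sign = Sign(key.lower())
            ranges[sign] = SignRange(
                ref_lo=float(rng["ref_lo"]),
                ref_hi=float(rng["ref_hi"]),
                crit_lo=None if rng.get("crit_lo") is None else float(rng["crit_lo"]),
                crit_hi=None if rng.get("crit_hi") is None else float(rng["crit_hi"]),
            )
        merged = dict(DEFAULT_RANGES)
        merged.update(ranges)
        return cls(soldier_id=str(d["soldier_id"]), ranges=merged)


@dataclass(frozen=True)
class VitalSnapshot:
    """One windowed set of vital-sign values for one soldier.

    Any sign may be ``None`` (sensor dropout); present values must be finite
    and positive, SpO2 in (0, 100].  ``mpa`` (mean physical activity, g) and
    ``body_position`` are carried for situational awareness but do not enter
    the color decision.
    """

    soldier_id: str
    timestamp: int  # ms UTC
    rr: float | None = None
    hr: float | None = None
    sbp: float | None = None
    spo2: float | None = None
    mpa: float | None = None
    body_position: BodyPosition | None = None

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise ValueError("timestamp must be >= 0")
        for name in ("rr", "hr", "sbp", "spo2"):
            v = getattr(self, name)
            if v is None:
                continue
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        if self.spo2 is not None and self.spo2 > 100:
            raise ValueError(f"spo2 must be in (0, 100], got {self.spo2!r}")

    def value_of(self, sign: Sign) -> float | None:
        return getattr(self, sign.value)

    @property
    def available_signs(self) -> frozenset[Sign]:
        return frozenset(s for s in Sign if self.value_of(s) is not None)


@dataclass(frozen=True)
class TriageDecision:
    """A triage outcome: color, reliability, optional survival chance."""

    soldier_id: str
    timestamp: int
    color: TriageColor
    reliability: int | None = None
    survival_chance: int | None = None
    source: str = "automatic"  # "automatic" | "manual"
    needs_confirmation: bool = False
    history: tuple["TriageDecision", ...] = ()

    def __post_init__(self) -> None:
        if self.color is TriageColor.BLUE and self.source != "manual":
            raise ValueError("blue may only be assigned manually")
        if self.color is TriageColor.BLACK and not self.needs_confirmation:
            raise ValueError("black decisions require confirmation")
        if self.survival_chance is not None:
            if self.reliability != 100:
                raise ValueError("survival chance only defined at 100% reliability")
            if self.color not in (TriageColor.GREEN, TriageColor.YELLOW, TriageColor.RED):
                raise ValueError("survival chance only defined for green/yellow/red")
            if self.color is TriageColor.GREEN and self.survival_chance != 100:
                raise ValueError("green implies survival chance 100")
            if not 1 <= self.survival_chance <= 100:
                raise ValueError("survival chance must be in [1, 100]")

    def to_event(self) -> dict:
        """Flat JSON-serialisable event record."""
        return {
            "soldier_id": self.soldier_id,
            "timestamp": self.timestamp,
            "color": self.color.value,
            "reliability": self.reliability,
            "survival_chance": self.survival_chance,
            "source": self.source,
            "needs_confirmation": self.needs_confirmation,
        }

    @classmethod
    def from_event(cls, d: Mapping) -> "TriageDecision":
        return cls(
            soldier_id=d["soldier_id"],
            timestamp=int(d["timestamp"]),
            color=TriageColor(d["color"]),
            reliability=d.get("reliability"),
            survival_chance=d.get("survival_chance"),
            source=d.get("source", "automatic"),
            needs_confirmation=bool(d.get("needs_confirmation", False)),
        )


def severity_of(value: float, sign: Sign, profile: ReferenceProfile) -> Severity:
    """Classify one measurement against its reference/critical bands.

    ``IN_REFERENCE`` iff the value lies inside the closed reference
    interval, ``CRITICAL`` iff it reaches a critical threshold
    (``value <= crit_lo`` or ``value >= crit_hi`` where defined),
    ``OUT_OF_REFERENCE`` otherwise.
    """
    if not isinstance(sign, Sign):
        sign = Sign(sign)
    if not math.isfinite(value) or value <= 0:
        raise ValueError(f"measurement must be finite and > 0, got {value!r}")
    rng = profile.range_for(sign)
    if rng.crit_lo is not None and value <= rng.crit_lo:
        return Severity.CRITICAL
    if rng.crit_hi is not None and value >= rng.crit_hi:
        return Severity.CRITICAL
    if rng.ref_lo <= value <= rng.ref_hi:
        return Severity.IN_REFERENCE
    return Severity.OUT_OF_REFERENCE


class _BlackSignal:
    """Sentinel: no heart-rate signal — the system cannot triage."""

    def __repr__(self) -> str:  # pragma: no cover
        return "BLACK_SIGNAL"


BLACK_SIGNAL = _BlackSignal()

#: Reliability of the degraded-mode cascade as a function of which sensors
#: delivered data.  HR is mandatory; without it the soldier is tagged black.
RELIABILITY_TABLE: Mapping[frozenset, int] = {
    frozenset({Sign.RR, Sign.HR, Sign.SBP, Sign.SPO2}): 100,
    frozenset({Sign.HR, Sign.RR, Sign.SBP}): 90,
    frozenset({Sign.HR, Sign.RR, Sign.SPO2}): 80,
    frozenset({Sign.HR, Sign.RR}): 70,
    frozenset({Sign.HR, Sign.SBP, Sign.SPO2}): 80,
    frozenset({Sign.HR, Sign.SBP}): 70,
    frozenset({Sign.HR, Sign.SPO2}): 60,
    frozenset({Sign.HR}): 50,
}


def reliability_of(available: Iterable[Sign]):
    """Reliability percentage for a sensor-availability set.

    Returns an ``int`` percent for the 8 subsets containing HR, or
    :data:`BLACK_SIGNAL` when HR is absent (the system does not work
    regardless of the other sensors).
    """
    avail = frozenset(Sign(s) for s in available)
    if Sign.HR not in avail:
        return BLACK_SIGNAL
    return RELIABILITY_TABLE[avail]


def triage(
    snapshot: VitalSnapshot,
    profile: ReferenceProfile,
    survival_fn: Callable[[VitalSnapshot], int] | None = None,
) -> TriageDecision:
    """Run the triage cascade on one snapshot.

    If HR is absent the casualty is tagged black (confirmation required).
    Otherwise each available sign is scored by :func:`severity_of` in
    priority order RR, HR, SBP, SpO2 with no downgrade — equivalently the
    color maps the maximum severity — and the decision is annotated with the
    reliability of the surviving sensor set.  ``survival_fn`` (typically a
    trained :class:`~fieldtriage.survival.SurvivalModel`) is consulted only
    at 100 % reliability; green always maps to 100 %.
    """
    if snapshot.soldier_id != profile.soldier_id:
        raise ValueError(
            f"snapshot for {snapshot.soldier_id!r} does not match profile "
            f"{profile.soldier_id!r}"
        )
    available = snapshot.available_signs
    rel = reliability_of(available)
    if rel is BLACK_SIGNAL:
        return TriageDecision(
            soldier_id=snapshot.soldier_id,
            timestamp=snapshot.timestamp,
            color=TriageColor.BLACK,
            reliability=None,
            needs_confirmation=True,
        )

    worst = Severity.IN_REFERENCE
    for sign in SIGN_PRIORITY:
        value = snapshot.value_of(sign)
        if value is None:
            continue  # dropped sensor: this cascade stage is skipped
        sev = severity_of(value, sign, profile)
        if sev > worst:
            worst = sev
    color = _SEVERITY_TO_COLOR[worst]

    survival: int | None = None
    if rel == 100:
        if color is TriageColor.GREEN:
            survival = 100
        elif survival_fn is not None:
            survival = int(survival_fn(snapshot))
    return TriageDecision(
        soldier_id=snapshot.soldier_id,
        timestamp=snapshot.timestamp,
        color=color,
        reliability=rel,
        survival_chance=survival,
    )


MEDICAL_ROLES = frozenset({"medic", "rescuer"})
OVERRIDABLE_COLORS = frozenset(
    {TriageColor.GREEN, TriageColor.YELLOW, TriageColor.RED, TriageColor.BLUE}
)


def apply_override(
    decision: TriageDecision, new_color: TriageColor, actor: str
) -> TriageDecision:
    """Manual re-tagging by medical personnel.

    Blue can *only* enter the system through this operation.  The previous
    decision is preserved in ``history``.  Actors outside the medical roles
    (medic, rescuer) are rejected.
    """
    if actor not in MEDICAL_ROLES:
        raise PermissionError_(
            f"actor {actor!r} is not authorised to override triage decisions"
        )
    new_color = TriageColor(new_color)
    if new_color not in OVERRIDABLE_COLORS:
        raise ValueError(f"cannot manually assign color {new_color.value!r}")
    return replace(
        decision,
        color=new_color,
        source="manual",
        needs_confirmation=False,
        survival_chance=decision.survival_chance
        if new_color is decision.color
        else None,
        history=decision.history + (replace(decision, history=()),),
    )


_STANDARD_RANK = {
    TriageColor.RED: 0,
    TriageColor.YELLOW: 1,
    TriageColor.GREEN: 2,
    TriageColor.BLACK: 3,  # pending confirmation, listed after the queue
    TriageColor.BLUE: 4,  # always last
}

_REVERSE_LIGHTNESS = {
    TriageColor.GREEN: 0,
    TriageColor.YELLOW: 1,
    TriageColor.RED: 2,
    TriageColor.BLACK: 3,
    TriageColor.BLUE: 4,
}


def evacuation_order(
    casualties: Sequence[TriageDecision], mode: str = "standard"
) -> list[TriageDecision]:
    """Order casualties by evacuation priority.

    ``standard``: red before yellow before green; within a color the lower
    survival chance goes first (the "more red" of the reds); black is
    appended after the queue pending confirmation and blue is always last.
    ``reverse`` (tactical reverse triage): lightest first — descending
    survival chance, greens before yellows before reds when chances are
    unknown; blue still last.  Ties break by earlier timestamp.
    """
    if mode not in ("standard", "reverse"):
        raise ValueError(f"unknown evacuation mode {mode!r}")

    def standard_key(d: TriageDecision):
        chance = d.survival_chance if d.survival_chance is not None else 101
        return (_STANDARD_RANK[d.color], chance, d.timestamp)

    def reverse_key(d: TriageDecision):
        if d.color in (TriageColor.BLACK, TriageColor.BLUE):
            return (1, _REVERSE_LIGHTNESS[d.color], 0, d.timestamp)
        chance = d.survival_chance if d.survival_chance is not None else -1
        return (0, -chance, _REVERSE_LIGHTNESS[d.color], d.timestamp)

    key = standard_key if mode == "standard" else reverse_key
    return sorted(casualties, key=key)
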