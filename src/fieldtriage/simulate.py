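"""Seeded generator of multichannel casualty biosignal streams.

Stands in for live soldiers (and for the high-fidelity injured-patient
simulator such systems are trained against): every scenario produces ECG,
red/IR PPG, respiration and 3-axis acceleration frames *plus* the exact
ground-truth vital-sign trajectories that were encoded, so extraction and
triage can be audited end to end.

Waveforms are template-based — a Gaussian-bump QRS train, beta-shaped PPG
pulses whose feet trail each R-peak by the pulse arrival time implied by
the target SBP, a respiration sinusoid and a gravity-plus-burst
accelerometer model — with additive Gaussian noise (default 20 dB SNR).
Verifiability is preferred over physiological realism: the encoded
quantities (rates, PAT, red/IR absorbance ratio) are exactly the ones the
extraction stage estimates.

A scenario is an ordered list of segments (baseline, exertion, hemorrhage,
respiratory failure, cardiac arrest), each ramping the four vitals linearly
to its target values; hemorrhage, for instance, drives HR up while SBP and
SpO2 fall.  Sensor dropout is injected afterwards by cutting samples out of
chosen channels, which downstream appears as missing signs and degraded
triage reliability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from fieldtriage.signals import (
    BiosignalFrame,
    CalibrationRecord,
    Channel,
    DEFAULT_RATES,
)
from fieldtriage.triage import BodyPosition

__all__ = [
    "Segment",
    "ScenarioSpec",
    "GeneratedStream",
    "STATE_TARGETS",
    "synth_ecg",
    "synth_ppg_pair",
    "synth_resp_acc",
    "generate_scenario",
    "inject_dropout",
]

#: Default end-of-segment vital targets per scenario state:
#: (HR bpm, RR /min, SBP mmHg, SpO2 %).
STATE_TARGETS: Mapping[str, tuple[float, float, float, float]] = {
    "baseline": (72.0, 14.0, 120.0, 97.0),
    "exertion": (115.0, 24.0, 140.0, 96.0),
    "hemorrhage": (150.0, 28.0, 75.0, 88.0),
    "respiratory_failure": (75.0, 34.0, 115.0, 80.0),
    "cardiac_arrest": (0.0, 4.5, 50.0, 60.0),
}

_POSTURE_GRAVITY: Mapping[BodyPosition, np.ndarray] = {
    BodyPosition.UPRIGHT: np.array([1.0, 0.0, 0.0]),
    BodyPosition.LATERAL: np.array([0.0, 1.0, 0.0]),
    BodyPosition.PRONE: np.array([0.0, 0.0, 1.0]),
    BodyPosition.SUPINE: np.array([0.0, 0.0, -1.0]),
}

_ACTIVITY_AMP_G = {"still": 0.0, "walk": 0.35, "run": 0.7}

DEFAULT_SNR_DB = 20.0


@dataclass(frozen=True)
class Segment:
    """One scenario phase: ramp vitals linearly to the segment-end targets.

    Omitted targets fall back to the state's defaults in
    :data:`STATE_TARGETS`.
    """

    duration_s: float
    state: str = "baseline"
    hr: float | None = None
    rr: float | None = None
    sbp: float | None = None
    spo2: float | None = None
    posture: BodyPosition = BodyPosition.UPRIGHT
    activity: str = "still"

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("segment duration must be > 0")
        if self.state not in STATE_TARGETS:
            raise ValueError(f"unknown scenario state {self.state!r}")
        if self.activity not in _ACTIVITY_AMP_G:
            raise ValueError(f"unknown activity label {self.activity!r}")
        if not isinstance(self.posture, BodyPosition):
            object.__setattr__(self, "posture", BodyPosition(self.posture))

    def targets(self) -> tuple[float, float, float, float]:
        d_hr, d_rr, d_sbp, d_spo2 = STATE_TARGETS[self.state]
        hr = d_hr if self.hr is None else self.hr
        rr = d_rr if self.rr is None else self.rr
        sbp = d_sbp if self.sbp is None else self.sbp
        spo2 = d_spo2 if self.spo2 is None else self.spo2
        if not (0 <= hr <= 250):
            raise ValueError(f"HR target {hr} outside [0, 250]")
        if not (0 < spo2 <= 100):
            raise ValueError(f"SpO2 target {spo2} outside (0, 100]")
        if not (0 < rr < 60):
            raise ValueError(f"RR target {rr} outside (0, 60)")
        if not (0 < sbp < 300):
            raise ValueError(f"SBP target {sbp} outside (0, 300)")
        return hr, rr, sbp, spo2


@dataclass(frozen=True)
class ScenarioSpec:
    """A soldier's injury timeline plus generator settings."""

    soldier_id: str
    seed: int
    segments: tuple[Segment, ...]
    snr_db: float = DEFAULT_SNR_DB
    calibration: CalibrationRecord | None = None
    start_time_ms: int = 0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("scenario needs at least one segment")
        segs = tuple(
            s if isinstance(s, Segment) else Segment(**s) for s in self.segments
        )
        object.__setattr__(self, "segments", segs)
        if self.calibration is None:
            object.__setattr__(
                self, "calibration", CalibrationRecord(soldier_id=self.soldier_id)
            )

    @property
    def duration_s(self) -> float:
        return sum(s.duration_s for s in self.segments)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioSpec":
        cal = d.get("calibration")
        return cls(
            soldier_id=str(d["soldier_id"]),
            seed=int(d["seed"]),
            segments=tuple(Segment(**s) for s in d["segments"]),
            snr_db=float(d.get("snr_db", DEFAULT_SNR_DB)),
            calibration=CalibrationRecord(**cal) if cal else None,
            start_time_ms=int(d.get("start_time_ms", 0)),
        )


def _piecewise_targets(spec: ScenarioSpec, t: np.ndarray) -> np.ndarray:
    """(n, 4) per-time HR/RR/SBP/SpO2 trajectory, linear ramp per segment.

    The first segment holds its targets from t=0 (no ramp-in); each later
    segment ramps linearly from the previous segment's end values.
    """
    knots_t = [0.0]
    knots_v = [np.asarray(spec.segments[0].targets(), float)]
    acc = 0.0
    for seg in spec.segments:
        acc += seg.duration_s
        knots_t.append(acc)
        knots_v.append(np.asarray(seg.targets(), float))
    knots_t = np.asarray(knots_t)
    knots_v = np.stack(knots_v)
    out = np.empty((t.size, 4))
    for j in range(4):
        out[:, j] = np.interp(t, knots_t, knots_v[:, j])
    return out


def _beat_times_s(hr_bpm: np.ndarray, fs: float) -> np.ndarray:
    """Beat instants from an instantaneous-rate trajectory (phase method).

    A beat fires each time the integrated phase crosses an integer; zero
    rate (arrest) produces no beats.  Crossing instants are linearly
    interpolated between samples, so beat times are continuous rather than
    grid-locked.  Shared between the ECG and PPG synthesisers so their
    beat trains coincide.
    """
    phase = np.cumsum(hr_bpm / 60.0) / fs
    k = np.floor(phase)
    idx = np.flatnonzero(np.diff(k) > 0) + 1
    if idx.size == 0:
        return np.array([])
    targets = k[idx]  # the integer each crossing reaches
    p0 = phase[idx - 1]
    p1 = phase[idx]
    frac = np.where(p1 > p0, (targets - p0) / (p1 - p0), 0.0)
    return (idx - 1 + frac) / fs


def _add_noise(x: np.ndarray, rng: np.random.Generator, snr_db: float) -> np.ndarray:
    p_sig = float(np.mean((x - np.mean(x)) ** 2))
    if p_sig <= 0 or not np.isfinite(snr_db):
        return x
    sigma = np.sqrt(p_sig / 10.0 ** (snr_db / 10.0))
    return x + rng.normal(0.0, sigma, size=x.shape)


def synth_ecg(
    hr_trajectory: float | np.ndarray,
    fs: float = DEFAULT_RATES[Channel.ECG],
    duration_s: float | None = None,
    seed: int = 0,
    start_time_ms: int = 0,
    snr_db: float = DEFAULT_SNR_DB,
) -> tuple[BiosignalFrame, np.ndarray]:
    """Synthesise a template-QRS ECG; returns the frame and true R times (ms).

    ``hr_trajectory`` is either a scalar rate (then ``duration_s`` is
    required) or a per-sample array of instantaneous bpm.  Rates must lie in
    (20, 250) bpm or be exactly zero (cardiac arrest: flatline).
    """
    if np.isscalar(hr_trajectory):
        if duration_s is None:
            raise ValueError("duration_s required with a scalar rate")
        hr = np.full(int(round(duration_s * fs)), float(hr_trajectory))
    else:
        hr = np.asarray(hr_trajectory, float)
    if np.any(hr < 0):
        raise ValueError("heart rate cannot be negative")
    if np.any((hr > 0) & (hr <= 20)) or np.any(hr >= 250):
        raise ValueError("nonzero heart rate must lie in (20, 250) bpm")
    rng = np.random.default_rng(seed)
    n = hr.size
    t = np.arange(n) / fs
    beats_s = _beat_times_s(hr, fs)

    x = np.zeros(n)
    qrs_width_s = 0.02
    for b in beats_s:
        # Gaussian R bump with a small S undershoot just after it
        lo = max(0, int((b - 0.08) * fs))
        hi = min(n, int((b + 0.12) * fs))
        tt = t[lo:hi] - b
        x[lo:hi] += 1.0 * np.exp(-(tt**2) / (2 * qrs_width_s**2))
        x[lo:hi] -= 0.25 * np.exp(-((tt - 0.05) ** 2) / (2 * (1.5 * qrs_width_s) ** 2))
    x = _add_noise(x, rng, snr_db)
    frame = BiosignalFrame(
        channel=Channel.ECG, sampling_rate=fs, start_time=start_time_ms, samples=x
    )
    return frame, start_time_ms + beats_s * 1000.0


_RISE_FRAC = 0.3


def _pulse_shape(u: np.ndarray) -> np.ndarray:
    """One PPG pulse over a cardiac cycle, u in [0, 1); foot at u = 0.

    Quarter-sine systolic upstroke over the first 30 % of the cycle, then a
    linear diastolic decay back to zero.  Both flanks arrive at the foot
    with nonzero slope, so the cycle minimum is a sharp V that beat
    detectors can localise precisely even in noise.
    """
    u = np.asarray(u, float)
    rise = np.sin(0.5 * np.pi * np.clip(u, 0, _RISE_FRAC) / _RISE_FRAC)
    decay = 1.0 - np.clip((u - _RISE_FRAC) / (1.0 - _RISE_FRAC), 0.0, 1.0)
    return np.where((u >= 0) & (u < 1), np.where(u < _RISE_FRAC, rise, decay), 0.0)


_PULSE_PEAK = 1.0


def synth_ppg_pair(
    hr_trajectory: np.ndarray,
    sbp_trajectory: np.ndarray,
    spo2_trajectory: np.ndarray,
    fs: float = DEFAULT_RATES[Channel.PPG_RED],
    cal: CalibrationRecord | None = None,
    seed: int = 0,
    start_time_ms: int = 0,
    snr_db: float = DEFAULT_SNR_DB,
    ir_perfusion: float = 0.05,
) -> tuple[BiosignalFrame, BiosignalFrame]:
    """Dual-wavelength PPG whose feet and amplitudes encode SBP and SpO2.

    Pulse feet trail the (shared-phase) beat train by
    ``PAT = (SBP - b) / a`` from the calibration record, and the red/IR
    AC-over-DC ratio is set to ``R = (c0 - SpO2)/c1``, so extraction under
    the same calibration recovers the encoded targets.
    """
    hr = np.asarray(hr_trajectory, float)
    sbp = np.asarray(sbp_trajectory, float)
    spo2 = np.asarray(spo2_trajectory, float)
    if not (hr.size == sbp.size == spo2.size):
        raise ValueError("trajectory lengths are inconsistent")
    cal = cal or CalibrationRecord(soldier_id="synthetic")
    rng = np.random.default_rng(seed)
    n = hr.size
    t = np.arange(n) / fs

    beats_s = _beat_times_s(hr, fs)
    idx = np.minimum((beats_s * fs).astype(int), n - 1)
    pat_s = cal.pat_for_sbp(sbp[idx]) / 1000.0
    feet_s = beats_s + pat_s

    # normalised pulse train: one beta-shaped pulse per foot-to-foot cycle
    pulse = np.zeros(n)
    for k in range(len(feet_s)):
        f0 = feet_s[k]
        f1 = feet_s[k + 1] if k + 1 < len(feet_s) else f0 + (
            feet_s[k] - feet_s[k - 1] if k > 0 else 1.0
        )
        lo, hi = int(np.ceil(f0 * fs)), min(n, int(np.ceil(f1 * fs)))
        if hi <= lo:
            continue
        u = (t[lo:hi] - f0) / (f1 - f0)
        pulse[lo:hi] = _pulse_shape(u) / _PULSE_PEAK

    ratio = cal.ratio_for_spo2(spo2)
    dc = 1.0
    ir_ac = ir_perfusion
    ir_samples = dc + ir_ac * pulse
    red_samples = dc + ir_ac * ratio * pulse
    ir_samples = _add_noise(ir_samples, rng, snr_db)
    red_samples = _add_noise(red_samples, rng, snr_db)
    red = BiosignalFrame(
        channel=Channel.PPG_RED, sampling_rate=fs, start_time=start_time_ms,
        samples=red_samples,
    )
    ir = BiosignalFrame(
        channel=Channel.PPG_IR, sampling_rate=fs, start_time=start_time_ms,
        samples=ir_samples,
    )
    return red, ir


def synth_resp_acc(
    rr_trajectory: np.ndarray,
    posture_labels: Sequence[BodyPosition] | BodyPosition,
    activity_labels: Sequence[str] | str = "still",
    fs_resp: float = DEFAULT_RATES[Channel.RESP],
    fs_acc: float = DEFAULT_RATES[Channel.ACC3],
    duration_s: float | None = None,
    seed: int = 0,
    start_time_ms: int = 0,
    snr_db: float = DEFAULT_SNR_DB,
) -> tuple[BiosignalFrame, BiosignalFrame]:
    """Respiration sinusoid at the target rate + gravity/activity ACC frames.

    ``rr_trajectory`` is per-resp-sample breaths/min in (4, 60); posture and
    activity are either constants or per-acc-sample label arrays.
    """
    rr = np.asarray(rr_trajectory, float)
    if np.any((rr <= 4) | (rr >= 60)):
        raise ValueError("respiratory rate must lie in (4, 60) breaths/min")
    rng = np.random.default_rng(seed)
    duration = duration_s if duration_s is not None else rr.size / fs_resp

    phase = 2 * np.pi * np.cumsum(rr / 60.0) / fs_resp
    resp_samples = _add_noise(np.sin(phase), rng, snr_db)
    resp = BiosignalFrame(
        channel=Channel.RESP, sampling_rate=fs_resp, start_time=start_time_ms,
        samples=resp_samples,
    )

    n_acc = int(round(duration * fs_acc))
    if isinstance(posture_labels, (BodyPosition, str)):
        posture_labels = [BodyPosition(posture_labels)] * n_acc
    if isinstance(activity_labels, str):
        activity_labels = [activity_labels] * n_acc
    if len(posture_labels) != n_acc or len(activity_labels) != n_acc:
        raise ValueError("label arrays must match the ACC sample count")
    acc = np.empty((n_acc, 3))
    t_acc = np.arange(n_acc) / fs_acc
    for i, (pos, act) in enumerate(zip(posture_labels, activity_labels)):
        pos = BodyPosition(pos)
        if pos not in _POSTURE_GRAVITY:
            raise ValueError(f"posture label {pos!r} has no gravity convention")
        try:
            amp = _ACTIVITY_AMP_G[act]
        except KeyError:
            raise ValueError(f"unknown activity label {act!r}") from None
        g = _POSTURE_GRAVITY[pos]
        burst = amp * np.sin(2 * np.pi * 2.0 * t_acc[i]) * np.array([1.0, 0.6, 0.8])
        acc[i] = g + burst
    acc += rng.normal(0.0, 0.01, size=acc.shape)  # sensor noise floor, g
    acc_frame = BiosignalFrame(
        channel=Channel.ACC3, sampling_rate=fs_acc, start_time=start_time_ms,
        samples=acc,
    )
    return resp, acc_frame


@dataclass
class GeneratedStream:
    """All channels of one simulated soldier plus the encoded ground truth.

    ``truth`` is a per-second table (time_s, hr, rr, sbp, spo2, state,
    posture, activity); ``events`` logs state changes and injected dropouts.
    """

    spec: ScenarioSpec
    frames: dict[Channel, list[BiosignalFrame]]
    truth: pd.DataFrame
    true_r_peaks_ms: np.ndarray
    events: list[dict] = field(default_factory=list)

    def truth_at(self, t_ms: float) -> pd.Series:
        i = int(np.clip((t_ms - self.spec.start_time_ms) / 1000.0, 0, len(self.truth) - 1))
        return self.truth.iloc[i]


def generate_scenario(spec: ScenarioSpec) -> GeneratedStream:
    """Render a full multichannel stream from a scenario timeline."""
    rng = np.random.default_rng(spec.seed)
    seeds = rng.integers(0, 2**31 - 1, size=4)
    duration = spec.duration_s
    t0 = spec.start_time_ms

    fs_ecg = DEFAULT_RATES[Channel.ECG]
    fs_ppg = DEFAULT_RATES[Channel.PPG_RED]
    fs_resp = DEFAULT_RATES[Channel.RESP]
    fs_acc = DEFAULT_RATES[Channel.ACC3]

    t_ecg = np.arange(int(round(duration * fs_ecg))) / fs_ecg
    t_ppg = np.arange(int(round(duration * fs_ppg))) / fs_ppg
    t_resp = np.arange(int(round(duration * fs_resp))) / fs_resp
    t_acc = np.arange(int(round(duration * fs_acc))) / fs_acc

    targ_ecg = _piecewise_targets(spec, t_ecg)
    targ_ppg = _piecewise_targets(spec, t_ppg)
    targ_resp = _piecewise_targets(spec, t_resp)

    ecg, r_peaks_ms = synth_ecg(
        targ_ecg[:, 0], fs=fs_ecg, seed=int(seeds[0]), start_time_ms=t0,
        snr_db=spec.snr_db,
    )
    red, ir = synth_ppg_pair(
        targ_ppg[:, 0], targ_ppg[:, 2], targ_ppg[:, 3], fs=fs_ppg,
        cal=spec.calibration, seed=int(seeds[1]), start_time_ms=t0,
        snr_db=spec.snr_db,
    )

    # per-acc-sample posture/activity labels from the segment timeline
    bounds = np.cumsum([s.duration_s for s in spec.segments])
    seg_idx_acc = np.searchsorted(bounds, t_acc, side="right")
    seg_idx_acc = np.minimum(seg_idx_acc, len(spec.segments) - 1)
    postures = [spec.segments[i].posture for i in seg_idx_acc]
    activities = [spec.segments[i].activity for i in seg_idx_acc]
    resp, acc = synth_resp_acc(
        targ_resp[:, 1], postures, activities, fs_resp=fs_resp, fs_acc=fs_acc,
        duration_s=duration, seed=int(seeds[2]), start_time_ms=t0,
        snr_db=spec.snr_db,
    )

    t_truth = np.arange(int(np.ceil(duration)))
    targ_truth = _piecewise_targets(spec, t_truth.astype(float))
    seg_idx = np.minimum(np.searchsorted(bounds, t_truth, side="right"),
                         len(spec.segments) - 1)
    truth = pd.DataFrame(
        {
            "time_s": t_truth,
            "hr": targ_truth[:, 0],
            "rr": targ_truth[:, 1],
            "sbp": targ_truth[:, 2],
            "spo2": targ_truth[:, 3],
            "state": [spec.segments[i].state for i in seg_idx],
            "posture": [spec.segments[i].posture.value for i in seg_idx],
            "activity": [spec.segments[i].activity for i in seg_idx],
        }
    )
    events = []
    acc_t = 0.0
    for seg in spec.segments:
        events.append(
            {"time_ms": t0 + acc_t * 1000.0, "event": "state", "state": seg.state}
        )
        acc_t += seg.duration_s
    return GeneratedStream(
        spec=spec,
        frames={
            Channel.ECG: [ecg],
            Channel.PPG_RED: [red],
            Channel.PPG_IR: [ir],
            Channel.RESP: [resp],
            Channel.ACC3: [acc],
        },
        truth=truth,
        true_r_peaks_ms=r_peaks_ms,
        events=events,
    )


def inject_dropout(
    stream: GeneratedStream,
    channels: Sequence[Channel],
    interval_ms: tuple[float, float],
) -> GeneratedStream:
    """Cut the samples of the named channels inside [start, end) ms.

    Returns a new stream; surviving samples are bit-identical to the
    original (dropout removes data, it never distorts it).  The truth event
    log gains one annotation per dropped channel.
    """
    start, end = interval_ms
    if not end > start:
        raise ValueError("dropout interval must have positive length")
    channels = [Channel(c) for c in channels]
    for c in channels:
        if c not in stream.frames:
            raise ValueError(f"unknown channel {c!r}")
    new_frames: dict[Channel, list[BiosignalFrame]] = {}
    for ch, frames in stream.frames.items():
        if ch not in channels:
            new_frames[ch] = list(frames)
            continue
        kept: list[BiosignalFrame] = []
        for f in frames:
            before = f.slice_window(f.start_time, start)
            after = f.slice_window(end, f.end_time)
            kept.extend(p for p in (before, after) if p is not None)
        new_frames[ch] = kept
    events = stream.events + [
        {"time_ms": start, "event": "dropout", "channel": c.value,
         "until_ms": end}
        for c in channels
    ]
    return replace(stream, frames=new_frames, events=events)
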