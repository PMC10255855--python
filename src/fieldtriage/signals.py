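"""Vital-sign extraction from raw body-worn biosignal frames.

This module plays the role of the on-body measurement computer: it turns
sampled channels (ECG, red/infrared PPG, respiration, 3-axis acceleration)
into windowed :class:`~fieldtriage.triage.VitalSnapshot` values.

* **HR** — R-peak detection (band-pass 5–15 Hz + adaptive threshold with a
  250 ms refractory period), then 60000 / mean RR-interval in the window.
* **SBP** — cuffless, from pulse arrival time (PAT): the delay between each
  ECG R-peak and the next PPG pulse foot.  PAT shortens as systolic
  pressure rises; a per-soldier linear calibration SBP = a*PAT + b (a < 0)
  converts the windowed median PAT to mmHg.
* **SpO2** — ratio-of-ratios pulse oximetry: R = (AC/DC)_red / (AC/DC)_ir,
  SpO2 = c0 - c1*R with a per-soldier (c0, c1) calibration curve.
* **RR** — dominant spectral frequency of the respiration channel in the
  4–60 breaths/min band.
* **MPA / posture** — mean magnitude of high-pass-filtered acceleration;
  when quasi-static (< 0.1 g) the gravity direction resolves body position
  (longitudinal => upright, anterior => prone, posterior => supine,
  lateral => lateral), otherwise "moving".

Windows are half-open ``[start, end)`` in ms; missing channels simply yield
missing signs, which the triage engine handles as degraded modes.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from fieldtriage.triage import BodyPosition, VitalSnapshot

__all__ = [
    "Channel",
    "BiosignalFrame",
    "BeatSeries",
    "CalibrationRecord",
    "detect_r_peaks",
    "detect_pulse_feet",
    "hr_from_beats",
    "pat_series",
    "sbp_from_pat",
    "spo2_from_ppg",
    "rr_from_resp",
    "activity_and_posture",
    "snapshot_from_signals",
]


class Channel(str, enum.Enum):
    ECG = "ecg"
    PPG_RED = "ppg_red"
    PPG_IR = "ppg_ir"
    RESP = "resp"
    ACC3 = "acc3"


#: Default sampling rates, Hz.
DEFAULT_RATES: Mapping[Channel, float] = {
    Channel.ECG: 250.0,
    Channel.PPG_RED: 100.0,
    Channel.PPG_IR: 100.0,
    Channel.RESP: 25.0,
    Channel.ACC3: 50.0,
}

#: Default analysis windows, seconds.
SHORT_WINDOW_S = 10.0  # HR, SBP, SpO2, activity
RR_WINDOW_S = 60.0  # respiratory rate needs a longer spectral window

REFRACTORY_MS = 250.0
PAT_MAX_MS = 600.0


@dataclass(frozen=True)
class BiosignalFrame:
    """One contiguous sampled segment of a single channel.

    ``samples`` is a 1-D float array, except for ACC3 where it is (n, 3)
    in g-units.  ``start_time`` is ms UTC.
    """

    channel: Channel
    sampling_rate: float
    start_time: int
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        arr = np.asarray(self.samples, dtype=float)
        if arr.size == 0:
            raise ValueError("samples must be non-empty")
        if self.channel is Channel.ACC3:
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError("ACC3 samples must be (n, 3) triples")
        elif arr.ndim != 1:
            raise ValueError("samples must be a 1-D sequence")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples must be finite")
        object.__setattr__(self, "samples", arr)

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_ms(self) -> float:
        return self.n / self.sampling_rate * 1000.0

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration_ms

    @property
    def times_ms(self) -> np.ndarray:
        return self.start_time + np.arange(self.n) / self.sampling_rate * 1000.0

    def slice_window(self, start_ms: float, end_ms: float) -> "BiosignalFrame | None":
        """Samples in [start_ms, end_ms); None if empty."""
        i0 = max(0, int(math.ceil((start_ms - self.start_time) * self.sampling_rate / 1000.0)))
        i1 = min(self.n, int(math.ceil((end_ms - self.start_time) * self.sampling_rate / 1000.0)))
        if i1 <= i0:
            return None
        return BiosignalFrame(
            channel=self.channel,
            sampling_rate=self.sampling_rate,
            start_time=int(self.start_time + i0 / self.sampling_rate * 1000.0),
            samples=self.samples[i0:i1],
        )

    # -- text I/O: CSV body + JSON sidecar header -------------------------
    def to_csv(self, path: str | Path) -> None:
        t = self.times_ms
        if self.channel is Channel.ACC3:
            df = pd.DataFrame(
                {"time_ms": t, "x": self.samples[:, 0], "y": self.samples[:, 1], "z": self.samples[:, 2]}
            )
        else:
            df = pd.DataFrame({"time_ms": t, "value": self.samples})
        df.to_csv(path, index=False)
        meta = {
            "channel": self.channel.value,
            "sampling_rate": self.sampling_rate,
            "start_time": self.start_time,
            "n_samples": self.n,
        }
        Path(str(path) + ".json").write_text(json.dumps(meta))

    @classmethod
    def from_csv(cls, path: str | Path) -> "BiosignalFrame":
        meta = json.loads(Path(str(path) + ".json").read_text())
        df = pd.read_csv(path)
        channel = Channel(meta["channel"])
        if channel is Channel.ACC3:
            samples = df[["x", "y", "z"]].to_numpy()
        else:
            samples = df["value"].to_numpy()
        return cls(
            channel=channel,
            sampling_rate=float(meta["sampling_rate"]),
            start_time=int(meta["start_time"]),
            samples=samples,
        )


@dataclass(frozen=True)
class BeatSeries:
    """Strictly increasing event times (ms) of R-peaks or pulse feet."""

    times_ms: np.ndarray
    source: Channel

    def __post_init__(self) -> None:
        arr = np.asarray(self.times_ms, dtype=float)
        if arr.size and np.any(np.diff(arr) <= 0):
            raise ValueError("beat times must be strictly increasing")
        object.__setattr__(self, "times_ms", arr)

    def __len__(self) -> int:
        return self.times_ms.size

    def in_window(self, start_ms: float, end_ms: float) -> np.ndarray:
        t = self.times_ms
        return t[(t >= start_ms) & (t < end_ms)]


@dataclass(frozen=True)
class CalibrationRecord:
    """Per-soldier calibration for cuffless SBP and the SpO2 curve.

    ``sbp_slope`` (mmHg/ms, negative: longer PAT means lower pressure) and
    ``sbp_intercept`` define SBP = slope * PAT + intercept.  ``spo2_c0`` and
    ``spo2_c1`` define SpO2 = c0 - c1 * R from the red/IR absorbance ratio.
    """

    soldier_id: str
    sbp_slope: float = -0.4
    sbp_intercept: float = 220.0
    spo2_c0: float = 110.0
    spo2_c1: float = 25.0

    def __post_init__(self) -> None:
        if self.sbp_slope >= 0:
            raise ValueError("sbp_slope must be negative")
        if self.spo2_c1 <= 0:
            raise ValueError("spo2_c1 must be positive")

    def pat_for_sbp(self, sbp: float) -> float:
        """Inverse map, used by the waveform generator: PAT in ms."""
        return (sbp - self.sbp_intercept) / self.sbp_slope

    def ratio_for_spo2(self, spo2: float) -> float:
        return (self.spo2_c0 - spo2) / self.spo2_c1


def _require_channel(frame: BiosignalFrame, allowed: Iterable[Channel]) -> None:
    allowed = tuple(allowed)
    if frame.channel not in allowed:
        names = "/".join(c.value for c in allowed)
        raise ValueError(f"expected {names} frame, got {frame.channel.value}")


def detect_r_peaks(ecg: BiosignalFrame) -> BeatSeries:
    """Locate QRS complexes in an ECG frame.

    Band-pass 5–15 Hz isolates the QRS energy, the squared signal is
    thresholded adaptively and a 250 ms refractory period suppresses
    double-triggering.  Needs at least 2 s of signal.
    """
    _require_channel(ecg, [Channel.ECG])
    if ecg.duration_ms < 2000:
        raise ValueError("ECG frame shorter than 2 s")
    fs = ecg.sampling_rate
    x = ecg.samples - np.mean(ecg.samples)
    nyq = fs / 2.0
    hi = min(15.0, 0.9 * nyq)
    sos = sps.butter(2, [5.0 / nyq, hi / nyq], btype="band", output="sos")
    filt = sps.sosfiltfilt(sos, x)
    energy = filt**2
    thresh = 0.3 * np.max(energy)
    if thresh <= 0 or np.max(energy) < 1e-12:
        return BeatSeries(times_ms=np.array([]), source=Channel.ECG)
    distance = max(1, int(round(REFRACTORY_MS / 1000.0 * fs)))
    idx, _ = sps.find_peaks(energy, height=thresh, distance=distance)
    # refine each detection to the local extremum of the raw signal
    half = max(1, int(round(0.05 * fs)))
    refined = []
    for i in idx:
        lo, hi_i = max(0, i - half), min(ecg.n, i + half + 1)
        refined.append(lo + int(np.argmax(np.abs(x[lo:hi_i]))))
    refined = np.unique(refined)
    times = ecg.start_time + refined / fs * 1000.0
    # enforce refractory after refinement
    keep = [0] if times.size else []
    for j in range(1, times.size):
        if times[j] - times[keep[-1]] >= REFRACTORY_MS:
            keep.append(j)
    return BeatSeries(times_ms=times[keep] if len(keep) else np.array([]), source=Channel.ECG)


def detect_pulse_feet(ppg: BiosignalFrame) -> BeatSeries:
    """Locate the foot of each PPG pulse.

    The foot is the local minimum immediately preceding the systolic
    upstroke; one foot per cardiac cycle.
    """
    _require_channel(ppg, [Channel.PPG_RED, Channel.PPG_IR])
    fs = ppg.sampling_rate
    x = np.asarray(ppg.samples, float)
    ac = x - np.mean(x)
    amp = np.max(ac) - np.min(ac)
    if amp < 1e-9:
        return BeatSeries(times_ms=np.array([]), source=ppg.channel)
    # smooth before the minimum search: the foot is a local feature and
    # wideband noise would drag the argmin up the shallow diastolic flank
    nyq = fs / 2.0
    sos = sps.butter(2, min(15.0, 0.8 * nyq) / nyq, output="sos")
    sm = sps.sosfiltfilt(sos, ac)
    distance = max(1, int(round(REFRACTORY_MS / 1000.0 * fs)))
    peaks, _ = sps.find_peaks(sm, height=0.3 * np.max(sm), distance=distance)
    feet_t = []
    search = int(round(0.4 * fs))  # look back up to 400 ms for the foot
    for p in peaks:
        lo = max(0, p - search)
        seg = sm[lo:p + 1]
        if seg.size < 2:
            continue
        m0 = lo + int(np.argmin(seg))
        feet_t.append(_refine_foot(sm, m0, fs))
    feet_t = sorted(set(feet_t))
    # enforce strict increase / refractory on the refined times
    kept: list[float] = []
    for t in feet_t:
        if not kept or t - kept[-1] >= REFRACTORY_MS / 1000.0:
            kept.append(t)
    times = ppg.start_time + np.asarray(kept, float) * 1000.0
    return BeatSeries(times_ms=times, source=ppg.channel)


def _refine_foot(sm: np.ndarray, m0: int, fs: float) -> float:
    """Sub-sample foot time (s) by intersecting tangents around index m0.

    A line is fitted to the late diastolic decay just before the raw
    minimum and another to the early systolic upstroke just after it; their
    intersection restores the sharp foot that smoothing rounds off (and
    biases toward the shallower flank).  Falls back to m0 when either fit
    is degenerate.
    """
    n = sm.size
    d0 = max(0, m0 - int(round(0.15 * fs)))
    d1 = max(0, m0 - int(round(0.05 * fs)))
    r0 = min(n - 1, m0 + int(round(0.03 * fs)))
    r1 = min(n, m0 + int(round(0.09 * fs)))
    if d1 - d0 >= 2 and r1 - r0 >= 2:
        td = np.arange(d0, d1) / fs
        tr = np.arange(r0, r1) / fs
        a1, b1 = np.polyfit(td, sm[d0:d1], 1)
        a2, b2 = np.polyfit(tr, sm[r0:r1], 1)
        if a2 > a1:  # upstroke steeper than decay: well-posed intersection
            t_x = (b1 - b2) / (a2 - a1)
            if abs(t_x - m0 / fs) <= 0.08:
                return float(t_x)
    return m0 / fs


def hr_from_beats(beats: BeatSeries, window: tuple[float, float]) -> float | None:
    """Heart rate in bpm from mean inter-beat interval; None if < 2 beats."""
    t = beats.in_window(*window)
    if t.size < 2:
        return None
    mean_ibi = float(np.mean(np.diff(t)))
    return 60000.0 / mean_ibi


def pat_series(r_peaks: BeatSeries, feet: BeatSeries) -> np.ndarray:
    """Pulse arrival times (ms): first pulse foot within 600 ms after each R.

    R-peaks with no matching foot are skipped; feet preceding the first
    R-peak never match.
    """
    out = []
    ft = feet.times_ms
    for r in r_peaks.times_ms:
        after = ft[(ft > r) & (ft <= r + PAT_MAX_MS)]
        if after.size:
            out.append(after[0] - r)
    return np.asarray(out, float)


def sbp_from_pat(pat_values: Sequence[float], cal: CalibrationRecord) -> float | None:
    """Systolic pressure from the windowed median PAT; None if < 3 values."""
    pat = np.asarray(pat_values, float)
    if pat.size < 3:
        return None
    return float(cal.sbp_slope * np.median(pat) + cal.sbp_intercept)


def _ac_dc(x: np.ndarray) -> tuple[float, float]:
    dc = float(np.mean(x))
    ac = float(np.std(x - dc))
    return ac, dc


def spo2_from_ppg(
    red: BiosignalFrame,
    ir: BiosignalFrame,
    window: tuple[float, float],
    cal: CalibrationRecord,
) -> float | None:
    """SpO2 by ratio-of-ratios over the window; None when DC vanishes."""
    _require_channel(red, [Channel.PPG_RED])
    _require_channel(ir, [Channel.PPG_IR])
    r_win = red.slice_window(*window)
    ir_win = ir.slice_window(*window)
    if r_win is None or ir_win is None:
        return None
    ac_r, dc_r = _ac_dc(r_win.samples)
    ac_ir, dc_ir = _ac_dc(ir_win.samples)
    if abs(dc_r) < 1e-9 or abs(dc_ir) < 1e-9 or ac_ir < 1e-12:
        return None
    R = (ac_r / dc_r) / (ac_ir / dc_ir)
    return float(np.clip(cal.spo2_c0 - cal.spo2_c1 * R, 0.0, 100.0))


def rr_from_resp(resp: BiosignalFrame, window: tuple[float, float]) -> float | None:
    """Respiratory rate (breaths/min) as the dominant spectral peak.

    Valid band 4–60 breaths/min; requires >= 30 s of signal in the window.
    Returns None for flat signals or when no convincing peak lies in band.
    """
    _require_channel(resp, [Channel.RESP])
    win = resp.slice_window(*window)
    if win is None or win.n / win.sampling_rate < 30.0:
        return None
    x = win.samples - np.mean(win.samples)
    if np.std(x) < 1e-9:
        return None
    fs = win.sampling_rate
    nfft = max(4096, 1 << int(np.ceil(np.log2(win.n * 4))))
    freqs, psd = sps.periodogram(x, fs=fs, nfft=nfft)
    band = (freqs >= 4.0 / 60.0) & (freqs <= 60.0 / 60.0)
    if not np.any(band):
        return None
    psd_band = psd[band]
    total = float(np.sum(psd))
    if total <= 0 or float(np.max(psd_band)) < 0.1 * float(np.max(psd)):
        return None
    f_peak = freqs[band][int(np.argmax(psd_band))]
    return float(f_peak * 60.0)


MPA_MOVING_THRESHOLD_G = 0.1

# Chest-unit axis convention: x = longitudinal (toward the head),
# y = lateral (toward the left arm), z = anterior (out of the chest).
_POSTURE_AXES = {
    (0, +1): BodyPosition.UPRIGHT,
    (0, -1): BodyPosition.UPRIGHT,  # head-down is still along the long axis
    (1, +1): BodyPosition.LATERAL,
    (1, -1): BodyPosition.LATERAL,
    (2, +1): BodyPosition.PRONE,  # gravity out of the chest: face down
    (2, -1): BodyPosition.SUPINE,
}


def activity_and_posture(
    acc: BiosignalFrame, window: tuple[float, float]
) -> tuple[float, BodyPosition]:
    """Mean physical activity (g) and body position from 3-axis acceleration.

    MPA is the mean magnitude of the dynamic (mean-removed per axis)
    acceleration.  When MPA < 0.1 g the posture follows the dominant gravity
    axis; otherwise the soldier is "moving".
    """
    _require_channel(acc, [Channel.ACC3])
    win = acc.slice_window(*window)
    if win is None or win.n / win.sampling_rate < 2.0:
        raise ValueError("need at least 2 s of acceleration in the window")
    a = win.samples
    gravity = np.mean(a, axis=0)
    dynamic = a - gravity
    mpa = float(np.mean(np.linalg.norm(dynamic, axis=1)))
    if mpa >= MPA_MOVING_THRESHOLD_G:
        return mpa, BodyPosition.MOVING
    axis = int(np.argmax(np.abs(gravity)))
    sign = 1 if gravity[axis] >= 0 else -1
    return mpa, _POSTURE_AXES[(axis, sign)]


def snapshot_from_signals(
    frames: Mapping[Channel, BiosignalFrame | Sequence[BiosignalFrame]],
    cal: CalibrationRecord,
    window: tuple[float, float],
    soldier_id: str | None = None,
    rr_window_s: float = RR_WINDOW_S,
) -> VitalSnapshot:
    """Assemble a :class:`VitalSnapshot` from whatever channels are present.

    ``window`` is the half-open [start, end) ms interval used for HR, SBP,
    SpO2 and activity; respiratory rate uses a longer window of
    ``rr_window_s`` seconds ending at the same instant.  Channels missing
    from ``frames`` (or empty in the window — sensor dropout) yield missing
    signs, which downstream triage treats as degraded modes.
    """
    start, end = window
    if not end > start:
        raise ValueError("window must have positive length")

    def get(channel: Channel, win: tuple[float, float]) -> BiosignalFrame | None:
        entry = frames.get(channel)
        if entry is None:
            return None
        if isinstance(entry, BiosignalFrame):
            entry = [entry]
        pieces = [f.slice_window(*win) for f in entry]
        pieces = [p for p in pieces if p is not None]
        if not pieces:
            return None
        if len(pieces) == 1:
            return pieces[0]
        # keep the longest contiguous piece; extraction never bridges gaps
        return max(pieces, key=lambda p: p.n)

    hr = sbp = spo2 = rr = mpa = None
    posture = None

    ecg = get(Channel.ECG, (start, end))
    r_peaks = None
    if ecg is not None and ecg.duration_ms >= 2000:
        r_peaks = detect_r_peaks(ecg)
        hr = hr_from_beats(r_peaks, (start, end))

    red = get(Channel.PPG_RED, (start, end))
    ir = get(Channel.PPG_IR, (start, end))
    if red is not None and ir is not None:
        spo2 = spo2_from_ppg(red, ir, (start, end), cal)
    if r_peaks is not None and ir is not None:
        feet = detect_pulse_feet(ir)
        pats = pat_series(r_peaks, feet)
        sbp = sbp_from_pat(pats, cal)

    resp = get(Channel.RESP, (end - rr_window_s * 1000.0, end))
    if resp is not None:
        rr = rr_from_resp(resp, (end - rr_window_s * 1000.0, end))

    # guard against non-physical estimates from degenerate windows
    if sbp is not None and sbp <= 0:
        sbp = None
    if spo2 is not None and spo2 <= 0:
        spo2 = None

    acc = get(Channel.ACC3, (start, end))
    if acc is not None and acc.n / acc.sampling_rate >= 2.0:
        mpa, posture = activity_and_posture(acc, (start, end))

    return VitalSnapshot(
        soldier_id=soldier_id or cal.soldier_id,
        timestamp=int(end),
        rr=rr,
        hr=hr,
        sbp=sbp,
        spo2=spo2,
        mpa=mpa,
        body_position=posture,
    )
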