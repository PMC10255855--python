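"""Vital-sign extraction: beat detection, PAT->SBP, SpO2, RR, posture."""

import numpy as np
import pytest

from fieldtriage.signals import (
    BeatSeries,
    BiosignalFrame,
    CalibrationRecord,
    Channel,
    activity_and_posture,
    detect_pulse_feet,
    detect_r_peaks,
    hr_from_beats,
    pat_series,
    rr_from_resp,
    sbp_from_pat,
    snapshot_from_signals,
    spo2_from_ppg,
)
from fieldtriage.simulate import synth_ecg
from fieldtriage.triage import BodyPosition, ReferenceProfile, TriageColor, triage

CAL = CalibrationRecord(soldier_id="s1")


def frame(channel, fs, samples, t0=0):
    return BiosignalFrame(
        channel=channel, sampling_rate=fs, start_time=t0, samples=np.asarray(samples)
    )


class TestFrames:
    def test_rejects_empty_and_nonfinite_samples(self):
        with pytest.raises(ValueError):
            frame(Channel.ECG, 250, [])
        with pytest.raises(ValueError):
            frame(Channel.ECG, 250, [1.0, np.nan])

    def test_acc_frames_need_triples(self):
        with pytest.raises(ValueError, match="triples"):
            frame(Channel.ACC3, 50, np.zeros(100))

    def test_csv_round_trip(self, tmp_path):
        f = frame(Channel.RESP, 25, np.sin(np.arange(100) / 10), t0=5000)
        f.to_csv(tmp_path / "resp.csv")
        back = BiosignalFrame.from_csv(tmp_path / "resp.csv")
        assert back.channel is Channel.RESP
        assert back.start_time == 5000
        np.testing.assert_allclose(back.samples, f.samples, atol=1e-9)


class TestRPeaks:
    def test_clean_60_bpm_30_s_yields_30_peaks(self):
        ecg, truth = synth_ecg(60.0, fs=250, duration_s=30, seed=1)
        beats = detect_r_peaks(ecg)
        assert abs(len(beats) - 30) <= 1
        assert np.all(np.diff(beats.times_ms) > 0)

    def test_flatline_yields_no_peaks(self):
        flat = frame(Channel.ECG, 250, np.zeros(2500))
        assert len(detect_r_peaks(flat)) == 0

    def test_noisy_ecg_hr_within_2_bpm(self):
        ecg, _ = synth_ecg(80.0, fs=250, duration_s=30, seed=3, snr_db=10)
        beats = detect_r_peaks(ecg)
        hr = hr_from_beats(beats, (0, 30_000))
        assert abs(hr - 80.0) <= 2.0

    def test_wrong_channel_rejected(self):
        ppg = frame(Channel.PPG_IR, 100, np.sin(np.arange(1000) / 10))
        with pytest.raises(ValueError, match="ecg"):
            detect_r_peaks(ppg)

    def test_refractory_period_enforced(self):
        ecg, _ = synth_ecg(240.0, fs=250, duration_s=10, seed=0)
        beats = detect_r_peaks(ecg)
        assert np.all(np.diff(beats.times_ms) >= 250.0)


class TestHrFromBeats:
    def test_metronome_1000_ms(self):
        beats = BeatSeries(np.arange(0, 10_000, 1000.0), Channel.ECG)
        assert hr_from_beats(beats, (0, 10_000)) == pytest.approx(60.0)

    def test_750_ms_interval_gives_80(self):
        beats = BeatSeries(np.arange(0, 9_000, 750.0), Channel.ECG)
        assert hr_from_beats(beats, (0, 9_000)) == pytest.approx(80.0, abs=1.0)

    def test_fewer_than_two_beats_is_absent(self):
        beats = BeatSeries(np.array([500.0]), Channel.ECG)
        assert hr_from_beats(beats, (0, 10_000)) is None


class TestPat:
    def test_constant_offset_recovered(self):
        peaks = BeatSeries(np.arange(0, 10_000, 1000.0), Channel.ECG)
        feet = BeatSeries(peaks.times_ms + 250.0, Channel.PPG_IR)
        np.testing.assert_allclose(pat_series(peaks, feet), 250.0)

    def test_foot_before_first_peak_ignored(self):
        peaks = BeatSeries(np.array([1000.0, 2000.0]), Channel.ECG)
        feet = BeatSeries(np.array([500.0, 1250.0, 2250.0]), Channel.PPG_IR)
        np.testing.assert_allclose(pat_series(peaks, feet), [250.0, 250.0])

    def test_unmatched_peak_skipped_and_values_bounded(self):
        peaks = BeatSeries(np.array([0.0, 1000.0, 5000.0]), Channel.ECG)
        feet = BeatSeries(np.array([250.0, 1250.0]), Channel.PPG_IR)
        pats = pat_series(peaks, feet)
        assert len(pats) == 2
        assert np.all((pats > 0) & (pats <= 600))


class TestSbp:
    @pytest.mark.parametrize("pat,expected", [(250.0, 120.0), (200.0, 140.0)])
    def test_linear_calibration(self, pat, expected):
        assert sbp_from_pat([pat] * 5, CAL) == pytest.approx(expected)

    def test_too_few_values_absent(self):
        assert sbp_from_pat([250.0, 250.0], CAL) is None

    def test_calibration_slope_must_be_negative(self):
        with pytest.raises(ValueError):
            CalibrationRecord(soldier_id="x", sbp_slope=0.4)


class TestSpo2:
    def _pair(self, ratio, fs=100, n=1000):
        pulse = 0.5 * (1 + np.sin(np.arange(n) / fs * 2 * np.pi))
        ir = frame(Channel.PPG_IR, fs, 1.0 + 0.05 * pulse)
        red = frame(Channel.PPG_RED, fs, 1.0 + 0.05 * ratio * pulse)
        return red, ir

    @pytest.mark.parametrize("ratio,expected", [(0.4, 100.0), (0.64, 94.0)])
    def test_ratio_of_ratios_closed_form(self, ratio, expected):
        red, ir = self._pair(ratio)
        got = spo2_from_ppg(red, ir, (0, 10_000), CAL)
        assert got == pytest.approx(expected, abs=0.5)

    def test_vanishing_dc_absent(self):
        n = 1000
        pulse = np.sin(np.arange(n) / 100 * 2 * np.pi)
        red = frame(Channel.PPG_RED, 100, pulse)  # zero mean: no DC
        ir = frame(Channel.PPG_IR, 100, 1.0 + 0.05 * pulse)
        assert spo2_from_ppg(red, ir, (0, 10_000), CAL) is None


class TestRr:
    def test_quarter_hz_sinusoid_gives_15(self):
        t = np.arange(0, 60, 1 / 25)
        resp = frame(Channel.RESP, 25, np.sin(2 * np.pi * 0.25 * t))
        assert rr_from_resp(resp, (0, 60_000)) == pytest.approx(15.0, abs=0.5)

    def test_flat_signal_absent(self):
        resp = frame(Channel.RESP, 25, np.ones(25 * 60))
        assert rr_from_resp(resp, (0, 60_000)) is None

    def test_window_shorter_than_30_s_absent(self):
        t = np.arange(0, 20, 1 / 25)
        resp = frame(Channel.RESP, 25, np.sin(2 * np.pi * 0.25 * t))
        assert rr_from_resp(resp, (0, 20_000)) is None


class TestActivityPosture:
    def _acc(self, gravity, n=250, fs=50, wobble=0.0, seed=0):
        rng = np.random.default_rng(seed)
        a = np.tile(np.asarray(gravity, float), (n, 1))
        a += wobble * rng.standard_normal((n, 3))
        return frame(Channel.ACC3, fs, a)

    @pytest.mark.parametrize(
        "gravity,expected",
        [
            ((1, 0, 0), BodyPosition.UPRIGHT),
            ((0, 0, -1), BodyPosition.SUPINE),
            ((0, 0, 1), BodyPosition.PRONE),
            ((0, 1, 0), BodyPosition.LATERAL),
        ],
    )
    def test_stationary_posture_from_gravity_axis(self, gravity, expected):
        mpa, pos = activity_and_posture(self._acc(gravity, wobble=0.01), (0, 5000))
        assert pos is expected
        assert mpa < 0.1

    def test_vigorous_motion_is_moving(self):
        t = np.arange(250) / 50
        a = np.stack(
            [1 + 0.5 * np.sin(2 * np.pi * 2 * t), 0.3 * np.cos(2 * np.pi * 2 * t),
             np.zeros_like(t)],
            axis=1,
        )
        mpa, pos = activity_and_posture(frame(Channel.ACC3, 50, a), (0, 5000))
        assert pos is BodyPosition.MOVING
        assert mpa >= 0.1


class TestSnapshotAssembly:
    def test_full_channel_set_yields_all_signs(self, baseline_stream):
        snap = snapshot_from_signals(
            baseline_stream.frames, CAL, (60_000, 70_000)
        )
        assert None not in (snap.rr, snap.hr, snap.sbp, snap.spo2)
        d = triage(snap, ReferenceProfile.default("s1"))
        assert d.color is TriageColor.GREEN
        assert d.reliability == 100

    def test_missing_ecg_yields_absent_hr_and_black_triage(self, baseline_stream):
        frames = {c: f for c, f in baseline_stream.frames.items() if c is not Channel.ECG}
        snap = snapshot_from_signals(frames, CAL, (60_000, 70_000))
        assert snap.hr is None
        assert snap.sbp is None  # PAT needs the R-peaks too
        d = triage(snap, ReferenceProfile.default("s1"))
        assert d.color is TriageColor.BLACK

    def test_zero_length_window_rejected(self, baseline_stream):
        with pytest.raises(ValueError, match="positive length"):
            snapshot_from_signals(baseline_stream.frames, CAL, (60_000, 60_000))

    def test_extraction_is_deterministic(self, baseline_stream):
        a = snapshot_from_signals(baseline_stream.frames, CAL, (60_000, 70_000))
        b = snapshot_from_signals(baseline_stream.frames, CAL, (60_000, 70_000))
        assert a == b


class TestParameterRecovery:
    """Clean 60 s streams: extracted vitals must match the encoded truth."""

    def test_recovery_within_declared_tolerances(self):
        from fieldtriage.simulate import ScenarioSpec, Segment, generate_scenario

        for seed in (0, 1, 2):
            spec = ScenarioSpec(
                soldier_id="x", seed=seed, segments=(Segment(duration_s=70.0),)
            )
            stream = generate_scenario(spec)
            snap = snapshot_from_signals(
                stream.frames, spec.calibration, (60_000, 70_000)
            )
            assert abs(snap.hr - 72.0) <= 2.0
            assert abs(snap.rr - 14.0) <= 1.0
            assert abs(snap.spo2 - 97.0) <= 2.0
            assert abs(snap.sbp - 120.0) <= 5.0
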