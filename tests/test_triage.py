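"""Triage cascade: severity bands, color assignment, reliability, ordering."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fieldtriage.triage import (
    BLACK_SIGNAL,
    DEFAULT_RANGES,
    RELIABILITY_TABLE,
    ReferenceProfile,
    Severity,
    Sign,
    TriageColor,
    TriageDecision,
    VitalSnapshot,
    apply_override,
    evacuation_order,
    reliability_of,
    severity_of,
    triage,
)

PROFILE = ReferenceProfile.default("s1")


def snap(rr=None, hr=None, sbp=None, spo2=None, ts=0, sid="s1"):
    return VitalSnapshot(soldier_id=sid, timestamp=ts, rr=rr, hr=hr, sbp=sbp, spo2=spo2)


class TestSeverity:
    @pytest.mark.parametrize(
        "value,sign,expected",
        [
            (15, Sign.RR, Severity.IN_REFERENCE),
            (9, Sign.RR, Severity.IN_REFERENCE),  # reference bounds inclusive
            (20, Sign.RR, Severity.IN_REFERENCE),
            (25, Sign.RR, Severity.OUT_OF_REFERENCE),
            (8, Sign.RR, Severity.OUT_OF_REFERENCE),
            (35, Sign.RR, Severity.CRITICAL),
            (30, Sign.RR, Severity.CRITICAL),  # critical bounds inclusive
            (5, Sign.RR, Severity.CRITICAL),
            (72, Sign.HR, Severity.IN_REFERENCE),
            (140, Sign.HR, Severity.CRITICAL),
            (120, Sign.SBP, Severity.IN_REFERENCE),
            (90, Sign.SBP, Severity.OUT_OF_REFERENCE),
            (97, Sign.SPO2, Severity.IN_REFERENCE),
            (90, Sign.SPO2, Severity.OUT_OF_REFERENCE),
            (85, Sign.SPO2, Severity.CRITICAL),  # one-sided low
        ],
    )
    def test_band_classification(self, value, sign, expected):
        assert severity_of(value, sign, PROFILE) is expected

    def test_spo2_has_no_upper_critical_band(self):
        assert severity_of(100, Sign.SPO2, PROFILE) is Severity.IN_REFERENCE

    def test_rejects_nonpositive_values(self):
        with pytest.raises(ValueError):
            severity_of(0, Sign.RR, PROFILE)

    def test_severity_total_order(self):
        assert Severity.IN_REFERENCE < Severity.OUT_OF_REFERENCE < Severity.CRITICAL


class TestTriage:
    def test_all_in_reference_is_green_with_full_survival(self):
        d = triage(snap(rr=14, hr=72, sbp=120, spo2=97), PROFILE)
        assert d.color is TriageColor.GREEN
        assert d.reliability == 100
        assert d.survival_chance == 100

    def test_one_out_of_reference_is_yellow(self):
        d = triage(snap(rr=25, hr=72, sbp=120, spo2=97), PROFILE)
        assert d.color is TriageColor.YELLOW

    def test_critical_sign_is_red_despite_later_normal_signs(self):
        d = triage(snap(rr=14, hr=150, sbp=120, spo2=97), PROFILE)
        assert d.color is TriageColor.RED

    def test_missing_hr_is_black_pending_confirmation(self):
        d = triage(snap(rr=14, sbp=120, spo2=97), PROFILE)
        assert d.color is TriageColor.BLACK
        assert d.needs_confirmation
        assert d.reliability is None
        assert d.survival_chance is None

    def test_missing_nonhr_sign_skips_stage_and_degrades_reliability(self):
        d = triage(snap(rr=14, hr=72, sbp=120), PROFILE)  # SpO2 sensor lost
        assert d.color is TriageColor.GREEN
        assert d.reliability == 90
        assert d.survival_chance is None  # suppressed below 100 %

    def test_survival_fn_consulted_only_at_full_reliability(self):
        calls = []

        def fn(s):
            calls.append(s)
            return 60

        d = triage(snap(rr=25, hr=72, sbp=120, spo2=97), PROFILE, survival_fn=fn)
        assert d.survival_chance == 60
        d2 = triage(snap(rr=25, hr=72, sbp=120), PROFILE, survival_fn=fn)
        assert d2.survival_chance is None
        assert len(calls) == 1

    def test_profile_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match profile"):
            triage(snap(hr=72, sid="someone_else"), PROFILE)


def _literal_cascade(rr, hr, sbp, spo2, profile):
    """Line-by-line transliteration of the published pseudocode.

    Sequential per-sign stages with the explicit no-downgrade state
    machine; serves as the independent oracle for the max-severity
    implementation.
    """
    color = None
    for sign, value in ((Sign.RR, rr), (Sign.HR, hr), (Sign.SBP, sbp), (Sign.SPO2, spo2)):
        rng = profile.range_for(sign)
        in_ref = rng.ref_lo <= value <= rng.ref_hi
        in_crit = (rng.crit_lo is not None and value <= rng.crit_lo) or (
            rng.crit_hi is not None and value >= rng.crit_hi
        )
        if color is None:  # first stage
            color = "green" if in_ref else ("red" if in_crit else "yellow")
        elif color == "green":
            color = "green" if in_ref else ("red" if in_crit else "yellow")
        elif color == "yellow":
            color = "red" if in_crit else "yellow"
        else:  # red stays red
            color = "red"
    return color


class TestOracleEquivalence:
    def test_cascade_equals_literal_pseudocode_on_exhaustive_grid(self):
        """20^4 grid spanning below-critical to above-critical values."""
        import numpy as np

        axes = {
            Sign.RR: np.linspace(1, 40, 20),
            Sign.HR: np.linspace(20, 180, 20),
            Sign.SBP: np.linspace(40, 260, 20),
            Sign.SPO2: np.linspace(70, 100, 20),
        }
        mismatches = 0
        for rr, hr, sbp, spo2 in itertools.product(*axes.values()):
            got = triage(snap(rr=rr, hr=hr, sbp=sbp, spo2=spo2), PROFILE).color.value
            want = _literal_cascade(rr, hr, sbp, spo2, PROFILE)
            if got != want:
                mismatches += 1
        assert mismatches == 0

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(
        rr=st.floats(1, 40),
        hr=st.floats(25, 180),
        sbp=st.floats(40, 260),
        spo2=st.floats(70, 100),
        sign=st.sampled_from(list(Sign)),
        delta=st.floats(0.5, 30),
        direction=st.sampled_from([-1, 1]),
    )
    def test_worsening_one_sign_never_lowers_severity(
        self, rr, hr, sbp, spo2, sign, delta, direction
    ):
        """Moving one sign further from its reference interval can only
        keep or raise the color's severity."""
        base = dict(rr=rr, hr=hr, sbp=sbp, spo2=spo2)
        rng = PROFILE.range_for(sign)
        v = base[sign.value]
        if v >= rng.ref_hi:
            worse = v + delta  # further out on the high side
        elif v <= rng.ref_lo:
            worse = v - delta  # further out on the low side
        else:
            worse = v + direction * delta  # inside: any move is >= as severe
        if worse <= 0 or (sign is Sign.SPO2 and worse > 100):
            return
        order = [TriageColor.GREEN, TriageColor.YELLOW, TriageColor.RED]
        before = triage(snap(**base), PROFILE).color
        base[sign.value] = worse
        after = triage(snap(**base), PROFILE).color
        assert order.index(after) >= order.index(before)


class TestReliability:
    @pytest.mark.parametrize(
        "available,expected",
        [
            ({Sign.RR, Sign.HR, Sign.SBP, Sign.SPO2}, 100),
            ({Sign.HR, Sign.RR, Sign.SBP}, 90),
            ({Sign.HR, Sign.RR, Sign.SPO2}, 80),
            ({Sign.HR, Sign.RR}, 70),
            ({Sign.HR, Sign.SBP, Sign.SPO2}, 80),
            ({Sign.HR, Sign.SBP}, 70),
            ({Sign.HR, Sign.SPO2}, 60),
            ({Sign.HR}, 50),
        ],
    )
    def test_printed_table(self, available, expected):
        assert reliability_of(available) == expected

    def test_any_hr_absent_subset_is_black_signal(self):
        others = [Sign.RR, Sign.SBP, Sign.SPO2]
        for r in range(len(others) + 1):
            for combo in itertools.combinations(others, r):
                assert reliability_of(set(combo)) is BLACK_SIGNAL

    def test_table_is_total_on_hr_subsets_with_exact_image(self):
        assert len(RELIABILITY_TABLE) == 8
        assert set(RELIABILITY_TABLE.values()) == {50, 60, 70, 80, 90, 100}


class TestOverride:
    def test_medic_assigns_blue(self):
        auto = triage(snap(rr=25, hr=72, sbp=120, spo2=97), PROFILE)
        manual = apply_override(auto, TriageColor.BLUE, "medic")
        assert manual.color is TriageColor.BLUE
        assert manual.source == "manual"
        assert manual.history[-1].color is TriageColor.YELLOW

    def test_confirmation_of_same_color_is_idempotent(self):
        auto = triage(snap(rr=2, hr=72, sbp=120, spo2=97), PROFILE)
        confirmed = apply_override(auto, TriageColor.RED, "medic")
        assert confirmed.color is TriageColor.RED
        assert confirmed.source == "manual"

    def test_non_medical_actor_rejected(self):
        auto = triage(snap(rr=25, hr=72, sbp=120, spo2=97), PROFILE)
        with pytest.raises(PermissionError):
            apply_override(auto, TriageColor.BLUE, "commander")

    def test_blue_cannot_be_constructed_automatically(self):
        with pytest.raises(ValueError):
            TriageDecision(
                soldier_id="s1", timestamp=0, color=TriageColor.BLUE, source="automatic"
            )

    def test_black_requires_confirmation_flag(self):
        with pytest.raises(ValueError):
            TriageDecision(
                soldier_id="s1", timestamp=0, color=TriageColor.BLACK,
                needs_confirmation=False,
            )


def _decision(sid, color, chance=None, ts=0, rel=100):
    kwargs = {}
    if color is TriageColor.BLACK:
        kwargs["needs_confirmation"] = True
        rel = None
    if color is TriageColor.BLUE:
        kwargs["source"] = "manual"
        rel = None
    return TriageDecision(
        soldier_id=sid, timestamp=ts, color=color, reliability=rel,
        survival_chance=chance, **kwargs,
    )


class TestEvacuationOrder:
    def test_standard_mode_red_first_blue_last(self):
        cs = [
            _decision("a", TriageColor.BLUE),
            _decision("b", TriageColor.YELLOW, 70),
            _decision("c", TriageColor.RED, 45),
            _decision("d", TriageColor.RED, 20),
        ]
        got = [d.soldier_id for d in evacuation_order(cs, "standard")]
        assert got == ["d", "c", "b", "a"]

    def test_reverse_mode_lightest_first(self):
        cs = [
            _decision("a", TriageColor.RED, 20),
            _decision("b", TriageColor.YELLOW, 70),
            _decision("c", TriageColor.GREEN, 100),
        ]
        got = [d.soldier_id for d in evacuation_order(cs, "reverse")]
        assert got == ["c", "b", "a"]

    def test_blue_last_even_in_reverse(self):
        cs = [_decision("a", TriageColor.BLUE), _decision("b", TriageColor.RED, 10)]
        assert [d.soldier_id for d in evacuation_order(cs, "reverse")] == ["b", "a"]

    def test_black_flagged_after_the_color_queue(self):
        cs = [
            _decision("a", TriageColor.BLACK),
            _decision("b", TriageColor.GREEN, 100),
        ]
        ordered = evacuation_order(cs, "standard")
        assert [d.soldier_id for d in ordered] == ["b", "a"]
        assert ordered[-1].needs_confirmation

    def test_ties_break_by_earlier_timestamp(self):
        cs = [
            _decision("late", TriageColor.RED, 30, ts=2000),
            _decision("early", TriageColor.RED, 30, ts=1000),
        ]
        assert [d.soldier_id for d in evacuation_order(cs)] == ["early", "late"]

    def test_empty_input(self):
        assert evacuation_order([], "standard") == []

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            evacuation_order([], "sideways")
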