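from datetime import datetime

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vox2mets.parser import (
    AUTO,
    FAILED,
    MANUAL,
    OpenSession,
    OrderingError,
    OrphanEndError,
    ParserError,
    TimeParseError,
    TranscriptParser,
    Utterance,
    close_session,
    conversion_rate,
    detect_triggers,
    manual_override,
    parse_time,
    parse_utterance,
)


class TestTriggers:
    def test_from_to_positions(self):
        assert detect_triggers("study from 9:00 to 12:00") == [("from", 1), ("to", 3)]

    def test_no_triggers(self):
        assert detect_triggers("get up at 7:00") == []

    def test_empty_text_is_precondition_error(self):
        with pytest.raises(ParserError):
            detect_triggers("   ")

    def test_all_five_words_detected_in_order(self):
        found = detect_triggers("do start end from to")
        assert [w for w, _ in found] == ["do", "start", "end", "from", "to"]


class TestParseTime:
    @pytest.mark.parametrize(
        "token,minute",
        [("9:00", 540), ("12:00", 720), ("0:00", 0), ("23:59", 1439), ("7:05", 425)],
    )
    def test_clock_forms(self, token, minute):
        assert parse_time(token) == minute

    @pytest.mark.parametrize("token", ["25:61", "24:00", "9:60", "noon", "9", ""])
    def test_unparseable(self, token):
        with pytest.raises(TimeParseError):
            parse_time(token)

    def test_oclock_form(self):
        assert parse_time("9 o'clock") == 540


class TestParseUtterance:
    @pytest.mark.parametrize(
        "text,activity,start,end",
        [
            ("study from 9:00 to 12:00", "study", 540, 720),
            ("start meal at 7:00, end meal at 8:00", "meal", 420, 480),
            ("do training from 18:00 to 19:00", "training", 1080, 1140),
            ("walking start 8:10 end 8:35", "walking", 490, 515),
            ("table tennis from 16:00 to 17:00", "table tennis", 960, 1020),
        ],
    )
    def test_auto_patterns(self, utterance, text, activity, start, end):
        (rec,) = parse_utterance(utterance(text))
        assert rec.parse_mode == AUTO
        assert (rec.activity, rec.start, rec.end) == (activity, start, end)

    @pytest.mark.parametrize(
        "text",
        [
            "get up at 7:00",
            "going home by riding a bicycle",
            "study from 12:00 to 9:00",  # reversed times
            "from 9:00 to 12:00",  # no activity word
            "do from 9:00 to 12:00",  # trigger 'do' alone names nothing
        ],
    )
    def test_failures_become_failed_records(self, utterance, text):
        (rec,) = parse_utterance(utterance(text))
        assert rec.parse_mode == FAILED
        assert rec.activity is None and rec.start is None and rec.end is None

    def test_start_end_activity_mismatch_first_wins(self, utterance):
        (rec,) = parse_utterance(utterance("start meal at 7:00, end study at 8:00"))
        assert rec.parse_mode == AUTO and rec.activity == "meal"

    def test_totality_on_arbitrary_text(self, utterance):
        for text in ("!!!", "a b c d e f", "12345", "to to to"):
            records = parse_utterance(utterance(text))
            assert len(records) == 1 and records[0].parse_mode == FAILED


class TestSessions:
    def test_start_now_then_end_now(self, utterance):
        parser = TranscriptParser()
        assert parser.feed(utterance("start run now", when=datetime(2020, 1, 6, 6, 0))) == []
        (rec,) = parser.feed(utterance("end run now", when=datetime(2020, 1, 6, 6, 45)))
        assert rec.parse_mode == AUTO
        assert (rec.activity, rec.start, rec.end) == ("run", 360, 405)

    def test_close_session_directly(self, utterance):
        pending = OpenSession("run", 360, datetime(2020, 1, 6).date(), "u0")
        rec = close_session(pending, utterance("end run now", when=datetime(2020, 1, 6, 6, 45)))
        assert (rec.start, rec.end) == (360, 405)

    def test_orphan_end(self, utterance):
        with pytest.raises(OrphanEndError):
            parse_utterance(utterance("end run now"), sessions={})

    def test_zero_length_session_rejected(self, utterance):
        pending = OpenSession("run", 420, datetime(2020, 1, 6).date(), "u0")
        with pytest.raises(OrderingError):
            close_session(pending, utterance("end run now", when=datetime(2020, 1, 6, 7, 0)))

    def test_cross_date_end_is_orphan(self, utterance):
        pending = OpenSession("run", 420, datetime(2020, 1, 5).date(), "u0")
        with pytest.raises(OrphanEndError):
            close_session(pending, utterance("end run now", when=datetime(2020, 1, 6, 8, 0)))


class TestManualOverride:
    def test_failed_record_becomes_manual(self, utterance):
        (rec,) = parse_utterance(utterance("get up at 7:00"))
        fixed = manual_override(rec, "grooming", 420, 425)
        assert fixed.parse_mode == MANUAL
        assert (fixed.activity, fixed.start, fixed.end) == ("grooming", 420, 425)

    def test_zero_length_override_rejected(self, utterance):
        (rec,) = parse_utterance(utterance("get up at 7:00"))
        with pytest.raises(OrderingError):
            manual_override(rec, "grooming", 420, 420)

    def test_auto_record_cannot_be_overridden(self, utterance):
        (rec,) = parse_utterance(utterance("study from 9:00 to 12:00"))
        with pytest.raises(ParserError):
            manual_override(rec, "study", 540, 720)


class TestConversionRate:
    def test_study_scale_counts(self, utterance):
        records = [parse_utterance(utterance("study from 9:00 to 12:00", uid=str(i)))[0] for i in range(471)]
        records += [parse_utterance(utterance("get up at 7:00", uid=str(i + 471)))[0] for i in range(130)]
        assert conversion_rate(records) == pytest.approx(471 / 601)
        assert round(conversion_rate(records), 3) == 0.784

    def test_mixed_modes(self, utterance):
        auto = [parse_utterance(utterance("study from 9:00 to 12:00", uid=str(i)))[0] for i in range(3)]
        (failed,) = parse_utterance(utterance("get up at 7:00", uid="f"))
        manual = manual_override(failed, "grooming", 420, 425)
        (failed2,) = parse_utterance(utterance("going home by riding a bicycle", uid="g"))
        assert conversion_rate(auto + [manual, failed2]) == pytest.approx(0.6)

    def test_all_auto_is_one_and_failure_decreases(self, utterance):
        auto = [parse_utterance(utterance("study from 9:00 to 12:00", uid=str(i)))[0] for i in range(5)]
        assert conversion_rate(auto) == 1.0
        (failed,) = parse_utterance(utterance("get up at 7:00", uid="f"))
        assert conversion_rate(auto + [failed]) < 1.0

    def test_empty_list_is_error(self):
        with pytest.raises(ValueError):
            conversion_rate([])


@settings(max_examples=60, derandomize=True)
@given(
    activity=st.sampled_from(["study", "walking", "meal", "training", "tv"]),
    start=st.integers(min_value=0, max_value=1438),
    duration=st.integers(min_value=1, max_value=120),
    pattern=st.integers(min_value=0, max_value=2),
)
def test_roundtrip_property(activity, start, duration, pattern):
    """Any well-formed trigger pattern reproduces its interval exactly."""
    end = min(start + duration, 1439)
    if end <= start:
        return
    t1 = f"{start // 60}:{start % 60:02d}"
    t2 = f"{end // 60}:{end % 60:02d}"
    text = [
        f"{activity} from {t1} to {t2}",
        f"start {activity} at {t1}, end {activity} at {t2}",
        f"{activity} start {t1} end {t2}",
    ][pattern]
    u = Utterance(id="x", text=text, input_time=datetime(2020, 1, 6, 23, 59))
    (rec,) = parse_utterance(u)
    assert rec.parse_mode == AUTO
    assert (rec.activity, rec.start, rec.end) == (activity, start, end)
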