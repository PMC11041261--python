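from datetime import date

import numpy as np
import pytest

from vox2mets.accelerometer import EPOCHS_PER_DAY, EpochSeries, detect_nonwear, epochs_to_minutes
from vox2mets.timeline import DayTimeline
from vox2mets.validation import (
    NoOverlapError,
    PairedDay,
    ParticipantDay,
    bland_altman,
    daily_pairs,
    paired_t,
    pearson,
    report,
    time_match,
)

DAY = date(2020, 1, 6)


def pairs_from(voice, accel, mode="ge10h"):
    return [
        PairedDay(participant=f"P{i}", date=DAY, voice_mean=v, accel_mean=a, mode=mode)
        for i, (v, a) in enumerate(zip(voice, accel))
    ]


# Three-pair fixture: differences (-0.2, 0.1, -0.1).  Expected values were
# frozen from an independent closed-form computation (textbook formulas in
# plain numpy; p-values via the t-distribution survival function).
FIX = pairs_from([1.0, 1.5, 2.0], [1.2, 1.4, 2.1])


class TestPairedT:
    def test_hand_computed_three_pairs(self):
        res = paired_t(FIX)
        assert res.t == pytest.approx(-0.7559289460184542, rel=1e-12)
        assert res.p == pytest.approx(0.5285954792089685, rel=1e-12)
        assert res.n == 3 and not res.degenerate

    def test_zero_variance_is_degenerate_not_p_zero(self):
        res = paired_t(pairs_from([1.0, 2.0], [0.5, 1.5]))
        assert res.degenerate and np.isnan(res.p)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            paired_t(pairs_from([1.0], [1.1]))


class TestPearson:
    def test_hand_computed_three_pairs(self):
        res = pearson(FIX)
        assert res.r == pytest.approx(0.9522165814091077, rel=1e-12)
        assert res.p == pytest.approx(0.19759612400303023, rel=1e-12)

    def test_perfect_positive_line(self):
        res = pearson(pairs_from([1.0, 2.0, 3.0], [1.1, 2.1, 3.1]))
        assert res.r == pytest.approx(1.0)

    def test_perfect_negative_line(self):
        res = pearson(pairs_from([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]))
        assert res.r == pytest.approx(-1.0)

    def test_constant_series_degenerate(self):
        res = pearson(pairs_from([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))
        assert res.degenerate

    def test_invariant_under_positive_affine_transform(self):
        base = pearson(FIX).r
        scaled = pairs_from([2 * 1.0 + 3, 2 * 1.5 + 3, 2 * 2.0 + 3], [1.2, 1.4, 2.1])
        assert pearson(scaled).r == pytest.approx(base, rel=1e-12)

    def test_two_pairs_rejected(self):
        with pytest.raises(ValueError):
            pearson(pairs_from([1.0, 2.0], [1.0, 2.0]))


class TestBlandAltman:
    def test_hand_computed_three_pairs(self):
        ba = bland_altman(FIX)
        assert ba.mean_diff == pytest.approx(-0.06666666666666665, rel=1e-12)
        assert ba.sd_diff == pytest.approx(0.1527525231651947, rel=1e-12)
        assert ba.loa_low == pytest.approx(-0.36606161207044824, rel=1e-12)
        assert ba.loa_high == pytest.approx(0.23272827873711494, rel=1e-12)
        assert ba.trend_slope == pytest.approx(0.057761732851985416, rel=1e-12)
        assert ba.trend_intercept == pytest.approx(-0.15523465703971095, rel=1e-12)
        assert ba.trend_r == pytest.approx(0.18167747380137333, rel=1e-12)
        assert ba.trend_p == pytest.approx(0.8836946313785946, rel=1e-12)

    def test_identical_series(self):
        ba = bland_altman(pairs_from([1.0, 1.5, 2.0], [1.0, 1.5, 2.0]))
        assert ba.mean_diff == 0.0 and ba.loa_low == 0.0 and ba.loa_high == 0.0
        assert ba.trend_slope == 0.0

    def test_constant_offset(self):
        ba = bland_altman(pairs_from([1.1, 1.6, 2.1], [1.0, 1.5, 2.0]))
        assert ba.mean_diff == pytest.approx(0.1)
        assert ba.sd_diff == pytest.approx(0.0, abs=1e-15)
        assert ba.trend_slope == pytest.approx(0.0, abs=1e-12)

    def test_loa_width_identity(self):
        ba = bland_altman(FIX)
        assert ba.loa_high - ba.loa_low == pytest.approx(2 * 1.96 * ba.sd_diff, rel=1e-12)
        assert ba.loa_low <= ba.mean_diff <= ba.loa_high

    def test_shift_both_leaves_agreement_unchanged(self):
        shifted = pairs_from([1.5, 2.0, 2.5], [1.7, 1.9, 2.6])
        a, b = bland_altman(FIX), bland_altman(shifted)
        assert b.mean_diff == pytest.approx(a.mean_diff, rel=1e-12)
        assert b.loa_low == pytest.approx(a.loa_low, rel=1e-12)
        assert b.loa_high == pytest.approx(a.loa_high, rel=1e-12)

    def test_shift_voice_only_shifts_mean_diff_by_c(self):
        c = 0.3
        shifted = pairs_from([1.0 + c, 1.5 + c, 2.0 + c], [1.2, 1.4, 2.1])
        assert bland_altman(shifted).mean_diff == pytest.approx(
            bland_altman(FIX).mean_diff + c, rel=1e-12
        )

    def test_constant_means_trend_degenerate(self):
        # pairwise means all equal, diffs vary
        ba = bland_altman(pairs_from([1.0, 1.2, 1.4], [1.4, 1.2, 1.0]))
        assert ba.trend_degenerate


def make_day(cover, accel_level=1.5, voice_level=1.5, zero_blocks=()):
    tl = DayTimeline(participant="P01", date=DAY)
    for s, e in cover:
        tl.intensity[s:e] = voice_level
        tl.covered[s:e] = True
    v = np.full(EPOCHS_PER_DAY, accel_level)
    for s, e in zero_blocks:
        v[s * 6 : e * 6] = 0.0
    ep = EpochSeries(participant="P01", date=DAY, values=v)
    return ParticipantDay(timeline=tl, epochs=ep)


class TestTimeMatch:
    def test_voice_window_against_fully_worn_day(self):
        day = make_day([(540, 720)])
        v, a = time_match(day.timeline, epochs_to_minutes(day.epochs),
                          detect_nonwear(day.epochs))
        assert v.size == a.size == 180

    def test_no_overlap_signalled(self):
        day = make_day([(540, 720)], zero_blocks=[(500, 760)])
        with pytest.raises(NoOverlapError):
            time_match(day.timeline, epochs_to_minutes(day.epochs),
                       detect_nonwear(day.epochs))

    def test_full_coverage_both(self):
        day = make_day([(0, 1440)])
        v, _ = time_match(day.timeline, epochs_to_minutes(day.epochs),
                          detect_nonwear(day.epochs))
        assert v.size == 1440


class TestDailyPairs:
    def test_voice_hours_thresholds(self):
        nine = make_day([(0, 540)])
        fourteen = make_day([(0, 840)])
        assert daily_pairs([nine], "ge10h") == []
        assert len(daily_pairs([fourteen], "ge10h")) == 1
        assert len(daily_pairs([fourteen], "ge14h")) == 1

    def test_accel_wear_filter_applies_in_all_modes(self):
        # only ~8 h of worn epochs: day must vanish from every mode
        day = make_day([(0, 840)], zero_blocks=[(480, 1440)])
        for mode in ("ge10h", "ge14h", "matched"):
            assert daily_pairs([day], mode) == []

    def test_matched_mode_identical_series_agree_exactly(self):
        day = make_day([(300, 900)])
        (pair,) = daily_pairs([day], "matched")
        assert pair.voice_mean == pair.accel_mean
        assert pair.matched_minutes == 600


class TestReport:
    def test_single_day_cohort_is_insufficient(self):
        reps = report([make_day([(0, 840)])])
        assert all(r.insufficient for r in reps.values())

    def test_zero_noise_matched_mode_exact_agreement(self):
        days = [make_day([(200 + 10 * i, 1100 + 10 * i)]) for i in range(5)]
        rep = report(days)["matched"]
        assert rep.n_days == 5
        assert rep.ttest.degenerate
        assert rep.bland_altman.mean_diff == 0.0
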