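"""I/O round-trips, adherence windows and daily-to-weekly alignment."""

import datetime as dt

import numpy as np
import pytest

from moodkit.questionnaires import MzResponse, ValidationError
from moodkit.timeline import (
    ALIGNMENT_METHODS,
    ParticipantTimeline,
    adherence_curve,
    align_daily_to_weekly,
    compute_adherence,
    read_study,
    write_study,
)

START = dt.date(2020, 1, 6)  # Monday


def make_tl(daily_dates=(), weekly=None, n_days=30, prompts=None, pid="p1"):
    daily = {d: MzResponse(4, 4, 4, 4, 4, 4) for d in daily_dates}
    tl = ParticipantTimeline(
        participant_id=pid, cohort="HC", enrolment_start=START,
        enrolment_end=START + dt.timedelta(days=n_days - 1),
        daily=daily, weekly=weekly or {},
        weekly_prompt_dates=list(prompts or []))
    return tl


def days(*offsets):
    return [START + dt.timedelta(days=k) for k in offsets]


# ------------------------------------------------------------------- I/O
def test_write_read_round_trip(tmp_path, small_study):
    paths = [tmp_path / n for n in ("daily.csv", "weekly.csv", "cohorts.csv")]
    write_study(small_study.timelines, *paths)
    back = read_study(*paths, weekly_prompt_weekday=0)
    assert len(back) == len(small_study.timelines)
    for a, b in zip(small_study.timelines, back):
        assert a.participant_id == b.participant_id
        assert a.cohort == b.cohort
        assert a.daily == b.daily
        assert a.weekly == b.weekly
        assert (a.enrolment_start, a.enrolment_end) == (
            b.enrolment_start, b.enrolment_end)


def test_round_trip_is_byte_stable(tmp_path, small_study):
    p1 = [tmp_path / n for n in ("d1.csv", "w1.csv", "c1.csv")]
    p2 = [tmp_path / n for n in ("d2.csv", "w2.csv", "c2.csv")]
    write_study(small_study.timelines, *p1)
    write_study(read_study(*p1), *p2)
    for a, b in zip(p1, p2):
        assert a.read_bytes() == b.read_bytes()


def test_strict_mode_rejects_bad_row(tmp_path, small_study):
    paths = [tmp_path / n for n in ("daily.csv", "weekly.csv", "cohorts.csv")]
    write_study(small_study.timelines, *paths)
    text = paths[0].read_text().splitlines()
    text[1] = text[1].rsplit(",", 1)[0] + ",9"  # energetic = 9
    paths[0].write_text("\n".join(text) + "\n")
    with pytest.raises(ValidationError, match="row 2"):
        read_study(*paths, strict=True)
    lenient = read_study(*paths, strict=False)
    n_daily = sum(len(tl.daily) for tl in lenient)
    assert n_daily == sum(len(tl.daily) for tl in small_study.timelines) - 1


def test_unknown_participant_rejected(tmp_path, small_study):
    paths = [tmp_path / n for n in ("daily.csv", "weekly.csv", "cohorts.csv")]
    write_study(small_study.timelines, *paths)
    with open(paths[0], "a") as fh:
        fh.write("ghost,2020-01-10,4,4,4,4,4,4\n")
    with pytest.raises(ValidationError, match="unknown participant"):
        read_study(*paths)


def test_empty_weekly_file(tmp_path, small_study):
    paths = [tmp_path / n for n in ("daily.csv", "weekly.csv", "cohorts.csv")]
    write_study(small_study.timelines, *paths)
    paths[1].write_text("")
    with pytest.warns(UserWarning, match="no data rows"):
        back = read_study(*paths)
    assert all(not tl.weekly for tl in back)


# -------------------------------------------------------------- adherence
def test_daily_adherence_arithmetic():
    tl = make_tl(daily_dates=days(*range(24)), n_days=30)
    rep = compute_adherence(tl)
    assert rep.daily_adherence == pytest.approx(80.0)


def test_weekly_window_rule():
    """A record 2 days after the prompt counts; 3 days after does not."""
    prompts = days(7)
    from moodkit.timeline import WeeklyRecord
    from moodkit.questionnaires import (AsrmResponse, Eq5dResponse,
                                        Gad7Response, QidsResponse)

    rec = WeeklyRecord(AsrmResponse((0,) * 5), QidsResponse((0,) * 16),
                       Gad7Response((0,) * 7), Eq5dResponse(80))
    ok = make_tl(weekly={days(9)[0]: rec}, prompts=prompts)
    assert compute_adherence(ok).weekly_adherence == pytest.approx(100.0)
    late = make_tl(weekly={days(10)[0]: rec}, prompts=prompts)
    assert compute_adherence(late).weekly_adherence == pytest.approx(0.0)


def test_weekly_record_satisfies_at_most_one_prompt():
    from moodkit.timeline import WeeklyRecord
    from moodkit.questionnaires import (AsrmResponse, Eq5dResponse,
                                        Gad7Response, QidsResponse)

    rec = WeeklyRecord(AsrmResponse((0,) * 5), QidsResponse((0,) * 16),
                       Gad7Response((0,) * 7), Eq5dResponse(80))
    # prompts at days 7 and 14; single record at day 12 is within 2 days of 14
    tl = make_tl(weekly={days(12)[0]: rec}, prompts=days(7, 14))
    assert compute_adherence(tl).weekly_adherence == pytest.approx(50.0)


def test_no_prompts_answered_is_zero():
    tl = make_tl(prompts=days(7, 14, 21))
    assert compute_adherence(tl).weekly_adherence == pytest.approx(0.0)


def test_deleting_records_never_increases_adherence(small_study):
    tl = small_study.timelines[0]
    rep = compute_adherence(tl)
    trimmed = ParticipantTimeline(
        participant_id=tl.participant_id, cohort=tl.cohort,
        enrolment_start=tl.enrolment_start, enrolment_end=tl.enrolment_end,
        daily=dict(list(tl.daily.items())[1:]),
        weekly=dict(list(tl.weekly.items())[1:]),
        weekly_prompt_dates=tl.weekly_prompt_dates)
    rep2 = compute_adherence(trimmed)
    assert rep2.daily_adherence <= rep.daily_adherence
    assert rep2.weekly_adherence <= rep.weekly_adherence


def test_full_adherence_flat_curve():
    tl = make_tl(daily_dates=days(*range(60)), n_days=60)
    curve = adherence_curve([tl], window_days=30)
    assert list(curve["median"]) == [100.0, 100.0]
    assert list(curve["iqr"]) == [0.0, 0.0]  # single participant


def test_adherence_curve_tracks_missingness():
    """With missingness 0.15 the cohort curve sits near 85%."""
    from moodkit.synthetic import CohortParams, StudyConfig, generate_study

    cfg = StudyConfig(cohorts=[CohortParams(
        label="HC", n_participants=20, n_days=90, neg_mean=0, pos_mean=0,
        neg_sd=0.5, pos_sd=0.5, ar_coef=0.4, daily_missing_prob=0.15)], seed=21)
    curve = adherence_curve(generate_study(cfg).timelines, window_days=30)
    # 3 binomial SEs around 85% for 20 participants x 30 days per window
    se = 100 * np.sqrt(0.85 * 0.15 / (20 * 30))
    assert all(abs(m - 85.0) < 3 * se + 2 for m in curve["median"])


def test_zero_length_enrolment_error():
    with pytest.raises(ValueError, match="enrolment"):
        ParticipantTimeline(participant_id="x", cohort="HC",
                            enrolment_start=START,
                            enrolment_end=START - dt.timedelta(days=1))


# -------------------------------------------------------------- alignment
def _weekly_rec():
    from moodkit.timeline import WeeklyRecord
    from moodkit.questionnaires import (AsrmResponse, Eq5dResponse,
                                        Gad7Response, QidsResponse)

    return WeeklyRecord(AsrmResponse((1, 1, 1, 1, 1)), QidsResponse((1,) * 16),
                        Gad7Response((1,) * 7), Eq5dResponse(75))


@pytest.mark.parametrize("method", ALIGNMENT_METHODS)
def test_constant_daily_series_preserved(method):
    tl = make_tl(daily_dates=days(*range(20)), weekly={days(10)[0]: _weekly_rec()},
                 n_days=30)
    result = align_daily_to_weekly(tl, method)
    assert result.n_dropped == 0
    (pair,) = result.pairs
    assert all(v == pytest.approx(4.0) for v in pair.mz_summary.values())
    assert pair.weekly_totals == {"ASRM": 5, "QIDS": 9, "GAD7": 7, "EQ5D": 75}


def test_alignment_hand_arithmetic():
    """anxious = 1..7 on days t-7..t-1: mean 4, median 4, last-3 mean 6."""
    t = days(10)[0]
    daily = {}
    for k, v in zip(range(7, 0, -1), range(1, 8)):
        daily[t - dt.timedelta(days=k)] = MzResponse(v, 4, 4, 4, 4, 4)
    tl = make_tl(n_days=30, weekly={t: _weekly_rec()})
    tl.daily = dict(sorted(daily.items()))
    for method, expected in [("mean_prev_week", 4.0), ("median_prev_week", 4.0),
                             ("last3_days", 6.0)]:
        (pair,) = align_daily_to_weekly(tl, method).pairs
        assert pair.mz_summary["anxious"] == pytest.approx(expected)
        assert pair.n_days_used == (3 if method == "last3_days" else 7)
    assert align_daily_to_weekly(tl, "same_day").n_dropped == 1


def test_same_day_uses_rating_day_only():
    t = days(10)[0]
    tl = make_tl(n_days=30, daily_dates=[t], weekly={t: _weekly_rec()})
    (pair,) = align_daily_to_weekly(tl, "same_day").pairs
    assert pair.n_days_used == 1
    # mean_prev_week excludes the rating day by default
    assert align_daily_to_weekly(tl, "mean_prev_week").n_dropped == 1
    with_day = align_daily_to_weekly(tl, "mean_prev_week",
                                     include_rating_day=True)
    assert len(with_day.pairs) == 1


def test_empty_window_dropped_and_counted():
    tl = make_tl(n_days=30, weekly={days(20)[0]: _weekly_rec()})
    result = align_daily_to_weekly(tl, "mean_prev_week")
    assert result.pairs == [] and result.n_dropped == 1


def test_unknown_method_rejected():
    tl = make_tl(n_days=30)
    with pytest.raises(ValueError, match="unknown alignment method"):
        align_daily_to_weekly(tl, "fortnight")


def test_mean_alignment_order_invariant():
    t = days(10)[0]
    rng = np.random.default_rng(3)
    daily = {t - dt.timedelta(days=int(k)): MzResponse(
        *(int(v) for v in rng.integers(1, 8, size=6))) for k in range(1, 8)}
    tl = make_tl(n_days=30, weekly={t: _weekly_rec()})
    tl.daily = dict(sorted(daily.items()))
    (a,) = align_daily_to_weekly(tl, "mean_prev_week").pairs
    tl.daily = dict(reversed(list(tl.daily.items())))
    (b,) = align_daily_to_weekly(tl, "mean_prev_week").pairs
    assert a.mz_summary == b.mz_summary
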