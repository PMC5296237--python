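"""Participant timelines: long-format I/O, adherence, daily-to-weekly alignment.

A participant contributes two irregular streams over an enrolment window:
daily Mood Zoom records (prompted every calendar day, counted as adherent
only when completed the same day) and weekly PROM records (prompted on a
fixed weekday, counted as adherent when completed within two days before or
after the prompt).  Daily records are aligned to each weekly record by
summarising the Mood Zoom items over a preceding window, so that daily and
weekly instruments can be correlated on a common weekly grid.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .questionnaires import (
    ASRM_ITEM_LABELS,
    GAD7_ITEM_LABELS,
    MZ_ITEM_LABELS,
    AsrmResponse,
    Eq5dResponse,
    Gad7Response,
    MzResponse,
    QidsResponse,
    ValidationError,
    qids_domains,
    score_asrm,
    score_gad7,
    score_qids,
)

__all__ = [
    "WeeklyRecord",
    "ParticipantTimeline",
    "AdherenceReport",
    "AlignedPair",
    "AlignmentResult",
    "ALIGNMENT_METHODS",
    "read_study",
    "write_study",
    "compute_adherence",
    "adherence_curve",
    "align_daily_to_weekly",
]

logger = logging.getLogger(__name__)

ALIGNMENT_METHODS = ("mean_prev_week", "median_prev_week", "last3_days", "same_day")

DAILY_COLUMNS = ["participant_id", "date", *MZ_ITEM_LABELS]
WEEKLY_COLUMNS = (
    ["participant_id", "date"]
    + [f"asrm_{i}" for i in range(1, 6)]
    + [f"qids_{i}" for i in range(1, 17)]
    + [f"gad7_{i}" for i in range(1, 8)]
    + ["eq5d_vas"]
)
COHORT_COLUMNS = ["participant_id", "cohort", "enrolment_start", "enrolment_end"]


@dataclass(frozen=True)
class WeeklyRecord:
    """One week's responses to the four weekly instruments."""

    asrm: AsrmResponse
    qids: QidsResponse
    gad7: Gad7Response
    eq5d: Eq5dResponse

    @property
    def totals(self) -> dict:
        return {
            "ASRM": score_asrm(self.asrm),
            "QIDS": score_qids(self.qids),
            "GAD7": score_gad7(self.gad7),
            "EQ5D": self.eq5d.vas,
        }


@dataclass
class ParticipantTimeline:
    """One participant's cohort label, enrolment window and record streams.

    ``daily`` and ``weekly`` map calendar dates to records; dates are unique
    per stream and kept in ascending order.  ``weekly_prompt_dates`` is the
    schedule against which weekly adherence is judged.
    """

    participant_id: str
    cohort: str
    enrolment_start: dt.date
    enrolment_end: dt.date
    daily: dict = field(default_factory=dict)
    weekly: dict = field(default_factory=dict)
    weekly_prompt_dates: list = field(default_factory=list)

    def __post_init__(self):
        if self.enrolment_end < self.enrolment_start:
            raise ValueError(
                f"{self.participant_id}: enrolment_end precedes enrolment_start"
            )
        self.daily = dict(sorted(self.daily.items()))
        self.weekly = dict(sorted(self.weekly.items()))
        for d in list(self.daily) + list(self.weekly):
            if not (self.enrolment_start <= d <= self.enrolment_end):
                raise ValueError(
                    f"{self.participant_id}: record date {d} outside enrolment window"
                )

    @property
    def n_enrolment_days(self) -> int:
        return (self.enrolment_end - self.enrolment_start).days + 1

    def daily_frame(self) -> pd.DataFrame:
        """Daily Mood Zoom items as a date-indexed DataFrame."""
        if not self.daily:
            return pd.DataFrame(columns=list(MZ_ITEM_LABELS), dtype=float)
        idx = pd.DatetimeIndex(list(self.daily), name="date")
        data = [rec.as_tuple() for rec in self.daily.values()]
        return pd.DataFrame(data, index=idx, columns=list(MZ_ITEM_LABELS))

    def weekly_frame(self) -> pd.DataFrame:
        """Weekly instrument totals (ASRM, QIDS, GAD7, EQ5D) date-indexed."""
        cols = ["ASRM", "QIDS", "GAD7", "EQ5D"]
        if not self.weekly:
            return pd.DataFrame(columns=cols, dtype=float)
        idx = pd.DatetimeIndex(list(self.weekly), name="date")
        rows = [rec.totals for rec in self.weekly.values()]
        return pd.DataFrame(rows, index=idx)[cols]

    def default_weekly_prompts(self, weekday: int | None = None) -> list:
        """Weekly prompt dates on a fixed weekday across the enrolment window.

        When ``weekday`` is None it defaults to the weekday of the first
        weekly record (or of enrolment start if there are none).
        """
        if weekday is None:
            anchor = next(iter(self.weekly), self.enrolment_start)
            weekday = anchor.weekday()
        d = self.enrolment_start
        d += dt.timedelta(days=(weekday - d.weekday()) % 7)
        prompts = []
        while d <= self.enrolment_end:
            prompts.append(d)
            d += dt.timedelta(days=7)
        return prompts


@dataclass
class AdherenceReport:
    """Per-participant completion rates, as percentages in [0, 100]."""

    participant_id: str
    daily_adherence: float
    weekly_adherence: float
    monthly_curve: list  # daily adherence % per successive 30-day window


@dataclass
class AlignedPair:
    """One weekly record paired with a summary of nearby daily Mood Zoom items."""

    weekly_date: dt.date
    mz_summary: dict  # item name -> summarised value in [1, 7]
    weekly: WeeklyRecord
    n_days_used: int

    @property
    def weekly_totals(self) -> dict:
        return self.weekly.totals


@dataclass
class AlignmentResult:
    """Aligned pairs for one participant plus the count of dropped prompts."""

    participant_id: str
    method: str
    pairs: list
    n_dropped: int


def _parse_date(value):
    if isinstance(value, dt.date) and not isinstance(value, dt.datetime):
        return value
    return dt.date.fromisoformat(str(value)[:10])


def _row_error(strict, msg, errors):
    if strict:
        raise ValidationError(msg)
    logger.warning("skipping row: %s", msg)
    errors.append(msg)


def read_study(daily_csv, weekly_csv, cohorts_csv, *, strict=True,
               weekly_prompt_weekday=None):
    """Read a study from long-format CSVs into `ParticipantTimeline` objects.

    In strict mode malformed rows raise `ValidationError` naming the row;
    in lenient mode they are logged and skipped.  Weekly prompt schedules
    default to the weekday of each participant's first weekly record.
    """
    cohorts = pd.read_csv(cohorts_csv)
    missing = set(COHORT_COLUMNS) - set(cohorts.columns)
    if missing:
        raise ValidationError(f"cohorts file missing columns: {sorted(missing)}")
    daily = pd.read_csv(daily_csv)
    try:
        weekly = pd.read_csv(weekly_csv)
    except pd.errors.EmptyDataError:
        weekly = pd.DataFrame(columns=WEEKLY_COLUMNS)
    if weekly.empty:
        warnings.warn("weekly file has no data rows", stacklevel=2)

    errors = []
    known = {}
    for _, row in cohorts.iterrows():
        pid = str(row["participant_id"])
        known[pid] = ParticipantTimeline(
            participant_id=pid,
            cohort=str(row["cohort"]),
            enrolment_start=_parse_date(row["enrolment_start"]),
            enrolment_end=_parse_date(row["enrolment_end"]),
        )

    for i, row in daily.iterrows():
        pid = str(row["participant_id"])
        where = f"daily row {i + 2} (participant {pid})"
        if pid not in known:
            _row_error(strict, f"{where}: unknown participant", errors)
            continue
        tl = known[pid]
        try:
            date = _parse_date(row["date"])
            rec = MzResponse(*(int(row[c]) for c in MZ_ITEM_LABELS))
        except (ValidationError, ValueError) as exc:
            _row_error(strict, f"{where}: {exc}", errors)
            continue
        if date in tl.daily:
            _row_error(strict, f"{where}: duplicate date {date}", errors)
            continue
        if not (tl.enrolment_start <= date <= tl.enrolment_end):
            _row_error(strict, f"{where}: date {date} outside enrolment", errors)
            continue
        tl.daily[date] = rec

    for i, row in weekly.iterrows():
        pid = str(row["participant_id"])
        where = f"weekly row {i + 2} (participant {pid})"
        if pid not in known:
            _row_error(strict, f"{where}: unknown participant", errors)
            continue
        tl = known[pid]
        try:
            date = _parse_date(row["date"])
            rec = WeeklyRecord(
                asrm=AsrmResponse(tuple(int(row[f"asrm_{i}"]) for i in range(1, 6))),
                qids=QidsResponse(tuple(int(row[f"qids_{i}"]) for i in range(1, 17))),
                gad7=Gad7Response(tuple(int(row[f"gad7_{i}"]) for i in range(1, 8))),
                eq5d=Eq5dResponse(float(row["eq5d_vas"])),
            )
        except (ValidationError, ValueError) as exc:
            _row_error(strict, f"{where}: {exc}", errors)
            continue
        if date in tl.weekly:
            _row_error(strict, f"{where}: duplicate date {date}", errors)
            continue
        if not (tl.enrolment_start <= date <= tl.enrolment_end):
            _row_error(strict, f"{where}: date {date} outside enrolment", errors)
            continue
        tl.weekly[date] = rec

    timelines = []
    for tl in known.values():
        tl.daily = dict(sorted(tl.daily.items()))
        tl.weekly = dict(sorted(tl.weekly.items()))
        tl.weekly_prompt_dates = tl.default_weekly_prompts(weekly_prompt_weekday)
        timelines.append(tl)
    return timelines


def write_study(timelines, daily_csv, weekly_csv, cohorts_csv):
    """Write timelines to the three long-format CSVs (inverse of `read_study`)."""
    daily_rows, weekly_rows, cohort_rows = [], [], []
    for tl in timelines:
        cohort_rows.append(
            {
                "participant_id": tl.participant_id,
                "cohort": tl.cohort,
                "enrolment_start": tl.enrolment_start.isoformat(),
                "enrolment_end": tl.enrolment_end.isoformat(),
            }
        )
        for date, rec in tl.daily.items():
            row = {"participant_id": tl.participant_id, "date": date.isoformat()}
            row.update(dict(zip(MZ_ITEM_LABELS, rec.as_tuple())))
            daily_rows.append(row)
        for date, rec in tl.weekly.items():
            row = {"participant_id": tl.participant_id, "date": date.isoformat()}
            row.update({f"asrm_{i+1}": v for i, v in enumerate(rec.asrm.items)})
            row.update({f"qids_{i+1}": v for i, v in enumerate(rec.qids.items)})
            row.update({f"gad7_{i+1}": v for i, v in enumerate(rec.gad7.items)})
            row["eq5d_vas"] = rec.eq5d.vas
            weekly_rows.append(row)
    pd.DataFrame(daily_rows, columns=DAILY_COLUMNS).to_csv(daily_csv, index=False)
    pd.DataFrame(weekly_rows, columns=WEEKLY_COLUMNS).to_csv(weekly_csv, index=False)
    pd.DataFrame(cohort_rows, columns=COHORT_COLUMNS).to_csv(cohorts_csv, index=False)


def _match_weekly_records(tl, window=2):
    """Greedily match weekly records to prompts within ±window days.

    Records are taken in date order; each record fills the nearest still-open
    prompt, ties going to the earlier prompt.  A record can satisfy at most
    one prompt.  Returns the set of filled prompt dates.
    """
    open_prompts = list(tl.weekly_prompt_dates)
    filled = set()
    for rec_date in tl.weekly:
        best = None
        for p in open_prompts:
            d = abs((rec_date - p).days)
            if d <= window and (best is None or d < abs((rec_date - best).days)):
                best = p  # ties keep the earlier prompt (list is ascending)
        if best is not None:
            filled.add(best)
            open_prompts.remove(best)
    return filled


def compute_adherence(tl: ParticipantTimeline, *, weekly_window=2,
                      curve_window_days=30) -> AdherenceReport:
    """Completion rates under the study's windows.

    Daily adherence is the percentage of enrolment days with a same-day
    Mood Zoom record.  Weekly adherence is the percentage of weekly prompts
    answered by a record dated within ±2 days of the prompt (each record
    credited to at most one prompt).  The monthly curve gives daily adherence
    per successive 30-day window of the enrolment.
    """
    n_days = tl.n_enrolment_days
    if n_days < 1:
        raise ValueError("zero-length enrolment: adherence undefined")
    daily_pct = 100.0 * len(tl.daily) / n_days

    if tl.weekly_prompt_dates:
        filled = _match_weekly_records(tl, weekly_window)
        weekly_pct = 100.0 * len(filled) / len(tl.weekly_prompt_dates)
    else:
        weekly_pct = float("nan")

    curve = []
    start = tl.enrolment_start
    while start <= tl.enrolment_end:
        end = min(start + dt.timedelta(days=curve_window_days - 1), tl.enrolment_end)
        span = (end - start).days + 1
        hits = sum(1 for d in tl.daily if start <= d <= end)
        curve.append(100.0 * hits / span)
        start = end + dt.timedelta(days=1)

    return AdherenceReport(tl.participant_id, daily_pct, weekly_pct, curve)


def adherence_curve(timelines, window_days=30) -> pd.DataFrame:
    """Cohort median and IQR of daily adherence per successive study window.

    Participants contribute only to windows that lie inside their enrolment.
    Returns a tidy DataFrame with one row per (cohort, window).
    """
    rows = []
    for tl in timelines:
        rep = compute_adherence(tl, curve_window_days=window_days)
        for w, pct in enumerate(rep.monthly_curve):
            rows.append({"cohort": tl.cohort, "window": w, "adherence": pct})
    per = pd.DataFrame(rows)
    if per.empty:
        return pd.DataFrame(columns=["cohort", "window", "median", "q1", "q3", "iqr", "n"])
    out = (
        per.groupby(["cohort", "window"])["adherence"]
        .agg(
            median="median",
            q1=lambda s: float(np.quantile(s, 0.25)),
            q3=lambda s: float(np.quantile(s, 0.75)),
            n="count",
        )
        .reset_index()
    )
    out["iqr"] = out["q3"] - out["q1"]
    return out[["cohort", "window", "median", "q1", "q3", "iqr", "n"]]


def align_daily_to_weekly(tl: ParticipantTimeline, method="mean_prev_week",
                          *, include_rating_day=False) -> AlignmentResult:
    """Summarise daily Mood Zoom items around each weekly record date.

    Methods: ``mean_prev_week`` / ``median_prev_week`` summarise the daily
    records in the 7 calendar days strictly preceding the rating date
    ([t-7, t-1]); ``last3_days`` uses [t-3, t-1]; ``same_day`` uses the
    record on the rating date itself.  ``include_rating_day=True`` widens
    the mean/median/last3 windows to include day t.  Weekly records with no
    qualifying daily record are dropped and counted.
    """
    if method not in ALIGNMENT_METHODS:
        raise ValueError(f"unknown alignment method {method!r}; "
                         f"choose from {ALIGNMENT_METHODS}")
    pairs = []
    n_dropped = 0
    for w_date, w_rec in tl.weekly.items():
        if method == "same_day":
            window_dates = [w_date]
        else:
            back = 3 if method == "last3_days" else 7
            last = 0 if include_rating_day else 1
            window_dates = [
                w_date - dt.timedelta(days=k) for k in range(back, last - 1, -1)
            ]
        values = [tl.daily[d].as_tuple() for d in window_dates if d in tl.daily]
        if not values:
            n_dropped += 1
            continue
        arr = np.asarray(values, dtype=float)
        summary = (
            np.median(arr, axis=0) if method == "median_prev_week" else arr.mean(axis=0)
        )
        pairs.append(
            AlignedPair(
                weekly_date=w_date,
                mz_summary=dict(zip(MZ_ITEM_LABELS, summary)),
                weekly=w_rec,
                n_days_used=len(values),
            )
        )
    return AlignmentResult(tl.participant_id, method, pairs, n_dropped)


def weekly_item_values(rec: WeeklyRecord) -> dict:
    """Flatten one weekly record to named item/domain/total values.

    ASRM and GAD-7 contribute their individual items, QIDS its nine clinical
    domains (the granularity at which depression is assessed), EQ-5D its VAS,
    plus the three questionnaire totals.
    """
    out = {}
    for label, v in zip(ASRM_ITEM_LABELS, rec.asrm.items):
        out[f"asrm_{label}"] = v
    for label, v in qids_domains(rec.qids).items():
        out[f"qids_{label}"] = v
    for label, v in zip(GAD7_ITEM_LABELS, rec.gad7.items):
        out[f"gad7_{label}"] = v
    out["eq5d_vas"] = rec.eq5d.vas
    out["total_asrm"] = score_asrm(rec.asrm)
    out["total_qids"] = score_qids(rec.qids)
    out["total_gad7"] = score_gad7(rec.gad7)
    return out
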