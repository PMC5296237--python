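"""Time-series variability statistics for longitudinal mood scores.

Four scalar descriptors of a participant's score series x_1..x_N quantify
mood instability:

* **std** — sample standard deviation (N-1 denominator): overall spread.
* **TKEO** — mean Teager-Kaiser energy, (1/N) * sum_{i=2}^{N-1}
  (x_i^2 - x_{i-1} * x_{i+1}): a nonlinear operator sensitive to both the
  amplitude and the frequency of fluctuation.  Individual terms may be
  negative, so the mean may be too.
* **entropy** — Shannon entropy of the empirical distribution of distinct
  observed values, -sum_j p_j log(p_j) (natural log by default): overall
  unpredictability, insensitive to the ordering of the series.
* **RMSSD** — root mean squared successive differences,
  sqrt((1/N) * sum_{i=1}^{N-1} (x_{i+1} - x_i)^2): amplitude of day-to-day
  (or week-to-week) change.  The 1/N normaliser over the N-1 squared
  differences is kept as such deliberately; see docs/methods.md.

All four are translation-invariant.  std and RMSSD scale linearly with the
series scale, TKEO quadratically; entropy depends only on value counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .latent import FACTOR_LABELS, daily_factor_series

__all__ = [
    "InsufficientDataError",
    "series_std",
    "series_tkeo",
    "series_entropy",
    "series_rmssd",
    "VariabilityProfile",
    "variability_profile",
    "profiles_frame",
    "STAT_NAMES",
]

STAT_NAMES = ("std", "tkeo", "entropy", "rmssd")


class InsufficientDataError(ValueError):
    """The series is shorter than the statistic's minimum length."""


def _as_series(s):
    x = np.asarray(s, dtype=float).ravel()
    if x.size == 0:
        raise InsufficientDataError("empty series")
    return x


def series_std(s) -> float:
    """Sample standard deviation (N-1 denominator).  Requires N >= 2."""
    x = _as_series(s)
    if x.size < 2:
        raise InsufficientDataError(f"std needs N >= 2, got N={x.size}")
    return float(np.std(x, ddof=1))


def series_tkeo(s, variant: str = "standard") -> float:
    """Mean Teager-Kaiser energy of the series.  Requires N >= 3.

    ``variant="standard"`` computes (1/N) * sum_{i=2}^{N-1}
    (x_i^2 - x_{i-1} * x_{i+1}).  ``variant="printed"`` instead uses
    x_i^2 - x_{i+1}^2 for each interior term — a telescoping form retained
    only for auditing; it is not the Teager-Kaiser operator.
    """
    x = _as_series(s)
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"TKEO needs N >= 3, got N={n}")
    if variant == "standard":
        terms = x[1:-1] ** 2 - x[:-2] * x[2:]
    elif variant == "printed":
        terms = x[1:-1] ** 2 - x[2:] ** 2
    else:
        raise ValueError(f"unknown TKEO variant {variant!r}")
    return float(terms.sum() / n)


def series_entropy(s, base: float | None = None) -> float:
    """Shannon entropy of the empirical value distribution.  N >= 1.

    Probabilities are relative frequencies of the distinct observed values;
    natural log by default (pass ``base=2`` for bits).  A constant series
    (one distinct value) has entropy 0.
    """
    x = _as_series(s)
    _, counts = np.unique(x, return_counts=True)
    p = counts / x.size
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def series_rmssd(s) -> float:
    """Root mean squared successive differences.  Requires N >= 2.

    The N-1 squared successive differences are averaged with a 1/N
    normaliser, so rmssd**2 * N equals the sum of squared differences
    exactly.
    """
    x = _as_series(s)
    n = x.size
    if n < 2:
        raise InsufficientDataError(f"RMSSD needs N >= 2, got N={n}")
    d = np.diff(x)
    return float(np.sqrt((d**2).sum() / n))


_MIN_N = {"std": 2, "tkeo": 3, "entropy": 1, "rmssd": 2}


def _segment(values, dates, max_gap_days):
    """Split a date-ordered series wherever consecutive dates are > g apart."""
    if max_gap_days is None or dates is None or len(values) < 2:
        return [np.asarray(values, dtype=float)]
    values = np.asarray(values, dtype=float)
    gaps = np.diff(np.asarray(dates, dtype="datetime64[D]")).astype(int)
    cuts = np.flatnonzero(gaps > max_gap_days) + 1
    return np.split(values, cuts)


def _stats_for(values, dates, max_gap_days, tkeo_variant, entropy_base):
    """All four statistics for one series, with missing-cell reasons.

    With a ``max_gap_days`` rule in force, std and entropy still pool every
    observation, while the successive-difference statistics (TKEO, RMSSD)
    accumulate terms within segments only and share the printed 1/N
    normaliser with N the total number of observations.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    out, reasons = {}, {}

    for stat, fn in (("std", series_std), ("entropy",
                      lambda v: series_entropy(v, base=entropy_base))):
        if n < _MIN_N[stat]:
            out[stat] = np.nan
            reasons[stat] = f"needs N >= {_MIN_N[stat]}, have {n}"
        else:
            out[stat] = fn(x)

    segments = _segment(x, dates, max_gap_days)
    for stat in ("tkeo", "rmssd"):
        if n < _MIN_N[stat]:
            out[stat] = np.nan
            reasons[stat] = f"needs N >= {_MIN_N[stat]}, have {n}"
            continue
        total = 0.0
        any_terms = False
        for seg in segments:
            if stat == "tkeo" and seg.size >= 3:
                if tkeo_variant == "standard":
                    total += float((seg[1:-1] ** 2 - seg[:-2] * seg[2:]).sum())
                else:
                    total += float((seg[1:-1] ** 2 - seg[2:] ** 2).sum())
                any_terms = True
            elif stat == "rmssd" and seg.size >= 2:
                total += float((np.diff(seg) ** 2).sum())
                any_terms = True
        if not any_terms:
            out[stat] = np.nan
            reasons[stat] = "no segment long enough after gap splitting"
        elif stat == "tkeo":
            out[stat] = total / n
        else:
            out[stat] = math.sqrt(total / n)
    return out, reasons


@dataclass
class VariabilityProfile:
    """All four statistics per score series for one participant.

    ``cells[series][stat]`` holds the value (NaN when the series is too
    short; the reason then appears in ``reasons[(series, stat)]``).
    """

    participant_id: str
    cohort: str
    cells: dict = field(default_factory=dict)
    reasons: dict = field(default_factory=dict)

    def to_rows(self):
        for series, stats in self.cells.items():
            row = {"participant_id": self.participant_id, "cohort": self.cohort,
                   "series": series}
            row.update(stats)
            yield row


def variability_profile(tl, loadings, *, include_items=False,
                        max_gap_days=None, tkeo_variant="standard",
                        entropy_base=None) -> VariabilityProfile:
    """Variability statistics for one participant's score series.

    Series covered: weekly ASRM/QIDS/GAD7 totals and the EQ-5D VAS (in date
    order), and the daily MZneg/MZpos/MZirr factor series (projected with
    ``loadings``).  ``include_items=True`` adds the six raw Mood Zoom item
    series.  Consecutive observed records are treated as adjacent regardless
    of calendar gaps unless ``max_gap_days`` is set, in which case the
    successive-difference statistics are pooled within gap-free segments.
    """
    prof = VariabilityProfile(tl.participant_id, tl.cohort)

    weekly = tl.weekly_frame()
    for col in ("ASRM", "QIDS", "GAD7", "EQ5D"):
        vals = weekly[col].to_numpy() if not weekly.empty else np.array([])
        dates = weekly.index.to_numpy() if not weekly.empty else None
        stats, reasons = _stats_for(vals, dates, max_gap_days, tkeo_variant,
                                    entropy_base)
        prof.cells[col] = stats
        prof.reasons.update({(col, k): v for k, v in reasons.items()})

    factors = daily_factor_series(tl, loadings)
    daily_dates = factors.index.to_numpy() if not factors.empty else None
    for col in FACTOR_LABELS:
        vals = factors[col].to_numpy() if not factors.empty else np.array([])
        stats, reasons = _stats_for(vals, daily_dates, max_gap_days,
                                    tkeo_variant, entropy_base)
        prof.cells[col] = stats
        prof.reasons.update({(col, k): v for k, v in reasons.items()})

    if include_items:
        frame = tl.daily_frame()
        for col in frame.columns:
            vals = frame[col].to_numpy() if not frame.empty else np.array([])
            stats, reasons = _stats_for(vals, daily_dates, max_gap_days,
                                        tkeo_variant, entropy_base)
            prof.cells[f"MZ_{col}"] = stats
            prof.reasons.update({(f"MZ_{col}", k): v for k, v in reasons.items()})
    return prof


def profiles_frame(profiles) -> pd.DataFrame:
    """Tidy DataFrame of many profiles: one row per (participant, series)."""
    rows = [row for p in profiles for row in p.to_rows()]
    return pd.DataFrame(rows, columns=["participant_id", "cohort", "series",
                                       *STAT_NAMES])
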