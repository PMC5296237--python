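"""Synthetic longitudinal mood cohorts for testing the analysis pipeline.

The real study data are restricted, so this module generates stand-in
cohorts (bipolar disorder BD, borderline personality disorder BPD, healthy
controls HC) with the statistical structure the downstream analysis assumes:

* two latent daily affect processes per participant — negative and positive
  affect — each a stationary Gaussian AR(1) around a cohort-specific mean;
* daily Mood Zoom items produced by an affine map of the latents plus item
  noise, rounded and clipped to the 1-7 Likert range (anxious/sad load on
  negative affect, elated/energetic on positive, angry/irritable on negative
  affect scaled by an ``irritability_share``);
* weekly instrument items generated on prompt days from the mean latent over
  the preceding seven days (QIDS and GAD-7 from negative affect, ASRM from
  positive, EQ-5D VAS inversely from negative), with independent item noise;
* Bernoulli missingness per record, and retained weekly responses jittered
  by up to ±2 days around the prompt.

Defaults (``default_presets``) order cohorts by both negative-affect level
and day-to-day variability as HC < BD < BPD, with roughly 85% adherence
over nine months — the structure the group-comparison stages should detect.
This generator is a test harness, not a model of the disorders.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy.signal import lfilter

from .questionnaires import (
    AsrmResponse,
    Eq5dResponse,
    Gad7Response,
    MzResponse,
    QidsResponse,
)
from .timeline import ParticipantTimeline, WeeklyRecord

__all__ = [
    "CohortParams",
    "StudyConfig",
    "GeneratedStudy",
    "generate_participant",
    "generate_study",
    "default_presets",
    "load_config",
    "save_config",
]

_STUDY_START = dt.date(2020, 1, 6)  # a Monday; all enrolments share it

# Affine latent-to-item maps: item value before noise/rounding is
# intercept + slope * latent (negative latent for anxious/sad/angry/irritable,
# positive latent for elated/energetic); angry/irritable slopes are further
# multiplied by irritability_share.
_MZ_INTERCEPTS = {"anxious": 2.5, "sad": 2.5, "angry": 2.5, "irritable": 2.5,
                  "elated": 3.5, "energetic": 3.5}
_WEEKLY_ITEM_NOISE_SD = 0.45
_EQ5D_NOISE_SD = 6.0


@dataclass
class CohortParams:
    """Generative settings for one cohort.

    Latent units are arbitrary: a one-unit change in negative affect moves
    the anxious/sad items by one Likert point before rounding.  ``neg_sd`` /
    ``pos_sd`` are AR(1) innovation standard deviations; the stationary
    spread is ``sd / sqrt(1 - ar_coef**2)``.
    """

    label: str
    n_participants: int
    n_days: int
    neg_mean: float
    pos_mean: float
    neg_sd: float
    pos_sd: float
    ar_coef: float
    daily_missing_prob: float = 0.0
    weekly_missing_prob: float = 0.0
    irritability_share: float = 0.6
    irr_sd: float | None = None  # innovation sd of the extra irritability AR(1)
    item_noise_sd: float = 0.7  # per-item daily noise before rounding

    def __post_init__(self):
        if self.n_participants < 0:
            raise ValueError(f"{self.label}: n_participants must be >= 0")
        if self.n_participants == 0:
            warnings.warn(f"cohort {self.label} has zero participants", stacklevel=3)
        if self.n_days < 14:
            raise ValueError(f"{self.label}: n_days must be >= 14")
        if self.neg_sd <= 0 or self.pos_sd <= 0:
            raise ValueError(f"{self.label}: innovation sds must be > 0")
        if not (0 <= self.ar_coef < 1):
            raise ValueError(f"{self.label}: ar_coef must be in [0, 1)")
        for name in ("daily_missing_prob", "weekly_missing_prob"):
            p = getattr(self, name)
            if not (0 <= p < 1):
                raise ValueError(f"{self.label}: {name} must be in [0, 1)")
        if self.irr_sd is None:
            self.irr_sd = 0.6 * self.neg_sd
        if self.irr_sd <= 0:
            raise ValueError(f"{self.label}: irr_sd must be > 0")
        if self.item_noise_sd < 0:
            raise ValueError(f"{self.label}: item_noise_sd must be >= 0")


@dataclass
class StudyConfig:
    """A full synthetic study: cohorts, master seed and prompt schedule."""

    cohorts: list
    seed: int = 0
    weekly_prompt_weekday: int = 0  # Monday

    def __post_init__(self):
        labels = [c.label for c in self.cohorts]
        if len(labels) != len(set(labels)):
            raise ValueError(f"duplicate cohort labels: {labels}")
        if not (0 <= self.weekly_prompt_weekday <= 6):
            raise ValueError("weekly_prompt_weekday must be in 0..6")


@dataclass
class GeneratedStudy:
    """Generated timelines plus an echo of the config that produced them."""

    timelines: list
    config: StudyConfig = field(repr=False, default=None)


def _ar1(rng, n, sd, ar):
    """Stationary zero-mean AR(1) path of length n."""
    stat_sd = sd / np.sqrt(1.0 - ar**2)
    eps = rng.normal(0.0, sd, size=n)
    eps[0] = rng.normal(0.0, stat_sd)
    return lfilter([1.0], [1.0, -ar], eps)


def _likert(rng, loc, lo, hi, noise_sd, size=None):
    if size is None:
        size = np.shape(loc)
    vals = np.rint(loc + rng.normal(0.0, noise_sd, size=size))
    return np.clip(vals, lo, hi).astype(int)


def generate_participant(params: CohortParams, participant_seed: int,
                         participant_id: str | None = None,
                         weekly_prompt_weekday: int = 0) -> ParticipantTimeline:
    """Generate one participant's daily and weekly streams.

    Fully determined by ``params`` and ``participant_seed``; weekly records
    are derived from the mean latent negative/positive affect over the seven
    days preceding each prompt, so daily-to-weekly alignment methods can be
    validated against a known ground truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence(int(participant_seed)))
    n = params.n_days
    pid = participant_id or f"{params.label}_{participant_seed}"
    start = _STUDY_START
    end = start + dt.timedelta(days=n - 1)

    neg = params.neg_mean + _ar1(rng, n, params.neg_sd, params.ar_coef)
    pos = params.pos_mean + _ar1(rng, n, params.pos_sd, params.ar_coef)
    # Irritability rides on negative affect (share) plus its own AR(1)
    # component, so the angry/irritable items fluctuate beyond what anxious/
    # sad explain and an irritability contrast carries cohort signal.
    irr = _ar1(rng, n, params.irr_sd, params.ar_coef)
    share = params.irritability_share

    item_latents = {
        "anxious": neg,
        "elated": pos,
        "sad": neg,
        "angry": share * neg + irr,
        "irritable": share * neg + irr,
        "energetic": pos,
    }
    items = {
        name: _likert(rng, _MZ_INTERCEPTS[name] + lat, 1, 7, params.item_noise_sd)
        for name, lat in item_latents.items()
    }

    daily_kept = rng.random(n) >= params.daily_missing_prob
    daily = {}
    for t in range(n):
        if daily_kept[t]:
            daily[start + dt.timedelta(days=t)] = MzResponse(
                *(int(items[name][t]) for name in item_latents)
            )

    # Weekly prompts on the configured weekday, answerable from day 7 on so a
    # full preceding week of latents exists.
    first = start + dt.timedelta(days=(weekly_prompt_weekday - start.weekday()) % 7)
    prompts = []
    d = first
    while d <= end:
        prompts.append(d)
        d += dt.timedelta(days=7)

    weekly = {}
    for p in prompts:
        t = (p - start).days
        if t < 7:
            continue  # no full preceding week of latent history yet
        if rng.random() < params.weekly_missing_prob:
            continue
        mean_neg = float(neg[t - 7:t].mean())
        mean_pos = float(pos[t - 7:t].mean())
        qids = QidsResponse(tuple(
            _likert(rng, 0.8 + 0.7 * mean_neg, 0, 3, _WEEKLY_ITEM_NOISE_SD, size=16)
        ))
        gad7 = Gad7Response(tuple(
            _likert(rng, 0.8 + 0.7 * mean_neg, 0, 3, _WEEKLY_ITEM_NOISE_SD, size=7)
        ))
        asrm = AsrmResponse(tuple(
            _likert(rng, 0.6 + 0.7 * mean_pos, 0, 4, _WEEKLY_ITEM_NOISE_SD, size=5)
        ))
        vas = float(np.clip(np.rint(75.0 - 12.0 * mean_neg
                                    + rng.normal(0.0, _EQ5D_NOISE_SD)), 0, 100))
        rec = WeeklyRecord(asrm=asrm, qids=qids, gad7=gad7, eq5d=Eq5dResponse(vas))
        # Completion jitter: within ±2 days of the prompt, clipped to the window.
        offset = int(rng.integers(-2, 3))
        rec_date = min(max(p + dt.timedelta(days=offset), start), end)
        weekly[rec_date] = rec

    return ParticipantTimeline(
        participant_id=pid,
        cohort=params.label,
        enrolment_start=start,
        enrolment_end=end,
        daily=daily,
        weekly=weekly,
        weekly_prompt_dates=prompts,
    )


def _participant_seed(master_seed, cohort_index, participant_index):
    # Stable per-participant hash: adding participants or cohorts never
    # perturbs earlier ones.
    return (int(master_seed) * 1_000_003
            + cohort_index * 75_029
            + participant_index * 193) % (2**31 - 1)


def generate_study(config: StudyConfig) -> GeneratedStudy:
    """Generate every cohort of a study configuration, deterministically."""
    timelines = []
    for ci, params in enumerate(config.cohorts):
        for pi in range(params.n_participants):
            seed = _participant_seed(config.seed, ci, pi)
            tl = generate_participant(
                params,
                seed,
                participant_id=f"{params.label}{pi + 1:03d}",
                weekly_prompt_weekday=config.weekly_prompt_weekday,
            )
            timelines.append(tl)
    return GeneratedStudy(timelines=timelines, config=config)


def default_presets(seed: int = 0, *, n_participants: int = 30,
                    n_days: int = 270) -> StudyConfig:
    """Study-condition presets for the three cohorts.

    Negative-affect levels and innovation spreads are ordered
    HC < BD < BPD; missingness 0.15 gives expected adherence of 85%.
    These reproduce the orderings the analysis is built to detect, not any
    particular study's printed coefficients.
    """
    common = dict(n_participants=n_participants, n_days=n_days,
                  daily_missing_prob=0.15, weekly_missing_prob=0.15)
    cohorts = [
        CohortParams(label="BD", neg_mean=0.4, pos_mean=0.2,
                     neg_sd=0.7, pos_sd=0.6, ar_coef=0.6, **common),
        CohortParams(label="BPD", neg_mean=1.4, pos_mean=0.4,
                     neg_sd=1.1, pos_sd=0.7, ar_coef=0.5, **common),
        CohortParams(label="HC", neg_mean=-0.8, pos_mean=0.3,
                     neg_sd=0.35, pos_sd=0.5, ar_coef=0.5, **common),
    ]
    return StudyConfig(cohorts=cohorts, seed=seed, weekly_prompt_weekday=0)


def save_config(config: StudyConfig, path):
    """Write a StudyConfig to YAML."""
    doc = {
        "seed": config.seed,
        "weekly_prompt_weekday": config.weekly_prompt_weekday,
        "cohorts": [asdict(c) for c in config.cohorts],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> StudyConfig:
    """Read a StudyConfig from YAML."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    cohorts = [CohortParams(**c) for c in doc["cohorts"]]
    return StudyConfig(
        cohorts=cohorts,
        seed=int(doc.get("seed", 0)),
        weekly_prompt_weekday=int(doc.get("weekly_prompt_weekday", 0)),
    )
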