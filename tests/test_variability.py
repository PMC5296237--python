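"""The four variability statistics against hand values and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moodkit.synthetic import default_presets, generate_study
from moodkit.latent import fit_mz_pca
from moodkit.variability import (
    InsufficientDataError,
    series_entropy,
    series_rmssd,
    series_std,
    series_tkeo,
    variability_profile,
)


# ---------------------------------------------------------------- oracles
def brute_std(x):
    n = len(x)
    m = sum(x) / n
    return math.sqrt(sum((v - m) ** 2 for v in x) / (n - 1))


def brute_tkeo(x):
    n = len(x)
    total = 0.0
    for i in range(1, n - 1):
        total += x[i] ** 2 - x[i - 1] * x[i + 1]
    return total / n


def brute_entropy(x):
    n = len(x)
    counts = {}
    for v in x:
        counts[v] = counts.get(v, 0) + 1
    h = 0.0
    for c in counts.values():
        p = c / n
        h -= p * math.log(p)
    return h


def brute_rmssd(x):
    n = len(x)
    total = 0.0
    for i in range(n - 1):
        total += (x[i + 1] - x[i]) ** 2
    return math.sqrt(total / n)


# ---------------------------------------------------------- hand examples
@pytest.mark.parametrize(
    "fn, series, expected",
    [
        (series_std, (0.0, 2.0), math.sqrt(2.0)),
        (series_tkeo, (1.0, 2.0, 3.0), 1.0 / 3.0),
        (series_tkeo, (2.0, 0.0, 2.0, 0.0), 0.0),
        (series_entropy, (1, 1, 2, 2), math.log(2)),
        (series_rmssd, (1.0, 2.0, 3.0), math.sqrt(2.0 / 3.0)),
        (series_rmssd, (0.0, 2.0, 0.0, 2.0), math.sqrt(3.0)),
    ],
)
def test_hand_computed_values(fn, series, expected):
    assert fn(series) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "fn", [series_std, series_tkeo, series_entropy, series_rmssd]
)
def test_constant_series_gives_zero(fn):
    assert fn([3.0] * 10) == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize(
    "fn, n_min", [(series_std, 2), (series_tkeo, 3), (series_rmssd, 2)]
)
def test_insufficient_data_errors(fn, n_min):
    with pytest.raises(InsufficientDataError):
        fn([1.0] * (n_min - 1))


def test_entropy_single_observation_is_zero():
    assert series_entropy([5.0]) == 0.0


def test_entropy_equifrequent_bound():
    """K equifrequent distinct values reach the ln K maximum."""
    for k in (2, 3, 7, 12):
        x = list(range(k)) * 4
        assert series_entropy(x) == pytest.approx(math.log(k), abs=1e-12)
        assert series_entropy(x + [0]) < math.log(k) + 1e-12


def test_entropy_base_option():
    assert series_entropy([1, 1, 2, 2], base=2) == pytest.approx(1.0, abs=1e-12)


def test_tkeo_printed_variant_telescopes():
    """The as-printed variant reduces to (x_1^2 + x_2^2 - x_{N-1}^2 - x_N^2)/N...

    i.e. a boundary difference; on (1,2,3,4): ((4-9)+(9-16))/4 = -3.
    """
    x = [1.0, 2.0, 3.0, 4.0]
    assert series_tkeo(x, variant="printed") == pytest.approx(-3.0, abs=1e-12)
    assert series_tkeo(x, variant="standard") == pytest.approx(
        ((4 - 3) + (9 - 8)) / 4, abs=1e-12)


def test_oracle_equivalence_on_random_series():
    """All four statistics match brute-force loops on 1,000 short series."""
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        n = int(rng.integers(3, 21))
        x = np.round(rng.normal(0, 3, size=n), 1)  # rounding forces ties
        xs = x.tolist()
        assert series_std(x) == pytest.approx(brute_std(xs), abs=1e-12)
        assert series_tkeo(x) == pytest.approx(brute_tkeo(xs), abs=1e-12)
        assert series_entropy(x) == pytest.approx(brute_entropy(xs), abs=1e-12)
        assert series_rmssd(x) == pytest.approx(brute_rmssd(xs), abs=1e-12)


@given(st.lists(st.integers(-50, 50), min_size=3, max_size=25),
       st.integers(-20, 20))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_translation_behaviour(values, shift):
    """std/rmssd/entropy ignore shifts; mean TKEO picks up an exact O(1/N)
    boundary term c*((x_2-x_1) + (x_{N-1}-x_N))/N."""
    x = np.asarray(values, dtype=float)
    y = x + shift
    assert series_std(y) == pytest.approx(series_std(x), abs=1e-9)
    assert series_rmssd(y) == pytest.approx(series_rmssd(x), abs=1e-9)
    assert series_entropy(y) == pytest.approx(series_entropy(x), abs=1e-12)
    boundary = shift * ((x[1] - x[0]) + (x[-2] - x[-1])) / len(x)
    assert series_tkeo(y) == pytest.approx(series_tkeo(x) + boundary, abs=1e-9)


@given(st.lists(st.integers(-20, 20), min_size=3, max_size=25),
       st.integers(1, 5))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_scaling_behaviour(values, c):
    """std/rmssd scale with |c|, TKEO with c^2, entropy not at all."""
    x = np.asarray(values, dtype=float)
    y = c * x
    assert series_std(y) == pytest.approx(c * series_std(x), rel=1e-9, abs=1e-9)
    assert series_rmssd(y) == pytest.approx(c * series_rmssd(x), rel=1e-9, abs=1e-9)
    assert series_tkeo(y) == pytest.approx(c**2 * series_tkeo(x), rel=1e-9, abs=1e-9)
    assert series_entropy(y) == pytest.approx(series_entropy(x), abs=1e-12)


def test_rmssd_identity():
    rng = np.random.default_rng(5)
    x = rng.normal(size=40)
    ssd = float((np.diff(x) ** 2).sum())
    assert series_rmssd(x) ** 2 * len(x) == pytest.approx(ssd, rel=1e-12)


# ------------------------------------------------------------- profiles
def test_profile_on_degenerate_generator(small_loadings):
    """Near-zero innovation and item variance yields all-zero MZ variability."""
    from moodkit.synthetic import CohortParams, StudyConfig, generate_study

    # means off the .5 rounding boundary so vanishing noise cannot flip items
    cfg = StudyConfig(cohorts=[CohortParams(
        label="FLAT", n_participants=1, n_days=30, neg_mean=0.3, pos_mean=0.3,
        neg_sd=1e-9, pos_sd=1e-9, ar_coef=0.0, irr_sd=1e-9,
        item_noise_sd=0.0)], seed=3)
    tl = generate_study(cfg).timelines[0]
    assert len({rec.as_tuple() for rec in tl.daily.values()}) == 1
    loadings = small_loadings
    prof = variability_profile(tl, loadings)
    for series in ("MZneg", "MZpos", "MZirr"):
        for stat in ("std", "tkeo", "entropy", "rmssd"):
            assert prof.cells[series][stat] == pytest.approx(0.0, abs=1e-9)


def test_profile_short_series_marked_missing(small_loadings):
    import datetime as dt

    from moodkit.questionnaires import MzResponse
    from moodkit.timeline import ParticipantTimeline

    day = dt.date(2020, 1, 6)
    tl = ParticipantTimeline(
        participant_id="x", cohort="HC", enrolment_start=day,
        enrolment_end=day + dt.timedelta(days=20),
        daily={day: MzResponse(4, 4, 4, 4, 4, 4)})
    prof = variability_profile(tl, small_loadings)
    assert np.isnan(prof.cells["MZneg"]["std"])
    assert ("MZneg", "std") in prof.reasons
    assert np.isnan(prof.cells["QIDS"]["rmssd"])
    # entropy needs only one observation
    assert prof.cells["MZneg"]["entropy"] == 0.0


def test_variability_increases_with_innovation_sd():
    """Monte-Carlo monotonicity: larger neg_sd -> larger MZneg std and RMSSD."""
    from moodkit.synthetic import CohortParams, StudyConfig
    from moodkit.inference import participant_variability_values

    medians = []
    for sd in (0.3, 0.7, 1.4):
        cfg = StudyConfig(cohorts=[CohortParams(
            label="G", n_participants=8, n_days=120, neg_mean=0.3, pos_mean=0.0,
            neg_sd=sd, pos_sd=0.5, ar_coef=0.5)], seed=11)
        study = generate_study(cfg)
        loadings = fit_mz_pca(study.timelines)
        vals = participant_variability_values(study.timelines, loadings)
        row = vals[vals.variable.isin(["MZneg_std", "MZneg_rmssd"])]
        medians.append(row.groupby("variable")["value"].median())
    for var in ("MZneg_std", "MZneg_rmssd"):
        seq = [m[var] for m in medians]
        assert seq[0] < seq[1] < seq[2]


def test_max_gap_splitting_drops_cross_gap_terms(small_loadings):
    """With a gap rule, successive-difference terms never straddle long gaps."""
    import datetime as dt

    from moodkit.questionnaires import MzResponse
    from moodkit.timeline import ParticipantTimeline

    start = dt.date(2020, 1, 6)
    daily = {}
    # two runs of constant-but-different values separated by a 10-day gap
    for k in range(5):
        daily[start + dt.timedelta(days=k)] = MzResponse(2, 4, 2, 2, 2, 4)
    for k in range(15, 20):
        daily[start + dt.timedelta(days=k)] = MzResponse(6, 4, 6, 6, 6, 4)
    tl = ParticipantTimeline(
        participant_id="g", cohort="HC", enrolment_start=start,
        enrolment_end=start + dt.timedelta(days=25), daily=daily)
    gapped = variability_profile(tl, small_loadings, max_gap_days=3)
    pooled = variability_profile(tl, small_loadings)
    # within each run the series is constant, so the only squared difference
    # comes from the jump across the gap; the gap rule removes it entirely
    assert gapped.cells["MZneg"]["rmssd"] == pytest.approx(0.0, abs=1e-12)
    assert pooled.cells["MZneg"]["rmssd"] > 0.5
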