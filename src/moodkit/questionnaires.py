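"""Self-report mood instruments: validation, total scores and clinical bands.

Four weekly patient-reported outcome measures (PROMs) are modelled:

* **ASRM** — Altman Self-Rating Mania scale; 5 items scored 0-4, total 0-20,
  with a manic-episode screening cut-off at 5.5.
* **QIDS-SR16** — Quick Inventory of Depressive Symptomatology (self-report);
  16 items scored 0-3, collapsed to nine clinical symptom domains, total 0-27.
* **GAD-7** — Generalised Anxiety Disorder scale; 7 items scored 0-3,
  total 0-21, severity cut-offs at 5 / 10 / 15.
* **EQ-5D VAS** — EuroQoL visual-analogue quality-of-life rating, 0-100.
  Only the VAS item is modelled; the descriptive EQ-5D dimensions are not.

Plus the daily **Mood Zoom** questionnaire: six mood adjectives (anxious,
elated, sad, angry, irritable, energetic), each rated on a 1-7 Likert scale.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ValidationError",
    "AsrmResponse",
    "QidsResponse",
    "Gad7Response",
    "Eq5dResponse",
    "MzResponse",
    "SeverityBand",
    "score_asrm",
    "classify_asrm",
    "qids_domains",
    "score_qids",
    "classify_qids",
    "score_gad7",
    "classify_gad7",
    "validate_mz",
    "ASRM_ITEM_LABELS",
    "GAD7_ITEM_LABELS",
    "QIDS_DOMAIN_LABELS",
    "MZ_ITEM_LABELS",
    "QIDS_BANDS",
    "GAD7_BANDS",
]

ASRM_ITEM_LABELS = ("happy", "confident", "sleep", "talkative", "active")
GAD7_ITEM_LABELS = (
    "nervous_anxious",
    "control_worries",
    "worried",
    "relaxed",
    "restless",
    "irritable",
    "afraid",
)
QIDS_DOMAIN_LABELS = (
    "sleep",
    "sad",
    "appetite_weight",
    "concentration",
    "self_view",
    "suicide",
    "interest",
    "energy",
    "restless",
)
MZ_ITEM_LABELS = ("anxious", "elated", "sad", "angry", "irritable", "energetic")


class ValidationError(ValueError):
    """An item value is outside its instrument's permitted range."""


def _is_int(v):
    import numbers

    return isinstance(v, numbers.Integral) and not isinstance(v, bool)


def _check_items(items, n, lo, hi, instrument):
    items = tuple(items)
    if len(items) != n:
        raise ValidationError(f"{instrument}: expected {n} items, got {len(items)}")
    for i, v in enumerate(items, start=1):
        if not _is_int(v) or not (lo <= v <= hi):
            raise ValidationError(
                f"{instrument}: item {i} must be an integer in [{lo}, {hi}], got {v!r}"
            )
    return tuple(int(v) for v in items)


@dataclass(frozen=True)
class AsrmResponse:
    """Five mania items (happy, confident, sleep, talkative, active), each 0-4."""

    items: tuple

    def __post_init__(self):
        object.__setattr__(self, "items", _check_items(self.items, 5, 0, 4, "ASRM"))


@dataclass(frozen=True)
class QidsResponse:
    """Sixteen depression items in standard QIDS-SR16 order, each 0-3."""

    items: tuple

    def __post_init__(self):
        object.__setattr__(self, "items", _check_items(self.items, 16, 0, 3, "QIDS"))


@dataclass(frozen=True)
class Gad7Response:
    """Seven anxiety items, each 0-3."""

    items: tuple

    def __post_init__(self):
        object.__setattr__(self, "items", _check_items(self.items, 7, 0, 3, "GAD-7"))


@dataclass(frozen=True)
class Eq5dResponse:
    """Quality-of-life visual-analogue rating on a 0-100 scale."""

    vas: float

    def __post_init__(self):
        if not (0 <= self.vas <= 100):
            raise ValidationError(f"EQ-5D: VAS must be in [0, 100], got {self.vas!r}")


@dataclass(frozen=True)
class MzResponse:
    """Daily Mood Zoom response: six mood adjectives on a 1-7 Likert scale."""

    anxious: int
    elated: int
    sad: int
    angry: int
    irritable: int
    energetic: int

    def __post_init__(self):
        for name in MZ_ITEM_LABELS:
            v = getattr(self, name)
            if not _is_int(v) or not (1 <= v <= 7):
                raise ValidationError(
                    f"Mood Zoom: item '{name}' must be an integer in [1, 7], got {v!r}"
                )
            object.__setattr__(self, name, int(v))

    def as_tuple(self):
        return tuple(getattr(self, name) for name in MZ_ITEM_LABELS)


@dataclass(frozen=True)
class SeverityBand:
    """One clinical severity band of an instrument's total-score range.

    Bands of a given instrument partition its full integer total range:
    every valid total falls in exactly one band.
    """

    instrument: str
    band: str
    lower: int
    upper: int

    def __contains__(self, total):
        return self.lower <= total <= self.upper


QIDS_BANDS = (
    SeverityBand("QIDS", "normal", 0, 5),
    SeverityBand("QIDS", "mild", 6, 10),
    SeverityBand("QIDS", "moderate", 11, 15),
    SeverityBand("QIDS", "severe", 16, 20),
    SeverityBand("QIDS", "very severe", 21, 27),
)

# Upper edges 9 and 14 are implied by the published cut-offs 5 / 10 / 15,
# not printed alongside them.
GAD7_BANDS = (
    SeverityBand("GAD-7", "none", 0, 4),
    SeverityBand("GAD-7", "mild", 5, 9),
    SeverityBand("GAD-7", "moderate", 10, 14),
    SeverityBand("GAD-7", "severe", 15, 21),
)

# Midpoint between largest integer total screening negative (5) and the
# smallest screening positive (6); integer totals cannot sit on it exactly.
ASRM_MANIA_CUTOFF = 5.5


def score_asrm(resp: AsrmResponse) -> int:
    """Total ASRM mania score: sum of the five items, range 0-20."""
    if not isinstance(resp, AsrmResponse):
        resp = AsrmResponse(tuple(resp))
    return sum(resp.items)


def classify_asrm(total: int) -> bool:
    """Screen a total ASRM score for a manic episode (cut-off 5.5).

    Returns True iff ``total > 5.5``, i.e. total >= 6 on integer totals.
    """
    if not (0 <= total <= 20):
        raise ValueError(f"ASRM total must be in [0, 20], got {total!r}")
    return total > ASRM_MANIA_CUTOFF


def qids_domains(resp: QidsResponse) -> dict:
    """Collapse the 16 QIDS-SR16 items into the nine clinical symptom domains.

    Standard QIDS-SR16 scoring: sleep = max of items 1-4, appetite/weight =
    max of items 6-9, psychomotor restlessness = max of items 15-16; the
    remaining six domains are single items. Each domain scores 0-3.
    """
    if not isinstance(resp, QidsResponse):
        resp = QidsResponse(tuple(resp))
    it = resp.items  # 0-based
    return {
        "sleep": max(it[0:4]),
        "sad": it[4],
        "appetite_weight": max(it[5:9]),
        "concentration": it[9],
        "self_view": it[10],
        "suicide": it[11],
        "interest": it[12],
        "energy": it[13],
        "restless": max(it[14:16]),
    }


def score_qids(resp: QidsResponse) -> int:
    """Total QIDS depression score: sum of the nine domain scores, range 0-27."""
    return sum(qids_domains(resp).values())


def _classify(total, bands, lo, hi, instrument):
    if not (lo <= total <= hi):
        raise ValueError(f"{instrument} total must be in [{lo}, {hi}], got {total!r}")
    for band in bands:
        if total in band:
            return band
    raise AssertionError("bands do not partition the total range")  # pragma: no cover


def classify_qids(total: int) -> SeverityBand:
    """Map a QIDS total to its clinical severity band (normal .. very severe)."""
    return _classify(total, QIDS_BANDS, 0, 27, "QIDS")


def score_gad7(resp: Gad7Response) -> int:
    """Total GAD-7 anxiety score: sum of the seven items, range 0-21."""
    if not isinstance(resp, Gad7Response):
        resp = Gad7Response(tuple(resp))
    return sum(resp.items)


def classify_gad7(total: int) -> SeverityBand:
    """Map a GAD-7 total to its severity band (cut-offs at 5, 10, 15)."""
    return _classify(total, GAD7_BANDS, 0, 21, "GAD-7")


def validate_mz(values) -> MzResponse:
    """Validate six Mood Zoom Likert values and return an `MzResponse`.

    Accepts an `MzResponse`, a mapping keyed by item name, or a sequence in
    canonical item order (anxious, elated, sad, angry, irritable, energetic).
    """
    if isinstance(values, MzResponse):
        return values
    if isinstance(values, dict):
        return MzResponse(**{k: values[k] for k in MZ_ITEM_LABELS})
    vals = tuple(values)
    if len(vals) != 6:
        raise ValidationError(f"Mood Zoom: expected 6 items, got {len(vals)}")
    return MzResponse(*vals)
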