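"""Latent structure of the daily Mood Zoom items.

Principal component analysis of the six Mood Zoom items, pooled over all
participants' daily records, yields six orthonormal components P1-P6.  The
first three carry the familiar interpretation: a negative-affect factor
(MZneg: anxious/sad with angry/irritable), a positive-affect factor (MZpos:
elated/energetic), and an irritability contrast (MZirr: angry/irritable
against anxious/sad).  Factor scores are linear projections of the centred
item vector onto these components; per-cohort refits are compared to the
pooled solution via Tucker congruence coefficients to assess stability.

PCA is run on the item covariance matrix by default (the six items share the
1-7 scale); a correlation-matrix variant is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .questionnaires import MZ_ITEM_LABELS

__all__ = [
    "MzLoadings",
    "FACTOR_LABELS",
    "fit_mz_pca",
    "factor_scores",
    "pooled_daily_matrix",
    "per_group_stability",
    "tucker_congruence",
]

FACTOR_LABELS = ("MZneg", "MZpos", "MZirr")
COMPONENT_LABELS = tuple(f"P{k}" for k in range(1, 7))


@dataclass
class MzLoadings:
    """Orthonormal 6x6 PCA loading matrix for the Mood Zoom items.

    Rows follow the canonical item order (anxious .. energetic); columns are
    components P1..P6 in decreasing eigenvalue order.  Sign convention: each
    column is flipped so its largest-magnitude loading is positive, which
    makes MZneg increase with sadness/anxiety and MZpos with elation/energy.
    ``item_scales`` is all-ones for covariance PCA and the per-item standard
    deviations for correlation PCA.
    """

    loadings: np.ndarray
    pct_variance: np.ndarray
    item_means: np.ndarray
    item_scales: np.ndarray
    method: str = "covariance"

    @property
    def cumulative_pct(self) -> np.ndarray:
        return np.cumsum(self.pct_variance)

    def to_frame(self) -> pd.DataFrame:
        """Loading matrix plus variance rows, one column per component."""
        df = pd.DataFrame(self.loadings, index=list(MZ_ITEM_LABELS),
                          columns=list(COMPONENT_LABELS))
        df.loc["pct_variance"] = self.pct_variance
        df.loc["cumulative_pct"] = self.cumulative_pct
        return df


def pooled_daily_matrix(timelines) -> np.ndarray:
    """Stack every participant's daily Mood Zoom rows into an (n, 6) array."""
    rows = [rec.as_tuple() for tl in timelines for rec in tl.daily.values()]
    return np.asarray(rows, dtype=float)


def fit_mz_pca(records, method: str = "covariance") -> MzLoadings:
    """Fit the pooled PCA of the six Mood Zoom items.

    ``records`` is an (n, 6) array-like of daily item rows (or a list of
    timelines, which are pooled first).  Components are ordered by
    decreasing explained variance; percentages sum to 100.
    """
    if method not in ("covariance", "correlation"):
        raise ValueError(f"unknown PCA method {method!r}")
    X = np.asarray(records, dtype=float) if not _is_timelines(records) \
        else pooled_daily_matrix(records)
    if X.ndim != 2 or X.shape[1] != 6:
        raise ValueError(f"expected an (n, 6) item matrix, got shape {X.shape}")
    n = X.shape[0]
    if n < 7:
        warnings.warn(f"only {n} rows for a 6-item PCA; solution is rank-deficient",
                      stacklevel=2)
    stds = X.std(axis=0, ddof=1) if n > 1 else np.zeros(6)
    dead = [MZ_ITEM_LABELS[i] for i in np.flatnonzero(stds == 0)]
    if dead:
        raise ValueError(f"zero-variance item(s): {dead}; PCA is degenerate")

    means = X.mean(axis=0)
    scales = stds if method == "correlation" else np.ones(6)
    Z = (X - means) / scales

    cov = np.cov(Z, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)  # guard tiny negative round-off
    loadings = evecs[:, order]
    for k in range(6):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1.0
    pct = 100.0 * evals / evals.sum()
    return MzLoadings(loadings=loadings, pct_variance=pct, item_means=means,
                      item_scales=scales, method=method)


def _is_timelines(obj):
    return isinstance(obj, (list, tuple)) and obj and hasattr(obj[0], "daily")


def factor_scores(records, loadings: MzLoadings, n_components=3) -> pd.DataFrame:
    """Project item rows onto the leading components.

    Scores are ``(items - item_means) / item_scales @ loadings[:, :k]``; the
    first three columns are labelled MZneg, MZpos, MZirr.
    """
    X = np.asarray(records, dtype=float)
    one = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != 6:
        raise ValueError(f"expected 6 items per row, got {X.shape[1]}")
    Z = (X - loadings.item_means) / loadings.item_scales
    S = Z @ loadings.loadings[:, :n_components]
    cols = [FACTOR_LABELS[k] if k < 3 else COMPONENT_LABELS[k]
            for k in range(n_components)]
    df = pd.DataFrame(S, columns=cols)
    return df.iloc[0] if one else df


def daily_factor_series(tl, loadings: MzLoadings) -> pd.DataFrame:
    """Date-indexed MZneg/MZpos/MZirr score series for one participant."""
    frame = tl.daily_frame()
    if frame.empty:
        return pd.DataFrame(columns=list(FACTOR_LABELS), dtype=float)
    scores = factor_scores(frame.to_numpy(), loadings)
    scores.index = frame.index
    return scores


def tucker_congruence(u, v) -> float:
    """Tucker congruence |cos angle| between two loading vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    return float(abs(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v)))


def per_group_stability(timelines, loadings: MzLoadings, n_components=3,
                        min_rows=7) -> pd.DataFrame:
    """Congruence of per-cohort PCA loadings with the pooled solution.

    Each cohort's daily rows are refit with the same PCA settings; every
    pooled component P1..Pk is matched to the per-cohort component with the
    largest |congruence| (greedy in component order, ties to the earlier
    component).  Cohorts with fewer than ``min_rows`` rows are skipped with
    a warning.
    """
    cohorts = {}
    for tl in timelines:
        cohorts.setdefault(tl.cohort, []).append(tl)
    rows = []
    for label in sorted(cohorts):
        X = pooled_daily_matrix(cohorts[label])
        if X.shape[0] < min_rows:
            warnings.warn(f"cohort {label}: only {X.shape[0]} rows; skipped",
                          stacklevel=2)
            continue
        local = fit_mz_pca(X, method=loadings.method)
        taken = set()
        for k in range(n_components):
            phis = [
                -np.inf if j in taken
                else tucker_congruence(loadings.loadings[:, k], local.loadings[:, j])
                for j in range(6)
            ]
            j = int(np.argmax(phis))
            taken.add(j)
            rows.append({
                "cohort": label,
                "component": COMPONENT_LABELS[k],
                "factor": FACTOR_LABELS[k] if k < 3 else COMPONENT_LABELS[k],
                "matched_component": COMPONENT_LABELS[j],
                "congruence": phis[j],
            })
    return pd.DataFrame(rows)
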