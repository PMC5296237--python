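"""Nonparametric association and group-comparison statistics.

Two families of analysis:

* Spearman rank correlations between weekly instrument items/totals and the
  aligned daily Mood Zoom summaries (items and PCA factors), pooled over
  all participants' aligned pairs.  Correlations of magnitude >= 0.3 are
  flagged as "statistically strong" (the conventional medical guideline);
  significance is flagged at p < 1e-4.
* Per-variable cohort summaries (median ± IQR of per-participant values)
  with pairwise two-sided Wilcoxon rank-sum tests between cohorts.

No multiple-testing correction is applied — tables report raw p-values and
the number of tests performed, so users may apply their own correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .latent import FACTOR_LABELS, factor_scores
from .questionnaires import MZ_ITEM_LABELS
from .timeline import align_daily_to_weekly, weekly_item_values
from .variability import STAT_NAMES, profiles_frame, variability_profile

__all__ = [
    "SpearmanResult",
    "spearman",
    "wilcoxon_rank_sum",
    "association_table",
    "comparison_table",
    "participant_summary_values",
    "participant_variability_values",
    "STRONG_RHO",
    "SIGNIFICANCE_P",
]

STRONG_RHO = 0.3
SIGNIFICANCE_P = 1e-4
_EXACT_SPEARMAN_N = 9
_EXACT_WILCOXON_TOTAL = 20


@dataclass
class SpearmanResult:
    rho: float
    p: float
    n: int
    undefined: bool = False


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation with mid-ranks for ties.

    rho is the Pearson correlation of the mid-rank transforms.  For n <= 9
    the p-value is an exact permutation tail probability (two-sided,
    P(|rho_perm| >= |rho_obs|) over all pairings); for larger n the
    large-sample t approximation is used.  Zero-variance input yields an
    undefined result rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return SpearmanResult(float("nan"), float("nan"), n, undefined=True)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= _EXACT_SPEARMAN_N:
        perms = np.array(list(itertools.permutations(rx)))
        zx = perms - rx.mean()
        zy = ry - ry.mean()
        rhos = (zx @ zy) / np.sqrt((zx**2).sum(axis=1) * (zy**2).sum())
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return SpearmanResult(rho, min(p, 1.0), n)


def wilcoxon_rank_sum(a, b, method: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``auto`` uses the exact null distribution when the combined sample has
    at most 20 observations and no ties, and the normal approximation with
    tie and continuity corrections otherwise.  ``exact`` / ``asymptotic``
    force the choice.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if method == "auto":
        ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        method = "exact" if (a.size + b.size <= _EXACT_WILCOXON_TOTAL and not ties) \
            else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.pvalue)


def _iqr(values):
    v = np.asarray(values, dtype=float)
    return float(np.quantile(v, 0.75) - np.quantile(v, 0.25))


def _aligned_pairs_frame(timelines, loadings, alignment_method):
    """Pool every participant's aligned (weekly, MZ-summary) pairs."""
    rows = []
    for tl in timelines:
        result = align_daily_to_weekly(tl, alignment_method)
        for pair in result.pairs:
            row = {"participant_id": tl.participant_id, "cohort": tl.cohort}
            row.update(weekly_item_values(pair.weekly))
            mz = [pair.mz_summary[item] for item in MZ_ITEM_LABELS]
            row.update({f"mz_{item}": v for item, v in zip(MZ_ITEM_LABELS, mz)})
            scores = factor_scores(mz, loadings)
            row.update({f: float(scores[f]) for f in FACTOR_LABELS})
            rows.append(row)
    return pd.DataFrame(rows)


def association_table(timelines, loadings, alignment_method="mean_prev_week",
                      min_pairs=3) -> pd.DataFrame:
    """Spearman association matrix of weekly measures vs Mood Zoom summaries.

    Rows pair each weekly item/domain/total with each of the six summarised
    Mood Zoom items and the three PCA factors, pooled over all participants'
    aligned pairs.  Cells with fewer than ``min_pairs`` complete pairs are
    marked insufficient.  Returns a tidy DataFrame with rho, p, n and the
    strong (|rho| >= 0.3) and significant (p < 1e-4) flags.
    """
    pooled = _aligned_pairs_frame(timelines, loadings, alignment_method)
    if pooled.empty:
        return pd.DataFrame(columns=["weekly_var", "mz_var", "rho", "p", "n",
                                     "strong", "significant", "insufficient"])
    weekly_vars = [c for c in pooled.columns
                   if c.startswith(("asrm_", "qids_", "gad7_", "eq5d_", "total_"))]
    mz_vars = [f"mz_{item}" for item in MZ_ITEM_LABELS] + list(FACTOR_LABELS)
    rows = []
    for wv in weekly_vars:
        for mv in mz_vars:
            sub = pooled[[wv, mv]].dropna()
            if len(sub) < min_pairs:
                rows.append({"weekly_var": wv, "mz_var": mv, "rho": np.nan,
                             "p": np.nan, "n": len(sub), "strong": False,
                             "significant": False, "insufficient": True})
                continue
            res = spearman(sub[wv].to_numpy(), sub[mv].to_numpy())
            rows.append({
                "weekly_var": wv, "mz_var": mv, "rho": res.rho, "p": res.p,
                "n": res.n,
                "strong": bool(not res.undefined and abs(res.rho) >= STRONG_RHO),
                "significant": bool(not res.undefined and res.p < SIGNIFICANCE_P),
                "insufficient": res.undefined,
            })
    return pd.DataFrame(rows)


def comparison_table(values: pd.DataFrame, *, cohort_order=("BD", "BPD", "HC"),
                     alpha=0.05, wilcoxon_method="auto") -> pd.DataFrame:
    """Cohort summaries and pairwise Wilcoxon tests per variable.

    ``values`` is tidy with columns participant_id, cohort, variable, value
    (one value per participant per variable).  Output has one row per
    variable with ``<cohort>_median`` / ``<cohort>_iqr`` columns, a p-value
    per cohort pair, and significance flags at ``alpha``.  Cohorts absent
    from ``cohort_order`` are appended in sorted order; empty cells are NaN.
    """
    present = list(values["cohort"].unique())
    if set(present) & set(cohort_order):
        # keep the full canonical layout; absent cohorts get NaN cells
        cohorts = list(cohort_order) + sorted(
            c for c in present if c not in cohort_order)
    else:
        cohorts = sorted(present)
    pairs = list(itertools.combinations(cohorts, 2))
    rows = []
    for var, sub in values.groupby("variable", sort=False):
        row = {"variable": var}
        groups = {}
        for c in cohorts:
            v = sub.loc[sub["cohort"] == c, "value"].dropna().to_numpy()
            groups[c] = v
            row[f"{c}_median"] = float(np.median(v)) if v.size else np.nan
            row[f"{c}_iqr"] = _iqr(v) if v.size else np.nan
        for c1, c2 in pairs:
            key = f"p_{c1}_vs_{c2}"
            if groups[c1].size and groups[c2].size:
                p = wilcoxon_rank_sum(groups[c1], groups[c2], wilcoxon_method)
                row[key] = p
                row[f"sig_{c1}_vs_{c2}"] = bool(p < alpha)
            else:
                row[key] = np.nan
                row[f"sig_{c1}_vs_{c2}"] = False
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["n_tests"] = sum(
        1 for r in rows for k in r if k.startswith("p_") and not pd.isna(r[k]))
    out.attrs["alpha"] = alpha
    return out


def participant_summary_values(timelines, loadings) -> pd.DataFrame:
    """Per-participant median of each score series (amplitude summaries).

    One row per participant per variable: medians of the weekly ASRM / QIDS
    / GAD7 totals and EQ-5D VAS, and of the daily MZneg / MZpos / MZirr
    factor series.  Feed to `comparison_table` for the cohort summary.
    """
    from .latent import daily_factor_series

    rows = []
    for tl in timelines:
        weekly = tl.weekly_frame()
        for col in ("ASRM", "QIDS", "GAD7", "EQ5D"):
            if not weekly.empty and weekly[col].notna().any():
                rows.append({"participant_id": tl.participant_id,
                             "cohort": tl.cohort, "variable": col,
                             "value": float(weekly[col].median())})
        factors = daily_factor_series(tl, loadings)
        for col in FACTOR_LABELS:
            if not factors.empty:
                rows.append({"participant_id": tl.participant_id,
                             "cohort": tl.cohort, "variable": col,
                             "value": float(factors[col].median())})
    return pd.DataFrame(rows, columns=["participant_id", "cohort", "variable",
                                       "value"])


def participant_variability_values(timelines, loadings, **profile_kwargs
                                   ) -> pd.DataFrame:
    """Per-participant variability statistics, tidied for `comparison_table`.

    Variables are named ``<series>_<stat>`` (e.g. ``MZneg_rmssd``), one row
    per participant per variable; cells missing for short series are
    omitted.
    """
    profiles = [variability_profile(tl, loadings, **profile_kwargs)
                for tl in timelines]
    wide = profiles_frame(profiles)
    long = wide.melt(id_vars=["participant_id", "cohort", "series"],
                     value_vars=list(STAT_NAMES), var_name="stat",
                     value_name="value").dropna(subset=["value"])
    long["variable"] = long["series"] + "_" + long["stat"]
    return long[["participant_id", "cohort", "variable", "value"]].reset_index(
        drop=True)
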