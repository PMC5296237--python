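# Methods

This note documents the models, conventions and numerical choices behind
moodkit, and what the synthetic test bed does and does not establish about
real data.

## Instruments and scoring

ASRM (5 items, 0–4), QIDS-SR16 (16 items, 0–3), GAD-7 (7 items, 0–3) and
the EQ-5D visual-analogue scale (0–100) are the weekly instruments; only
the EQ-5D VAS item is modelled, not the five descriptive dimensions. The
daily instrument is the six-adjective Mood Zoom rated on a 1–7 Likert
scale. Scoring conventions:

* QIDS totals sum nine clinical domains rather than the 16 items: sleep =
  max(items 1–4), appetite/weight = max(items 6–9), psychomotor
  restlessness = max(items 15–16), the remaining six domains single items.
  This is the standard published QIDS-SR16 rule, consistent with
  depression being clinically assessed at domain granularity.
* Severity bands partition each instrument's full integer range: QIDS
  ≤5 normal / 6–10 mild / 11–15 moderate / 16–20 severe / 21–27 very
  severe; GAD-7 cut-offs 5, 10, 15 — the implied upper edges 9 and 14 are
  interpolated from the published cut-offs, not printed with them.
* The ASRM manic-episode screen uses the published 5.5 cut-off; on integer
  totals this is total ≥ 6. The boundary is reported as the midpoint 5.5
  between the largest negative (5) and smallest positive (6) totals.

Validators reject out-of-range or non-integer items naming the offending
item; responses are immutable once constructed.

## Adherence

Daily adherence is the percentage of enrolment days carrying a same-day
Mood Zoom record. Weekly adherence is the percentage of scheduled weekly
prompts answered by a record dated within ±2 days; each record can satisfy
at most one prompt, matched greedily in date order to the nearest open
prompt with ties to the earlier one. Longitudinal curves use tumbling
30-day windows (a rolling variant would change smoothness, not level);
participants contribute only to windows inside their own enrolment.

## Daily→weekly alignment

Weekly instruments describe the preceding week, so each weekly record at
date t is paired with a summary of the daily items over the 7 calendar
days strictly before t ([t−7, t−1]); the rating day itself is excluded by
default so that the `same_day` variant remains a distinct method, and can
be included via `include_rating_day=True`. Variants: median over the same
window, mean over [t−3, t−1] (`last3_days`), and the same-day record.
Missing days are simply absent from the summary (no imputation); a pair
needs at least one qualifying day, otherwise it is dropped and counted.

## Latent mood factors

The pooled daily item rows (all participants stacked, no within-person
demeaning) are decomposed by PCA on the item covariance matrix — the six
items share one scale, so covariance is the default; a correlation-matrix
option standardises items first. The fit is an explicit eigendecomposition
of the 6×6 covariance matrix, which also behaves sensibly in the
rank-deficient (<7 rows) case, where a warning is raised. Components are
ordered by decreasing eigenvalue; each loading column is sign-flipped so
its largest-magnitude loading is positive, making MZneg increase with
sadness/anxiety and MZpos with elation/energy. Factor scores are
`(x − mean) / scale · v_k` for the first three components. Per-cohort
stability refits the PCA within each cohort and reports the Tucker
congruence |u·v|/(‖u‖‖v‖) of each pooled component with its best-matching
cohort component (greedy max-|φ| assignment, ties to component order). No
rotation is applied.

## Variability statistics

For a series x₁..x_N in observation order:

* std — sample standard deviation, N−1 denominator (N ≥ 2);
* TKEO — mean Teager–Kaiser energy (1/N)·Σ_{i=2}^{N−1}(xᵢ² − xᵢ₋₁xᵢ₊₁)
  (N ≥ 3). A variant replacing the cross-term by xᵢ₊₁² is kept behind
  `variant="printed"` purely for audit: it telescopes to a boundary
  difference and is not the Teager–Kaiser operator.
* entropy — Shannon entropy of the empirical distribution over distinct
  observed values, natural log by default (configurable base); 0·ln 0 = 0,
  so a constant series scores 0. No binning is applied; on an effectively
  continuous series (e.g. long factor-score series) nearly every value is
  distinct and the entropy approaches ln N, so it is most informative on
  integer-valued totals.
* RMSSD — √[(1/N)·Σ(xᵢ₊₁ − xᵢ)²] with the 1/N normaliser over N−1 squared
  differences kept deliberately (not 1/(N−1)), so rmssd²·N is exactly the
  sum of squared successive differences.

All four ignore a constant shift except TKEO, which acquires the exact
boundary term c·((x₂−x₁)+(x_{N−1}−x_N))/N — an O(1/N) edge effect, zero
in expectation for stationary series.

Successive observed records are treated as adjacent regardless of calendar
gaps (no imputation, no gap rule by default); an optional `max_gap_days`
splits a series at longer gaps, accumulates the successive-difference
terms within segments only, and keeps the 1/N normaliser with N the total
observation count. Series shorter than a statistic's minimum yield a
missing cell with a recorded reason. Statistics are computed over each
participant's full observation window.

## Inference

Spearman ρ is the Pearson correlation of mid-rank transforms (ties get
average ranks). For n ≤ 9 pairs the p-value is an exact two-sided
permutation tail; otherwise the large-sample t approximation
t = ρ√((n−2)/(1−ρ²)). Associations pool all participants' aligned pairs
into single coefficients (no within-person averaging); |ρ| ≥ 0.3 is
flagged "statistically strong" per the common guideline in medical
applications, p < 10⁻⁴ as significant. Zero-variance inputs yield an
undefined-correlation flag.

The Wilcoxon rank-sum test is two-sided; exact when the combined sample
has ≤ 20 observations without ties, otherwise the normal approximation
with tie-corrected variance (mandatory for Likert-type data) and
continuity correction. Group summaries are median ± IQR with type-7
(linear-interpolation) quantiles. No multiple-testing correction is
applied; tables carry the number of tests performed (`attrs["n_tests"]`)
so users can apply their own.

## Synthetic cohorts

The generator is a test harness that reproduces the statistical *structure*
the analysis assumes — not a model of the disorders, and it makes no
attempt to match any study's printed coefficients.

Per participant, two latent affect processes (negative, positive) follow
stationary Gaussian AR(1) dynamics zₜ = φzₜ₋₁ + εₜ around cohort means.
Items are affine maps of the latents plus N(0, 0.7²) item noise, rounded
and clipped to 1–7: anxious/sad ← negative; elated/energetic ← positive;
angry/irritable ← `irritability_share`·negative plus an additional
independent AR(1) irritability component (innovation sd `irr_sd`, default
0.6·neg_sd). That extra component is what gives the angry/irritable-vs-
anxious/sad contrast (the third PCA component) cohort-dependent variance;
with a pure shared-latent route the contrast would be item noise alone and
identical across cohorts. Weekly items derive from the mean latent over
the 7 days preceding each prompt — matching the alignment assumption, so
alignment methods have a known ground truth — mapped affinely into each
instrument's range with independent noise (QIDS/GAD-7 from negative
affect, ASRM from positive, EQ-5D VAS inversely from negative). Records
are dropped i.i.d. with the configured missingness, and kept weekly
responses get an integer jitter in {−2..+2} days.

Default presets (the study conditions for all structural tests): three
cohorts × 30 participants × 270 days, daily and weekly missingness 0.15
(≈85% expected adherence, matching the >80% adherence regime of this kind
of study), negative-affect means −0.8 / 0.4 / 1.4 and innovation sds
0.35 / 0.7 / 1.1 for HC / BD / BPD (AR coefficients 0.5 / 0.6 / 0.5), so
both level and variability order HC < BD < BPD. A one-unit latent change
moves the directly loaded items by one Likert point. Sub-seeds are stable
hashes of (master seed, cohort index, participant index), so enlarging a
study never perturbs existing participants, and identical configurations
reproduce byte-identical CSVs.

What passing tests on this bed do **not** show about real data: no
medication or episode structure, no gender effects, no informative
(mood-dependent) missingness, no sensor modalities, no time-of-day
effects, and Likert marginals that are rounded Gaussians rather than the
zero-inflated shapes real controls produce. Results on the presets
demonstrate that the pipeline *recovers structure that is present*, not
that such structure exists in any particular population.

## Problem sizes and reproducibility

Structural tests run the presets across 20 master seeds (90 participants,
270 days each) — large enough that the built-in cohort orderings are
detected with high power, small enough to keep the whole suite fast on one
CPU. The pipeline writes a manifest (full config echo, package versions,
seed) from which every output is re-derivable; re-running a configuration
reproduces identical bytes.

## Known limitations

* Entropy on continuous-valued series saturates near ln N (see above);
  binned variants are deliberately out of scope.
* The exact Spearman permutation p is enumerated only to n = 9 (9! pairings);
  beyond that the t approximation is used.
* Calendar-gap handling is the simple split-and-pool rule; no detrending,
  spectral or circadian modelling.
* The weekly-prompt schedule for CSV-loaded data defaults to the weekday of
  each participant's first weekly record, which misestimates adherence if
  a participant's true schedule changed mid-study.
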