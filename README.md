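# moodkit

Analysis toolkit for longitudinal smartphone-based mood monitoring in
clinical psychiatry. It targets studies in which participants with bipolar
disorder (BD), borderline personality disorder (BPD) and healthy controls
(HC) complete a brief daily mood questionnaire ("Mood Zoom": anxious,
elated, sad, angry, irritable, energetic — each rated 1–7) alongside weekly
standardized instruments (ASRM for mania, QIDS-SR16 for depression, GAD-7
for anxiety, EQ-5D VAS for quality of life), and in which the scientific
question is whether *mood instability* — not just mood level — separates
the diagnostic groups.

The package provides, as a plain Python library:

* **Instrument scoring and banding** — validated item types, totals
  (ASRM 0–20, QIDS 0–27 via the nine clinical domains, GAD-7 0–21),
  severity bands and the ASRM manic-episode screen (cut-off 5.5).
* **Adherence accounting** — daily prompts count when answered the same
  day; weekly prompts when answered within ±2 days; cohort adherence
  curves over 30-day windows.
* **Daily→weekly alignment** — the daily items summarised over the week
  preceding each weekly rating (mean; variants: median, last 3 days,
  same day).
* **Latent mood factors** — PCA of the six daily items, giving negative
  affect (MZneg), positive affect (MZpos) and an irritability contrast
  (MZirr), with per-cohort loading-stability checks (Tucker congruence).
* **Variability statistics** — for a score series x₁..x_N:
  - standard deviation (N−1 denominator),
  - mean Teager–Kaiser energy, TKEO = (1/N) Σᵢ₌₂^{N−1} (xᵢ² − xᵢ₋₁·xᵢ₊₁),
  - Shannon entropy of the empirical value distribution,
    H = −Σⱼ pⱼ ln pⱼ,
  - RMSSD = √[(1/N) Σᵢ₌₁^{N−1} (xᵢ₊₁ − xᵢ)²].
* **Nonparametric inference** — pooled Spearman association matrices
  (|ρ| ≥ 0.3 flagged as statistically strong, p < 10⁻⁴ as significant)
  and per-variable cohort summaries (median ± IQR) with pairwise
  two-sided Wilcoxon rank-sum tests.
* **A synthetic-cohort generator** — latent AR(1) affect processes mapped
  to Likert items, with cohort-ordered levels and variability
  (HC < BD < BPD), realistic missingness and response jitter — so the
  whole pipeline is testable although clinical study data of this kind
  cannot be shared.

## Worked example

```python
from moodkit.synthetic import default_presets, generate_study
from moodkit.latent import fit_mz_pca
from moodkit.inference import (comparison_table,
                               participant_variability_values)

study = generate_study(default_presets(seed=42, n_participants=15,
                                       n_days=180))
loadings = fit_mz_pca(study.timelines)
table = comparison_table(
    participant_variability_values(study.timelines, loadings))
print(table[table.variable.isin(["MZneg_rmssd", "MZirr_rmssd"])]
      [["variable", "BD_median", "BPD_median", "HC_median",
        "p_BPD_vs_HC", "p_BD_vs_BPD"]].round(4).to_string(index=False))
```

prints

```
   variable  BD_median  BPD_median  HC_median  p_BPD_vs_HC  p_BD_vs_BPD
MZneg_rmssd     1.6432      2.4660     1.0883          0.0       0.0000
MZirr_rmssd     1.1622      1.4129     1.0003          0.0       0.0000
```

Each row is one variability measure of a daily mood factor: the cohort
medians of per-participant RMSSD order BPD > BD > HC — day-to-day swings in
negative affect and irritability are largest in the BPD group — and the
Wilcoxon p-values show both the BPD-vs-HC and BD-vs-BPD contrasts are
significant at these sample sizes.

The `examples/` directory walks through each capability (scoring, cohort
generation and adherence, mood factors, variability, group comparison);
each script prints its results with a note on what they mean. A thin CLI
wraps the pipeline end to end:

```bash
moodkit demo --seed 0 --out demo_out   # presets -> all report CSVs
moodkit generate --seed 0 --out csv    # synthetic study as CSVs
moodkit run --config pipeline.yaml     # full pipeline on CSV inputs
```

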