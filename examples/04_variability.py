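"""Quantify mood instability with the four variability statistics.

For each participant and score series: standard deviation (spread), mean
Teager-Kaiser energy (amplitude x frequency of fluctuation), Shannon
entropy (unpredictability of the value distribution) and RMSSD (amplitude
of successive change).
"""

from moodkit.latent import fit_mz_pca
from moodkit.synthetic import default_presets, generate_study
from moodkit.variability import (
    series_entropy,
    series_rmssd,
    series_std,
    series_tkeo,
    variability_profile,
)

# the statistics on a toy series
x = [1, 3, 2, 5, 4, 4, 6]
print(f"series {x}:")
print(f"  std     {series_std(x):.3f}")
print(f"  TKEO    {series_tkeo(x):.3f}")
print(f"  entropy {series_entropy(x):.3f} (ln units)")
print(f"  RMSSD   {series_rmssd(x):.3f}")

# a full per-participant profile on synthetic data
study = generate_study(default_presets(seed=42, n_participants=5, n_days=120))
loadings = fit_mz_pca(study.timelines)
prof = variability_profile(study.timelines[0], loadings)
print(f"\nprofile for {prof.participant_id} ({prof.cohort}):")
for series, stats in prof.cells.items():
    cells = ", ".join(f"{k}={v:.2f}" for k, v in stats.items())
    print(f"  {series:6s} {cells}")
# Weekly totals give short series (tens of points); daily factors give long
# ones (hundreds). RMSSD and TKEO respond to day-to-day swings that the
# plain standard deviation understates.
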