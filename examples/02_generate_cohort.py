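"""Generate a small synthetic three-cohort study and measure adherence.

The generator emulates the study conditions: daily six-item mood ratings
and weekly questionnaires over months of follow-up, with ~15% missingness
and weekly responses completed within +/-2 days of the prompt.
"""

import numpy as np

from moodkit.synthetic import default_presets, generate_study
from moodkit.timeline import adherence_curve, compute_adherence

study = generate_study(default_presets(seed=42, n_participants=10, n_days=120))
print(f"generated {len(study.timelines)} participants "
      f"({len(study.timelines[0].daily)} daily records for the first)")

daily_pct = [compute_adherence(tl).daily_adherence for tl in study.timelines]
print(f"median daily adherence: {np.median(daily_pct):.1f}% "
      "(expected ~85% at missingness 0.15)")

curve = adherence_curve(study.timelines, window_days=30)
print("\nper-cohort adherence by 30-day window (median %):")
print(curve.pivot(index="window", columns="cohort", values="median").round(1))
# A flat curve near 85% shows missingness is stationary; the real interest
# with observed data is whether adherence decays over months in the study.
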