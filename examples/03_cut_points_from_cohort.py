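"""Derive sedentary-vs-activity cut-points from a synthetic cohort.

Generates a reduced-scale cohort (8 participants, 2-minute activities,
ActiGraph-like and GENEActiv-like devices at hip and wrist), runs the full
pipeline (auto-calibration, 5-s ENMO/MAD epochs, central-window labelling)
and prints the threshold battery for two contrasting discriminations:
walking (separates almost perfectly) and standing still (does not --
magnitude metrics carry no posture information).
"""

import warnings

from accelcut import CohortConfig, generate_cohort, run_study

cfg = CohortConfig(n_participants=8, fs=50.0, activity_s=120.0, break_s=10.0)
cohort = generate_cohort(config=cfg, seed=42)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    labeled, battery = run_study(cohort)

cols = [
    "metric", "brand", "placement", "discrimination",
    "threshold_mg", "sensitivity", "specificity", "auroc", "loocv_auroc",
]
show = battery[battery.discrimination.isin(["walk", "standing"])]
print(show[cols].round(3).to_string(index=False))
print()
print(
    "Walking AUROCs are ~1.0: a single mg threshold separates it from the\n"
    "pooled lying/sitting class.  Standing AUROCs hover near 0.5 (and the\n"
    "LOOCV AUROC drops further, a known pessimism of pooled leave-one-out\n"
    "predictions under the null): a magnitude threshold cannot isolate\n"
    "standing from sitting or lying."
)
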