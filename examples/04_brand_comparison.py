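"""Compare metric levels between device brands with unpaired t-tests.

The GENEActiv-like device model carries more sensor noise than the
ActiGraph-like one, which inflates both metrics at low intensities (noise
passes straight into the magnitude) but is negligible during vigorous
movement.  Per-participant sedentary and walking means are compared
between brands at the hip.
"""

import warnings

from accelcut import CohortConfig, compare_brands, generate_cohort, process_cohort
from accelcut.io import SEDENTARY_IDS

cfg = CohortConfig(
    n_participants=10, fs=50.0, activity_s=120.0, break_s=10.0, placements=("hip",)
)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    labeled = process_cohort(generate_cohort(config=cfg, seed=7))

for group, ids in [("sedentary", list(SEDENTARY_IDS)), ("walk", [16])]:
    per_brand = {}
    for brand in ("AG", "GA"):
        df = labeled[(labeled.brand == brand) & labeled.activity_id.isin(ids)]
        per_brand[brand] = df.groupby("participant_id")["mad_mg"].mean()
    res = compare_brands(per_brand["AG"], per_brand["GA"])
    print(
        f"{group:10s} AG mean {per_brand['AG'].mean():7.2f} mg | "
        f"GA mean {per_brand['GA'].mean():7.2f} mg | "
        f"t = {res.t:6.2f}, p = {res.p:.3g}"
    )
print()
print(
    "The brand gap is large and significant for sedentary behaviours (noise\n"
    "dominates the signal) but negligible for walking -- the reason\n"
    "cut-points must be derived per brand."
)
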