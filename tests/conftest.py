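"""Shared fixtures: small synthetic cohorts and the standing-null sweep.

Simulation sizes here are deliberately smaller than the full laboratory
protocol (fewer participants, shorter activities, lower sampling rate)
so the suite stays fast; the generator's structure is identical.
"""

import numpy as np
import pytest

from accelcut import (
    CohortConfig,
    auroc,
    build_discrimination,
    generate_cohort,
    process_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """5 participants, 4 devices, full 16-activity protocol at reduced scale."""
    cfg = CohortConfig(
        n_participants=5, fs=40.0, activity_s=120.0, break_s=10.0
    )
    return generate_cohort(config=cfg, seed=11)


@pytest.fixture(scope="session")
def small_labeled(small_cohort):
    return process_cohort(small_cohort)


def standing_null_aurocs(n_seeds: int = 50) -> dict[str, np.ndarray]:
    """Standing-vs-sedentary AUROCs over seeded scaled cohorts.

    33 participants (the cohort size of interest), activities 1-12 only,
    single AG hip device, 20 Hz / 2-minute activities to keep each seed
    cheap.
    """
    vals = {"enmo": [], "mad": []}
    for seed in range(n_seeds):
        cfg = CohortConfig(
            n_participants=33,
            fs=20.0,
            activity_s=120.0,
            break_s=10.0,
            brands=("AG",),
            placements=("hip",),
            activity_ids=tuple(range(1, 13)),
        )
        labeled = process_cohort(generate_cohort(config=cfg, seed=seed))
        for metric in vals:
            ds = build_discrimination(labeled, metric, "standing")
            vals[metric].append(auroc(ds.values, ds.labels).auroc)
    return {k: np.asarray(v) for k, v in vals.items()}


@pytest.fixture(scope="session")
def standing_null_sweep():
    return standing_null_aurocs(50)
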