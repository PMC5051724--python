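"""Joining epoch metrics to activity logs and assembling analysis datasets.

The laboratory protocol is 16 five-minute activities: 11 lying/sitting
postures pooled as the *sedentary behaviours* class, and 5 upright
light-intensity activities (standing still, washing pots, dusting,
sweeping, self-paced walking).  The first and last 30 s of each activity
window are discarded as likely transitional movement, leaving the central
4 minutes; only epochs lying wholly inside the trimmed window are labelled.

Each *discrimination* is a binary task: pooled sedentary behaviours versus
one upright activity.  Observations enter at one of two granularities:

* ``participant_activity_mean`` (default) — each participant contributes
  one value per activity (the mean metric over that activity's labelled
  epochs): 11 sedentary observations and 1 positive per participant.
* ``epoch`` — every labelled epoch is an observation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ActivityLog, SEDENTARY_IDS

__all__ = [
    "DISCRIMINATIONS",
    "DiscriminationDataset",
    "trim_and_label",
    "build_discrimination",
    "summarize_by_activity",
]

DEFAULT_TRIM_S = 30.0

#: discrimination id -> target (positive-class) activity id
DISCRIMINATIONS = {
    "standing": 12,
    "washing_pots": 13,
    "dusting": 14,
    "sweeping": 15,
    "walk": 16,
}

ACTIVITY_GROUP_LABELS = {
    12: "Standing Still",
    13: "Washing Pots",
    14: "Dusting",
    15: "Sweeping Floor",
    16: "Self-Paced Free-Living Walk",
}


@dataclass
class DiscriminationDataset:
    """Labelled observations for one sedentary-vs-activity discrimination.

    ``label`` is 0 for sedentary behaviours (activities 1-11) and 1 for the
    single target activity.
    """

    discrimination_id: str
    metric: str
    granularity: str
    observations: pd.DataFrame  # columns: value_mg, label, participant_id

    def __post_init__(self) -> None:
        obs = self.observations
        for col in ("value_mg", "label", "participant_id"):
            if col not in obs.columns:
                raise ValidationError(f"observations missing column {col!r}")
        counts = obs["label"].value_counts()
        if counts.get(0, 0) < 2 or counts.get(1, 0) < 2:
            raise ValidationError(
                f"discrimination {self.discrimination_id!r} needs >= 2 observations "
                f"in each class; got {counts.to_dict()}"
            )

    @property
    def values(self) -> np.ndarray:
        return self.observations["value_mg"].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.observations["label"].to_numpy(dtype=int)

    @property
    def n_pos(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_neg(self) -> int:
        return int((self.labels == 0).sum())


def trim_and_label(
    metrics: pd.DataFrame,
    log: ActivityLog,
    trim_s: float = DEFAULT_TRIM_S,
    epoch_s: float = 5.0,
) -> pd.DataFrame:
    """Assign activity ids to epochs wholly inside trimmed activity windows.

    An epoch ``[start, start + epoch_s)`` is labelled with an activity when
    it lies entirely within ``[activity_start + trim_s, activity_end -
    trim_s]``; epochs straddling a trim boundary and epochs in breaks are
    dropped.  Raises when any activity is too short to survive trimming.
    """
    if trim_s < 0:
        raise ValidationError("trim_s must be non-negative")
    for e in log:
        if e.duration_s <= 2 * trim_s:
            raise ValidationError(
                f"activity {e.activity_id} ({e.label!r}) lasts {e.duration_s:g} s, "
                f"too short for a {trim_s:g}-s trim at each end"
            )
    starts = metrics["epoch_start"].to_numpy(dtype=float)
    ends = starts + epoch_s
    activity = np.full(len(metrics), -1)
    tol = 1e-9  # text-format rounding slack on epoch boundaries
    for e in log:
        inside = (starts >= e.start_s + trim_s - tol) & (ends <= e.end_s - trim_s + tol)
        activity[inside] = e.activity_id
    labeled = metrics.loc[activity >= 0].copy()
    labeled["activity_id"] = pd.array(activity[activity >= 0], dtype="Int64")
    return labeled.reset_index(drop=True)


def _participant_activity_means(labeled: pd.DataFrame, metric_col: str) -> pd.DataFrame:
    return (
        labeled.groupby(["participant_id", "activity_id"], observed=True)[metric_col]
        .mean()
        .reset_index()
    )


def build_discrimination(
    labeled: pd.DataFrame,
    metric: str,
    discrimination_id: str,
    granularity: str = "participant_activity_mean",
) -> DiscriminationDataset:
    """Assemble sedentary-vs-target observations for one discrimination.

    Sedentary observations come only from activities 1-11; positives only
    from the discrimination's single target activity.
    """
    if metric not in ("enmo", "mad"):
        raise ValidationError(f"unknown metric {metric!r}")
    if discrimination_id not in DISCRIMINATIONS:
        raise ValidationError(f"unknown discrimination {discrimination_id!r}")
    if granularity not in ("participant_activity_mean", "epoch"):
        raise ValidationError(f"unknown granularity {granularity!r}")
    if len(labeled) == 0:
        raise ValidationError("labelled epoch set is empty")
    target_id = DISCRIMINATIONS[discrimination_id]
    metric_col = f"{metric}_mg"

    if granularity == "participant_activity_mean":
        base = _participant_activity_means(labeled, metric_col)
    else:
        base = labeled[["participant_id", "activity_id", metric_col]]

    sed = base[base["activity_id"].isin(SEDENTARY_IDS)]
    pos = base[base["activity_id"] == target_id]
    if len(pos) == 0:
        raise ValidationError(
            f"no epochs labelled with target activity {target_id} "
            f"({discrimination_id})"
        )
    obs = pd.concat(
        [
            pd.DataFrame(
                {
                    "value_mg": sed[metric_col].to_numpy(dtype=float),
                    "label": 0,
                    "participant_id": sed["participant_id"].to_numpy(),
                }
            ),
            pd.DataFrame(
                {
                    "value_mg": pos[metric_col].to_numpy(dtype=float),
                    "label": 1,
                    "participant_id": pos["participant_id"].to_numpy(),
                }
            ),
        ],
        ignore_index=True,
    )
    return DiscriminationDataset(
        discrimination_id=discrimination_id,
        metric=metric,
        granularity=granularity,
        observations=obs,
    )


def summarize_by_activity(labeled: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Mean and standard error per activity group, sedentary pooled.

    Each participant contributes one value per group: for the sedentary
    group, activities 1-11 are pooled within participant first (mean of the
    11 per-activity means), then averaged across participants; the SE is the
    between-participant standard error.  With a single participant the SE is
    reported as NaN.
    """
    if metric not in ("enmo", "mad"):
        raise ValidationError(f"unknown metric {metric!r}")
    if len(labeled) == 0:
        raise ValidationError("labelled epoch set is empty")
    metric_col = f"{metric}_mg"
    pa = _participant_activity_means(labeled, metric_col)

    rows = []

    def _group_row(name: str, per_participant: pd.Series) -> dict:
        n = len(per_participant)
        se = float(per_participant.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        return {
            "group": name,
            "mean_mg": float(per_participant.mean()),
            "se_mg": se,
            "n_participants": n,
        }

    sed = pa[pa["activity_id"].isin(SEDENTARY_IDS)]
    if len(sed):
        per_part = sed.groupby("participant_id", observed=True)[metric_col].mean()
        rows.append(_group_row("Sedentary Behaviours", per_part))
    for act_id, label in ACTIVITY_GROUP_LABELS.items():
        sub = pa[pa["activity_id"] == act_id]
        if len(sub):
            per_part = sub.set_index("participant_id")[metric_col]
            rows.append(_group_row(label, per_part))
    return pd.DataFrame(rows)
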