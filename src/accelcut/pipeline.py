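"""End-to-end composition: raw signal -> calibrated epoch metrics -> thresholds."""

from __future__ import annotations

import pandas as pd

from .calibration import (
    DEFAULT_SD_THRESHOLD_MG,
    DEFAULT_WINDOW_S,
    CalibrationParams,
    calibrate_recording,
)
from .io import ActivityLog, RawRecording
from .labeling import DEFAULT_TRIM_S, trim_and_label
from .metrics import DEFAULT_EPOCH_S, compute_epoch_metrics
from .synth import ParticipantData
from .thresholds import run_threshold_battery

__all__ = ["process_recording", "process_cohort", "run_study"]


def process_recording(
    rec: RawRecording,
    log: ActivityLog,
    *,
    calibrate: bool = True,
    calibrate_mad: bool = True,
    epoch_s: float = DEFAULT_EPOCH_S,
    trim_s: float = DEFAULT_TRIM_S,
    truncate_per_sample: bool = True,
    cal_window_s: float = DEFAULT_WINDOW_S,
    cal_sd_threshold_mg: float = DEFAULT_SD_THRESHOLD_MG,
) -> tuple[pd.DataFrame, CalibrationParams]:
    """Calibrate, epoch, compute ENMO/MAD, and label one recording.

    Auto-calibration is always applied before ENMO (which is sensitive to
    offset errors); ``calibrate_mad=False`` restricts it to ENMO and leaves
    MAD computed from the uncalibrated signal (MAD is offset-robust, and
    whether its inputs should be calibrated is a study choice).
    """
    cal = CalibrationParams(flagged=True)
    rec_cal = rec
    if calibrate:
        rec_cal, cal = calibrate_recording(
            rec, window_s=cal_window_s, sd_threshold_mg=cal_sd_threshold_mg
        )
    metrics = compute_epoch_metrics(rec_cal, epoch_s, truncate_per_sample)
    if calibrate and not calibrate_mad:
        raw_metrics = compute_epoch_metrics(rec, epoch_s, truncate_per_sample)
        metrics["mad_mg"] = raw_metrics["mad_mg"]
    labeled = trim_and_label(metrics, log, trim_s=trim_s, epoch_s=epoch_s)
    return labeled, cal


def process_cohort(cohort: list[ParticipantData], **kwargs) -> pd.DataFrame:
    """Labelled epoch metrics for every recording of every participant."""
    frames = []
    for part in cohort:
        for rec in part.recordings.values():
            labeled, _ = process_recording(rec, part.log, **kwargs)
            frames.append(labeled)
    return pd.concat(frames, ignore_index=True)


def run_study(
    cohort: list[ParticipantData],
    granularity: str = "participant_activity_mean",
    loocv_unit: str = "observation",
    **process_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Process a cohort and derive the full threshold battery.

    Returns ``(labeled_epochs, battery)`` where the battery holds one row
    per metric x brand x placement x discrimination.
    """
    labeled = process_cohort(cohort, **process_kwargs)
    battery = run_threshold_battery(
        labeled, granularity=granularity, loocv_unit=loocv_unit
    )
    return labeled, battery
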