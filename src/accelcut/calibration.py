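"""Accelerometer auto-calibration from stationary periods.

A resting accelerometer measures only gravity, so its vector magnitude
should be 1000 mg regardless of orientation.  Sensor offset and gain errors
move stationary readings off that sphere, which biases ENMO directly (it
subtracts a fixed 1000 mg).  This module

1. finds stationary windows (all three axes' standard deviation below a
   threshold, default 13 mg over 10-s windows),
2. fits per-axis gain and offset so the calibrated window means lie as
   close as possible to the 1000-mg sphere, by iterative least squares
   against the closest sphere point, and
3. applies the affine correction ``gain * xyz + offset`` to a recording.

The fit is a simplified gravity-sphere calibration: no temperature
covariates, no nonlinear sensor model.  When too few stationary windows
are found or their orientations are clustered around a single axis the fit
is ill-posed, and an identity calibration is returned with ``flagged=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io import RawRecording

__all__ = [
    "CalibrationParams",
    "detect_stationary_windows",
    "estimate_calibration",
    "apply_calibration",
    "calibrate_recording",
]

ONE_G_MG = 1000.0
DEFAULT_WINDOW_S = 10.0
DEFAULT_SD_THRESHOLD_MG = 13.0
MIN_WINDOWS_DEFAULT = 10
ORIENTATION_CONE_DEG = 30.0
MAX_ITER = 100
PARAM_TOL = 1e-9
GAIN_BOUNDS = (0.5, 2.0)
OFFSET_BOUND_MG = 500.0


@dataclass
class CalibrationParams:
    """Per-axis affine correction: calibrated = gain * raw + offset (mg)."""

    offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gain: np.ndarray = field(default_factory=lambda: np.ones(3))
    residual_mg: float = 0.0
    n_windows: int = 0
    flagged: bool = False
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.offset = np.asarray(self.offset, dtype=float).reshape(3)
        self.gain = np.asarray(self.gain, dtype=float).reshape(3)

    @property
    def is_identity(self) -> bool:
        return bool(np.all(self.gain == 1.0) and np.all(self.offset == 0.0))


def detect_stationary_windows(
    rec: RawRecording,
    window_s: float = DEFAULT_WINDOW_S,
    sd_threshold_mg: float = DEFAULT_SD_THRESHOLD_MG,
) -> list[tuple[int, int]]:
    """Non-overlapping windows whose three per-axis SDs are all below threshold.

    Returns half-open ``(start_index, end_index)`` sample ranges; a recording
    shorter than one window yields an empty list.
    """
    n_per = int(round(rec.fs * window_s))
    if n_per < 2:
        raise ValidationError("stationary window must span at least 2 samples")
    n_win = rec.n_samples // n_per
    if n_win == 0:
        return []
    blocks = rec.xyz[: n_win * n_per].reshape(n_win, n_per, 3)
    sds = blocks.std(axis=1)  # (n_win, 3)
    keep = np.all(sds < sd_threshold_mg, axis=1)
    return [(k * n_per, (k + 1) * n_per) for k in np.flatnonzero(keep)]


def window_means(rec: RawRecording, windows: list[tuple[int, int]]) -> np.ndarray:
    """Mean tri-axial vector (mg) over each stationary window; shape (W, 3)."""
    return np.array([rec.xyz[a:b].mean(axis=0) for a, b in windows]).reshape(-1, 3)


def _orientation_clustered(means: np.ndarray, cone_deg: float = ORIENTATION_CONE_DEG) -> bool:
    """True when every window orientation lies within one axis-aligned cone."""
    norms = np.linalg.norm(means, axis=1)
    if np.any(norms == 0):
        return True
    u = means / norms[:, None]
    cos_cone = np.cos(np.deg2rad(cone_deg))
    for axis in range(3):
        for sign in (1.0, -1.0):
            if np.all(sign * u[:, axis] > cos_cone):
                return True
    return False


def _sphere_residual(means: np.ndarray, gain: np.ndarray, offset: np.ndarray) -> float:
    c = gain * means + offset
    return float(np.abs(np.linalg.norm(c, axis=1) - ONE_G_MG).mean())


def estimate_calibration(
    windows_means: np.ndarray,
    min_windows: int = MIN_WINDOWS_DEFAULT,
    max_iter: int = MAX_ITER,
    tol: float = PARAM_TOL,
) -> CalibrationParams:
    """Fit gain/offset so calibrated window means sit on the 1000-mg sphere.

    Iterates: project current calibrated means radially onto the sphere,
    then refit each axis by ordinary least squares against its projection.
    Falls back to an identity calibration (``flagged=True``) when fewer than
    ``min_windows`` windows are given, when all orientations cluster within
    30 degrees of a single axis, or when the fit leaves sanity bounds
    (gain outside (0.5, 2), |offset| >= 500 mg) or fails to reduce the
    sphere residual.
    """
    means = np.asarray(windows_means, dtype=float).reshape(-1, 3)
    if means.shape[0] < 1:
        raise ValidationError("estimate_calibration needs at least one window mean")
    n_w = means.shape[0]
    identity_residual = _sphere_residual(means, np.ones(3), np.zeros(3))

    def identity(flagged: bool) -> CalibrationParams:
        return CalibrationParams(
            offset=np.zeros(3),
            gain=np.ones(3),
            residual_mg=identity_residual,
            n_windows=n_w,
            flagged=flagged,
        )

    if n_w < min_windows or _orientation_clustered(means):
        return identity(True)

    gain = np.ones(3)
    offset = np.zeros(3)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        c = gain * means + offset
        norms = np.linalg.norm(c, axis=1)
        if np.any(norms == 0):
            return identity(True)
        target = ONE_G_MG * c / norms[:, None]
        new_gain = gain.copy()
        new_offset = offset.copy()
        for j in range(3):
            x = means[:, j]
            var = x.var()
            if var < 1e-12:  # no spread on this axis: offset-only update
                new_gain[j] = gain[j]
                new_offset[j] = float((target[:, j] - gain[j] * x).mean())
            else:
                slope = float(np.cov(x, target[:, j], bias=True)[0, 1] / var)
                new_gain[j] = slope
                new_offset[j] = float(target[:, j].mean() - slope * x.mean())
        delta = max(
            np.max(np.abs(new_gain - gain)), np.max(np.abs(new_offset - offset))
        )
        gain, offset = new_gain, new_offset
        if delta < tol:
            break

    residual = _sphere_residual(means, gain, offset)
    out_of_bounds = (
        np.any(gain <= GAIN_BOUNDS[0])
        or np.any(gain >= GAIN_BOUNDS[1])
        or np.any(np.abs(offset) >= OFFSET_BOUND_MG)
    )
    if out_of_bounds or residual > identity_residual:
        return identity(True)
    return CalibrationParams(
        offset=offset,
        gain=gain,
        residual_mg=residual,
        n_windows=n_w,
        flagged=False,
        n_iter=n_iter,
    )


def apply_calibration(rec: RawRecording, cal: CalibrationParams) -> RawRecording:
    """Return a copy of the recording with ``gain * xyz + offset`` applied."""
    return rec.with_xyz(cal.gain * rec.xyz + cal.offset)


def calibrate_recording(
    rec: RawRecording,
    window_s: float = DEFAULT_WINDOW_S,
    sd_threshold_mg: float = DEFAULT_SD_THRESHOLD_MG,
    min_windows: int = MIN_WINDOWS_DEFAULT,
) -> tuple[RawRecording, CalibrationParams]:
    """Detect stationary windows, fit, and apply the calibration in one call."""
    windows = detect_stationary_windows(rec, window_s, sd_threshold_mg)
    if not windows:
        cal = CalibrationParams(n_windows=0, flagged=True)
        return rec, cal
    cal = estimate_calibration(window_means(rec, windows), min_windows=min_windows)
    return apply_calibration(rec, cal), cal
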