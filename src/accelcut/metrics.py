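"""Epoch-level intensity metrics from raw tri-axial acceleration.

Both metrics summarise the per-sample vector magnitude
``r_i = sqrt(x_i^2 + y_i^2 + z_i^2)`` (mg) over fixed non-overlapping
epochs (5 s by default; at 100 Hz an epoch holds n = 500 samples):

* **MAD** (mean amplitude deviation): ``(1/n) * sum_i |r_i - rbar|`` with
  ``rbar`` the epoch mean magnitude.  The static (gravitational) component
  cancels, so MAD measures only the dynamic part of the signal.
* **ENMO** (Euclidean norm minus one): per-sample ``e_i = r_i - 1000`` mg,
  i.e. magnitude minus one gravitational unit; negatives are rounded up to
  zero and the epoch mean taken.  By default the clamp is applied per
  sample before averaging (the convention of the reference ENMO toolchain);
  ``truncate_per_sample=False`` instead averages the raw ``e_i`` and clamps
  the epoch mean.

Neither metric requires band-pass filtering: gravity is handled inside the
metric itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import RawRecording

__all__ = [
    "Epoch",
    "epoch_signal",
    "compute_mad",
    "compute_enmo",
    "compute_epoch_metrics",
    "DEFAULT_EPOCH_S",
]

DEFAULT_EPOCH_S = 5.0
ONE_G_MG = 1000.0


@dataclass
class Epoch:
    """One fixed-length window of vector magnitudes (mg)."""

    start_t: float
    magnitudes: np.ndarray

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if self.magnitudes.ndim != 1 or self.magnitudes.size < 1:
            raise ValidationError("an epoch needs a 1-D, non-empty magnitude vector")
        if np.any(self.magnitudes < 0):
            raise ValidationError("vector magnitudes cannot be negative")

    @property
    def n(self) -> int:
        return self.magnitudes.size

    @property
    def mean_magnitude(self) -> float:
        return float(self.magnitudes.mean())


def epoch_signal(rec: RawRecording, epoch_s: float = DEFAULT_EPOCH_S) -> list[Epoch]:
    """Cut a recording into consecutive non-overlapping epochs.

    Epochs are anchored at the recording start; a trailing partial epoch is
    dropped (never padded — a short epoch would bias MAD).
    """
    n_per = int(round(rec.fs * epoch_s))
    if n_per < 1:
        raise ValidationError(f"epoch of {epoch_s} s holds no sample at fs={rec.fs}")
    n_epochs = rec.n_samples // n_per
    if n_epochs == 0:
        return []
    r = rec.magnitudes()[: n_epochs * n_per].reshape(n_epochs, n_per)
    return [Epoch(start_t=k * epoch_s, magnitudes=r[k]) for k in range(n_epochs)]


def compute_mad(ep: Epoch) -> float:
    """Mean absolute deviation of the epoch's magnitudes about their mean (mg)."""
    r = ep.magnitudes
    return float(np.abs(r - r.mean()).mean())


def compute_enmo(ep: Epoch, truncate_per_sample: bool = True) -> float:
    """Epoch ENMO in mg; see module docstring for the two truncation modes."""
    e = ep.magnitudes - ONE_G_MG
    if truncate_per_sample:
        return float(np.maximum(e, 0.0).mean())
    return float(max(e.mean(), 0.0))


def _metrics_arrays(
    rec: RawRecording, epoch_s: float, truncate_per_sample: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised (epoch_start, enmo, mad) arrays for a whole recording."""
    n_per = int(round(rec.fs * epoch_s))
    if n_per < 1:
        raise ValidationError(f"epoch of {epoch_s} s holds no sample at fs={rec.fs}")
    n_epochs = rec.n_samples // n_per
    if n_epochs == 0:
        return np.empty(0), np.empty(0), np.empty(0)
    r = rec.magnitudes()[: n_epochs * n_per].reshape(n_epochs, n_per)
    starts = np.arange(n_epochs) * epoch_s
    mad = np.abs(r - r.mean(axis=1, keepdims=True)).mean(axis=1)
    e = r - ONE_G_MG
    if truncate_per_sample:
        enmo = np.maximum(e, 0.0).mean(axis=1)
    else:
        enmo = np.maximum(e.mean(axis=1), 0.0)
    return starts, enmo, mad


def compute_epoch_metrics(
    rec: RawRecording,
    epoch_s: float = DEFAULT_EPOCH_S,
    truncate_per_sample: bool = True,
) -> pd.DataFrame:
    """Compute ENMO and MAD for every full epoch of a recording.

    Returns a DataFrame with columns ``epoch_start, participant_id, brand,
    placement, activity_id, enmo_mg, mad_mg`` (``activity_id`` unset until
    labelling).
    """
    starts, enmo, mad = _metrics_arrays(rec, epoch_s, truncate_per_sample)
    return pd.DataFrame(
        {
            "epoch_start": starts,
            "participant_id": rec.participant_id,
            "brand": rec.brand,
            "placement": rec.placement,
            "activity_id": pd.array([pd.NA] * len(starts), dtype="Int64"),
            "enmo_mg": enmo,
            "mad_mg": mad,
        }
    )
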