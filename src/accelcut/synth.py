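"""Synthetic raw accelerometry emulating the laboratory protocol.

Generates 100 Hz tri-axial recordings for a cohort wearing four devices
(ActiGraph-like "AG" and GENEActiv-like "GA", each at hip and wrist) while
performing 16 five-minute activities (11 lying/sitting postures, standing
still, washing pots, dusting, sweeping, self-paced walking) separated by
30-second breaks.

Signal model, per activity::

    s(t) = 1000 * o  +  sum_k  a * w_k * sin(2*pi*f_k*t + phi_k) * d_k  +  eps
    y(t) = gain * s(t) + offset

with ``o`` the gravity orientation in the device frame, ``a`` the activity's
movement amplitude (mg) split over 2-4 sinusoids (weights ``w_k``,
frequencies 0.8-3 Hz) along random unit directions ``d_k`` with random
phases, white Gaussian noise ``eps`` (activity noise plus a brand-specific
extra term), and a brand-specific affine distortion.  GA devices carry
larger noise and offsets than AG, reproducing the observed brand gap at low
intensities; wrist amplitudes for the motion activities are several-fold
larger than hip amplitudes, reflecting arm movement.

Standing still is generated from the *same* movement-amplitude distribution
as the sedentary pool (a per-participant draw from the 11 sedentary
amplitudes): magnitude-based metrics carry no posture information, so the
standing-vs-sedentary discrimination is an exact null by construction.

Default movement amplitudes were calibrated with
:func:`fit_generator_to_targets` against published mean ENMO/MAD values for
each activity group, so mean epoch metrics land in realistic ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ActivityEntry, ActivityLog, RawRecording, SEDENTARY_IDS
from .metrics import _metrics_arrays

__all__ = [
    "ActivityModel",
    "DeviceModel",
    "CohortConfig",
    "ParticipantData",
    "default_activity_models",
    "default_device",
    "generate_recording",
    "generate_cohort",
    "fit_generator_to_targets",
]

ONE_G_MG = 1000.0
DEFAULT_FREQS_HZ = (0.9, 1.7, 2.8)
DEFAULT_FREQ_WEIGHTS = (0.5, 0.3, 0.2)
BASE_NOISE_SD_MG = 1.0
DEFAULT_BETWEEN_SUBJECT_SD = 0.3
BREAK_AMP_MG = 15.0  # transitional movement during inter-activity breaks

ACTIVITY_LABELS = {
    1: "Lying flat on back",
    2: "Lying on back, legs bent",
    3: "Lying on side, legs straight",
    4: "Lying on side, legs bent",
    5: "Sitting, feet on floor",
    6: "Sitting, legs crossed",
    7: "Sitting, foot on thigh",
    8: "Sitting, legs stretched",
    9: "Sitting, legs bent back",
    10: "Sitting, typing",
    11: "Sitting, mobile phone",
    12: "Standing still",
    13: "Washing pots",
    14: "Dusting",
    15: "Sweeping floor",
    16: "Self-paced walk",
}

# gravity direction in the device frame per activity; deliberately spread
# over +/- axes so stationary periods give the sphere fit orientation
# diversity
ACTIVITY_ORIENTATIONS = {
    1: (1.0, 0.0, 0.0),
    2: (0.9, 0.1, -0.3),
    3: (0.0, 1.0, 0.0),
    4: (0.0, -1.0, 0.1),
    5: (0.1, 0.2, 1.0),
    6: (-0.2, 0.3, 0.9),
    7: (0.3, -0.2, 0.9),
    8: (0.5, 0.0, 0.8),
    9: (-0.4, 0.1, 0.9),
    10: (0.2, 0.4, 0.9),
    11: (-0.1, -0.4, 0.9),
    12: (0.0, 0.1, -1.0),
    13: (0.1, -0.1, -1.0),
    14: (-0.1, 0.2, -0.95),
    15: (0.2, 0.1, -0.95),
    16: (0.0, 0.0, -1.0),
}

# movement amplitudes (mg) frozen after calibrating the generator against
# published per-activity mean MAD values with fit_generator_to_targets
# (AG noise level, ideal gain/offset); sedentary postures keep a fixed
# relative profile (typing/phone busier than still lying/sitting)
DEFAULT_AMPS_HIP = {
    1: 0.4, 2: 0.4, 3: 0.5, 4: 0.5,
    5: 0.8, 6: 0.8, 7: 0.9, 8: 0.9, 9: 0.9,
    10: 3.2, 11: 3.8,
    12: None,          # standing: drawn from the sedentary pool (exact null)
    13: 37.0, 14: 161.0, 15: 206.0, 16: 668.0,
}
DEFAULT_AMPS_WRIST = {
    1: 17.0, 2: 17.0, 3: 20.0, 4: 20.0,
    5: 25.0, 6: 25.0, 7: 28.0, 8: 28.0, 9: 28.0,
    10: 73.0, 11: 84.0,
    12: None,
    13: 557.0, 14: 466.0, 15: 985.0, 16: 855.0,
}


@dataclass
class ActivityModel:
    """Movement model for one protocol activity."""

    activity_id: int
    label: str
    orientation: np.ndarray
    movement_amp_mg: float | None  # None: draw from the sedentary pool
    movement_freqs_hz: tuple[float, ...] = DEFAULT_FREQS_HZ
    freq_weights: tuple[float, ...] = DEFAULT_FREQ_WEIGHTS
    noise_sd_mg: float = BASE_NOISE_SD_MG

    def __post_init__(self) -> None:
        o = np.asarray(self.orientation, dtype=float).reshape(3)
        norm = np.linalg.norm(o)
        if norm == 0:
            raise ValidationError("orientation must be a non-zero vector")
        self.orientation = o / norm
        if self.movement_amp_mg is not None and self.movement_amp_mg < 0:
            raise ValidationError("movement amplitude must be non-negative")


@dataclass
class DeviceModel:
    """Brand-specific affine distortion and extra sensor noise."""

    brand: str
    offset_mg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gain: np.ndarray = field(default_factory=lambda: np.ones(3))
    extra_noise_sd_mg: float = 0.0

    def __post_init__(self) -> None:
        self.offset_mg = np.asarray(self.offset_mg, dtype=float).reshape(3)
        self.gain = np.asarray(self.gain, dtype=float).reshape(3)


#: GA carries larger noise and offsets than AG, mimicking the brand gap
#: reported at low intensities
DEFAULT_DEVICES = {
    "AG": DeviceModel(
        brand="AG",
        offset_mg=np.array([3.0, -4.0, 2.0]),
        gain=np.array([1.004, 0.997, 1.002]),
        extra_noise_sd_mg=0.6,
    ),
    "GA": DeviceModel(
        brand="GA",
        offset_mg=np.array([9.0, -7.0, 6.0]),
        gain=np.array([1.012, 0.991, 1.008]),
        extra_noise_sd_mg=10.5,
    ),
}


def default_device(brand: str) -> DeviceModel:
    if brand not in DEFAULT_DEVICES:
        raise ValidationError(f"unknown brand {brand!r}")
    d = DEFAULT_DEVICES[brand]
    return replace(d, offset_mg=d.offset_mg.copy(), gain=d.gain.copy())


def default_activity_models(
    placement: str = "hip", activity_ids: tuple[int, ...] | None = None
) -> list[ActivityModel]:
    """The 16 default activity models for a wear site (or a subset)."""
    amps = DEFAULT_AMPS_HIP if placement == "hip" else DEFAULT_AMPS_WRIST
    ids = activity_ids if activity_ids is not None else tuple(range(1, 17))
    return [
        ActivityModel(
            activity_id=i,
            label=ACTIVITY_LABELS[i],
            orientation=ACTIVITY_ORIENTATIONS[i],
            movement_amp_mg=amps[i],
        )
        for i in ids
    ]


#: cosine of the angle between movement directions and gravity.  Fixing the
#: radial coupling (random azimuth only) keeps the metric response to a
#: given amplitude stable, so between-subject spread is governed by the
#: log-normal amplitude multipliers rather than direction luck.
MOVEMENT_GRAVITY_COUPLING = 0.5


def _cone_direction(o: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unit vector at a fixed angle from ``o`` with uniform random azimuth."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(o @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(o, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(o, e1)
    c = MOVEMENT_GRAVITY_COUPLING * rng.choice([-1.0, 1.0])
    s = np.sqrt(1.0 - c * c)
    phi = rng.uniform(0, 2 * np.pi)
    return c * o + s * (np.cos(phi) * e1 + np.sin(phi) * e2)


def _movement(
    n: int,
    fs: float,
    amp: float,
    model: ActivityModel,
    rng: np.random.Generator,
    orientation: np.ndarray | None = None,
) -> np.ndarray:
    """Sum-of-sinusoids movement; directions on a cone around gravity; (n, 3) mg."""
    o = model.orientation if orientation is None else orientation
    t = np.arange(n) / fs
    out = np.zeros((n, 3))
    for f, w in zip(model.movement_freqs_hz, model.freq_weights):
        d = _cone_direction(o, rng)
        phi = rng.uniform(0, 2 * np.pi)
        out += (amp * w * np.sin(2 * np.pi * f * t + phi))[:, None] * d
    return out


def _effective_amps(
    models: list[ActivityModel],
    multipliers: dict[int, float] | None,
    rng: np.random.Generator,
) -> dict[int, float]:
    """Per-activity amplitudes after between-subject multipliers.

    Standing-still models with ``movement_amp_mg=None`` receive the
    amplitude of one randomly chosen sedentary activity, making standing
    exchangeable with the sedentary pool.
    """
    mult = multipliers or {}
    eff: dict[int, float] = {}
    sed_pool = []
    for m in models:
        if m.movement_amp_mg is not None:
            eff[m.activity_id] = m.movement_amp_mg * mult.get(m.activity_id, 1.0)
            if m.activity_id in SEDENTARY_IDS:
                sed_pool.append(eff[m.activity_id])
    for m in models:
        if m.movement_amp_mg is None:
            if sed_pool:
                eff[m.activity_id] = float(rng.choice(sed_pool))
            else:
                eff[m.activity_id] = 0.0
    return eff


def generate_recording(
    participant_id: str,
    models: list[ActivityModel],
    device: DeviceModel,
    fs: float = 100.0,
    activity_s: float = 300.0,
    break_s: float = 30.0,
    seed: int | None = 0,
    placement: str = "hip",
    amp_multipliers: dict[int, float] | None = None,
    orientation_jitter: float = 0.06,
    motion_rng: np.random.Generator | None = None,
    noise_rng: np.random.Generator | None = None,
) -> tuple[RawRecording, ActivityLog]:
    """Simulate one device recording plus its ground-truth activity log.

    ``motion_rng`` and ``noise_rng`` may be supplied separately so two
    devices at the same wear site share the same latent movement but see
    independent sensor noise; by default both derive from ``seed``.
    Identical seeds yield byte-identical output.
    """
    if motion_rng is None or noise_rng is None:
        ss = np.random.SeedSequence(seed)
        kids = ss.spawn(2)
        motion_rng = motion_rng or np.random.default_rng(kids[0])
        noise_rng = noise_rng or np.random.default_rng(kids[1])

    n_act = int(round(activity_s * fs))
    n_brk = int(round(break_s * fs))
    eff = _effective_amps(models, amp_multipliers, motion_rng)

    segments = []
    entries = []
    t_cursor = 0.0
    for idx, m in enumerate(models):
        o = m.orientation + orientation_jitter * motion_rng.normal(size=3)
        o /= np.linalg.norm(o)
        s = ONE_G_MG * o + _movement(n_act, fs, eff[m.activity_id], m, motion_rng, o)
        sd = m.noise_sd_mg + device.extra_noise_sd_mg
        s = s + noise_rng.normal(scale=sd, size=(n_act, 3)) if sd > 0 else s
        segments.append(s)
        entries.append(
            ActivityEntry(
                activity_id=m.activity_id,
                label=m.label,
                start_s=t_cursor,
                end_s=t_cursor + n_act / fs,
            )
        )
        t_cursor += n_act / fs
        if idx < len(models) - 1 and n_brk > 0:
            b = ONE_G_MG * o + _movement(n_brk, fs, BREAK_AMP_MG, m, motion_rng, o)
            sd = m.noise_sd_mg + device.extra_noise_sd_mg
            b = b + noise_rng.normal(scale=sd, size=(n_brk, 3)) if sd > 0 else b
            segments.append(b)
            t_cursor += n_brk / fs

    xyz = np.vstack(segments)
    xyz = device.gain * xyz + device.offset_mg
    rec = RawRecording(
        xyz=xyz,
        fs=fs,
        brand=device.brand,
        placement=placement,
        participant_id=participant_id,
    )
    return rec, ActivityLog(entries=entries)


@dataclass
class CohortConfig:
    """Study-design parameters for cohort generation.

    Defaults mirror the laboratory protocol: 33 participants, 100 Hz,
    16 activities of 5 minutes with 30-second breaks, two brands at two
    wear sites, log-normal between-subject amplitude variation.
    """

    n_participants: int = 33
    fs: float = 100.0
    activity_s: float = 300.0
    break_s: float = 30.0
    brands: tuple[str, ...] = ("AG", "GA")
    placements: tuple[str, ...] = ("hip", "wrist")
    between_subject_sd: float = DEFAULT_BETWEEN_SUBJECT_SD
    activity_ids: tuple[int, ...] | None = None  # None: full 16-activity protocol
    device_jitter: bool = True


@dataclass
class ParticipantData:
    participant_id: str
    log: ActivityLog
    recordings: dict[tuple[str, str], RawRecording]  # (brand, placement) -> rec


def _jittered_device(base: DeviceModel, rng: np.random.Generator) -> DeviceModel:
    """Per-unit manufacturing spread around the brand's nominal distortion."""
    return DeviceModel(
        brand=base.brand,
        offset_mg=base.offset_mg + rng.normal(scale=0.3 * np.abs(base.offset_mg) + 0.5),
        gain=base.gain + rng.normal(scale=0.003, size=3),
        extra_noise_sd_mg=base.extra_noise_sd_mg,
    )


def generate_cohort(
    n_participants: int | None = None,
    config: CohortConfig | None = None,
    seed: int = 0,
) -> list[ParticipantData]:
    """Generate the full cohort: one log and 4 recordings per participant.

    Within a participant, devices at the same wear site share the latent
    movement process (same sinusoid directions/phases and between-subject
    amplitude multipliers) and differ only by brand distortion and sensor
    noise; hip and wrist see the same multipliers but site-specific
    amplitude profiles.
    """
    config = config or CohortConfig()
    if n_participants is not None:
        config = replace(config, n_participants=n_participants)
    if config.n_participants < 1:
        raise ValidationError("need at least one participant")
    master = np.random.SeedSequence(seed)
    part_seqs = master.spawn(config.n_participants)

    cohort = []
    for p_idx, p_seq in enumerate(part_seqs):
        pid = f"P{p_idx + 1:02d}"
        p_rng = np.random.default_rng(p_seq)
        mult = {
            i: float(np.exp(p_rng.normal(scale=config.between_subject_sd)))
            for i in range(1, 17)
        }
        recordings: dict[tuple[str, str], RawRecording] = {}
        log = None
        for placement in config.placements:
            models = default_activity_models(placement, config.activity_ids)
            motion_seed, *noise_seeds = p_rng.integers(0, 2**31 - 1, size=1 + len(config.brands))
            for brand, noise_seed in zip(config.brands, noise_seeds):
                base = default_device(brand)
                dev_rng = np.random.default_rng(int(noise_seed))
                device = _jittered_device(base, dev_rng) if config.device_jitter else base
                rec, rec_log = generate_recording(
                    pid,
                    models,
                    device,
                    fs=config.fs,
                    activity_s=config.activity_s,
                    break_s=config.break_s,
                    placement=placement,
                    amp_multipliers=mult,
                    motion_rng=np.random.default_rng(int(motion_seed)),
                    noise_rng=dev_rng,
                )
                recordings[(brand, placement)] = rec
                log = rec_log  # identical timing for all four devices
        cohort.append(ParticipantData(participant_id=pid, log=log, recordings=recordings))
    return cohort


def _simulated_mean_metric(
    amp: float,
    metric: str,
    model: ActivityModel,
    noise_sd_mg: float,
    fs: float,
    duration_s: float,
    seed: int,
    n_reps: int = 8,
) -> float:
    """Expected mean epoch metric at a given amplitude.

    Averages over several independent movement-direction draws: a single
    draw couples the sinusoids to the gravity axis by a random amount, so
    one replicate is an unrepresentative sample of the cohort mean.
    """
    out = 0.0
    for rep_seq in np.random.SeedSequence(seed).spawn(n_reps):
        rng = np.random.default_rng(rep_seq)
        n = int(round(duration_s * fs))
        s = ONE_G_MG * model.orientation + _movement(n, fs, amp, model, rng)
        if noise_sd_mg > 0:
            s = s + rng.normal(scale=noise_sd_mg, size=(n, 3))
        rec = RawRecording(xyz=s, fs=fs)
        _, enmo, mad = _metrics_arrays(rec, 5.0, True)
        out += float(enmo.mean() if metric == "enmo" else mad.mean())
    return out / n_reps


def fit_generator_to_targets(
    target_means: pd.DataFrame,
    seed: int = 0,
    placement: str = "hip",
    noise_sd_mg: float = BASE_NOISE_SD_MG + DEFAULT_DEVICES["AG"].extra_noise_sd_mg,
    fs: float = 100.0,
    duration_s: float = 120.0,
    rel_tol: float = 0.15,
    max_iter: int = 30,
) -> list[ActivityModel]:
    """Calibrate per-activity movement amplitudes to target mean metrics.

    ``target_means`` has columns ``activity_id``, ``metric`` (``enmo`` or
    ``mad``) and ``mean_mg``.  For each row a one-dimensional multiplicative
    search adjusts the amplitude until the simulated mean epoch metric is
    within ``rel_tol`` of the target (the metric mean is increasing in
    amplitude).  A target below the noise floor returns amplitude 0; a
    negative target raises.
    """
    for col in ("activity_id", "metric", "mean_mg"):
        if col not in target_means.columns:
            raise ValidationError(f"target table missing column {col!r}")
    models = {m.activity_id: m for m in default_activity_models(placement)}
    fitted = []
    rng = np.random.default_rng(seed)
    for _, row in target_means.iterrows():
        act = int(row["activity_id"])
        metric = str(row["metric"])
        target = float(row["mean_mg"])
        if target < 0:
            raise ValidationError(f"negative target {target} for activity {act}")
        if metric not in ("enmo", "mad"):
            raise ValidationError(f"unknown metric {metric!r}")
        model = models[act]
        sim_seed = int(rng.integers(0, 2**31 - 1))
        floor = _simulated_mean_metric(
            0.0, metric, model, noise_sd_mg, fs, duration_s, sim_seed
        )
        if target <= floor:
            fitted.append(replace(model, movement_amp_mg=0.0))
            continue
        amp = max(4.0 * target, 1.0)
        ok = False
        for _ in range(max_iter):
            sim = _simulated_mean_metric(
                amp, metric, model, noise_sd_mg, fs, duration_s, sim_seed
            )
            if abs(sim - target) <= rel_tol * target * 0.5:
                ok = True
                break
            amp *= float(np.clip(target / max(sim, 1e-9), 0.25, 4.0))
        if not ok:
            sim = _simulated_mean_metric(
                amp, metric, model, noise_sd_mg, fs, duration_s, sim_seed
            )
            if abs(sim - target) > rel_tol * target:
                raise ValidationError(
                    f"could not reach target {target} mg for activity {act} "
                    f"(best {sim:.2f} mg)"
                )
        fitted.append(replace(model, movement_amp_mg=float(amp)))
    return fitted
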