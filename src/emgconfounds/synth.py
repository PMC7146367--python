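"""Synthetic surface-EMG generation with limb-position and contraction-intensity
confounds.

The generator replaces external multi-condition EMG corpora with a controlled
stochastic model.  Each trial is built from a per-channel innovation process — a
Gaussian/Laplacian amplitude mixture, band-shaped to the 20–450 Hz surface-EMG
band with an additional resonant low-frequency power peak — scaled by a per-class
per-channel activation envelope, and then distorted by the condition under study:

* **position** conditions re-mix channels through a row-stochastic matrix
  ``W = (1 - alpha) I + alpha M`` (electrode/fibre topography shift) and inject
  band-limited stabilization activity on a seeded half of the channels, growing
  with the distance from the reference position;
* **intensity** conditions apply an amplitude gain ``level ** gamma``, shift the
  low-frequency spectral peak linearly across the configured range (10 → 40 Hz by
  default), and move the innovation distribution between its Gaussian and
  Laplacian components.

Everything is deterministic given ``(config, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "GeneratorConfig",
    "EmgRecording",
    "ClassProfile",
    "ConditionTransform",
    "ConditionError",
    "make_class_profiles",
    "make_condition_transform",
    "synthesize_trial",
    "generate_dataset",
    "d1_like_config",
    "d4_like_config",
]

# Relative weight of the resonant low-frequency component in the shaped
# innovation (both components are RMS-normalised before mixing).
_PEAK_WEIGHT = 0.8
# Quality factor of the resonant peak filter.
_PEAK_Q = 5.0
# Stream tags keeping the per-purpose RNG streams disjoint.
_STREAM_PROFILE = 101
_STREAM_MIXING = 202
_STREAM_STABILIZATION = 303
_STREAM_TRIAL = 404


class ConditionError(ValueError):
    """Raised when a condition value is not part of the configured conditions."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterisation of a synthetic multi-subject EMG dataset.

    ``conditions`` are limb-position indices (``condition_kind="position"``) or
    MVC fractions in (0, 1] (``condition_kind="intensity"``).  The first entry is
    the reference condition; all confound effects are defined relative to it.
    """

    n_subjects: int = 2
    n_channels: int = 8
    motion_classes: tuple[str, ...] = (
        "no_motion",
        "power_grip",
        "pinch_grip",
        "wrist_flexion",
        "wrist_extension",
        "pronation",
        "supination",
        "hand_open",
    )
    no_motion_class: str = "no_motion"
    condition_kind: str = "position"
    conditions: tuple = (0, 1, 2, 3, 4)
    reps_per_condition: int = 10
    fs: float = 1000.0
    trial_duration: float = 1.0
    position_mixing_strength: float = 0.5  # alpha
    baseline_activity_level: float = 0.3  # beta, mV RMS per unit position distance
    intensity_gain_exponent: float = 1.0  # gamma; gain = level ** gamma
    peak_shift_range: tuple[float, float] = (10.0, 40.0)
    laplacian_weight_range: tuple[float, float] = (0.2, 0.8)
    # lognormal sigma of per-trial per-channel amplitude jitter: repeated
    # contractions of the same motion are never identical in amplitude
    trial_amplitude_jitter: float = 0.2
    noise_floor: float = 0.02  # mV RMS
    seed: int = 0
    # Minimum window the downstream chain will cut; used only for validation.
    min_window_ms: float = 150.0

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_channels < 1:
            raise ValueError("n_subjects and n_channels must be >= 1")
        if not self.conditions:
            raise ValueError("conditions must be nonempty")
        if self.condition_kind not in ("position", "intensity"):
            raise ValueError(f"unknown condition_kind {self.condition_kind!r}")
        if self.condition_kind == "intensity":
            for level in self.conditions:
                if not (0.0 < float(level) <= 1.0):
                    raise ValueError("MVC fractions must lie strictly in (0, 1]")
        if self.motion_classes.count(self.no_motion_class) != 1:
            raise ValueError("exactly one motion class must be the no-motion class")
        if len(set(self.motion_classes)) != len(self.motion_classes):
            raise ValueError("motion class names must be unique")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.trial_duration * self.fs < self.min_window_ms * self.fs / 1000.0:
            raise ValueError("trial_duration must cover at least one analysis window")
        if not (0.0 <= self.position_mixing_strength <= 1.0):
            raise ValueError("position_mixing_strength must lie in [0, 1]")
        if self.baseline_activity_level < 0:
            raise ValueError("baseline_activity_level must be nonnegative")
        if self.intensity_gain_exponent <= 0:
            raise ValueError("intensity_gain_exponent must be positive")
        lo, hi = self.laplacian_weight_range
        if not (0.0 <= lo <= 1.0 and 0.0 <= hi <= 1.0):
            raise ValueError("laplacian_weight_range must lie in [0, 1]")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be nonnegative")
        if self.trial_amplitude_jitter < 0:
            raise ValueError("trial_amplitude_jitter must be nonnegative")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration * self.fs))


@dataclass(frozen=True)
class EmgRecording:
    """One trial of multi-channel surface EMG (channels x samples, mV)."""

    data: np.ndarray
    fs: float
    subject_id: int
    motion_label: str
    condition_kind: str
    condition_value: object
    trial_index: int

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[0] < 1 or data.shape[1] < 1:
            raise ValueError("data must be a channels x samples matrix")
        if not np.all(np.isfinite(data)):
            raise ValueError("EMG samples must all be finite")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        object.__setattr__(self, "data", data)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class ClassProfile:
    """Per-subject activation envelopes: one row of per-channel amplitudes (mV)
    per motion class, plus the seeded subset of channels that picks up
    stabilization activity."""

    base_amplitude: np.ndarray  # classes x channels, mV
    subject_scale: float
    stabilization_channels: np.ndarray  # indices of channels receiving baseline

    def __post_init__(self):
        amp = np.asarray(self.base_amplitude, dtype=float)
        if np.any(amp < 0):
            raise ValueError("activation envelopes must be nonnegative")
        object.__setattr__(self, "base_amplitude", amp)


@dataclass(frozen=True)
class ConditionTransform:
    """Signal distortion attached to one (subject, condition) pair."""

    mixing_matrix: np.ndarray  # channels x channels, row-stochastic
    baseline_gain: float
    gain: float
    spectral_peak: float  # Hz
    laplacian_weight: float

    def __post_init__(self):
        w = np.asarray(self.mixing_matrix, dtype=float)
        if not np.allclose(w.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("mixing matrix rows must sum to 1")
        if self.baseline_gain < 0 or self.gain <= 0:
            raise ValueError("baseline_gain must be >= 0 and gain > 0")
        object.__setattr__(self, "mixing_matrix", w)


def _rng(config: GeneratorConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed,) + key))


def make_class_profiles(config: GeneratorConfig, subject_index: int) -> ClassProfile:
    """Draw the per-subject class activation envelopes.

    Deterministic given ``(config.seed, subject_index)``.  Active-class rows are
    i.i.d. uniform on [0.1, 1.0] mV (pairwise distinct almost surely); the
    no-motion row sits at the noise floor.
    """
    if subject_index >= config.n_subjects:
        raise ValueError("subject_index out of range")
    rng = _rng(config, _STREAM_PROFILE, subject_index)
    n_classes = len(config.motion_classes)
    amp = rng.uniform(0.1, 1.0, size=(n_classes, config.n_channels))
    nm = config.motion_classes.index(config.no_motion_class)
    amp[nm] = config.noise_floor
    scale = rng.uniform(0.7, 1.3)
    stab_rng = _rng(config, _STREAM_STABILIZATION, subject_index)
    half = max(1, config.n_channels // 2)
    stab = np.sort(stab_rng.choice(config.n_channels, size=half, replace=False))
    return ClassProfile(base_amplitude=amp, subject_scale=scale, stabilization_channels=stab)


def make_condition_transform(
    config: GeneratorConfig, condition_value, subject_index: int
) -> ConditionTransform:
    """Build the distortion for one condition.

    Position kind: ``W = (1 - alpha) I + alpha M`` with M a seeded row-stochastic
    perturbation unique to each (subject, position) — the reference position keeps
    W = I — plus baseline activity growing with the index distance from the
    reference.  Intensity kind: pure gain ``level ** gamma`` with the spectral
    peak and the Laplacian weight interpolated linearly across the level range.
    """
    if condition_value not in config.conditions:
        raise ConditionError(f"unknown condition value {condition_value!r}")
    n = config.n_channels
    idx = list(config.conditions).index(condition_value)
    if config.condition_kind == "position":
        alpha = config.position_mixing_strength
        if alpha == 0.0 or idx == 0:
            w = np.eye(n)
        else:
            rng = _rng(config, _STREAM_MIXING, subject_index, idx)
            m = rng.uniform(0.0, 1.0, size=(n, n))
            m /= m.sum(axis=1, keepdims=True)
            w = (1.0 - alpha) * np.eye(n) + alpha * m
        return ConditionTransform(
            mixing_matrix=w,
            baseline_gain=config.baseline_activity_level * idx,
            gain=1.0,
            spectral_peak=config.peak_shift_range[0],
            laplacian_weight=config.laplacian_weight_range[0],
        )
    # intensity
    level = float(condition_value)
    levels = [float(c) for c in config.conditions]
    lo, hi = min(levels), max(levels)
    t = 0.0 if hi == lo else (level - lo) / (hi - lo)
    p0, p1 = config.peak_shift_range
    w0, w1 = config.laplacian_weight_range
    return ConditionTransform(
        mixing_matrix=np.eye(n),
        baseline_gain=0.0,
        gain=level**config.intensity_gain_exponent,
        spectral_peak=p0 + t * (p1 - p0),
        laplacian_weight=w0 + t * (w1 - w0),
    )


def _shaping_filters(config: GeneratorConfig, spectral_peak: float):
    nyq = config.fs / 2.0
    high = min(450.0, 0.9 * nyq)
    low = min(20.0, 0.5 * high)
    sos = signal.butter(4, [low, high], btype="bandpass", fs=config.fs, output="sos")
    peak = min(max(spectral_peak, 1.0), 0.9 * nyq)
    b, a = signal.iirpeak(peak, _PEAK_Q, fs=config.fs)
    return sos, (b, a)


def _shape_innovation(x: np.ndarray, sos, ba) -> np.ndarray:
    """Band-shape white innovations: broadband 20–450 Hz component plus a
    resonant low-frequency peak, each RMS-normalised before mixing, then
    normalised to unit RMS overall."""
    broad = signal.sosfilt(sos, x, axis=-1)
    narrow = signal.lfilter(ba[0], ba[1], x, axis=-1)

    def _unit(v):
        rms = np.sqrt(np.mean(v**2, axis=-1, keepdims=True))
        return np.divide(v, rms, out=np.zeros_like(v), where=rms > 0)

    shaped = _unit(broad) + _PEAK_WEIGHT * _unit(narrow)
    return _unit(shaped)


def synthesize_trial(
    profile: ClassProfile,
    transform: ConditionTransform,
    motion_label: str,
    config: GeneratorConfig,
    trial_seed,
    *,
    subject_id: int = 0,
    condition_value=None,
    trial_index: int = 0,
) -> EmgRecording:
    """Generate one trial.  ``trial_seed`` may be an int or a SeedSequence; the
    same seed reproduces the recording bit-exactly."""
    if motion_label not in config.motion_classes:
        raise ValueError(f"unknown motion class {motion_label!r}")
    n = config.n_samples
    if n < 1:
        raise ValueError("trial duration shorter than one sample")
    if isinstance(trial_seed, np.random.SeedSequence):
        rng = np.random.default_rng(trial_seed)
    else:
        rng = np.random.default_rng(np.random.SeedSequence(trial_seed))
    c = config.n_channels
    w_lap = transform.laplacian_weight
    # Gaussian/Laplacian amplitude mixture, both components unit variance.
    use_lap = rng.random((c, n)) < w_lap
    gauss = rng.standard_normal((c, n))
    lap = rng.laplace(0.0, 1.0 / math.sqrt(2.0), size=(c, n))
    innov = np.where(use_lap, lap, gauss)

    sos, ba = _shaping_filters(config, transform.spectral_peak)
    shaped = _shape_innovation(innov, sos, ba)

    class_idx = config.motion_classes.index(motion_label)
    amp = transform.gain * profile.subject_scale * profile.base_amplitude[class_idx]
    if config.trial_amplitude_jitter > 0:
        amp = amp * rng.lognormal(0.0, config.trial_amplitude_jitter, size=c)
    data = transform.mixing_matrix @ (shaped * amp[:, None])

    if transform.baseline_gain > 0 and profile.stabilization_channels.size:
        stab = rng.standard_normal((profile.stabilization_channels.size, n))
        stab = _shape_innovation(stab, sos, ba)
        data[profile.stabilization_channels] += transform.baseline_gain * stab
    if config.noise_floor > 0:
        data += config.noise_floor * rng.standard_normal((c, n))

    return EmgRecording(
        data=data,
        fs=config.fs,
        subject_id=subject_id,
        motion_label=motion_label,
        condition_kind=config.condition_kind,
        condition_value=condition_value if condition_value is not None else config.conditions[0],
        trial_index=trial_index,
    )


def generate_dataset(config: GeneratorConfig) -> list[EmgRecording]:
    """Generate the full balanced dataset:
    ``n_subjects x |conditions| x |motion_classes| x reps_per_condition`` trials,
    deterministic and bit-exact under a fixed ``(config, seed)``."""
    config.validate()
    recordings: list[EmgRecording] = []
    for s in range(config.n_subjects):
        profile = make_class_profiles(config, s)
        for ci, cond in enumerate(config.conditions):
            transform = make_condition_transform(config, cond, s)
            for ki, motion in enumerate(config.motion_classes):
                for rep in range(config.reps_per_condition):
                    seed_seq = np.random.SeedSequence(
                        (config.seed, _STREAM_TRIAL, s, ci, ki, rep)
                    )
                    recordings.append(
                        synthesize_trial(
                            profile,
                            transform,
                            motion,
                            config,
                            seed_seq,
                            subject_id=s,
                            condition_value=cond,
                            trial_index=rep,
                        )
                    )
    return recordings


def d1_like_config(**overrides) -> GeneratorConfig:
    """Limb-position study shape: 8 channels, 8 motions, 10 reps, 5 positions,
    1000 Hz."""
    base = dict(
        n_subjects=2,
        n_channels=8,
        condition_kind="position",
        conditions=(0, 1, 2, 3, 4),
        reps_per_condition=10,
        fs=1000.0,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def d4_like_config(**overrides) -> GeneratorConfig:
    """Contraction-intensity study shape: 8 channels, 7 motions, 4 reps,
    7 MVC levels 20%..80% in steps of 10%, 1000 Hz."""
    base = dict(
        n_subjects=2,
        n_channels=8,
        motion_classes=(
            "no_motion",
            "power_grip",
            "pinch_grip",
            "wrist_flexion",
            "wrist_extension",
            "pronation",
            "supination",
        ),
        condition_kind="intensity",
        conditions=tuple(round(0.2 + 0.1 * i, 1) for i in range(7)),
        reps_per_condition=4,
        fs=1000.0,
    )
    base.update(overrides)
    return GeneratorConfig(**base)
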