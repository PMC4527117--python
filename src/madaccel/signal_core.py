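"""Resultant acceleration, epoch segmentation and MAD computation.

The mean amplitude deviation (MAD) of an epoch is the mean absolute
deviation of the resultant (Euclidean-norm) acceleration about the epoch
mean::

    MAD = (1/n) * sum_i |r_i - rbar|        [unit: mg]

where ``n`` is the number of samples in the epoch, ``r_i`` the i-th
resultant sample and ``rbar`` the epoch-mean resultant.  Because gravity
contributes a near-constant offset to the resultant during steady
activity, the subtraction of the epoch mean cancels it: a motionless
recording has MAD exactly 0 regardless of orientation.

Epoch lengths are powers of two chosen to approximate a target duration
(default 5 s): 512 samples at 100 Hz (5.12 s) and 128 samples at 30 Hz
(4.27 s).

All accelerations are in milligravity units (mg; 1000 mg = 1 g).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ACTIVITY_CLASS",
    "ACTIVITY_LABELS",
    "INTENSITY_NAMES",
    "ActivityBout",
    "BoutTooShortError",
    "Epoch",
    "EpochSpec",
    "InsufficientDataError",
    "InvalidSampleError",
    "MadSeries",
    "RawRecording",
    "bout_three_epoch_mads",
    "choose_epoch_spec",
    "compute_mad",
    "minute_mad_series",
    "resultant",
    "segment_epochs",
]

INTENSITY_NAMES = ("sedentary", "light", "moderate", "vigorous")

#: Fixed mapping of protocol activity labels to pattern-based intensity
#: classes: five sedentary, two light, one moderate, two vigorous.
ACTIVITY_CLASS = {
    "lying_supine": 0,
    "sitting": 0,
    "sitting_computer": 0,
    "standing": 0,
    "standing_handweights": 0,
    "slow_walk": 1,
    "normal_walk": 1,
    "brisk_walk": 2,
    "jogging": 3,
    "running": 3,
}

ACTIVITY_LABELS = tuple(ACTIVITY_CLASS)


class InvalidSampleError(ValueError):
    """A sample contains a non-finite axis value."""


class InsufficientDataError(ValueError):
    """A recording is too short for the requested segmentation."""


class BoutTooShortError(ValueError):
    """A bout cannot accommodate the three-epoch extraction scheme."""


@dataclass(frozen=True)
class RawRecording:
    """A single device's tri-axial sample stream.

    Parameters
    ----------
    device_id
        Free-text device identifier.
    sampling_rate_hz
        Sampling frequency, strictly positive.
    dynamic_range_mg
        Symmetric saturation limit of each axis (±).
    samples
        Array of shape ``(n, 3)`` with columns ax, ay, az in mg.
    start_time_s
        Session-clock time of the first sample.
    """

    device_id: str
    sampling_rate_hz: float
    dynamic_range_mg: float
    samples: np.ndarray
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(f"samples must have shape (n, 3); got {arr.shape}")
        if arr.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.dynamic_range_mg <= 0:
            raise ValueError("dynamic_range_mg must be positive")
        if not np.isfinite(arr).all():
            raise InvalidSampleError("recording contains non-finite samples")
        if np.abs(arr).max() > self.dynamic_range_mg * (1 + 1e-12):
            raise ValueError(
                "axis value exceeds declared dynamic range "
                f"(±{self.dynamic_range_mg} mg)"
            )
        object.__setattr__(self, "samples", arr)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass(frozen=True)
class EpochSpec:
    """Analysis-epoch geometry: a power-of-two sample count at a rate."""

    n_samples: int
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        if self.n_samples < 1 or (self.n_samples & (self.n_samples - 1)) != 0:
            raise ValueError("n_samples must be a positive power of two")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass(frozen=True)
class Epoch:
    """A contiguous window of resultant samples."""

    start_index: int
    resultant: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.resultant, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("resultant must be a non-empty 1-d sequence")
        if (arr < 0).any():
            raise ValueError("resultant samples must be non-negative")
        object.__setattr__(self, "resultant", arr)


@dataclass(frozen=True)
class MadSeries:
    """Epoch-indexed MAD values for one recording."""

    epoch_start_times_s: np.ndarray
    mad_mg: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.epoch_start_times_s, dtype=float)
        m = np.asarray(self.mad_mg, dtype=float)
        if t.shape != m.shape or t.ndim != 1:
            raise ValueError("times and MAD values must be equal-length 1-d")
        if (m < -1e-12).any():
            raise ValueError("MAD values must be non-negative")
        object.__setattr__(self, "epoch_start_times_s", t)
        object.__setattr__(self, "mad_mg", m)

    def __len__(self) -> int:
        return self.mad_mg.size


@dataclass(frozen=True)
class ActivityBout:
    """A labelled protocol segment with its pattern-based intensity class.

    The default protocol uses 2-min bouts; ``intensity_class`` defaults to
    the fixed label→class map (:data:`ACTIVITY_CLASS`).
    """

    label: str
    start_s: float
    end_s: float
    intensity_class: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.label not in ACTIVITY_CLASS:
            raise ValueError(f"unknown activity label {self.label!r}")
        if self.end_s <= self.start_s:
            raise ValueError("bout must have positive duration")
        if self.intensity_class == -1:
            object.__setattr__(self, "intensity_class", ACTIVITY_CLASS[self.label])
        elif self.intensity_class != ACTIVITY_CLASS[self.label]:
            raise ValueError(
                f"intensity_class {self.intensity_class} conflicts with the "
                f"pattern map for {self.label!r} ({ACTIVITY_CLASS[self.label]})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)


def resultant(samples: np.ndarray) -> np.ndarray | float:
    """Euclidean norm of the three axis accelerations.

    Accepts a single ``(ax, ay, az)`` triple or an ``(n, 3)`` array; returns
    a scalar or a length-n vector of non-negative values in mg.
    """
    arr = np.asarray(samples, dtype=float)
    if not np.isfinite(arr).all():
        raise InvalidSampleError("non-finite acceleration sample")
    if arr.ndim == 1:
        if arr.shape != (3,):
            raise ValueError("a single sample must be an (ax, ay, az) triple")
        return float(np.sqrt(arr @ arr))
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"expected shape (n, 3); got {arr.shape}")
    return np.sqrt(np.einsum("ij,ij->i", arr, arr))


def choose_epoch_spec(
    sampling_rate_hz: float, target_duration_s: float = 5.0
) -> EpochSpec:
    """Pick the power-of-two epoch length closest to a target duration.

    Returns the ``n = 2**k`` minimising ``|n - target_duration_s * rate|``,
    with ties broken toward the smaller ``n``.  At 100 Hz with the default
    5 s target this yields 512 samples (5.12 s); at 30 Hz, 128 samples
    (4.27 s).
    """
    if sampling_rate_hz <= 0 or target_duration_s <= 0:
        raise ValueError("sampling rate and target duration must be positive")
    target = sampling_rate_hz * target_duration_s
    if target <= 1:
        return EpochSpec(1, sampling_rate_hz)
    k = math.floor(math.log2(target))
    lo, hi = 2**k, 2 ** (k + 1)
    # tie toward smaller n: strict inequality for hi to win
    n = hi if (hi - target) < (target - lo) else lo
    return EpochSpec(int(n), sampling_rate_hz)


def compute_mad(epoch: Epoch | np.ndarray) -> float:
    """Mean absolute deviation of an epoch's resultant about its mean (mg)."""
    r = epoch.resultant if isinstance(epoch, Epoch) else np.asarray(epoch, float)
    if r.size == 0:
        raise ValueError("cannot compute MAD of an empty epoch")
    return float(np.mean(np.abs(r - r.mean())))


def segment_epochs(recording: RawRecording, spec: EpochSpec) -> MadSeries:
    """Cut a recording into consecutive non-overlapping epochs and MAD each.

    Epochs are anchored at sample 0; a trailing remainder shorter than one
    epoch is discarded.
    """
    n = spec.n_samples
    n_epochs = recording.n_samples // n
    if n_epochs == 0:
        raise InsufficientDataError(
            f"recording has {recording.n_samples} samples; epoch needs {n}"
        )
    r = resultant(recording.samples[: n_epochs * n])
    windows = r.reshape(n_epochs, n)
    mad = np.mean(np.abs(windows - windows.mean(axis=1, keepdims=True)), axis=1)
    starts = recording.start_time_s + np.arange(n_epochs) * (
        n / recording.sampling_rate_hz
    )
    return MadSeries(starts, mad)


def _epoch_mad_at(recording: RawRecording, start_s: float, spec: EpochSpec) -> float:
    """MAD of one epoch whose start snaps to the nearest sample index."""
    idx = int(round((start_s - recording.start_time_s) * recording.sampling_rate_hz))
    if idx < 0 or idx + spec.n_samples > recording.n_samples:
        raise InsufficientDataError(
            f"epoch at t={start_s:.2f}s falls outside the recording"
        )
    r = resultant(recording.samples[idx : idx + spec.n_samples])
    return compute_mad(r)


def bout_three_epoch_mads(
    recording: RawRecording, bout: ActivityBout, spec: EpochSpec
) -> tuple[float, float, float]:
    """MAD of three epochs within a bout: near its start, middle and end.

    The first epoch starts 5 s after the bout begins, the middle epoch is
    centred on the bout midpoint, and the last epoch ends 5 s before the
    bout ends.  Epoch boundaries snap to the nearest sample index.
    """
    dur = spec.duration_s
    if bout.duration_s < 10.0 + dur:
        raise BoutTooShortError(
            f"bout of {bout.duration_s:.1f}s cannot hold a {dur:.2f}s epoch "
            "with 5 s margins"
        )
    starts = (
        bout.start_s + 5.0,
        bout.midpoint_s - dur / 2.0,
        bout.end_s - 5.0 - dur,
    )
    return tuple(_epoch_mad_at(recording, s, spec) for s in starts)


def minute_mad_series(mads: MadSeries, session_duration_s: float) -> np.ndarray:
    """Average epoch MADs into minute bins by epoch start time.

    Returns one value per whole-or-partial minute of the session; minutes
    containing no epoch start are NaN (missing).
    """
    if len(mads) == 0:
        raise ValueError("empty MAD series")
    n_minutes = int(math.ceil(session_duration_s / 60.0))
    minute_idx = np.floor(mads.epoch_start_times_s / 60.0).astype(int)
    out = np.full(n_minutes, np.nan)
    for m in range(n_minutes):
        sel = minute_idx == m
        if sel.any():
            out[m] = mads.mad_mg[sel].mean()
    return out
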