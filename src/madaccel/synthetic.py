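"""Synthetic two-device accelerometry sessions emulating a lab protocol.

The generator emulates a supervised protocol of ten 2-min activities —
five sedentary postures, slow and normal walking, brisk walking, jogging
and running — separated by 15 s transitions, recorded simultaneously by
two hip-worn virtual devices:

* a wide-range device sampling at 100 Hz with a ±16 000 mg axis range, and
* a narrow-range device sampling at 30 Hz with a ±3000 mg axis range.

A master body-acceleration process is synthesised at 400 Hz (≥4× the
fastest device) and each device observes it by nearest-sample decimation,
adds its own sensor noise, and saturates each axis at its dynamic range.
Per bout the tri-axial specific force is gravity (1000 mg on the
vertical axis) plus a gait component and white postural tremor.  Walking
gaits are a sinusoid at the step frequency along a fixed, mostly
vertical body direction.  Jogging and running alternate between a flight
phase (near free fall, resultant ≈ 0) and a ground-contact impact along
a near-vertical direction, so vertical-axis peaks exceed 3000 mg at
running amplitudes while the mean amplitude deviation stays high.

Clipping at ±3000 mg is the mechanism by which the narrow-range device
under-reads the most vigorous activities, so paired MAD values diverge
only at high accelerations; at low accelerations the devices agree up to
resampling and noise.

Heart rate is approximately linear in the bout's true MAD with a
per-subject intercept, plus an optional "excitement" elevation on
sedentary bouts reproducing the observation that measurement-related
arousal can push sedentary heart rate above light-activity heart rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.special import expit

from .signal_core import ACTIVITY_CLASS, ActivityBout, RawRecording, compute_mad

__all__ = [
    "DEFAULT_ACTIVITY_MODELS",
    "DEFAULT_DEVICES",
    "ActivityModel",
    "DeviceProfile",
    "HeartRateModel",
    "HeartRateObservation",
    "SessionDataset",
    "SubjectEffects",
    "default_heart_rate_model",
    "expected_resultant_mad",
    "generate_cohort",
    "generate_heart_rate",
    "generate_session",
    "simulate_ordinal_mad",
]

MASTER_RATE_HZ = 400.0
BOUT_DURATION_S = 120.0
TRANSITION_S = 15.0
GRAVITY_MG = 1000.0
#: Tremor noise (mg, per axis) during transitions between activities.
TRANSITION_TREMOR_SD_MG = 1.0


@dataclass(frozen=True)
class DeviceProfile:
    """Virtual accelerometer: rate, symmetric range and sensor noise."""

    device_id: str
    sampling_rate_hz: float
    dynamic_range_mg: float
    noise_sd_mg: float = 1.5

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0 or self.dynamic_range_mg <= 0:
            raise ValueError("rate and dynamic range must be positive")
        if self.noise_sd_mg < 0:
            raise ValueError("noise_sd_mg must be non-negative")


DEFAULT_DEVICES = (
    DeviceProfile("wide_100hz", 100.0, 16000.0, 1.5),
    DeviceProfile("narrow_30hz", 30.0, 3000.0, 1.5),
)


@dataclass(frozen=True)
class ActivityModel:
    """Signal and heart-rate parameters for one protocol activity.

    ``resultant_amplitude_mg`` is the peak amplitude of the fundamental
    gait sinusoid on the vertical axis; sedentary postures have amplitude
    0 and move only through postural tremor (``tremor_sd_mg``).  The MAD
    of a pure sinusoid of amplitude A is 2A/π, which anchors the default
    amplitudes to the MAD levels each activity should produce.
    """

    label: str
    intensity_class: int
    resultant_amplitude_mg: float
    step_frequency_hz: float
    tremor_sd_mg: float
    hr_mean_bpm: float
    hr_sd_bpm: float

    def __post_init__(self) -> None:
        if self.label not in ACTIVITY_CLASS:
            raise ValueError(f"unknown activity label {self.label!r}")
        if self.intensity_class != ACTIVITY_CLASS[self.label]:
            raise ValueError("intensity_class conflicts with the pattern map")
        if self.intensity_class == 0 and self.resultant_amplitude_mg > 25:
            raise ValueError("sedentary activities allow only postural noise")
        if min(self.resultant_amplitude_mg, self.step_frequency_hz,
               self.tremor_sd_mg, self.hr_sd_bpm) < 0:
            raise ValueError("amplitudes, frequencies and SDs must be >= 0")


# Fixed body directions of the gait component (unit vectors): walking
# oscillation and ground-contact impact both load mostly the vertical
# (z) axis with smaller antero-posterior / medio-lateral shares.
_U_WALK = np.array([0.6, 0.25, 0.76])
_U_WALK = _U_WALK / np.linalg.norm(_U_WALK)
_U_IMPACT = np.array([0.45, 0.2, 0.87])
_U_IMPACT = _U_IMPACT / np.linalg.norm(_U_IMPACT)
#: Residual resultant during the flight phase of jogging/running (mg);
#: a body in flight is nearly in free fall, so the sensed specific force
#: is close to zero.
FLIGHT_RESIDUAL_MG = 100.0

# Amplitudes (mg) are solved numerically on the noiseless waveform so the
# unclipped 100 Hz epoch MAD hits each activity's target: 75 (slow walk),
# 150 (normal), 450 (brisk), 1050 (jogging) and 1600 mg (running); the
# closed form 2A/π only holds for a small vertical sinusoid.  Class-wise
# MAD distributions then span roughly 2-20 mg (sedentary), 40-200
# (light), 350-550 (moderate) and 650-1800 (vigorous), matching lying
# supine near 3 mg and running near 1600 mg.  Heart-rate means follow the
# protocol's observed values (92/99/118/155/180 bpm from slow walking to
# running).
DEFAULT_ACTIVITY_MODELS = (
    ActivityModel("lying_supine", 0, 0.0, 0.0, 3.6, 72.0, 8.0),
    ActivityModel("sitting", 0, 0.0, 0.0, 6.0, 76.0, 8.0),
    ActivityModel("sitting_computer", 0, 0.0, 0.0, 10.0, 78.0, 8.0),
    ActivityModel("standing", 0, 0.0, 0.0, 8.0, 80.0, 8.0),
    ActivityModel("standing_handweights", 0, 0.0, 0.0, 18.0, 84.0, 8.0),
    ActivityModel("slow_walk", 1, 156.0, 1.4, 5.0, 92.0, 8.0),
    ActivityModel("normal_walk", 1, 314.0, 1.8, 5.0, 99.0, 12.0),
    ActivityModel("brisk_walk", 2, 1108.0, 2.2, 8.0, 118.0, 15.0),
    ActivityModel("jogging", 3, 2580.0, 2.6, 10.0, 155.0, 19.0),
    ActivityModel("running", 3, 3882.0, 3.0, 12.0, 180.0, 13.0),
)


@dataclass(frozen=True)
class SubjectEffects:
    """Per-participant random effects applied to every bout."""

    pace_multiplier: float = 1.0
    hr_intercept_bpm: float = 0.0


@dataclass(frozen=True)
class HeartRateModel:
    """Linear map from true bout MAD (mg) to expected heart rate (bpm)."""

    intercept_bpm: float
    slope_bpm_per_mg: float
    sedentary_excitement_bpm: float = 10.0

    def predict(self, mad_mg: float) -> float:
        return self.intercept_bpm + self.slope_bpm_per_mg * mad_mg


@dataclass(frozen=True)
class HeartRateObservation:
    """Heart rate at bout start, 1 min into the bout, and at its end."""

    bout_label: str
    hr_start_bpm: float
    hr_1min_bpm: float
    hr_2min_bpm: float

    def __post_init__(self) -> None:
        for v in (self.hr_start_bpm, self.hr_1min_bpm, self.hr_2min_bpm):
            if not 30.0 <= v <= 250.0:
                raise ValueError(f"heart rate {v:.1f} bpm outside 30-250 bpm")


@dataclass(frozen=True)
class SessionDataset:
    """One participant's protocol session on all devices."""

    participant_id: str
    recordings: dict[str, RawRecording]
    bouts: tuple[ActivityBout, ...]
    heart_rate: tuple[HeartRateObservation, ...]
    effects: SubjectEffects = field(default_factory=SubjectEffects)

    @property
    def duration_s(self) -> float:
        return self.bouts[-1].end_s


def _gait_signal(theta: np.ndarray, amplitude: float, vigorous: bool) -> np.ndarray:
    """Noise-free tri-axial specific force (incl. gravity) over phase ``theta``.

    Walking is a sinusoid of the given amplitude along the fixed body
    direction :data:`_U_WALK`, superposed on gravity.  Vigorous gait
    alternates between near free fall (resultant ≈ ``FLIGHT_RESIDUAL_MG``)
    and a ground-contact impact of the given magnitude along
    :data:`_U_IMPACT`, blended by a smoothed square-wave contact envelope.
    """
    if vigorous:
        contact = 0.5 * (1.0 + np.tanh(3.0 * np.sin(theta)))
        sig = np.outer(contact * amplitude, _U_IMPACT)
        sig[:, 2] += (1.0 - contact) * FLIGHT_RESIDUAL_MG
        return sig
    sig = np.outer(amplitude * np.sin(theta), _U_WALK)
    sig[:, 2] += GRAVITY_MG
    return sig


@lru_cache(maxsize=64)
def _expected_mad_cached(amplitude: float, step_hz: float, tremor: float,
                         vigorous: bool) -> float:
    if amplitude == 0.0 or step_hz == 0.0:
        # motionless posture: resultant ≈ gravity + vertical tremor; the
        # mean absolute deviation of N(0, σ) is σ·sqrt(2/π)
        return tremor * math.sqrt(2.0 / math.pi)
    # noiseless waveform over an integer number of periods
    n_per = max(8, int(round(8 * step_hz)))
    t = np.arange(int(round(n_per / step_hz * MASTER_RATE_HZ))) / MASTER_RATE_HZ
    theta = 2 * math.pi * step_hz * t
    sig = _gait_signal(theta, amplitude, vigorous)
    r = np.sqrt(np.einsum("ij,ij->i", sig, sig))
    return compute_mad(r)


def expected_resultant_mad(model: ActivityModel, pace_multiplier: float = 1.0) -> float:
    """Noise-free MAD (mg) the activity produces on an unclipped device."""
    return _expected_mad_cached(
        model.resultant_amplitude_mg * pace_multiplier,
        model.step_frequency_hz,
        model.tremor_sd_mg,
        model.intensity_class == 3,
    )


@lru_cache(maxsize=1)
def default_heart_rate_model() -> HeartRateModel:
    """Heart-rate line anchored at slow walking (92 bpm) and running (180 bpm)."""
    by_label = {m.label: m for m in DEFAULT_ACTIVITY_MODELS}
    mad_slow = expected_resultant_mad(by_label["slow_walk"])
    mad_run = expected_resultant_mad(by_label["running"])
    slope = (180.0 - 92.0) / (mad_run - mad_slow)
    return HeartRateModel(92.0 - slope * mad_slow, slope)


def _default_schedule(n_bouts: int) -> list[tuple[float, float]]:
    starts = [i * (BOUT_DURATION_S + TRANSITION_S) for i in range(n_bouts)]
    return [(s, s + BOUT_DURATION_S) for s in starts]


def generate_heart_rate(
    model: ActivityModel,
    subject: SubjectEffects,
    mad_true: float,
    rng: np.random.Generator,
    hr_model: HeartRateModel | None = None,
) -> HeartRateObservation:
    """Draw the three per-bout heart-rate readings.

    The 1-min and 2-min readings scatter about the linear MAD→HR
    prediction plus the subject intercept; sedentary bouts receive the
    model's excitement elevation.  The start reading sits slightly below
    the steady-state level (heart rate still adapting).  All readings are
    clamped to the physiologic 30-250 bpm range.
    """
    hr_model = hr_model or default_heart_rate_model()
    pred = hr_model.predict(mad_true) + subject.hr_intercept_bpm
    if model.intensity_class == 0:
        pred += hr_model.sedentary_excitement_bpm

    def draw(offset: float) -> float:
        v = pred + offset + rng.normal(0.0, model.hr_sd_bpm)
        return float(np.clip(v, 30.0, 250.0))

    return HeartRateObservation(model.label, draw(-8.0), draw(0.0), draw(0.0))


def generate_session(
    participant_id: str,
    activity_models: tuple[ActivityModel, ...] = DEFAULT_ACTIVITY_MODELS,
    device_profiles: tuple[DeviceProfile, ...] = DEFAULT_DEVICES,
    subject_effects: SubjectEffects = SubjectEffects(),
    seed: int | np.random.SeedSequence | None = None,
    hr_model: HeartRateModel | None = None,
) -> SessionDataset:
    """Synthesise one participant's session on every device.

    A seed is mandatory: the generator is a pure function of its
    configuration and seed, and refuses to produce irreproducible data.
    """
    if seed is None:
        raise ValueError("generate_session requires an explicit seed")
    if len(device_profiles) < 1:
        raise ValueError("at least one device profile is required")
    rng = np.random.default_rng(seed)

    schedule = _default_schedule(len(activity_models))
    total_s = schedule[-1][1]
    n_master = int(round(total_s * MASTER_RATE_HZ))
    t = np.arange(n_master) / MASTER_RATE_HZ

    sig = np.zeros((n_master, 3))
    sig[:, 2] = GRAVITY_MG
    tremor_sd = np.full(n_master, TRANSITION_TREMOR_SD_MG)

    bouts: list[ActivityBout] = []
    hr_obs: list[HeartRateObservation] = []
    for model, (start, end) in zip(activity_models, schedule):
        i0 = int(round(start * MASTER_RATE_HZ))
        i1 = int(round(end * MASTER_RATE_HZ))
        amp = model.resultant_amplitude_mg * subject_effects.pace_multiplier
        if amp > 0 and model.step_frequency_hz > 0:
            phase = rng.uniform(0.0, 2.0 * math.pi)
            theta = 2 * math.pi * model.step_frequency_hz * t[i0:i1] + phase
            sig[i0:i1] = _gait_signal(theta, amp, model.intensity_class == 3)
        tremor_sd[i0:i1] = model.tremor_sd_mg

        bouts.append(ActivityBout(model.label, start_s=start, end_s=end))
        mad_true = expected_resultant_mad(model, subject_effects.pace_multiplier)
        hr_obs.append(
            generate_heart_rate(model, subject_effects, mad_true, rng, hr_model)
        )

    sig += rng.standard_normal((n_master, 3)) * tremor_sd[:, None]

    recordings: dict[str, RawRecording] = {}
    for dev in device_profiles:
        n_dev = int(math.floor((n_master - 1) / MASTER_RATE_HZ * dev.sampling_rate_hz)) + 1
        idx = np.round(
            np.arange(n_dev) / dev.sampling_rate_hz * MASTER_RATE_HZ
        ).astype(int)
        observed = sig[np.minimum(idx, n_master - 1)].copy()
        if dev.noise_sd_mg > 0:
            observed += rng.standard_normal(observed.shape) * dev.noise_sd_mg
        np.clip(observed, -dev.dynamic_range_mg, dev.dynamic_range_mg, out=observed)
        recordings[dev.device_id] = RawRecording(
            device_id=dev.device_id,
            sampling_rate_hz=dev.sampling_rate_hz,
            dynamic_range_mg=dev.dynamic_range_mg,
            samples=observed,
            start_time_s=0.0,
        )

    return SessionDataset(
        participant_id=participant_id,
        recordings=recordings,
        bouts=tuple(bouts),
        heart_rate=tuple(hr_obs),
        effects=subject_effects,
    )


def generate_cohort(
    n_participants: int = 20,
    seed: int | None = None,
    activity_models: tuple[ActivityModel, ...] = DEFAULT_ACTIVITY_MODELS,
    device_profiles: tuple[DeviceProfile, ...] = DEFAULT_DEVICES,
    pace_sd: float = 0.10,
    hr_intercept_sd_bpm: float = 6.0,
    hr_model: HeartRateModel | None = None,
) -> list[SessionDataset]:
    """Generate a cohort of sessions with per-participant random effects.

    Each participant receives a log-normal pace multiplier (scaling all
    movement amplitudes) and a normal heart-rate intercept; child seeds
    derive deterministically from the master seed.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if seed is None:
        raise ValueError("generate_cohort requires an explicit seed")
    master = np.random.SeedSequence(seed)
    sessions = []
    for i, child in enumerate(master.spawn(n_participants)):
        eff_rng = np.random.default_rng(child)
        effects = SubjectEffects(
            pace_multiplier=float(np.exp(eff_rng.normal(0.0, pace_sd))),
            hr_intercept_bpm=float(eff_rng.normal(0.0, hr_intercept_sd_bpm)),
        )
        sessions.append(
            generate_session(
                participant_id=f"P{i + 1:02d}",
                activity_models=activity_models,
                device_profiles=device_profiles,
                subject_effects=effects,
                seed=child.spawn(1)[0],
                hr_model=hr_model,
            )
        )
    return sessions


def simulate_ordinal_mad(
    boundaries: tuple[float, float, float] = (100.0, 400.0, 800.0),
    slopes: tuple[float, float, float] = (0.08, 0.03, 0.02),
    n_subjects: int = 20,
    n_per_subject: int = 30,
    subject_sd: float = 0.5,
    mad_range: tuple[float, float] = (5.0, 2000.0),
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (MAD, ordinal class, subject) triples from a known cumulative model.

    Classes follow cumulative logits P(class ≥ k | MAD) = expit(slope_k ·
    (MAD − B_k) + u_j) with a shared per-subject intercept u_j ~ N(0,
    subject_sd) inducing exchangeable within-subject correlation.  Because
    expit is symmetric, the marginal 0.5-probability crossing of each
    cumulative curve stays exactly at B_k, so the boundaries are the
    ground truth a cut-point fit should recover.

    MAD values are log-uniform over ``mad_range`` so all four classes are
    well represented.  Returns arrays (mad_mg, classes, subject_ids).
    """
    if seed is None:
        raise ValueError("simulate_ordinal_mad requires an explicit seed")
    if not boundaries[0] < boundaries[1] < boundaries[2]:
        raise ValueError("boundaries must be strictly increasing")
    rng = np.random.default_rng(seed)
    n = n_subjects * n_per_subject
    subj = np.repeat(np.arange(n_subjects), n_per_subject)
    u = np.repeat(rng.normal(0.0, subject_sd, n_subjects), n_per_subject)
    lo, hi = mad_range
    mad = np.exp(rng.uniform(math.log(lo), math.log(hi), n))
    p = np.column_stack(
        [expit(s * (mad - b) + u) for s, b in zip(slopes, boundaries)]
    )
    # guard against tiny ordering violations far in the tails
    p = np.minimum.accumulate(p, axis=1)
    udraw = rng.uniform(size=n)
    classes = (udraw[:, None] < p).sum(axis=1)
    return mad, classes.astype(int), subj
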