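"""Tests of the synthetic protocol generator's contracts and calibration."""

import numpy as np
import pytest

from madaccel.pipeline import extract_bout_mads
from madaccel.signal_core import EpochSpec, segment_epochs
from madaccel.synthetic import (
    DEFAULT_ACTIVITY_MODELS,
    DEFAULT_DEVICES,
    ActivityModel,
    DeviceProfile,
    HeartRateModel,
    SubjectEffects,
    default_heart_rate_model,
    expected_resultant_mad,
    generate_cohort,
    generate_heart_rate,
    generate_session,
    simulate_ordinal_mad,
)

MODELS = {m.label: m for m in DEFAULT_ACTIVITY_MODELS}


def test_seed_is_mandatory():
    with pytest.raises(ValueError):
        generate_session("P01")
    with pytest.raises(ValueError):
        generate_cohort(2)
    with pytest.raises(ValueError):
        simulate_ordinal_mad()


def test_same_seed_bit_identical():
    a = generate_session("P01", seed=11)
    b = generate_session("P01", seed=11)
    for dev in a.recordings:
        np.testing.assert_array_equal(
            a.recordings[dev].samples, b.recordings[dev].samples
        )
    assert a.heart_rate == b.heart_rate


def test_cohort_shape_and_determinism(default_cohort):
    assert len(default_cohort) == 20
    assert sum(len(s.bouts) for s in default_cohort) == 200
    single = generate_cohort(1, seed=3)
    assert len(single[0].bouts) == 10
    again = generate_cohort(1, seed=3)
    np.testing.assert_array_equal(
        single[0].recordings["wide_100hz"].samples,
        again[0].recordings["wide_100hz"].samples,
    )


def test_dynamic_range_respected(default_cohort):
    for session in default_cohort[:3]:
        for dev in DEFAULT_DEVICES:
            samples = session.recordings[dev.device_id].samples
            assert np.abs(samples).max() <= dev.dynamic_range_mg


def test_sedentary_noiseless_gives_zero_mad():
    models = tuple(
        ActivityModel(m.label, 0, 0.0, 0.0, 0.0, m.hr_mean_bpm, 0.0)
        for m in DEFAULT_ACTIVITY_MODELS
        if m.intensity_class == 0
    )
    devices = tuple(
        DeviceProfile(d.device_id, d.sampling_rate_hz, d.dynamic_range_mg, 0.0)
        for d in DEFAULT_DEVICES
    )
    import madaccel.synthetic as syn

    old = syn.TRANSITION_TREMOR_SD_MG
    syn.TRANSITION_TREMOR_SD_MG = 0.0
    try:
        session = generate_session(
            "P01", activity_models=models, device_profiles=devices, seed=5
        )
    finally:
        syn.TRANSITION_TREMOR_SD_MG = old
    for rec in session.recordings.values():
        spec = EpochSpec(512 if rec.sampling_rate_hz == 100 else 128,
                         rec.sampling_rate_hz)
        assert np.allclose(segment_epochs(rec, spec).mad_mg, 0.0, atol=1e-9)


def test_clipping_reduces_running_mad_at_equal_rate():
    # same 100 Hz sampling, zero noise: the only difference between the
    # devices is the ±3000 mg saturation, which strictly shrinks the
    # running epochs' amplitude deviations and leaves walking untouched
    devices = (
        DeviceProfile("wide", 100.0, 16000.0, 0.0),
        DeviceProfile("narrow", 100.0, 3000.0, 0.0),
    )
    session = generate_session("P01", device_profiles=devices, seed=21)
    table = extract_bout_mads([session])
    run = table[table["label"] == "running"]
    wide = run[run["device"] == "wide"]["mad_mg"].to_numpy()
    narrow = run[run["device"] == "narrow"]["mad_mg"].to_numpy()
    assert np.all(wide > narrow)
    walk = table[table["label"] == "slow_walk"]
    np.testing.assert_allclose(
        walk[walk["device"] == "wide"]["mad_mg"].to_numpy(),
        walk[walk["device"] == "narrow"]["mad_mg"].to_numpy(),
        rtol=1e-9,
    )


def test_devices_agree_on_steady_unclipped_bout():
    # full sinusoid periods in both epoch lengths (5.12 s and 4.267 s):
    # f = 150/128 Hz; no tremor, no device noise, no clipping
    model = ActivityModel("slow_walk", 1, 300.0, 150.0 / 128.0, 0.0, 92.0, 0.0)
    devices = tuple(
        DeviceProfile(d.device_id, d.sampling_rate_hz, d.dynamic_range_mg, 0.0)
        for d in DEFAULT_DEVICES
    )
    session = generate_session(
        "P01", activity_models=(model,), device_profiles=devices, seed=9
    )
    table = extract_bout_mads([session])
    wide = table[table["device"] == "wide_100hz"]["mad_mg"].to_numpy()
    narrow = table[table["device"] == "narrow_30hz"]["mad_mg"].to_numpy()
    np.testing.assert_allclose(wide, narrow, rtol=0.02)


def test_default_calibration_anchors(default_cohort):
    """Lying-supine MAD ≈ 3 mg and running ≈ 1600 mg within a factor of 2."""
    table = extract_bout_mads(default_cohort)
    wide = table[table["device"] == "wide_100hz"]
    lying = wide[wide["label"] == "lying_supine"]["mad_mg"].mean()
    running = wide[wide["label"] == "running"]["mad_mg"].mean()
    assert 1.5 <= lying <= 6.0
    assert 800.0 <= running <= 3200.0


def test_expected_mad_matches_generated(default_cohort):
    table = extract_bout_mads(default_cohort[:1])
    session = default_cohort[0]
    wide = table[table["device"] == "wide_100hz"]
    for label in ("slow_walk", "brisk_walk", "running"):
        measured = wide[wide["label"] == label]["mad_mg"].mean()
        predicted = expected_resultant_mad(
            MODELS[label], session.effects.pace_multiplier
        )
        assert measured == pytest.approx(predicted, rel=0.10)


class TestHeartRate:
    def test_linear_map_interpolation(self, rng):
        # zero noise, zero effects: mad 800 on a 70→180 bpm line over
        # 0→1600 mg lands exactly at 125 bpm
        model = ActivityModel("normal_walk", 1, 300.0, 1.8, 0.0, 99.0, 0.0)
        hr_model = HeartRateModel(70.0, 110.0 / 1600.0, 0.0)
        obs = generate_heart_rate(model, SubjectEffects(), 800.0, rng, hr_model)
        assert obs.hr_1min_bpm == pytest.approx(125.0)
        assert obs.hr_2min_bpm == pytest.approx(125.0)

    def test_excitement_elevates_sedentary_above_slow_walk(self, rng):
        hr_model = HeartRateModel(70.0, 110.0 / 1600.0, 30.0)
        lying = ActivityModel("lying_supine", 0, 0.0, 0.0, 0.0, 72.0, 0.0)
        slow = ActivityModel("slow_walk", 1, 156.0, 1.4, 0.0, 92.0, 0.0)
        hr_lying = generate_heart_rate(lying, SubjectEffects(), 3.0, rng, hr_model)
        hr_slow = generate_heart_rate(slow, SubjectEffects(), 75.0, rng, hr_model)
        assert hr_lying.hr_1min_bpm > hr_slow.hr_1min_bpm

    def test_reproducible_given_seed(self):
        model = MODELS["jogging"]
        a = generate_heart_rate(
            model, SubjectEffects(), 1050.0, np.random.default_rng(4)
        )
        b = generate_heart_rate(
            model, SubjectEffects(), 1050.0, np.random.default_rng(4)
        )
        assert a == b

    def test_default_model_hits_anchor_means(self):
        hr = default_heart_rate_model()
        assert hr.predict(expected_resultant_mad(MODELS["slow_walk"])) == (
            pytest.approx(92.0, abs=0.5)
        )
        assert hr.predict(expected_resultant_mad(MODELS["running"])) == (
            pytest.approx(180.0, abs=0.5)
        )


def test_ordinal_simulator_contracts():
    mad, classes, subj = simulate_ordinal_mad(seed=77)
    assert mad.shape == classes.shape == subj.shape == (600,)
    assert set(np.unique(classes)) == {0, 1, 2, 3}
    assert np.unique(subj).size == 20
    mad2, classes2, _ = simulate_ordinal_mad(seed=77)
    np.testing.assert_array_equal(mad, mad2)
    np.testing.assert_array_equal(classes, classes2)
    # higher MAD must raise the average class
    order = np.argsort(mad)
    lo = classes[order[:200]].mean()
    hi = classes[order[-200:]].mean()
    assert hi > lo + 1.0
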