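"""Unit and property tests for resultant, epoch and MAD computation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from madaccel.signal_core import (
    ActivityBout,
    BoutTooShortError,
    EpochSpec,
    InsufficientDataError,
    InvalidSampleError,
    MadSeries,
    RawRecording,
    bout_three_epoch_mads,
    choose_epoch_spec,
    compute_mad,
    minute_mad_series,
    resultant,
    segment_epochs,
)


def mad_loop_oracle(r):
    """Scalar-loop reference implementation of the MAD formula."""
    mean = sum(r) / len(r)
    return sum(abs(v - mean) for v in r) / len(r)


def make_recording(samples, rate=100.0, rng_mg=16000.0, start=0.0):
    return RawRecording("dev", rate, rng_mg, np.asarray(samples, float), start)


class TestResultant:
    @pytest.mark.parametrize(
        "sample, expected",
        [
            ((3.0, 4.0, 0.0), 5.0),
            ((0.0, 0.0, -1000.0), 1000.0),
            ((1.0, 1.0, 1.0), math.sqrt(3.0)),
        ],
    )
    def test_known_values(self, sample, expected):
        assert resultant(sample) == pytest.approx(expected, rel=1e-12)

    def test_vectorized_matches_per_sample(self, rng):
        arr = rng.normal(size=(50, 3)) * 1000
        vec = resultant(arr)
        for row, v in zip(arr, vec):
            assert v == pytest.approx(resultant(row), rel=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(InvalidSampleError):
            resultant((np.nan, 0.0, 0.0))
        with pytest.raises(InvalidSampleError):
            resultant((np.inf, 0.0, 0.0))


class TestChooseEpochSpec:
    @pytest.mark.parametrize(
        "rate, target, expected_n",
        [
            (100.0, 5.0, 512),
            (30.0, 5.0, 128),
            (1.0, 4.0, 4),
            # 96 samples is equidistant from 64 and 128: tie goes down
            (1.0, 96.0, 64),
        ],
    )
    def test_power_of_two_rule(self, rate, target, expected_n):
        spec = choose_epoch_spec(rate, target)
        assert spec.n_samples == expected_n
        assert spec.duration_s == expected_n / rate

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            choose_epoch_spec(0.0, 5.0)
        with pytest.raises(ValueError):
            choose_epoch_spec(100.0, -1.0)

    def test_epoch_spec_requires_power_of_two(self):
        with pytest.raises(ValueError):
            EpochSpec(100, 100.0)


class TestComputeMad:
    def test_constant_epoch_is_zero(self):
        assert compute_mad(np.full(64, 1000.0)) == 0.0

    def test_hand_example(self):
        # mean 2.5, deviations 1.5, 0.5, 0.5, 1.5
        assert compute_mad(np.array([1.0, 2.0, 3.0, 4.0])) == pytest.approx(1.0)

    def test_sinusoid_closed_form(self):
        # MAD of c + A sin(wt) over whole periods tends to 2A/pi
        t = np.arange(4000) / 1000.0  # 8 full periods at 2 Hz
        r = 1000.0 + 100.0 * np.sin(2 * np.pi * 2.0 * t)
        assert compute_mad(r) == pytest.approx(200.0 / np.pi, abs=0.5)

    def test_matches_loop_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 65))
            r = rng.uniform(0.0, 2000.0, n)
            assert compute_mad(r) == pytest.approx(
                mad_loop_oracle(list(r)), rel=1e-9
            )

    def test_empty_epoch_rejected(self):
        with pytest.raises(ValueError):
            compute_mad(np.array([]))


@settings(deadline=None, max_examples=50)
@given(
    r=st.lists(st.floats(0.0, 5000.0), min_size=2, max_size=64),
    shift=st.floats(0.0, 1000.0),
    scale=st.floats(0.01, 100.0),
)
def test_mad_shift_invariance_and_scale_equivariance(r, shift, scale):
    r = np.asarray(r)
    base = compute_mad(r)
    assert base >= 0.0
    assert compute_mad(r + shift) == pytest.approx(base, abs=1e-6)
    assert compute_mad(r * scale) == pytest.approx(base * scale, rel=1e-9, abs=1e-9)


class TestSegmentEpochs:
    def test_exact_division(self, rng):
        rec = make_recording(rng.uniform(-100, 100, (1024, 3)))
        assert len(segment_epochs(rec, EpochSpec(512, 100.0))) == 2

    def test_remainder_dropped(self, rng):
        rec = make_recording(rng.uniform(-100, 100, (1023, 3)))
        assert len(segment_epochs(rec, EpochSpec(512, 100.0))) == 1

    def test_too_short_rejected(self, rng):
        rec = make_recording(rng.uniform(-100, 100, (100, 3)))
        with pytest.raises(InsufficientDataError):
            segment_epochs(rec, EpochSpec(512, 100.0))

    def test_static_posture_gives_zero_mad(self):
        # fixed orientation with |v| = 1000 mg: gravity cancels through
        # the epoch mean, MAD is exactly 0
        v = np.array([600.0, 0.0, 800.0])
        rec = make_recording(np.tile(v, (2048, 1)))
        series = segment_epochs(rec, EpochSpec(512, 100.0))
        assert np.all(series.mad_mg == 0.0)

    def test_epoch_start_times(self):
        rec = make_recording(np.zeros((1024, 3)) + [0, 0, 1000.0], start=10.0)
        series = segment_epochs(rec, EpochSpec(512, 100.0))
        np.testing.assert_allclose(series.epoch_start_times_s, [10.0, 15.12])


class TestBoutThreeEpochs:
    SPEC = EpochSpec(512, 100.0)

    def _bout_recording(self, signal_fn, duration=120.0, rate=100.0):
        t = np.arange(int(duration * rate)) / rate
        r = signal_fn(t)
        samples = np.column_stack([np.zeros_like(r), np.zeros_like(r), r])
        return make_recording(samples, rate=rate)

    def test_constant_bout(self):
        rec = self._bout_recording(lambda t: np.full_like(t, 1000.0))
        bout = ActivityBout("standing", start_s=0.0, end_s=120.0)
        assert bout_three_epoch_mads(rec, bout, self.SPEC) == (0.0, 0.0, 0.0)

    def test_stationary_sinusoid_all_three_equal(self):
        # full periods inside each 5.12 s epoch: f = 1.171875 Hz
        f, amp = 150.0 / 128.0, 200.0
        rec = self._bout_recording(
            lambda t: 1000.0 + amp * np.sin(2 * np.pi * f * t)
        )
        bout = ActivityBout("slow_walk", start_s=0.0, end_s=120.0)
        mads = bout_three_epoch_mads(rec, bout, self.SPEC)
        for m in mads:
            assert m == pytest.approx(2 * amp / np.pi, rel=0.01)

    def test_piecewise_amplitude_step(self):
        # amplitude A in the first half, 2A in the second: the first and
        # last epochs see pure sinusoids, checked against a loop oracle
        f, amp = 150.0 / 128.0, 100.0

        def signal(t):
            a = np.where(t < 60.0, amp, 2 * amp)
            return 1000.0 + a * np.sin(2 * np.pi * f * t)

        rec = self._bout_recording(signal)
        bout = ActivityBout("slow_walk", start_s=0.0, end_s=120.0)
        first, middle, last = bout_three_epoch_mads(rec, bout, self.SPEC)
        assert first == pytest.approx(2 * amp / np.pi, rel=0.01)
        assert last == pytest.approx(4 * amp / np.pi, rel=0.01)
        # oracle for the middle epoch straddling the step
        r = rec.samples[:, 2]
        i0 = int(round((60.0 - self.SPEC.duration_s / 2) * 100))
        expected_mid = compute_mad(r[i0 : i0 + 512])
        assert middle == pytest.approx(expected_mid, rel=1e-12)

    def test_bout_too_short(self):
        rec = self._bout_recording(lambda t: np.full_like(t, 1000.0))
        bout = ActivityBout("standing", start_s=0.0, end_s=14.0)
        with pytest.raises(BoutTooShortError):
            bout_three_epoch_mads(rec, bout, self.SPEC)


class TestMinuteSeries:
    def test_constant_series(self):
        mads = MadSeries(np.arange(0, 300, 5.0), np.full(60, 42.0))
        out = minute_mad_series(mads, 300.0)
        np.testing.assert_allclose(out, 42.0)

    def test_mean_within_minute_and_missing(self):
        mads = MadSeries(np.array([0.0, 30.0, 130.0]), np.array([10.0, 20.0, 7.0]))
        out = minute_mad_series(mads, 180.0)
        assert out[0] == pytest.approx(15.0)
        assert np.isnan(out[1])
        assert out[2] == pytest.approx(7.0)

    def test_one_epoch_per_minute(self):
        mads = MadSeries(np.array([0.0, 60.0, 120.0]), np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(minute_mad_series(mads, 180.0), [1, 2, 3])


class TestValidation:
    def test_recording_range_enforced(self):
        with pytest.raises(ValueError):
            make_recording([[0, 0, 4000.0]], rng_mg=3000.0)

    def test_bout_label_and_class_map(self):
        bout = ActivityBout("jogging", start_s=0.0, end_s=120.0)
        assert bout.intensity_class == 3
        with pytest.raises(ValueError):
            ActivityBout("jogging", start_s=0.0, end_s=120.0, intensity_class=1)
        with pytest.raises(ValueError):
            ActivityBout("moonwalk", start_s=0.0, end_s=120.0)
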