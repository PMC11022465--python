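"""Walk-test feature extraction: preprocessing, events, four families."""

import numpy as np
import pytest

from strollpipe.errors import (
    InsufficientGaitError,
    TooShortError,
    UndefinedFeatureError,
)
from strollpipe.features import (
    FEATURE_REGISTRY,
    GaitEventSeries,
    compute_asymmetry,
    compute_complexity,
    compute_frequency,
    compute_spatiotemporal,
    detect_gait_events,
    extract_features,
    preprocess,
    sample_entropy,
    symmetry_index,
)
from strollpipe.recording import GRAVITY, RawImuRecording, SensorStream
from strollpipe.synthetic import GaitTruth, generate_2mwt_signals


def _stream(placement, t, acc, gyr, rate):
    return SensorStream(placement=placement, t=t, acc=acc, gyr=gyr, rate=rate)


def _synthetic_events(stride=1.0, n=20, offset=1.0):
    """Idealized alternating events for direct family-level tests."""
    r_ic = offset + stride * np.arange(n)
    l_ic = r_ic[:-1] + 0.5 * stride
    feet = {}
    for name, ic in (("left_foot", l_ic), ("right_foot", r_ic)):
        fc = ic - 0.4 * stride
        feet[name] = {"ic": ic, "fc": fc}
    return GaitEventSeries(feet=feet)


class TestPreprocess:
    def test_identity_on_uniform_100hz(self):
        t = np.arange(500) / 100.0
        acc = np.column_stack([np.sin(t), np.cos(t), GRAVITY + 0 * t])
        gyr = np.zeros((500, 3))
        rec = RawImuRecording({"low_back": _stream("low_back", t, acc, gyr, 100.0)})
        out = preprocess(rec)
        assert np.allclose(out["low_back"].acc, acc, atol=1e-9)
        assert np.allclose(out["low_back"].gyr, 0.0, atol=1e-9)

    def test_constant_gyro_bias_removed_when_stationary(self):
        t = np.arange(400) / 100.0
        acc = np.tile([0, 0, GRAVITY], (400, 1)).astype(float)
        gyr = np.tile([0.05, -0.02, 0.01], (400, 1))
        rec = RawImuRecording({"low_back": _stream("low_back", t, acc, gyr, 100.0)})
        out = preprocess(rec)
        assert np.max(np.abs(out["low_back"].gyr.mean(axis=0))) < 1e-6

    def test_resampling_matches_analytic_sinusoid(self):
        rate, f = 104.0, 2.0
        t = np.arange(int(10 * rate)) / rate
        acc = np.column_stack([np.sin(2 * np.pi * f * t), 0 * t, GRAVITY + 0 * t])
        rec = RawImuRecording(
            {"low_back": _stream("low_back", t, acc, np.zeros((t.size, 3)), rate)})
        out = preprocess(rec)
        grid = out["low_back"].t
        expected = np.sin(2 * np.pi * f * grid)
        err = np.sqrt(np.mean((out["low_back"].acc[:, 0] - expected) ** 2))
        assert err < 0.01 * np.sqrt(0.5)  # 1% of signal RMS

    def test_too_short_rejected(self):
        t = np.arange(100) / 100.0
        acc = np.tile([0, 0, GRAVITY], (100, 1)).astype(float)
        rec = RawImuRecording({"low_back": _stream("low_back", t, acc, None, 100.0)})
        with pytest.raises(TooShortError):
            preprocess(rec)


class TestEventDetection:
    def test_recovers_stride_time(self, walk_recording):
        truth, rec, events = walk_recording
        ev = detect_gait_events(preprocess(rec))
        for foot in ("left_foot", "right_foot"):
            det = np.diff(ev.feet[foot]["ic"]).mean()
            assert det == pytest.approx(1.2, abs=0.01)

    def test_stationary_recording_has_no_gait(self):
        t = np.arange(1000) / 100.0
        acc = np.tile([0, 0, GRAVITY], (1000, 1)).astype(float)
        sensors = {
            f: _stream(f, t, acc, np.zeros((1000, 3)), 100.0)
            for f in ("left_foot", "right_foot")
        }
        with pytest.raises(InsufficientGaitError):
            detect_gait_events(RawImuRecording(sensors))

    def test_recovers_step_time_asymmetry(self, walk_recording):
        truth, rec, events = walk_recording
        ev = detect_gait_events(preprocess(rec))
        out = compute_asymmetry(ev)
        assert out["ratio_step_time"] == pytest.approx(1.2, abs=0.05)


class TestSpatiotemporal:
    def test_stride_length_is_speed_times_stride_time(self):
        ev = _synthetic_events(stride=1.2)
        out = compute_spatiotemporal(ev, distance=0.8 * 19 * 1.2,
                                     duration=19 * 1.2)
        assert out["stride_length_mean"] == pytest.approx(0.96, abs=1e-9)

    def test_constant_strides_have_zero_cv(self):
        ev = _synthetic_events(stride=1.0)
        out = compute_spatiotemporal(ev, distance=10.0)
        assert out["stride_time_cv"] == 0.0
        assert out["cadence"] == pytest.approx(120.0)

    def test_cv_recovered_from_generator_events(self):
        truth = GaitTruth(stride_time=1.0, gait_speed=0.8, stride_time_cv=0.1)
        rec, _ = generate_2mwt_signals(truth, duration=120, seed=11)
        ev = detect_gait_events(preprocess(rec))
        out = compute_spatiotemporal(ev, distance=rec.meta["distance_m"])
        assert out["stride_time_cv"] == pytest.approx(0.1, abs=0.03)


class TestFrequency:
    def _trunk_recording(self, z=None, x=None, duration=30.0, rate=100.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(int(duration * rate)) / rate
        zs = GRAVITY + (z(t) if z is not None else 1e-3 * rng.standard_normal(t.size))
        xs = x(t) if x is not None else 1e-3 * rng.standard_normal(t.size)
        ys = 1e-3 * rng.standard_normal(t.size)
        acc = np.column_stack([xs, ys, zs])
        return RawImuRecording({"low_back": _stream("low_back", t, acc, None, rate)})

    def test_pure_sinusoid_dominant_frequency(self):
        rec = self._trunk_recording(z=lambda t: np.sin(2 * np.pi * 2.0 * t))
        out = compute_frequency(rec, _synthetic_events(stride=1.0, n=29))
        assert out["dom_freq_v"] == pytest.approx(2.0, abs=0.05)
        assert out["harmonicity_v"] >= 0.95

    def test_equal_two_tone_harmonic_ratio_near_one(self):
        rec = self._trunk_recording(
            x=lambda t: np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 2.0 * t))
        out = compute_frequency(rec, _synthetic_events(stride=1.0, n=29))
        assert out["harmonic_ratio_ap"] == pytest.approx(1.0, abs=0.1)

    def test_white_noise_yields_finite_small_peak(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rec = self._trunk_recording(z=lambda t: rng.standard_normal(t.size),
                                        seed=seed)
            out = compute_frequency(rec, _synthetic_events(stride=1.0, n=29))
            assert np.isfinite(out["dom_amp_v"])
            # dominant peak holds a small share of broadband power
            assert out["harmonicity_v"] <= 1.0

    def test_constant_axis_raises_with_names(self):
        t = np.arange(3000) / 100.0
        acc = np.tile([0.0, 0.0, GRAVITY], (3000, 1))
        rec = RawImuRecording({"low_back": _stream("low_back", t, acc, None, 100.0)})
        with pytest.raises(UndefinedFeatureError) as err:
            compute_frequency(rec, _synthetic_events(stride=1.0, n=29))
        assert any("dom_freq" in n for n in err.value.names)


class TestComplexity:
    def test_periodic_signal_is_highly_regular(self):
        t = np.arange(9000) / 100.0
        z = GRAVITY + np.sin(2 * np.pi * 2.0 * t)
        acc = np.column_stack([0.1 * np.sin(2 * np.pi * t), 0.1 * np.cos(2 * np.pi * t), z])
        rec = RawImuRecording({"low_back": _stream("low_back", t, acc, None, 100.0)})
        out = compute_complexity(rec)
        assert out["stride_regularity"] >= 0.99

    def test_noise_entropy_exceeds_sinusoid_entropy(self):
        t = np.arange(1500) / 100.0
        sine = np.sin(2 * np.pi * 2.0 * t)
        for seed in range(10):
            noise = np.random.default_rng(seed).normal(scale=sine.std(), size=t.size)
            assert sample_entropy(noise, max_n=1500) > sample_entropy(sine, max_n=1500)

    def test_constant_signal_is_degenerate(self):
        with pytest.raises(UndefinedFeatureError):
            sample_entropy(np.ones(500))

    def test_short_series_rejected(self):
        t = np.arange(3000) / 100.0  # 30 s < required 60 s
        acc = np.column_stack([np.sin(t), np.cos(t), GRAVITY + np.sin(2 * t)])
        rec = RawImuRecording({"low_back": _stream("low_back", t, acc, None, 100.0)})
        with pytest.raises(TooShortError):
            compute_complexity(rec)


class TestAsymmetry:
    def test_symmetric_events_have_zero_si_unit_ratio(self):
        ev = _synthetic_events(stride=1.0)
        out = compute_asymmetry(ev)
        for q in ("step_time", "stance_time", "swing_time"):
            assert out[f"si_{q}"] == pytest.approx(0.0, abs=1e-9)
            assert out[f"ratio_{q}"] == pytest.approx(1.0, abs=1e-9)

    def test_stated_formula_arithmetic(self):
        assert symmetry_index(0.66, 0.54) == pytest.approx(20.0)

    def test_insufficient_strides_rejected(self):
        ev = _synthetic_events(stride=1.0, n=4)
        with pytest.raises(InsufficientGaitError):
            compute_asymmetry(ev)


class TestEndToEnd:
    def test_registry_covers_four_families(self):
        fams = {s.family for s in FEATURE_REGISTRY.values()}
        assert fams == {"spatiotemporal", "frequency", "complexity", "asymmetry"}
        assert len(FEATURE_REGISTRY) >= 28

    def test_full_vector_recovers_truth(self, walk_recording):
        truth, rec, _ = walk_recording
        fv = extract_features(rec)
        assert set(fv.values) == set(FEATURE_REGISTRY)
        assert all(np.isfinite(v) for v in fv.values.values())
        assert fv["gait_speed"] == pytest.approx(truth.gait_speed, abs=0.02)
        assert fv["stride_time_mean"] == pytest.approx(1.2, abs=0.01)
        assert fv["ratio_step_time"] == pytest.approx(1.2, abs=0.05)
        # one sample period at 100 Hz for event-level quantities
        assert fv["stance_time_mean"] == pytest.approx(0.6 * 1.2, abs=0.02)

    def test_rate_commutes_with_extraction(self):
        truth = GaitTruth(stride_time=1.1, gait_speed=0.9)
        rec104, _ = generate_2mwt_signals(truth, rate=104, noise_sd=0.0, seed=2)
        rec100, _ = generate_2mwt_signals(truth, rate=100, noise_sd=0.0, seed=2)
        f104 = extract_features(rec104)
        f100 = extract_features(rec100)
        for name in ("gait_speed", "stride_time_mean", "cadence",
                     "stance_fraction", "dom_freq_v"):
            assert f104[name] == pytest.approx(f100[name], rel=0.02)
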