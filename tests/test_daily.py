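"""Daily-life chain: epochs, classification, steps, ZUPT speed, summaries."""

import numpy as np
import pytest
from conftest import make_epoch

from strollpipe.daily import (
    EPOCH_S,
    RuleBasedClassifier,
    attach_epoch_speeds,
    classify_epochs,
    count_steps,
    epoch_speed,
    linear_acceleration,
    process_daily_recording,
    split_epochs,
    summarize_day,
    zupt_segment,
)
from strollpipe.errors import ContractViolationError, NoZuptWarning, TooShortError
from strollpipe.recording import GRAVITY, RawImuRecording, SensorStream
from strollpipe.synthetic import (
    ActivityTimeline,
    Bout,
    GaitTruth,
    generate_daily_recording,
)


def _recording(duration_s, rate=52.0):
    n = int(duration_s * rate)
    t = np.arange(n) / rate
    acc = np.tile([0.0, 0.0, GRAVITY], (n, 1))
    return RawImuRecording({"calf": SensorStream("calf", t, acc, None, rate)})


class TestSplitEpochs:
    def test_partial_trailing_epoch_dropped(self):
        assert len(split_epochs(_recording(95))) == 9

    def test_single_epoch(self):
        assert len(split_epochs(_recording(10))) == 1

    def test_boundaries_at_multiples_of_ten_seconds(self):
        eps = split_epochs(_recording(40))
        assert [e.start_time for e in eps] == pytest.approx([0, 10, 20, 30], abs=1 / 52)

    def test_too_short_rejected(self):
        with pytest.raises(TooShortError):
            split_epochs(_recording(9))


class TestClassification:
    def test_pure_gravity_is_off_body(self):
        ep = make_epoch()
        assert RuleBasedClassifier()(ep) == "off_body"

    def test_generated_gait_epoch_is_gait(self, gait_day):
        _, rec, _ = gait_day
        eps = classify_epochs(split_epochs(rec))
        labels = [e.label for e in eps]
        assert labels.count("gait") >= 0.95 * len(labels)

    def test_accuracy_against_generator_truth(self):
        """Balanced synthetic days: label accuracy >= 0.90 over 20 seeds."""
        truth = GaitTruth(stride_time=1.2, gait_speed=0.8)
        hits = total = 0
        for seed in range(20):
            tl = ActivityTimeline([
                Bout("gait", 120, truth), Bout("sedentary", 120),
                Bout("standing", 120), Bout("off_body", 120),
                Bout("gait", 120, truth),
            ])
            rec, _ = generate_daily_recording(tl, noise_sd=0.3, seed=seed)
            eps = classify_epochs(split_epochs(rec))
            bounds, t0 = [], 0.0
            for b in tl.bouts:
                lab = b.label if b.label in ("gait", "off_body") else "non_gait"
                bounds.append((t0, t0 + b.duration, lab))
                t0 += b.duration
            for ep in eps:
                mid = ep.start_time + EPOCH_S / 2
                want = next(lab for a, b, lab in bounds if a <= mid < b)
                hits += ep.label == want
                total += 1
        assert hits / total >= 0.90

    def test_classifier_contract_is_pluggable(self):
        eps = [make_epoch(), make_epoch()]
        classify_epochs(eps, classifier=lambda e: "non_gait")
        assert all(e.label == "non_gait" for e in eps)


class TestSteps:
    def test_day_without_gait_has_zero_steps(self):
        eps = [make_epoch(label="non_gait"), make_epoch(label="off_body")]
        assert count_steps(eps) == 0

    @pytest.mark.parametrize("noise_sd,tol", [(0.0, 0.02), (0.5, 0.05)])
    def test_recovery_against_day_truth(self, noise_sd, tol):
        truth = GaitTruth(stride_time=1.2, gait_speed=1.0)
        tl = ActivityTimeline([Bout("gait", 600, truth)])
        rec, day = generate_daily_recording(tl, noise_sd=noise_sd, seed=1)
        eps = classify_epochs(split_epochs(rec))
        steps = count_steps(eps)
        assert abs(steps - day.steps) <= tol * day.steps

    def test_amplitude_invariance(self, gait_day):
        _, rec, _ = gait_day
        eps = classify_epochs(split_epochs(rec))[:12]
        base = count_steps(eps)
        for ep in eps:
            ep.acc = np.tile([0, 0, GRAVITY], (ep.acc.shape[0], 1)) + 2.0 * (
                ep.acc - [0, 0, GRAVITY])
        assert count_steps(eps) == base


class TestLinearAcceleration:
    def test_stationary_upright_gravity_removed(self):
        ep = make_epoch(label="gait")
        _, ap = linear_acceleration(ep)
        lin, _ = linear_acceleration(ep)
        assert np.linalg.norm(lin, axis=1).max() < 0.05

    def test_requires_gait_label(self):
        with pytest.raises(ContractViolationError):
            linear_acceleration(make_epoch(label="non_gait"))

    def test_recovered_ap_correlates_with_truth(self, gait_day):
        _, rec, _ = gait_day
        eps = classify_epochs(split_epochs(rec))
        ep = eps[3]
        _, ap = linear_acceleration(ep)
        truth_ap = ep.acc[:, 0] - ep.acc[:, 0].mean()
        r = abs(np.corrcoef(ap, truth_ap)[0, 1])
        assert r > 0.9

    def test_yaw_rotation_leaves_ap_magnitude(self, gait_day):
        _, rec, _ = gait_day
        ep = classify_epochs(split_epochs(rec))[3]
        _, ap = linear_acceleration(ep)
        th = np.deg2rad(30)
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        ep_rot = make_epoch(label="gait", rate=ep.rate, acc=ep.acc @ rot.T)
        _, ap_rot = linear_acceleration(ep_rot)
        assert np.std(ap_rot) == pytest.approx(np.std(ap), rel=0.02)


class TestZupt:
    def test_stance_fraction_recovered(self, gait_day):
        # generator uses a 0.5 swing fraction for daily gait
        _, rec, _ = gait_day
        eps = classify_epochs(split_epochs(rec))
        fracs = []
        for ep in eps[2:8]:
            iv = zupt_segment(ep)
            stance = sum(e - s for s, e, p in iv if p == "stance")
            fracs.append(stance / iv[-1][1])
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.05)

    def test_intervals_tile_epoch_exactly(self, gait_day):
        _, rec, _ = gait_day
        ep = classify_epochs(split_epochs(rec))[4]
        iv = zupt_segment(ep)
        assert iv[0][0] == 0 and iv[-1][1] == ep.acc.shape[0]
        for (s0, e0, _), (s1, e1, _) in zip(iv[:-1], iv[1:]):
            assert e0 == s1

    def test_constant_motion_warns_no_zupt(self):
        rng = np.random.default_rng(0)
        n = 520
        acc = np.tile([0, 0, GRAVITY], (n, 1)) + 5.0 * rng.standard_normal((n, 3))
        ep = make_epoch(label="gait", acc=acc)
        with pytest.warns(NoZuptWarning):
            assert zupt_segment(ep) is None


class TestEpochSpeed:
    def test_zero_ap_gives_zero_speed(self):
        ep = make_epoch(label="gait", rate=100.0)
        n = ep.acc.shape[0]
        iv = [(0, 100, "stance"), (100, 141, "swing"), (141, n, "stance")]
        assert epoch_speed(ep, iv, np.zeros(n)) == 0.0

    def test_constant_acceleration_closed_form(self):
        """0.4 s swing at 1 m/s2 integrates to exactly 0.08 m."""
        ep = make_epoch(label="gait", rate=100.0)
        n = ep.acc.shape[0]
        ap = np.zeros(n)
        ap[100:141] = 1.0  # 41 samples -> 0.40 s span
        iv = [(0, 100, "stance"), (100, 141, "swing"), (141, n, "stance")]
        speed = epoch_speed(ep, iv, ap, drift_correction=False)
        assert speed * EPOCH_S == pytest.approx(0.08, abs=1e-9)

    def test_daily_speed_recovery(self, gait_day):
        truth, rec, _ = gait_day
        eps = classify_epochs(split_epochs(rec))
        attach_epoch_speeds(eps)
        speeds = [e.speed for e in eps if e.label == "gait" and e.speed is not None]
        assert np.mean(speeds) == pytest.approx(truth.gait_speed, abs=0.1)


class TestSummaries:
    def test_low_speed_epochs_excluded(self):
        eps = [make_epoch(label="gait", speed=s) for s in (0.04, 0.5, 0.7)]
        s = summarize_day(eps)
        assert s.avg_speed == pytest.approx(0.6)
        assert s.n_excluded_epochs == 1

    def test_eight_hour_wear_rule(self):
        n_wear = int(7.9 * 360)  # 7.9 h of 10-s epochs
        eps = [make_epoch(label="non_gait", acc=np.zeros((1, 3))) for _ in range(n_wear)]
        s = summarize_day(eps)
        assert s.wear_time_h == pytest.approx(7.9)
        assert not s.valid

    def test_all_off_body_day(self):
        eps = [make_epoch(label="off_body", acc=np.zeros((1, 3))) for _ in range(50)]
        s = summarize_day(eps)
        assert s.wear_time_h == 0.0 and not s.valid
        assert s.avg_speed is None and s.max_speed is None and s.steps == 0

    def test_max_at_least_average(self):
        rng = np.random.default_rng(5)
        eps = [make_epoch(label="gait", speed=float(s))
               for s in rng.uniform(0.2, 1.5, size=40)]
        s = summarize_day(eps)
        assert s.max_speed >= s.avg_speed

    def test_full_chain_summary(self, gait_day):
        truth, rec, day = gait_day
        summ = process_daily_recording(rec)
        assert len(summ) == 1
        s = summ[0]
        assert s.avg_speed == pytest.approx(truth.gait_speed, abs=0.1)
        assert abs(s.steps - day.steps) <= 0.05 * day.steps
        assert s.max_speed >= s.avg_speed
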