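"""Gait measures: planted-event detection, hand-computed PCI, regularity."""

import numpy as np
import pytest

import physcap as pc
from physcap.gait import (GAIT_FEATURE_NAMES, InsufficientStepsError,
                          StepEvents, cadence_features, detect_heel_strikes,
                          extract_gait_features, gait_jerk, gait_speed,
                          phase_coordination_index, regularity)
from physcap.recording import G, ImuRecording


def _events(times):
    return StepEvents(times=np.asarray(times, float))


class TestHeelStrikeDetection:
    def test_planted_strikes_recovered(self, walk_recording):
        ev = detect_heel_strikes(walk_recording)
        planted = walk_recording.meta["events"]
        assert ev.times.size == len(planted)
        assert np.abs(ev.times - planted).max() < 0.030

    def test_flat_signal_raises(self):
        n = 1000
        acc = np.column_stack([np.zeros(n), np.zeros(n), np.full(n, G)])
        rec = ImuRecording("7MW", (np.arange(n) * 10_000_000).astype(np.int64),
                           acc)
        with pytest.raises(InsufficientStepsError):
            detect_heel_strikes(rec)

    def test_planted_asymmetry_labels_long_series(self):
        rec = pc.generate_walk_recording(
            pc.GaitSimParams(asymmetry=1.2, cadence=110), seed=5)
        ev = detect_heel_strikes(rec)
        # generator plants the long step first
        assert ev.long_starts_first
        ratio = np.mean(np.diff(ev.times)[0::2]) / np.mean(np.diff(ev.times)[1::2])
        assert ratio == pytest.approx(1.2, rel=0.05)


class TestCadence:
    def test_20_steps_over_12_seconds(self):
        ev = _events(np.linspace(0.0, 12.0, 21))  # 20 steps spanning 12 s
        out = cadence_features(ev)
        assert out["Cadence"] == pytest.approx(100.0)
        assert out["SD_Cadence"] == pytest.approx(0.0, abs=1e-9)
        assert out["Duration"] == pytest.approx(12.0)

    def test_alternating_step_times_hand_oracle(self):
        times = np.concatenate(([0.0], np.cumsum([0.5, 0.6] * 5)))
        out = cadence_features(_events(times))
        per_step = 60.0 / np.array([0.5, 0.6] * 5)
        assert out["SD_Cadence"] == pytest.approx(per_step.std(ddof=1))


class TestRegularity:
    def test_periodic_signal_near_one(self):
        rate = 100.0
        t = np.arange(0, 20, 1 / rate)
        x = np.sin(2 * np.pi * 2.0 * t)  # step frequency 2 Hz
        ev = _events(np.arange(0.0, 19.5, 0.5))
        out = regularity(x, rate, ev)
        assert out["StepReg"] > 0.99
        assert out["StrideReg"] > 0.99

    def test_asymmetric_gait_stride_exceeds_step(self):
        # period-2 alternation: strong stride periodicity, weak step
        rate = 100.0
        t = np.arange(0, 20, 1 / rate)
        x = np.sin(2 * np.pi * 2.0 * t) + 0.8 * np.sin(2 * np.pi * 1.0 * t)
        ev = _events(np.arange(0.0, 19.5, 0.5))
        out = regularity(x, rate, ev)
        # brute-force oracle: full normalized unbiased autocorrelation
        xm = x - x.mean()
        n = xm.size
        lags = np.arange(1, 180)
        ac = np.array([(xm[:n - L] * xm[L:]).sum() / (n - L) for L in lags])
        ac = ac / ((xm * xm).sum() / n)
        step_win = (lags >= 25) & (lags <= 75)
        stride_win = (lags >= 50) & (lags <= 150)
        assert out["StepReg"] == pytest.approx(ac[step_win].max(), abs=1e-9)
        assert out["StrideReg"] == pytest.approx(ac[stride_win].max(), abs=1e-9)
        assert out["StrideReg"] > out["StepReg"]

    def test_white_noise_low_regularity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(3000)
        ev = _events(np.arange(0.0, 25.0, 0.5))
        out = regularity(x, 100.0, ev)
        assert abs(out["StepReg"]) < 0.1
        assert abs(out["StrideReg"]) < 0.1

    def test_bounded_and_scale_invariant(self, walk_recording):
        sig = pc.resample_uniform(walk_recording)
        ev = detect_heel_strikes(walk_recording)
        x = sig["acc_v"]
        r1 = regularity(x, 100.0, ev)
        r2 = regularity(5.0 * x, 100.0, ev)
        for key in ("StepReg", "StrideReg"):
            assert -1.0 <= r1[key] <= 1.0
            assert r1[key] == pytest.approx(r2[key], rel=1e-12)


class TestPci:
    def test_perfect_alternation_zero(self):
        ev = _events(np.arange(0.0, 10.0, 0.5))
        assert phase_coordination_index(ev) == pytest.approx(0.0, abs=1e-9)

    def test_constant_phase_162(self):
        # phi == 162 for every stride: PhaseCV = 0, PCI = 100 * 18/180 = 10
        times = np.concatenate(([0.0], np.cumsum([0.45, 0.55] * 6)))
        ev = _events(times)
        assert not ev.long_starts_first  # 0.45 first: short leads
        assert phase_coordination_index(ev) == pytest.approx(10.0, abs=1e-6)

    def test_alternating_phase_hand_value(self):
        # phi alternates {170, 190}: PhaseCV = 100*10/180, accuracy term
        # = 100*10/180, PCI = 11.11...
        long_steps = [170 / 360, 190 / 360] * 4
        times = [0.0]
        for ls in long_steps:
            times.append(times[-1] + ls)        # long step
            times.append(times[-1] + 1.0 - ls)  # completes 1 s stride
        ev = _events(times)
        assert phase_coordination_index(ev) == pytest.approx(100 * 20 / 180 / 2
                                                             + 100 * 10 / 180,
                                                             rel=1e-6)


class TestGaitJerk:
    def test_identical_steps_mean_equals_single(self):
        rate = 100.0
        t = np.arange(0, 10, 1 / rate)
        x = np.sin(2 * np.pi * 2.0 * t)
        many = gait_jerk(x, rate, _events(np.arange(0.0, 9.5, 0.5)))
        one = gait_jerk(x, rate, _events([0.0, 0.5, 1.0, 1.5]))
        assert many == pytest.approx(one, rel=1e-6)

    def test_closed_form_oracle(self):
        # a(t) = A sin(w t): per step of duration T,
        # NJS = sqrt(T^5/2 * A^2 w^2 T/2) for integer periods per step
        A, rate = 0.9, 400.0
        w = 2 * np.pi * 4.0  # 2 full periods per 0.5 s step
        t = np.arange(0, 8, 1 / rate)
        x = A * np.sin(w * t)
        ev = _events(np.arange(0.0, 7.5, 0.5))
        T = 0.5
        oracle = np.sqrt(T ** 5 / 2.0 * A ** 2 * w ** 2 * T / 2.0)
        assert gait_jerk(x, rate, ev) == pytest.approx(oracle, rel=0.01)

    def test_time_rescaling_closed_form(self):
        # doubling all durations with a(t/2): T^5 -> 32x, (da/dt)^2 -> 1/4,
        # dt -> 2x  =>  NJS^2 -> 16x  =>  NJS -> 4x
        rate = 200.0
        t1 = np.arange(0, 4, 1 / rate)
        x1 = np.sin(2 * np.pi * 2.0 * t1)
        njs1 = gait_jerk(x1, rate, _events(np.arange(0.0, 3.6, 0.5)))
        t2 = np.arange(0, 8, 1 / rate)
        x2 = np.sin(2 * np.pi * 1.0 * t2)
        njs2 = gait_jerk(x2, rate, _events(np.arange(0.0, 7.2, 1.0)))
        assert njs2 / njs1 == pytest.approx(4.0, rel=0.01)


class TestExtractGait:
    def test_exactly_19_named_measures(self, walk_recording):
        feats = extract_gait_features(walk_recording)
        assert len(feats) == 19
        assert feats.notna().all()
        assert set(feats.index) == set(GAIT_FEATURE_NAMES)
        assert set(feats.index) == set(pc.load_loading_matrix("7mw").index)

    def test_gait_speed(self):
        assert gait_speed(7.0) == pytest.approx(1.0)
        assert gait_speed(10.0, distance_m=7.0) == pytest.approx(0.7)

    def test_deterministic(self, walk_recording):
        assert extract_gait_features(walk_recording).equals(
            extract_gait_features(walk_recording))

    def test_planted_cadence_recovered_within_2pct(self):
        for cadence in (95.0, 110.0, 125.0):
            rec = pc.generate_walk_recording(
                pc.GaitSimParams(cadence=cadence), seed=9)
            feats = extract_gait_features(rec)
            assert feats["Cadence"] == pytest.approx(cadence, rel=0.02)

    def test_pci_monotone_in_planted_asymmetry(self):
        pcis = []
        for asym in (1.0, 1.1, 1.2, 1.3):
            rec = pc.generate_walk_recording(
                pc.GaitSimParams(asymmetry=asym), seed=4)
            pcis.append(extract_gait_features(rec)["PCI"])
        assert all(a < b for a, b in zip(pcis, pcis[1:]))
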