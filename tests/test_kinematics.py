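"""Bout detection and per-bout kinematics against constructed signals
and generator ground truth."""

import numpy as np
import pandas as pd
import pytest

from larvaswim import (DetectionParams, SessionRejected, analyze_trace,
                       bout_rate, compute_bout_kinematics, detect_bends,
                       detect_bouts, simulate_slow_session)
from conftest import make_trace, match_bouts


def lobe_train(amps, lobe=10, pad=100):
    """Tail-angle array of half-sine lobes with given signed peaks."""
    sig = [np.zeros(pad)]
    for a in amps:
        sig.append(a * np.sin(np.linspace(0, np.pi, lobe, endpoint=False)))
    sig.append(np.zeros(pad))
    return np.concatenate(sig)


class TestDetectBouts:
    def test_all_zero_trace_has_no_bouts(self):
        trace = make_trace(np.zeros(2000))
        assert detect_bouts(trace, rate=100.0) == []

    def test_single_synthetic_bout_onset_within_two_frames(self, mut_fish):
        hits = 0
        for seed in range(3):
            trace, gt = simulate_slow_session(mut_fish, 20.0, 100.0, rng=seed)
            intervals = detect_bouts(trace, rate=100.0)
            pairs, missed, spurious = match_bouts(gt, intervals)
            assert missed == 0 and spurious == 0
            for idx, (s, e) in pairs.items():
                assert abs(s - gt.loc[idx, "onset_frame"]) <= 2
                hits += 1
        assert hits > 5

    def test_rejects_session_with_many_flagged_frames(self):
        trace = make_trace(np.zeros(1000))
        trace["flagged"] = np.arange(1000) % 4 == 0  # 25% flagged
        with pytest.raises(SessionRejected):
            detect_bouts(trace, rate=100.0)

    def test_flag_interpolation_below_threshold(self, mut_fish):
        trace, gt = simulate_slow_session(mut_fish, 20.0, 100.0, rng=4)
        trace["flagged"] = np.arange(len(trace)) % 50 == 3  # 2% flagged
        intervals = detect_bouts(trace, rate=100.0)
        _, missed, _ = match_bouts(gt, intervals)
        assert missed == 0


class TestDetectBends:
    def test_single_half_cycle_gives_one_peak(self):
        trace = make_trace(lobe_train([30.0]))
        [(s, e)] = detect_bouts(trace, rate=100.0)
        bends = detect_bends(trace, (s, e))
        assert len(bends) == 1
        assert bends[0] == pytest.approx(30.0, abs=2.0)

    def test_symmetric_sinusoid_gives_alternating_peaks(self):
        trace = make_trace(lobe_train([15.0, -15.0, 15.0, -15.0]))
        [(s, e)] = detect_bouts(trace, rate=100.0)
        bends = np.array(detect_bends(trace, (s, e)))
        assert len(bends) == 4
        assert (np.sign(bends) == [1, -1, 1, -1]).all()
        assert np.abs(np.abs(bends) - 15.0).max() < 2.0

    def test_noisy_bout_bend_amplitudes_track_injected(self, mut_fish):
        """Detected peak amplitudes track injected bend amplitudes.

        Budget: 1 degree or 7% of the amplitude, whichever is larger — a
        40-degree bend spans only ~4 frames at 100 Hz, so any smoothing
        that suppresses the 0.5-degree sensor noise attenuates such a
        narrow lobe by a couple of degrees.
        """
        trace, gt = simulate_slow_session(mut_fish, 30.0, 100.0, rng=12)
        intervals = detect_bouts(trace, rate=100.0)
        pairs, _, _ = match_bouts(gt, intervals)
        errs = []
        for idx, iv in pairs.items():
            bends = detect_bends(trace, iv)
            row = gt.loc[idx]
            first = abs(row.first_bend_deg)
            assert abs(abs(bends[0]) - first) < max(1.5, 0.07 * first)
            assert (abs(max(np.abs(bends)) - row.max_bend_deg)
                    < max(1.5, 0.07 * row.max_bend_deg))
            errs.append(abs(bends[0]) - first)
        assert len(errs) >= 5
        assert abs(np.mean(errs)) < 1.0


class TestBoutKinematics:
    def test_oscillation_and_tbf_arithmetic(self):
        # 8 bends over 0.25 s -> n_osc = 4, TBF = 16 Hz
        trace = make_trace(np.zeros(200))
        bends = [10, -8, 7, -6, 5, -4, 3, -2.5]
        bout = compute_bout_kinematics(trace, (50, 75), bends, rate=100.0)
        assert bout.n_osc == 4
        assert bout.tbf_hz == pytest.approx(16.0)
        assert bout.duration_s == pytest.approx(0.25)
        assert bout.median_bend_deg == pytest.approx(np.median(np.abs(bends)))
        assert bout.max_bend_deg >= bout.median_bend_deg >= 0

    def test_distance_is_path_length_over_half_open_interval(self):
        # 0.02 mm/frame for a 27-frame interval -> 27 steps -> 0.54 mm
        n = 400
        x = 0.02 * np.arange(n)
        trace = make_trace(np.zeros(n), x=x)
        bout = compute_bout_kinematics(trace, (100, 127), [10.0], rate=100.0)
        assert bout.distance_mm == pytest.approx(0.54, rel=1e-6)
        assert bout.speed_mm_s == pytest.approx(0.54 / 0.27, rel=1e-6)

    def test_translation_invariance(self, mut_fish):
        trace, _ = simulate_slow_session(mut_fish, 20.0, 100.0, rng=3)
        shifted = trace.copy()
        shifted["x_mm"] += 5.0
        shifted["y_mm"] -= 3.0
        a = analyze_trace(trace, rate=100.0)
        b = analyze_trace(shifted, rate=100.0)
        pd.testing.assert_frame_equal(a, b)

    def test_time_reversal_preserves_duration_distance_count(self):
        amps = [18, -12, 8, -5, 3.5]
        sig = lobe_train(amps, lobe=8)
        x = np.cumsum(np.full(len(sig), 0.015))
        trace = make_trace(sig, x=x)
        rev = make_trace(sig[::-1], x=x[::-1].copy())
        [(s1, e1)] = detect_bouts(trace, rate=100.0)
        [(s2, e2)] = detect_bouts(rev, rate=100.0)
        b1 = compute_bout_kinematics(trace, (s1, e1),
                                     detect_bends(trace, (s1, e1)), rate=100.0)
        b2 = compute_bout_kinematics(rev, (s2, e2),
                                     detect_bends(rev, (s2, e2)), rate=100.0)
        assert b1.duration_s == pytest.approx(b2.duration_s, abs=0.03)
        assert b1.distance_mm == pytest.approx(b2.distance_mm, rel=0.05)
        assert b1.n_osc == b2.n_osc

    def test_per_bout_recovery_close_to_ground_truth(self, cohort):
        """Paired recovery of duration/distance/TBF/bends vs ground truth.

        The tolerance combines 2 SEM of the paired differences with a
        small resolution floor (frame quantisation, smoothing of narrow
        lobes and envelope edge conventions bound the achievable per-bout
        accuracy at the default noise level).  Distance unbiasedness is
        asserted for bouts travelling at least 0.25 mm: below that, a
        bout's total displacement approaches the accumulated positional
        noise (0.01 mm per frame) and the path length is noise-limited;
        the all-bout median distance error is bounded instead.
        """
        rows = []
        for k, (_, fish) in enumerate(cohort.head(4).iterrows()):
            trace, gt = simulate_slow_session(fish, 250.0, 100.0, rng=40 + k)
            bt = analyze_trace(trace, rate=100.0)
            for _, g in gt.iterrows():
                d = bt[(bt.onset_frame - g.onset_frame).abs() <= 5]
                if len(d) != 1:
                    continue
                b = d.iloc[0]
                rows.append({
                    "dur": b.duration_s / g.duration_s - 1,
                    "dist": b.distance_mm / g.distance_mm - 1,
                    "tbf": b.tbf_hz / g.tbf_hz - 1,
                    "maxb": b.max_bend_deg - g.max_bend_deg,
                    "dist_true": g.distance_mm,
                })
        df = pd.DataFrame(rows)
        assert len(df) > 600
        for col, floor in [("dur", 0.03), ("tbf", 0.03)]:
            tol = max(2 * df[col].std() / np.sqrt(len(df)), floor)
            assert abs(df[col].mean()) < tol, col
        moving = df[df["dist_true"] >= 0.25]
        tol = max(2 * moving["dist"].std() / np.sqrt(len(moving)), 0.03)
        assert abs(moving["dist"].mean()) < tol
        assert abs(df["dist"].median()) < 0.05
        tol = max(2 * df["maxb"].std() / np.sqrt(len(df)), 0.6)
        assert abs(df["maxb"].mean()) < tol


class TestBoutRate:
    @pytest.mark.parametrize("n,duration,expected",
                             [(0, 300.0, 0.0), (273, 300.0, 0.91),
                              (285, 300.0, 0.95)])
    def test_rate_is_count_over_duration(self, n, duration, expected):
        assert bout_rate([None] * n, duration) == pytest.approx(expected)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            bout_rate([], 0.0)
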