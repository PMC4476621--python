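"""Behavioral pipeline: filters, PCA, events, matching, statistics."""

import numpy as np
import pytest
import scipy.signal as sps

from duomeg import behavior as bh
from duomeg import synthgen as sg

FS = 1000.0


def _sine(freq, dur=10.0, fs=FS):
    t = np.arange(int(dur * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


class TestNotchFilter:
    def test_constant_passes_unchanged(self):
        x = np.full(5000, 3.7)
        np.testing.assert_allclose(bh.notch_filter(x, FS), x, atol=1e-9)

    def test_line_frequency_strongly_attenuated(self):
        # oracle: the designed biquad's squared magnitude response at 50 Hz
        b, a = sps.iirnotch(50.0, 50.0, fs=FS)
        _, h = sps.freqz(b, a, worN=[50.0], fs=FS)
        assert 40 * np.log10(1 / np.abs(h[0])) > 40  # double pass, in dB
        # steady-state attenuation, away from the filter's edge-settling
        # region (~2 s for a 1-Hz-wide notch)
        y = bh.notch_filter(_sine(50.0), FS)
        rms_ratio = np.sqrt(np.mean(y[3000:7000] ** 2) / 0.5)
        assert 20 * np.log10(rms_ratio) < -40

    def test_passband_tone_preserved(self):
        y = bh.notch_filter(_sine(2.0), FS)
        mid = slice(2000, 8000)  # away from edges
        assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.01)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            bh.notch_filter(np.zeros(10), FS)


class TestLowpass:
    def test_constant_passes_unchanged(self):
        # Chebyshev II passband gain is 1 up to the (tiny) passband droop
        x = np.full(5000, -1.2)
        np.testing.assert_allclose(bh.lowpass_pc1(x, FS), x, rtol=1e-3)

    def test_stopband_tone_attenuated_60db(self):
        # two zero-phase passes double the single-pass stopband attenuation
        y = bh.lowpass_pc1(_sine(10.0), FS)
        rms_ratio = np.sqrt(np.mean(y[2000:8000] ** 2) / 0.5)
        assert 20 * np.log10(rms_ratio) < -60

    def test_passband_tone_within_2pct(self):
        y = bh.lowpass_pc1(_sine(0.3, dur=30.0), FS)
        mid = slice(5000, 25000)
        assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.02)

    @pytest.mark.parametrize("filt", [bh.notch_filter, bh.lowpass_pc1])
    def test_zero_phase_time_reversal_symmetry(self, filt, rng):
        # forward-backward symmetry holds to numerical precision away from
        # the edge-settling regions
        x = rng.normal(size=10_000)
        fwd = filt(x, FS)
        rev = filt(x[::-1], FS)[::-1]
        np.testing.assert_allclose(rev[3000:7000], fwd[3000:7000], atol=1e-5)
        np.testing.assert_allclose(rev, fwd, atol=1e-3)

    def test_zero_phase_no_delay_on_passband_tone(self):
        x = _sine(0.5, dur=20.0)
        y = bh.lowpass_pc1(x, FS)
        xc = sps.correlate(y[2000:18000], x[2000:18000], mode="full")
        lag = np.argmax(xc) - (16000 - 1)
        assert abs(lag) <= 1


def _rec(samples, fs=FS):
    return bh.AccelRecording(site="X", subject="s", fs_hz=fs, samples=samples)


class TestPCA:
    def test_rank_one_motion_recovers_axis(self, rng):
        x = np.zeros((3, 5000))
        x[0] = _sine(0.5, dur=5.0)
        x += rng.normal(0, 1e-4, x.shape)
        s = bh.pca_reduce(_rec(x))
        assert abs(s.loadings[0, 0]) > 0.999

    def test_isotropic_noise_equal_variance_fractions(self, rng):
        x = rng.normal(size=(3, 240_000))
        s = bh.pca_reduce(_rec(x))
        np.testing.assert_allclose(s.explained_var, 1 / 3, atol=0.02)

    def test_known_axis_recovered_from_generator(self, default_pair):
        cfg, rec_a, _, _ = default_pair
        clean = bh.notch_filter(rec_a.samples, cfg.fs_hz)
        s = bh.pca_reduce(_rec(clean, cfg.fs_hz))
        assert abs(s.loadings[:, 0] @ cfg.axis_vector) > 0.99

    def test_energy_conservation(self, rng):
        x = rng.normal(size=(3, 10_000)) * np.array([[3.0], [1.0], [0.2]])
        xc = x - x.mean(axis=1, keepdims=True)
        s = bh.pca_reduce(_rec(x))
        axis_var = xc.var(axis=1, ddof=1).sum()
        pc_var = s.pc_traces.var(axis=1, ddof=1).sum()
        assert pc_var == pytest.approx(axis_var, rel=1e-8)

    def test_explained_var_sorted_and_normalized(self, rng):
        x = rng.normal(size=(3, 5000)) * np.array([[2.0], [1.0], [0.5]])
        s = bh.pca_reduce(_rec(x))
        assert np.all(np.diff(s.explained_var) <= 0)
        assert s.explained_var.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(s.loadings.T @ s.loadings, np.eye(3),
                                   atol=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            bh.pca_reduce(_rec(np.ones((3, 2000))))


class TestAlignSign:
    def _summary(self, lp):
        return bh.MovementSummary(
            pc_traces=np.vstack([lp, np.zeros((2, lp.size))]),
            loadings=np.eye(3), explained_var=np.array([1.0, 0.0, 0.0]),
            sign=1, lp_trace=lp, fs_hz=FS,
        )

    def test_same_polarity_keeps_plus(self):
        lp = _sine(0.5)
        assert bh.align_sign(self._summary(lp), lp).sign == 1

    def test_opposite_polarity_flips(self):
        lp = _sine(0.5)
        s = bh.align_sign(self._summary(lp), -lp)
        assert s.sign == -1
        np.testing.assert_allclose(s.lp_trace, -lp)

    def test_small_shift_same_polarity_keeps_plus(self):
        lp = _sine(0.5)
        shifted = np.roll(lp, 200)  # 200 ms at 1 kHz
        assert bh.align_sign(self._summary(lp), shifted).sign == 1

    def test_degenerate_partner_warns_and_defaults_plus(self):
        lp = _sine(0.5)
        with pytest.warns(UserWarning, match="degenerate"):
            assert bh.align_sign(self._summary(lp), np.zeros_like(lp)).sign == 1


class TestDetectEvents:
    def test_analytic_sine_crossings(self):
        # sin(2*pi*0.5*t) on [0, 10): rising crossings at 2, 4, 6, 8 s
        # (t=0 has no preceding negative sample)
        ev = bh.detect_events(_sine(0.5, dur=10.0), FS)
        np.testing.assert_allclose(ev.times_s, [2.0, 4.0, 6.0, 8.0],
                                    atol=1.0 / FS)

    def test_strictly_positive_trace_empty(self):
        ev = bh.detect_events(np.ones(1000), FS)
        assert len(ev) == 0

    def test_exact_zero_run_fires_once_at_run_start(self):
        lp = np.concatenate([-np.ones(10), np.zeros(5), np.ones(10)])
        ev = bh.detect_events(lp, FS)
        assert len(ev) == 1
        assert ev.times_s[0] == pytest.approx(10 / FS)

    def test_offset_time_base(self):
        ev = bh.detect_events(_sine(0.5, dur=10.0), FS, t0_s=100.0)
        np.testing.assert_allclose(ev.times_s, [102.0, 104.0, 106.0, 108.0],
                                    atol=1.0 / FS)


class TestSelectBlock:
    def test_equal_trains_earliest_window(self):
        times = np.arange(1.0, 299.0, 2.0)
        ea = bh.EventSeries(times, "A")
        eb = bh.EventSeries(times + 0.05, "B")
        window, ca, cb = bh.select_block(ea, eb, 0.0, 300.0, block_s=240.0)
        assert window[0] == pytest.approx(0.0)
        assert len(ca) == len(cb)

    def test_missing_early_event_shifts_window_right(self):
        # exhaustive-scan oracle: the earliest admissible start excludes
        # site A's unmatched first event
        ta = np.arange(1.0, 246.0, 2.0)
        tb = ta[1:] + 0.05  # B misses the event near t=1
        ea, eb = bh.EventSeries(ta, "A"), bh.EventSeries(tb, "B")
        window, ca, cb = bh.select_block(ea, eb, 0.0, 246.0, block_s=240.0)
        assert window[0] > 1.0
        assert len(ca) == len(cb)
        starts = np.arange(0.0, 246.0 - 240.0 + 1e-9, 0.1)
        oracle = next(
            s for s in starts
            if len(ea.clipped(s, s + 240)) == len(eb.clipped(s, s + 240)) > 0
        )
        assert window[0] == pytest.approx(oracle)

    def test_synthetic_pair_full_span_admissible(self):
        # a 240-s generated pair admits its single full-span window, since
        # the ground-truth trains are equal-count and lag-valid by design
        cfg = sg.PairConfig(duration_s=240.0, seed=1)
        _, _, gt = sg.gen_movement_pair(cfg)
        ea = bh.EventSeries(gt.events_a, "Aalto")
        eb = bh.EventSeries(gt.events_b, "HUCH")
        window, ca, cb = bh.select_block(ea, eb, 0.0, 240.0, block_s=240.0)
        assert window == (0.0, 240.0)
        assert len(ca) == len(gt.events_a)

    def test_short_recording_rejected(self):
        ea = bh.EventSeries(np.arange(1.0, 100.0, 2.0), "A")
        with pytest.raises(ValueError, match="shorter"):
            bh.select_block(ea, ea, 0.0, 100.0, block_s=240.0)


class TestMatchEvents:
    def test_identical_trains_zero_lags(self):
        e = bh.EventSeries(np.arange(1.0, 50.0, 2.0), "A")
        m = bh.match_events(e, bh.EventSeries(e.times_s.copy(), "B"))
        assert np.all(m.signed_lags_ms == 0)
        assert np.all(m.valid)

    def test_constant_shift(self):
        ta = np.arange(1.0, 50.0, 2.0)
        m = bh.match_events(bh.EventSeries(ta, "A"),
                            bh.EventSeries(ta + 0.1, "B"))
        np.testing.assert_allclose(m.signed_lags_ms, 100.0, atol=1e-9)
        assert np.all(m.valid)  # 0.1 s < (2/3) s

    def test_jittered_synthetic_lags_recovered(self):
        cfg = sg.PairConfig(lag_mean_ms=150.0, lag_sd_ms=40.0, seed=9)
        _, _, gt = sg.gen_movement_pair(cfg)
        m = bh.match_events(bh.EventSeries(gt.events_a, "A"),
                            bh.EventSeries(gt.events_b, "B"))
        np.testing.assert_allclose(m.signed_lags_ms, gt.true_lags_ms,
                                    atol=1000.0 / cfg.fs_hz)
        assert np.all(m.valid)

    def test_unequal_counts_rejected(self):
        ea = bh.EventSeries(np.arange(5.0), "A")
        eb = bh.EventSeries(np.arange(4.0), "B")
        with pytest.raises(ValueError, match="unequal"):
            bh.match_events(ea, eb)


class TestLagStatistics:
    def test_all_zero(self):
        e = bh.EventSeries(np.arange(1.0, 20.0, 2.0), "A")
        m = bh.match_events(e, bh.EventSeries(e.times_s.copy(), "B"))
        s = bh.lag_statistics(m)
        assert (s.median_signed_ms, s.mean_abs_ms, s.max_abs_ms) == (0, 0, 0)

    def test_hand_computed_three_lags(self):
        m = bh.MatchedEvents(
            t_a_s=np.array([10.0, 20.0, 30.0]),
            t_b_s=np.array([9.9, 20.0, 30.1]),
            signed_lags_ms=np.array([-100.0, 0.0, 100.0]),
            valid=np.ones(3, bool), site_a="A", site_b="B",
        )
        s = bh.lag_statistics(m)
        assert s.median_signed_ms == 0.0
        assert s.mean_abs_ms == pytest.approx(200.0 / 3.0)
        assert s.p25_signed_ms <= s.median_signed_ms <= s.p75_signed_ms

    def test_constant_generator_lag_reproduced(self):
        # lag 215 ms, zero spread: mean absolute lag is exactly 215 ms
        cfg = sg.PairConfig(lag_mean_ms=215.0, lag_sd_ms=0.0, seed=4,
                            mean_cycle_s=4.0)
        _, _, gt = sg.gen_movement_pair(cfg)
        m = bh.match_events(bh.EventSeries(gt.events_a, "A"),
                            bh.EventSeries(gt.events_b, "B"))
        s = bh.lag_statistics(m)
        assert s.mean_abs_ms == pytest.approx(215.0, abs=1000.0 / cfg.fs_hz)

    def test_empty_rejected(self):
        m = bh.MatchedEvents(np.array([1.0]), np.array([1.0]),
                             np.array([0.0]), np.zeros(1, bool), "A", "B")
        with pytest.raises(ValueError, match="no valid"):
            bh.lag_statistics(m)


class TestCycleStatistics:
    def test_uniform_train(self):
        s = bh.cycle_statistics(bh.EventSeries(np.array([0.0, 2, 4, 6]), "A"))
        np.testing.assert_array_equal(s.durations_s, [2, 2, 2])
        assert s.mean_s == 2.0 and s.rate_hz == 0.5
        assert s.max_rel_deviation_pct == 0.0

    def test_single_event_rejected(self):
        with pytest.raises(ValueError, match="2 events"):
            bh.cycle_statistics(bh.EventSeries(np.array([1.0]), "A"))

    def test_count_is_events_minus_one(self, default_pair):
        _, _, _, gt = default_pair
        s = bh.cycle_statistics(bh.EventSeries(gt.events_a, "A"))
        assert s.durations_s.size == gt.events_a.size - 1


class TestSegmentAndAverage:
    def test_constant_signal(self):
        ev = bh.EventSeries(np.array([5.0, 10.0, 15.0]), "A")
        _, _, mean = bh.segment_and_average(np.full(20_000, 2.5), FS, ev)
        np.testing.assert_allclose(mean, 2.5)

    def test_impulse_train_peaks_at_zero_lag(self):
        x = np.zeros(20_000)
        centers = [5000, 10000, 15000]
        x[centers] = 1.0
        ev = bh.EventSeries(np.array(centers) / FS, "A")
        epochs, lags, mean = bh.segment_and_average(x, FS, ev)
        assert epochs.shape[0] == 3
        assert mean[np.argmin(np.abs(lags))] == 1.0

    def test_edge_epochs_dropped(self):
        ev = bh.EventSeries(np.array([0.5, 5.0, 19.9]), "A")
        epochs, _, _ = bh.segment_and_average(np.zeros(20_000), FS, ev)
        assert epochs.shape[0] == 1  # only the event at 5 s fits (-1, +3) s

    def test_partner_locked_average_peak_displaced_by_lag(self):
        # averaging A's acceleration on B's events shifts the waveform by
        # the ground-truth mean lag
        cfg = sg.PairConfig(lag_mean_ms=300.0, lag_sd_ms=0.0, seed=5,
                            mean_cycle_s=4.0, noise_sd=0.01)
        rec_a, _, gt = sg.gen_movement_pair(cfg)
        x = cfg.axis_vector @ rec_a.samples
        ev_b = bh.EventSeries(gt.events_b, "B")
        _, lags, mean_on_b = bh.segment_and_average(x, cfg.fs_hz, ev_b)
        _, _, mean_on_a = bh.segment_and_average(
            x, cfg.fs_hz, bh.EventSeries(gt.events_a, "A")
        )
        shift = (np.argmax(mean_on_a) - np.argmax(mean_on_b)) / cfg.fs_hz
        assert shift * 1000.0 == pytest.approx(300.0, abs=20.0)


class TestEndToEndLagRecovery:
    @pytest.mark.parametrize("lag_mean", [50.0, 150.0, 300.0])
    def test_pipeline_recovers_mean_absolute_lag(self, lag_mean):
        from duomeg.pipeline import run_behavior

        cfg = sg.PairConfig(lag_mean_ms=lag_mean, lag_sd_ms=30.0, seed=11)
        rec_a, rec_b, gt = sg.gen_movement_pair(cfg)
        report, _ = run_behavior(rec_a, rec_b)
        assert report.lag_stats.mean_abs_ms == pytest.approx(
            np.abs(gt.true_lags_ms).mean(), abs=10.0
        )
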