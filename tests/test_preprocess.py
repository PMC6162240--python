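"""Continuous-data cleaning: excision, filtering, bad channels, epoching."""

import logging

import numpy as np
import pytest

from fearprobe import preprocess, synth
from fearprobe.core import InvalidParameterError, RawRecording, Trial, TrialSchedule


def make_rec(data, layout, fs=250.0, tms_times=()):
    trials = [
        Trial(condition="CSplus", us_paired=False, cue_onset_s=t - 1.0,
              cue_duration_s=5.0, iti_s=5.0, tms_time_s=t)
        for t in tms_times
    ]
    return RawRecording(data=data, fs_hz=fs, schedule=TrialSchedule(trials),
                        layout=layout)


class TestExcision:
    def test_no_events_identity(self, layout16):
        rng = np.random.default_rng(0)
        rec = make_rec(rng.normal(size=(16, 5000)), layout16)
        out = preprocess.excise_tms_artifact(rec)
        assert np.array_equal(out.data, rec.data)

    def test_window_rounded_outward_covers_stated_interval(self, layout16):
        """Pulse at 10.0 s, 250 Hz: all samples covering 9.995-10.020 s are
        replaced and nothing outside the outward-rounded window changes."""
        rng = np.random.default_rng(1)
        data = rng.normal(size=(16, 5000))
        rec = make_rec(data, layout16, tms_times=[10.0])
        out = preprocess.excise_tms_artifact(rec)
        changed = np.flatnonzero(np.any(out.data != data, axis=0))
        lo, hi = changed.min(), changed.max()
        assert lo / 250.0 <= 9.995 and hi / 250.0 >= 10.020
        assert lo == int(np.floor(9.995 * 250)) and hi == int(np.ceil(10.020 * 250))

    def test_linear_ramp_restored_exactly_by_linear_fill(self, layout16):
        t = np.arange(5000) / 250.0
        data = np.tile(3.0 * t + 1.0, (16, 1))
        data_art = data.copy()
        data_art[:, 2498:2506] += 500.0  # artifact inside the window
        rec = make_rec(data_art, layout16, tms_times=[10.0])
        out = preprocess.excise_tms_artifact(rec, method="linear")
        assert np.allclose(out.data, data, atol=1e-9)

    def test_window_exceeding_pulse_gap_rejected(self, layout16):
        rng = np.random.default_rng(2)
        rec = make_rec(rng.normal(size=(16, 5000)), layout16, tms_times=[10.0, 10.01])
        with pytest.raises(InvalidParameterError, match="pulse"):
            preprocess.excise_tms_artifact(rec)

    def test_artifact_actually_removed(self, layout16):
        """After excision no sample in the window exceeds 5x the pre-pulse
        robust amplitude."""
        rng = np.random.default_rng(3)
        data = rng.normal(size=(16, 5000))
        data[:, 2500:2503] += 2000.0
        rec = make_rec(data, layout16, tms_times=[10.0])
        out = preprocess.excise_tms_artifact(rec)
        pre = out.data[:, 2000:2400]
        robust = 1.4826 * np.median(np.abs(pre - np.median(pre)))
        assert np.max(np.abs(out.data[:, 2498:2506])) < 5 * max(robust, 1.0)


class TestFilters:
    def test_notch_removes_mains_tone(self, layout16):
        t = np.arange(10000) / 250.0
        rec = make_rec(np.tile(np.sin(2 * np.pi * 50 * t), (16, 1)), layout16)
        out = preprocess.remove_line_noise(rec)
        assert np.sqrt(np.mean(out.data[:, 500:-500] ** 2)) < 0.01 * np.sqrt(0.5)

    def test_notch_leaves_dc_and_low_frequencies(self, layout16):
        rec = make_rec(np.full((16, 5000), 7.0), layout16)
        out = preprocess.remove_line_noise(rec)
        assert np.allclose(out.data, 7.0, atol=1e-6)
        t = np.arange(10000) / 250.0
        rec10 = make_rec(np.tile(np.sin(2 * np.pi * 10 * t), (16, 1)), layout16)
        out10 = preprocess.remove_line_noise(rec10)
        mid = out10.data[0, 2000:8000]
        assert np.max(np.abs(mid)) == pytest.approx(1.0, rel=0.01)

    def test_notch_above_nyquist_rejected(self, layout16):
        rec = make_rec(np.zeros((16, 1000)), layout16)
        with pytest.raises(InvalidParameterError):
            preprocess.remove_line_noise(rec, freq_hz=130.0)

    def test_detrend_removes_line_and_preserves_noise(self, layout16):
        t = np.arange(5000)
        line = np.tile(0.5 * t + 20.0, (16, 1))
        rec = make_rec(line, layout16)
        assert np.allclose(preprocess.detrend(rec).data, 0.0, atol=1e-8)
        rng = np.random.default_rng(0)
        noise = rng.normal(size=(16, 5000))
        out = preprocess.detrend(make_rec(noise, layout16))
        assert np.all(np.abs(out.data.var(axis=1) / noise.var(axis=1) - 1) < 0.05)

    def test_lowpass_passband_and_stopband(self, layout16):
        t = np.arange(10000) / 250.0
        for freq, ok in [(5.0, True), (70.0, False)]:
            rec = make_rec(np.tile(np.sin(2 * np.pi * freq * t), (16, 1)), layout16)
            out = preprocess.filter_lowpass(rec)
            amp = np.max(np.abs(out.data[0, 2000:8000]))
            if ok:
                assert amp == pytest.approx(1.0, rel=0.02)
            else:
                assert amp < 0.1

    def test_lowpass_spec_attenuation_and_ripple(self):
        """>= 20 dB at 1.5x cutoff; passband ripple < 1 dB (frequency
        response of the zero-phase filter)."""
        from scipy import signal as sps

        taps = sps.firwin(101, 35, fs=250.0)
        w, h = sps.freqz(taps, worN=4096, fs=250.0)
        gain_db = 20 * np.log10(np.maximum(np.abs(h) ** 2, 1e-12))  # filtfilt
        assert gain_db[np.argmin(np.abs(w - 52.5))] <= -20.0
        assert np.all(np.abs(gain_db[w <= 30.0]) < 1.0)

    def test_lowpass_dc_unchanged(self, layout16):
        rec = make_rec(np.full((16, 5000), 3.3), layout16)
        out = preprocess.filter_lowpass(rec)
        assert np.allclose(out.data, 3.3, atol=1e-6)


class TestBadChannels:
    def test_homogeneous_noise_flags_nothing(self, layout16):
        rng = np.random.default_rng(0)
        rec = make_rec(rng.normal(size=(16, 10000)), layout16)
        assert preprocess.detect_bad_channels(rec) == []

    def test_scaled_channel_is_flagged(self, layout16):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(16, 10000))
        data[5] *= 50.0
        rec = make_rec(data, layout16)
        assert preprocess.detect_bad_channels(rec) == [5]

    def test_two_corrupted_channels_both_flagged(self, layout16):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(16, 10000))
        data[3] *= 40.0
        data[11] *= 60.0
        rec = make_rec(data, layout16)
        assert preprocess.detect_bad_channels(rec) == [3, 11]

    def test_interpolation_identity_on_empty_list(self, layout16):
        rng = np.random.default_rng(3)
        rec = make_rec(rng.normal(size=(16, 1000)), layout16)
        out = preprocess.interpolate_channels(rec, [])
        assert np.array_equal(out.data, rec.data)

    def test_interpolation_copies_identical_neighbors(self, layout16):
        common = np.sin(np.arange(1000) / 40.0)
        data = np.tile(common, (16, 1))
        data[7] = 999.0
        rec = make_rec(data, layout16)
        out = preprocess.interpolate_channels(rec, [7])
        assert np.allclose(out.data[7], common)
        assert np.array_equal(out.data[:7], data[:7])  # good channels untouched

    def test_interpolation_matches_direct_idw_oracle(self, layout16):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(16, 500))
        rec = make_rec(data, layout16)
        bad = 2
        out = preprocess.interpolate_channels(rec, [bad], k=4)
        good = [i for i in range(16) if i != bad]
        d = np.linalg.norm(layout16.positions[good] - layout16.positions[bad], axis=1)
        order = np.argsort(d)[:4]
        w = 1.0 / d[order]
        w /= w.sum()
        oracle = w @ data[np.asarray(good)[order]]
        assert np.allclose(out.data[bad], oracle)


class TestEpoching:
    def test_constant_signal_yields_zero_epochs(self, layout16):
        sched = synth.generate_trial_schedule(n_trials=3, iti_range_s=(5, 5), seed=0)
        n = int(sched.duration_s * 250) + 500
        rec = RawRecording(data=np.full((16, n), 42.0), fs_hz=250.0,
                          schedule=sched, layout=layout16)
        ep = preprocess.epoch_and_baseline(rec)
        assert np.allclose(ep.data, 0.0, atol=1e-12)

    def test_epoch_count_matches_default_schedule(self, quiet_recording):
        ep = preprocess.epoch_and_baseline(quiet_recording)
        assert ep.n_epochs == 90
        assert ep.times_ms[0] == -500.0 and ep.times_ms[-1] == 2000.0

    def test_baseline_matches_direct_mean_subtraction(self, layout16):
        rng = np.random.default_rng(5)
        sched = synth.generate_trial_schedule(n_trials=2, iti_range_s=(5, 5), seed=1)
        n = int(sched.duration_s * 250) + 500
        data = rng.normal(size=(16, n))
        rec = RawRecording(data=data, fs_hz=250.0, schedule=sched, layout=layout16)
        ep = preprocess.epoch_and_baseline(rec)
        fs = 250.0
        for k, trial in enumerate(sched.trials):
            onset = int(round(trial.cue_onset_s * fs))
            raw = data[:, onset - 125 : onset + 501]
            base = raw[:, :125].mean(axis=1, keepdims=True)
            assert np.allclose(ep.data[k], raw - base)
            # per-channel baseline mean is zero after correction
            assert np.allclose(ep.data[k][:, :125].mean(axis=1), 0.0, atol=1e-12)

    def test_trial_near_edge_dropped_with_warning(self, layout16, caplog):
        sched = synth.generate_trial_schedule(n_trials=3, iti_range_s=(5, 5),
                                              lead_in_s=0.1, seed=0)
        n = int(sched.duration_s * 250) + 500
        rec = RawRecording(data=np.zeros((16, n)), fs_hz=250.0, schedule=sched,
                          layout=layout16)
        with caplog.at_level(logging.WARNING):
            ep = preprocess.epoch_and_baseline(rec)
        assert ep.n_epochs == 2
        assert any("dropped" in r.message for r in caplog.records)


class TestTrialSelection:
    def test_default_schedule_gives_36_per_condition(self, quiet_recording):
        ep = preprocess.epoch_and_baseline(quiet_recording)
        out = preprocess.select_analysis_trials(ep)
        assert int(np.sum(out.conditions == "T")) == 36
        assert int(np.sum(out.conditions == "NT")) == 36

    def test_no_us_pairing_removes_nothing(self, layout16):
        sched = synth.generate_trial_schedule(n_trials=6, frac_us=0.0,
                                              iti_range_s=(5, 5), seed=0)
        n = int(sched.duration_s * 250) + 500
        rec = RawRecording(data=np.zeros((16, n)), fs_hz=250.0, schedule=sched,
                          layout=layout16)
        out = preprocess.select_analysis_trials(preprocess.epoch_and_baseline(rec))
        assert out.n_epochs == 6

    def test_all_us_csplus_leaves_zero_threat_epochs(self, layout16, caplog):
        sched = synth.generate_trial_schedule(n_trials=6, frac_csplus=0.5,
                                              frac_us=1.0, iti_range_s=(5, 5), seed=0)
        n = int(sched.duration_s * 250) + 500
        rec = RawRecording(data=np.zeros((16, n)), fs_hz=250.0, schedule=sched,
                          layout=layout16)
        with caplog.at_level(logging.WARNING):
            out = preprocess.select_analysis_trials(preprocess.epoch_and_baseline(rec))
        assert int(np.sum(out.conditions == "T")) == 0
        assert any("no threat" in r.message for r in caplog.records)


def test_pipeline_rerun_is_identical(quiet_recording):
    """Identical input and configuration give identical cleaned output."""
    a = preprocess.clean(quiet_recording)
    b = preprocess.clean(quiet_recording)
    assert np.array_equal(a.data, b.data)
    assert a.fs_hz == quiet_recording.fs_hz
    assert a.layout.labels == quiet_recording.layout.labels
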