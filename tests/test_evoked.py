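"""Evoked averaging, peak detection/labelling, markers, regional SNR."""

import numpy as np
import pytest

from fearprobe import evoked, synth
from fearprobe.core import EvokedWaveform, InvalidParameterError, Peak, PeakSet
from tests.conftest import make_epochs

FS = 250.0


def wave_from(values, t0_ms=-500.0, condition="T", labels=None):
    values = np.atleast_2d(values)
    if labels is None:
        labels = [f"E{i:03d}" for i in range(values.shape[0])]
    times = t0_ms + np.arange(values.shape[1]) / FS * 1000.0
    return EvokedWaveform(condition=condition, values=values, times_ms=times,
                          n_trials=1, row_labels=labels)


def brute_force_peaks(v, times, window, flank=3):
    """Exhaustive scan: every sample whose `flank` neighbours on both
    sides are all strictly smaller (max) or larger (min)."""
    out = []
    for i in range(flank, len(v) - flank):
        if not (window[0] <= times[i] <= window[1]):
            continue
        left, right = v[i - flank : i], v[i + 1 : i + 1 + flank]
        if np.all(left < v[i]) and np.all(right < v[i]):
            out.append((times[i], v[i]))
        elif np.all(left > v[i]) and np.all(right > v[i]):
            out.append((times[i], v[i]))
    return out


class TestAverage:
    def test_single_epoch_identity(self, layout16):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(1, 16, 200))
        ep = make_epochs(data, FS, layout16)
        ev = evoked.average_evoked(ep, "T")
        assert np.array_equal(ev.values, data[0])
        assert ev.n_trials == 1

    def test_two_constant_epochs_average(self, layout16):
        data = np.stack([np.full((16, 100), 2.0), np.full((16, 100), 6.0)])
        ep = make_epochs(data, FS, layout16)
        assert np.allclose(evoked.average_evoked(ep, "T").values, 4.0)

    def test_missing_condition_rejected(self, layout16):
        ep = make_epochs(np.zeros((2, 16, 50)), FS, layout16)
        with pytest.raises(InvalidParameterError):
            evoked.average_evoked(ep, "NT")


class TestDetectPeaks:
    def test_single_hann_bump_gives_one_peak_at_apex(self):
        t = np.arange(400) / FS * 1000.0 - 500.0
        v = np.zeros_like(t)
        center = 300.0
        x = (t - center) / 80.0
        m = np.abs(x) <= 0.5
        v[m] = 0.5 * (1 + np.cos(2 * np.pi * x[m]))
        peaks = evoked.detect_peaks(wave_from(v), (0.0, 900.0))
        assert len(peaks) == 1
        assert peaks.peaks[0].latency_ms == pytest.approx(center, abs=1.0)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle_on_random_waveforms(self, seed):
        """Sample-grid peak list identical to the exhaustive scan."""
        rng = np.random.default_rng(seed)
        v = rng.normal(size=300)
        w = wave_from(v)
        window = (-100.0, 500.0)
        got = evoked.detect_peaks(w, window, refine=False)
        expected = brute_force_peaks(v, w.times_ms, window)
        assert [(p.latency_ms, p.amplitude_uV) for p in got] == [
            (pytest.approx(t), pytest.approx(a)) for t, a in expected
        ]

    def test_negative_peaks_reported_with_signed_amplitude(self):
        t = np.arange(300)
        v = -np.exp(-((t - 150.0) ** 2) / 50.0)
        peaks = evoked.detect_peaks(wave_from(v), (-400.0, 600.0), refine=False)
        assert len(peaks) == 1
        assert peaks.peaks[0].amplitude_uV < 0

    def test_plateau_does_not_qualify(self):
        v = np.zeros(100)
        v[40:45] = 1.0  # flat top: strict inequality fails
        peaks = evoked.detect_peaks(wave_from(v), (-400.0, -200.0), refine=False)
        assert len(peaks) == 0

    def test_window_too_short_rejected(self):
        w = wave_from(np.zeros(100))
        with pytest.raises(InvalidParameterError):
            evoked.detect_peaks(w, (-500.0, -490.0))

    def test_parabolic_refinement_recovers_off_grid_apex(self):
        """A smooth bump centred between samples is localized to sub-sample
        accuracy."""
        t = (np.arange(500) / FS) * 1000.0 - 500.0
        center = 141.0  # not a multiple of 4 ms
        x = (t - center) / 100.0
        v = np.where(np.abs(x) <= 0.5, 0.5 * (1 + np.cos(2 * np.pi * x)), 0.0)
        peaks = evoked.detect_peaks(wave_from(v), (0.0, 900.0), refine=True)
        assert len(peaks) == 1
        assert peaks.peaks[0].latency_ms == pytest.approx(center, abs=0.3)


class TestLabelPeaks:
    def make_peaks(self, entries, condition="T"):
        return PeakSet(
            peaks=[Peak("unlabelled", lat, amp, "E000") for lat, amp in entries],
            condition=condition,
        )

    def test_six_post_tms_bumps_labelled_in_latency_order(self):
        lats = [1041.0, 1057.0, 1081.0, 1117.0, 1197.0, 1317.0]
        amps = [16.0, -6.0, 12.0, -12.0, 12.0, -14.0]
        out = evoked.label_peaks(self.make_peaks(list(zip(lats, amps))), "tep")
        labelled = out.labelled()
        for k, lat in enumerate(lats):
            assert labelled[f"TEP{k + 1}"].latency_ms == lat

    def test_empty_peakset_stays_empty(self):
        out = evoked.label_peaks(self.make_peaks([]), "tep")
        assert len(out) == 0

    def test_single_late_bump_is_lpp_without_erp152(self):
        out = evoked.label_peaks(self.make_peaks([(500.0, 10.0)]), "erp")
        labelled = out.labelled()
        assert set(labelled) == {"LPP"}

    def test_erp_scheme_first_supra_threshold_peak_is_erp152(self):
        out = evoked.label_peaks(
            self.make_peaks([(120.0, 1.0), (152.0, 8.0), (200.0, 9.0), (500.0, 12.0)]),
            "erp", min_amplitude_uV=2.0,
        )
        labelled = out.labelled()
        assert labelled["ERP152"].latency_ms == 152.0
        assert labelled["LPP"].latency_ms == 500.0

    def test_unknown_scheme_rejected(self):
        with pytest.raises(InvalidParameterError):
            evoked.label_peaks(self.make_peaks([]), "xyz")


class TestMarkers:
    def labelled(self, amps, condition):
        return PeakSet(
            peaks=[Peak(lab, lat, amp, "E000") for lab, lat, amp in amps],
            condition=condition,
        )

    def test_identical_conditions_give_zero_markers(self):
        pk = [("ERP152", 152.0, 8.0), ("LPP", 500.0, 20.0)]
        m = evoked.tnt_markers(self.labelled(pk, "T"), self.labelled(pk, "NT"))
        assert np.allclose(m["marker_uV"], 0.0)

    def test_amplitude_difference_is_t_minus_nt(self):
        m = evoked.tnt_markers(
            self.labelled([("LPP", 500.0, 10.0)], "T"),
            self.labelled([("LPP", 500.0, 4.0)], "NT"),
        )
        assert m["marker_uV"].tolist() == [6.0]

    def test_component_missing_in_one_condition_skipped_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="fearprobe.evoked"):
            m = evoked.tnt_markers(
                self.labelled([("LPP", 500.0, 10.0), ("ERP152", 152.0, 5.0)], "T"),
                self.labelled([("LPP", 500.0, 4.0)], "NT"),
            )
        assert m["label"].tolist() == ["LPP"]
        assert any("only one condition" in r.message for r in caplog.records)

    def test_peak_to_peak_equal_amplitudes_zero(self):
        pk = self.labelled([("Cue", 0.0, 5.0), ("ERP152", 152.0, 5.0)], "T")
        pp = evoked.peak_to_peak(pk)
        assert pp["value_uV"].tolist() == [0.0]

    def test_peak_to_peak_matches_direct_subtraction_and_naming(self):
        pk = self.labelled(
            [("Cue", 0.0, 1.0), ("ERP152", 152.0, 8.0), ("LPP", 500.0, 20.0),
             ("TMS", 1000.0, 3.0), ("TEP1", 1041.0, 16.0), ("TEP2", 1057.0, -6.0)],
            "T",
        )
        pp = evoked.peak_to_peak(pk)
        assert pp["pair"].tolist() == [
            "0-to-ERP152", "ERP152-to-LPP", "LPP-to-TMS", "TMS-to-TEP41",
            "TEP41-to-TEP57",
        ]
        assert pp["value_uV"].tolist() == [7.0, 12.0, -17.0, 13.0, -22.0]

    def test_tnt_peak_to_peak_differences(self):
        pk_t = self.labelled([("Cue", 0.0, 0.0), ("LPP", 500.0, 20.0)], "T")
        pk_nt = self.labelled([("Cue", 0.0, 0.0), ("LPP", 500.0, 12.0)], "NT")
        out = evoked.tnt_peak_to_peak(
            evoked.peak_to_peak(pk_t), evoked.peak_to_peak(pk_nt)
        )
        assert out["marker_uV"].tolist() == [8.0]


class TestRegionalAverage:
    def test_identical_channels_preserved(self, layout16):
        v = np.tile(np.sin(np.arange(100) / 10.0), (16, 1))
        reg = evoked.regional_average(wave_from(v, labels=list(layout16.labels)),
                                      layout16)
        assert reg.kind == "regions"
        for row in reg.values:
            assert np.allclose(row, v[0])

    def test_scaling_one_region_only_scales_that_region(self, layout16):
        v = np.ones((16, 50))
        idx = layout16.region_channels("frontal")
        v[idx] *= 2.0
        reg = evoked.regional_average(wave_from(v, labels=list(layout16.labels)),
                                      layout16)
        frontal_row = reg.row_labels.index("frontal")
        assert np.allclose(reg.values[frontal_row], 2.0)
        for r, name in enumerate(reg.row_labels):
            if name != "frontal":
                assert np.allclose(reg.values[r], 1.0)

    def test_matches_group_mean_oracle(self, layout16):
        rng = np.random.default_rng(3)
        v = rng.normal(size=(16, 80))
        reg = evoked.regional_average(wave_from(v, labels=list(layout16.labels)),
                                      layout16)
        for r, name in enumerate(reg.row_labels):
            oracle = v[layout16.region_channels(name)].mean(axis=0)
            assert np.allclose(reg.values[r], oracle)


class TestSnr:
    def build(self, signal_level, noise_level):
        t = np.arange(-500.0, 2001.0, 4.0)
        v = np.where((t >= 0) & (t <= 500.0), signal_level, 0.0)
        v = np.where(t < 0, noise_level, v).astype(float)
        return EvokedWaveform(condition="T", values=v[None, :], times_ms=t,
                              n_trials=10, row_labels=["E000"])

    def test_equal_windows_give_zero_db(self):
        res = evoked.compute_snr(self.build(3.0, 3.0), (0.0, 500.0), (-500.0, 0.0))
        assert res.snr_db == pytest.approx(0.0, abs=1e-12)

    def test_tenfold_ratio_gives_twenty_db(self):
        res = evoked.compute_snr(self.build(30.0, 3.0), (0.0, 500.0), (-500.0, 0.0))
        assert res.snr_db == pytest.approx(20.0, abs=1e-9)

    def test_matches_independent_formula_oracle(self, layout16):
        rng = np.random.default_rng(9)
        data = rng.normal(size=(8, 16, 626))
        ep = make_epochs(data, FS, layout16)
        res = evoked.compute_snr(ep, (100.0, 600.0), (-500.0, 0.0))
        avg = data.mean(axis=0)
        times = ep.times_ms
        tl_s = np.mean(np.abs(avg[:, (times >= 100.0) & (times <= 600.0)]))
        tl_n = np.mean(np.abs(avg[:, (times >= -500.0) & (times < 0.0)]))
        assert res.snr_db == pytest.approx(20 * np.log10(tl_s / tl_n), abs=1e-9)

    def test_invariant_under_global_positive_rescaling(self, layout16):
        rng = np.random.default_rng(10)
        data = rng.normal(size=(4, 16, 626))
        a = evoked.compute_snr(make_epochs(data, FS, layout16),
                               (0.0, 500.0), (-500.0, 0.0))
        b = evoked.compute_snr(make_epochs(data * 7.3, FS, layout16),
                               (0.0, 500.0), (-500.0, 0.0))
        assert a.snr_db == pytest.approx(b.snr_db, abs=1e-9)

    def test_wrong_signal_window_length_rejected(self):
        with pytest.raises(InvalidParameterError):
            evoked.compute_snr(self.build(1.0, 1.0), (0.0, 400.0), (-500.0, 0.0))

    def test_zero_baseline_rejected(self):
        w = self.build(1.0, 0.0)
        with pytest.raises(InvalidParameterError):
            evoked.compute_snr(w, (0.0, 500.0), (-500.0, 0.0))


class TestParameterRecovery:
    def test_injected_condition_effect_recovered_across_subjects(self, layout16):
        """Across 50 synthetic subjects with a LPP-only T-NT effect, the
        mean LPP marker is within 2 SE of the injected effect and the null
        ERP152 marker within 2 SE of 0 (epoch-level simulation)."""
        delta = 6.0
        rng = np.random.default_rng(42)
        t = np.arange(-500.0, 2001.0, 4.0)
        lpp = np.where(np.abs(t - 500.0) <= 300.0,
                       0.5 * (1 + np.cos(2 * np.pi * (t - 500.0) / 1200.0)), 0.0)
        erp = np.where(np.abs(t - 152.0) <= 30.0,
                       0.5 * (1 + np.cos(2 * np.pi * (t - 152.0) / 120.0)), 0.0)
        lpp_markers, erp_markers = [], []
        for _ in range(50):
            amps = {"T": (10.0 + delta, 8.0), "NT": (10.0, 8.0)}
            res = {}
            for cond, (a_lpp, a_erp) in amps.items():
                n_tr = 36
                base = a_lpp * lpp + a_erp * erp
                epochs = base[None, None, :] + rng.normal(
                    0, 4.0, size=(n_tr, 1, t.size)
                )
                avg = epochs.mean(axis=0)
                w = EvokedWaveform(condition=cond, values=avg, times_ms=t,
                                   n_trials=n_tr, row_labels=["E000"])
                pk = evoked.label_peaks(
                    evoked.detect_peaks(w, (0.0, 1000.0)), "erp",
                    min_amplitude_uV=1.0,
                )
                res[cond] = pk.labelled()
            if "LPP" in res["T"] and "LPP" in res["NT"]:
                lpp_markers.append(res["T"]["LPP"].amplitude_uV
                                   - res["NT"]["LPP"].amplitude_uV)
            if "ERP152" in res["T"] and "ERP152" in res["NT"]:
                erp_markers.append(res["T"]["ERP152"].amplitude_uV
                                   - res["NT"]["ERP152"].amplitude_uV)
        lpp_markers, erp_markers = np.array(lpp_markers), np.array(erp_markers)
        assert len(lpp_markers) >= 45 and len(erp_markers) >= 45
        se = lpp_markers.std(ddof=1) / np.sqrt(len(lpp_markers))
        assert abs(lpp_markers.mean() - delta) < 2 * se + 0.2
        se0 = erp_markers.std(ddof=1) / np.sqrt(len(erp_markers))
        assert abs(erp_markers.mean()) < 2 * se0 + 0.2


def test_select_marker_channel_grand_average_targets_component_maximum(layout16):
    rng = np.random.default_rng(1)
    v_t = rng.normal(0, 0.1, size=(16, 626))
    v_nt = rng.normal(0, 0.1, size=(16, 626))
    t = np.arange(-500.0, 2001.0, 4.0)
    bump = np.where(np.abs(t - 152.0) <= 30.0, 10.0, 0.0)
    v_t[5] += bump
    v_nt[5] += bump
    w_t = EvokedWaveform("T", v_t, t, 10, [f"E{i:03d}" for i in range(16)])
    w_nt = EvokedWaveform("NT", v_nt, t, 10, [f"E{i:03d}" for i in range(16)])
    assert evoked.select_marker_channel(w_t, w_nt, (100.0, 250.0)) == "E005"


class TestPeakDetectorProperties:
    """Property-based check: the detector equals the exhaustive scan on
    arbitrary waveforms, and refinement never moves an apex by more than
    half a sample."""

    from hypothesis import given, settings, strategies as st
    from hypothesis.extra import numpy as hnp

    @given(hnp.arrays(np.float64, st.integers(30, 120),
                      elements=st.floats(-50, 50, allow_nan=False)))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_equals_brute_force_on_arbitrary_waveforms(self, v):
        w = wave_from(v)
        window = (float(w.times_ms[0]), float(w.times_ms[-1]))
        got = evoked.detect_peaks(w, window, refine=False)
        expected = brute_force_peaks(v, w.times_ms, window)
        assert [(p.latency_ms, p.amplitude_uV) for p in got] == expected

    @given(hnp.arrays(np.float64, st.integers(30, 120),
                      elements=st.floats(-50, 50, allow_nan=False)))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_refinement_stays_within_half_a_sample(self, v):
        w = wave_from(v)
        window = (float(w.times_ms[0]), float(w.times_ms[-1]))
        grid = evoked.detect_peaks(w, window, refine=False)
        refined = evoked.detect_peaks(w, window, refine=True)
        assert len(grid) == len(refined)
        for g, r in zip(grid, refined):
            assert abs(g.latency_ms - r.latency_ms) <= 2.0 + 1e-9  # half of 4 ms
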