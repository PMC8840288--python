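import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stressreport.features import (
    FeatureMatrix,
    Window,
    detect_r_peaks,
    eda_features,
    emg_features,
    extract_features,
    hrv_frequency_features,
    hrv_time_features,
    nn_intervals,
    resp_features,
    segment_windows,
    temp_features,
)
from stressreport.registry import (
    FEATURE_NAMES,
    InsufficientBeatsError,
    StressReportError,
)
from stressreport.synthetic import Recording, default_subject_params, simulate_subject


def _labels_only_recording(intervals):
    """Recording stub carrying only label intervals (for windowing tests)."""
    dur = intervals[-1][1]
    fs = 4.0
    n = int(dur * fs)
    chan = (np.zeros(n), fs)
    return Recording(
        subject_id="X",
        channels={name: chan for name in
                  ("ecg", "emg_chest", "eda_chest", "eda_wrist", "temp_wrist", "resp")},
        label_intervals=intervals,
    )


class TestSegmentWindows:
    def test_floor_division_placement(self):
        rec = _labels_only_recording([(0.0, 270.0, "baseline")])
        assert len(segment_windows(rec, 90.0, 90.0)) == 3

    def test_short_recording_single_window(self):
        rec = _labels_only_recording([(0.0, 100.0, "baseline")])
        assert len(segment_windows(rec, 90.0, 30.0)) == 1

    def test_matches_brute_force_placement_oracle(self):
        intervals = [(0.0, 1200.0, "baseline"), (1200.0, 1560.0, "amusement"),
                     (1560.0, 2160.0, "stress")]
        rec = _labels_only_recording(intervals)
        windows = segment_windows(rec, 90.0, 30.0)
        # oracle: enumerate every stride placement and test containment
        expected = [
            (s0 + 30.0 * k, cond)
            for (s0, e0, cond) in intervals
            for k in range(int((e0 - s0) / 30.0) + 1)
            if s0 + 30.0 * k + 90.0 <= e0 + 1e-9
        ]
        assert [(w.start_s, w.condition) for w in windows] == expected

    def test_stress_windows_labelled_positive(self):
        rec = _labels_only_recording([(0.0, 90.0, "amusement"), (90.0, 180.0, "stress")])
        ws = segment_windows(rec, 90.0, 90.0)
        assert [w.y for w in ws] == [0, 1]

    def test_recording_shorter_than_window_yields_empty(self):
        rec = _labels_only_recording([(0.0, 50.0, "baseline")])
        assert segment_windows(rec, 90.0, 30.0) == []


class TestRPeakDetection:
    def test_impulse_train_recovered_at_impulse_locations(self):
        fs = 256.0
        n = int(90 * fs)
        x = np.zeros(n)
        locs = (np.arange(90) * fs).astype(int)  # exactly 1 Hz
        x[locs] = 1.0
        peaks = detect_r_peaks(x, fs)
        assert abs(len(peaks) - 90) <= 1
        assert np.all(np.isin(peaks, locs))

    def test_all_zero_signal_gives_no_peaks(self):
        assert len(detect_r_peaks(np.zeros(1024), 256.0)) == 0

    def test_simulated_72bpm_count(self):
        p = default_subject_params(seed=0, jitter_scale=0.0)
        p.hr_mean_bpm = {c: 72.0 for c in p.hr_mean_bpm}
        p.sdnn_ms = {c: 5.0 for c in p.sdnn_ms}
        p.modulation = {k: 0.0 for k in p.modulation}  # fixed-rate train
        rec = simulate_subject(p, [("baseline", 90.5)], seed=3)
        peaks = detect_r_peaks(*rec.channels["ecg"])
        assert abs(len(peaks) - 108) <= 2

    def test_amplitude_scaling_does_not_move_peaks(self):
        p = default_subject_params(seed=0, jitter_scale=0.0)
        rec = simulate_subject(p, [("baseline", 120.0)], seed=4)
        samples, fs = rec.channels["ecg"]
        assert np.array_equal(detect_r_peaks(samples, fs), detect_r_peaks(3.5 * samples, fs))


class TestNNIntervals:
    def test_regular_train(self):
        peaks = np.arange(0, 250 * 20, 250)
        assert np.all(nn_intervals(peaks, 250.0) == 1000.0)

    def test_spurious_split_beat_rejected_by_range_rule(self):
        # 1000 ms rhythm with one extra peak splitting a beat into 100+900 ms
        fs = 1000.0
        peaks = [0, 1000, 2000, 2100, 3000, 4000, 5000]
        nn = nn_intervals(np.array(peaks), fs)
        assert 100.0 not in nn
        assert nn.min() >= 300.0

    def test_dropout_gap_rejected(self):
        fs = 1000.0
        peaks = [0, 1000, 2000, 5000, 6000, 7000]  # 3 s dropout
        nn = nn_intervals(np.array(peaks), fs)
        assert 3000.0 not in nn

    def test_too_few_peaks_raises(self):
        with pytest.raises(InsufficientBeatsError):
            nn_intervals(np.array([0, 250, 500]), 250.0)


class TestHrvTime:
    def test_hand_computed_statistics(self):
        out = hrv_time_features(np.array([800.0, 810.0, 790.0, 805.0, 795.0]))
        assert out["RMSSD_NN"] == pytest.approx(np.sqrt(825.0 / 4.0), abs=1e-9)
        assert out["Mad_NN"] == 5.0
        assert out["Med_NN"] == 800.0
        assert out["MCV_NN"] == pytest.approx(0.00625)

    def test_constant_series_degenerates_to_zero_variability(self):
        out = hrv_time_features(np.full(10, 1000.0))
        assert out["mu_HR"] == 60.0
        assert out["sigma_HR"] == 0.0
        assert out["RMSSD_NN"] == 0.0
        assert out["pNN20"] == 0.0 and out["pNN50"] == 0.0

    def test_pnn_thresholds_counted_by_hand(self):
        out = hrv_time_features(np.array([800.0, 825.0, 810.0, 800.0]))
        # successive differences: 25, -15, -10
        assert out["pNN20"] == pytest.approx(100.0 / 3.0)
        assert out["pNN50"] == 0.0


class TestHrvFrequency:
    @staticmethod
    def _modulated(freq_hz):
        times, nn = [0.0], []
        while times[-1] < 120.0:
            nn_ms = 1000.0 + 100.0 * np.sin(2 * np.pi * freq_hz * times[-1])
            nn.append(nn_ms)
            times.append(times[-1] + nn_ms / 1000.0)
        return np.array(nn), np.array(times[1:])

    def test_hf_modulation_lands_in_hf_band(self):
        nn, t = self._modulated(0.25)
        out = hrv_frequency_features(nn, t)
        assert out["HF_HRV"] > 5 * out["LF_HRV"]

    def test_lf_modulation_lands_in_lf_band(self):
        nn, t = self._modulated(0.10)
        out = hrv_frequency_features(nn, t)
        assert out["LF_HRV"] > 5 * out["HF_HRV"]

    def test_constant_series_has_negligible_power(self):
        nn_mod, t_mod = self._modulated(0.25)
        ref = hrv_frequency_features(nn_mod, t_mod)["HF_HRV"]
        t = np.arange(1.0, 121.0)
        out = hrv_frequency_features(np.full(len(t), 1000.0), t)
        assert out["LF_HRV"] < 1e-6 * ref and out["HF_HRV"] < 1e-6 * ref

    def test_short_span_rejected(self):
        with pytest.raises(InsufficientBeatsError):
            hrv_frequency_features(np.full(30, 1000.0), np.arange(30.0))


class TestEmg:
    def test_all_zero_signal(self):
        out = emg_features(np.zeros(30 * 256), 256.0)
        assert all(v == 0.0 for v in out.values())

    def test_white_noise_rms_recovered(self):
        rng = np.random.default_rng(0)
        out = emg_features(0.1 * rng.standard_normal(90 * 256), 256.0)
        assert out["RMS_EMG"] == pytest.approx(0.1, abs=0.005)

    def test_offset_invariance_of_rms_features(self):
        rng = np.random.default_rng(1)
        x = 0.05 * rng.standard_normal(30 * 256)
        a = emg_features(x, 256.0)
        b = emg_features(x + 2.5, 256.0)
        for key in ("RMS_EMG", "RMS50P_EMG", "RMS90P_EMG", "sigma_EMG"):
            assert a[key] == pytest.approx(b[key], rel=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_rank_ordered_rms_percentiles_monotone(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(15 * 64) * rng.uniform(0.01, 1.0)
        out = emg_features(x, 64.0)
        assert out["RMS50P_EMG"] <= out["RMS90P_EMG"]
        assert out["Min_EMG"] <= out["mu_EMG"] <= out["Max_EMG"]


class TestEda:
    def test_constant_level(self):
        out = eda_features(np.full(60 * 32, 5.0), 32.0, site="chest")
        assert out["mu_ChestEDA"] == out["Max_ChestEDA"] == out["Min_ChestEDA"] == 5.0
        assert out["sigma_ChestEDA"] == 0.0
        assert out["mu_ChestSCL"] == pytest.approx(5.0)
        assert out["mu_ChestSCR"] == pytest.approx(0.0, abs=1e-9)

    def test_slow_ramp_tracked_by_tonic_component(self):
        fs = 32.0
        x = np.linspace(2.0, 4.0, int(90 * fs))
        out = eda_features(x, fs, site="chest")
        assert out["mu_ChestSCL"] == pytest.approx(3.0, abs=0.05)
        assert out["sigma_ChestSCR"] < 0.05 * out["sigma_ChestEDA"]

    def test_phasic_events_raise_scr_variability(self):
        p = default_subject_params(seed=0, jitter_scale=0.0)
        p.scr_rate_per_min = {c: 6.0 for c in p.scr_rate_per_min}
        with_events = simulate_subject(p, [("baseline", 90.0)], seed=5)
        p.scr_rate_per_min = {c: 0.0 for c in p.scr_rate_per_min}
        without = simulate_subject(p, [("baseline", 90.0)], seed=5)
        a = eda_features(*with_events.channels["eda_chest"], site="chest")
        b = eda_features(*without.channels["eda_chest"], site="chest")
        assert a["sigma_ChestSCR"] > b["sigma_ChestSCR"]

    def test_wrist_site_has_no_tonic_phasic_split(self):
        out = eda_features(np.full(60 * 4, 1.0), 4.0, site="wrist")
        assert set(out) == {"mu_WristEDA", "sigma_WristEDA", "Max_WristEDA", "Min_WristEDA"}


class TestResp:
    @pytest.mark.parametrize("freq,expected", [(0.25, 15.0), (0.2, 12.0)])
    def test_sinusoid_rate_recovered(self, freq, expected):
        fs = 64.0
        t = np.arange(int(90 * fs)) / fs
        out = resp_features(np.sin(2 * np.pi * freq * t), fs)
        assert out["mu_RespRate"] == pytest.approx(expected, abs=0.5)
        assert out["sigma_RespRate"] < 0.5

    def test_constant_signal_rejected(self):
        with pytest.raises(InsufficientBeatsError):
            resp_features(np.full(60 * 32, 1.0), 32.0)


class TestTemp:
    def test_constant(self):
        out = temp_features(np.full(100, 34.0))
        assert (out["mu_WristTemp"], out["sigma_WristTemp"]) == (34.0, 0.0)
        assert out["Max_WristTemp"] == out["Min_WristTemp"] == 34.0

    def test_linear_ramp_closed_form(self):
        out = temp_features(np.linspace(33.0, 35.0, 201))
        assert out["mu_WristTemp"] == pytest.approx(34.0)
        assert out["Max_WristTemp"] == 35.0 and out["Min_WristTemp"] == 33.0

    def test_single_sample(self):
        out = temp_features(np.array([34.0]))
        assert out["mu_WristTemp"] == 34.0 and out["sigma_WristTemp"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(StressReportError):
            temp_features(np.array([]))


class TestExtractFeatures:
    def test_canonical_registry_order(self, flat_subject_recording):
        _, rec = flat_subject_recording
        window = Window(rec.subject_id, 0.0, 90.0, "baseline")
        values = extract_features(rec, window)
        assert list(values) == list(FEATURE_NAMES)

    def test_min_mean_max_triples_ordered(self, flat_feature_matrix):
        df = flat_feature_matrix.frame
        for sig in ("HR", "WristEDA", "ChestEDA", "RespRate", "WristTemp", "EMG"):
            assert (df[f"Min_{sig}"] <= df[f"mu_{sig}"] + 1e-12).all()
            assert (df[f"mu_{sig}"] <= df[f"Max_{sig}"] + 1e-12).all()

    def test_rms_percentile_ordering_holds_matrix_wide(self, flat_feature_matrix):
        df = flat_feature_matrix.frame
        assert (df["RMS50P_EMG"] <= df["RMS90P_EMG"]).all()

    def test_identical_windows_identical_vectors(self, flat_subject_recording):
        _, rec = flat_subject_recording
        w = Window(rec.subject_id, 30.0, 90.0, "baseline")
        assert extract_features(rec, w) == extract_features(rec, w)

    def test_extractor_failure_identifies_window(self, flat_subject_recording):
        _, rec = flat_subject_recording
        bad = Recording(
            subject_id=rec.subject_id,
            channels={**rec.channels, "ecg": (np.zeros_like(rec.channels["ecg"][0]),
                                              rec.channels["ecg"][1])},
            label_intervals=rec.label_intervals,
        )
        with pytest.raises(StressReportError, match="window at 0"):
            extract_features(bad, Window(rec.subject_id, 0.0, 90.0, "baseline"))
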