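"""Hand-crafted feature battery: decomposition, SCR detection, statistics,
dPhEDA/TVSymp and the full window-set extraction."""

import numpy as np
import pandas as pd
import pytest

from edapain.features import (FEATURE_REGISTRY, FeatureConfig,
                              decompose_tonic_phasic, detect_scrs, dpheda,
                              extract_features, feature_matrix_from_csv,
                              feature_matrix_to_csv, statistical_features,
                              tvsymp, window_features)
from edapain.synth import EDAWindow, WindowSet, desk_protocol, scr_kernel


def _pulse_trace(fs=32.0, dur=16.0, onset=4.0, amp=0.5, baseline=5.0):
    t = np.arange(int(fs * dur)) / fs
    return baseline + amp * scr_kernel(t - onset)


class TestDecomposition:
    def test_constant_input(self):
        tonic, phasic = decompose_tonic_phasic(np.full(100, 4.2), 10.0)
        assert np.allclose(tonic, 4.2)
        assert np.allclose(phasic, 0.0)

    def test_additivity_exact(self, rng):
        for _ in range(20):
            v = rng.uniform(1, 10, size=200)
            tonic, phasic = decompose_tonic_phasic(v, 25.0)
            assert np.allclose(tonic + phasic, v, atol=1e-12, rtol=0)

    def test_known_pulse_separates(self):
        # one 0.5 µS unit-peak pulse on a flat 5 µS baseline
        x = _pulse_trace()
        tonic, phasic = decompose_tonic_phasic(x, 32.0, tonic_span_s=8.0)
        assert 0.35 <= phasic.max() <= 0.55
        assert np.abs(tonic - 5.0).mean() < 0.1


class TestScrDetection:
    def test_flat_phasic_gives_no_events(self):
        assert detect_scrs(np.zeros(100), 10.0) == []

    def test_single_pulse_detected_with_amplitude(self):
        x = _pulse_trace()
        _, phasic = decompose_tonic_phasic(x, 32.0, tonic_span_s=8.0)
        events = detect_scrs(phasic, 32.0)
        assert len(events) == 1
        e = events[0]
        assert 0.45 <= e.amplitude <= 0.55
        assert e.onset_idx < e.peak_idx
        assert e.rise_time == pytest.approx((e.peak_idx - e.onset_idx) / 32.0)
        assert e.half_recovery is not None and e.half_recovery > 0

    def test_threshold_dominates(self):
        x = _pulse_trace()
        _, phasic = decompose_tonic_phasic(x, 32.0, tonic_span_s=8.0)
        assert detect_scrs(phasic, 32.0, amp_threshold=0.6) == []

    def test_events_ordered_by_onset(self):
        t = np.arange(0, 30, 1 / 16)
        x = 0.4 * scr_kernel(t - 3) + 0.3 * scr_kernel(t - 15)
        events = detect_scrs(x, 16.0)
        assert len(events) == 2
        assert events[0].onset_idx < events[1].onset_idx


class TestStatisticalFeatures:
    def test_constant_trace(self):
        f = statistical_features(np.full(50, 2.5), 10.0)
        assert f["rms"] == pytest.approx(2.5)
        assert f["mavfd"] == 0.0
        assert f["diff_start_end"] == 0.0
        assert f["norm_sd"] == 0.0

    def test_ramp(self):
        f = statistical_features(np.array([0, 0.25, 0.5, 0.75, 1.0]), 1.0)
        assert f["argmax"] == 5 and f["argmin"] == 1
        assert f["diff_start_end"] == 1.0
        assert f["mavfd"] == pytest.approx(0.25)

    def test_against_straight_line_reimplementation(self, rng):
        # independent, formula-by-formula re-derivation
        for _ in range(200):
            x = rng.uniform(0.5, 10, size=rng.integers(10, 80))
            f = statistical_features(x, 10.0)
            d1, d2 = np.diff(x), np.diff(x, n=2)
            z = (x - x.mean()) / x.std()
            nrm = (x - x.min()) / (x.max() - x.min())
            expected = {
                "rms": np.sqrt((x ** 2).mean()),
                "mav": np.abs(x).mean(),
                "mavfd": np.abs(d1).mean(),
                "mavfd_std": np.abs(np.diff(z)).mean(),
                "mavsd": np.abs(d2).mean(),
                "var_moment1": d1.var(),
                "var_moment2": d2.var(),
                "iqr": np.percentile(x, 75) - np.percentile(x, 25),
                "argmax": np.argmax(x) + 1,
                "argmin": np.argmin(x) + 1,
                "diff_start_end": x[-1] - x[0],
                "norm_mean": nrm.mean(),
                "norm_sd": nrm.std(),
                "norm_var": nrm.var(),
            }
            for k, v in expected.items():
                assert f[k] == pytest.approx(v, abs=1e-10), k

    def test_arg_features_invariant_under_monotone_transform(self, rng):
        x = rng.uniform(1, 5, size=60)
        f = statistical_features(x, 10.0)
        g = statistical_features(np.exp(0.3 * x) + 1, 10.0)
        assert f["argmax"] == g["argmax"] and f["argmin"] == g["argmin"]
        assert (f["diff_start_end"] > 0) == (g["diff_start_end"] > 0)


class TestDpheda:
    def test_constant_gives_zero_vector(self):
        assert np.allclose(dpheda(np.full(320, 5.0), 32.0), 0.0)
        assert dpheda(np.full(320, 5.0), 32.0).size == 20

    @pytest.mark.parametrize("n_out", [1, 5, 20, 50])
    def test_output_length_contract(self, n_out):
        out = dpheda(np.linspace(1, 2, 200), 20.0, n_out=n_out)
        assert out.size == n_out

    def test_invalid_n_out(self):
        with pytest.raises(ValueError):
            dpheda(np.ones(100), 10.0, n_out=0)

    def test_pulse_gives_positive_then_negative(self):
        x = _pulse_trace(fs=32.0, dur=16.0, onset=6.0)
        d = dpheda(x, 32.0)
        pos = np.flatnonzero(d > 1e-6)
        neg = np.flatnonzero(d < -1e-6)
        assert pos.size and neg.size
        assert pos[0] < neg[neg > pos[0]][0]


class TestTvsymp:
    def test_constant_gives_zeros(self):
        assert np.allclose(tvsymp(np.full(320, 5.0), 32.0), 0.0)

    def test_band_selectivity(self):
        t = np.arange(0, 20, 1 / 32)
        inband = tvsymp(5 + np.sin(2 * np.pi * 0.16 * t), 32.0).mean()
        outband = tvsymp(5 + np.sin(2 * np.pi * 1.0 * t), 32.0).mean()
        assert inband > outband

    @pytest.mark.parametrize("variant", ["standard", "modified"])
    def test_output_length(self, variant, rng):
        out = tvsymp(rng.uniform(2, 4, 320), 32.0, variant)
        assert out.size == 5

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            tvsymp(np.ones(320), 32.0, "fancy")


class TestExtractFeatures:
    def test_shape_and_registry(self, small_windowset):
        df = extract_features(small_windowset)
        assert df.shape == (len(small_windowset), 2 + len(FEATURE_REGISTRY))
        assert list(df.columns[:2]) == ["subject_id", "label"]
        assert not df.isna().any().any()

    def test_identical_windows_give_identical_rows(self):
        proto = desk_protocol(n_subjects=1, reps_per_label=2)
        v = _pulse_trace(fs=32.0, dur=10.0, onset=3.0)
        wins = [EDAWindow(values=v.copy(), fs=32.0, label="no_pain",
                          subject_id="S0", rep=r) for r in range(2)]
        ws = WindowSet(windows=wins, protocol=proto)
        df = extract_features(ws)
        assert df.iloc[0].equals(df.iloc[1])

    def test_pain_contrast_in_diff_start_end(self, small_windowset):
        df = extract_features(small_windowset)
        by = df.groupby("label")["diff_start_end"].mean()
        assert by["high_pain"] > by["no_pain"]

    def test_scr_count_consistency(self, small_windowset):
        df = extract_features(small_windowset)
        none = df["n_scrs"] == 0
        assert (df.loc[none, "sum_amplitudes"] == 0).all()
        assert (df.loc[none, "first_amplitude"] == 0).all()
        some = ~none
        assert (df.loc[some, "sum_amplitudes"] > 0).all()

    def test_csv_roundtrip(self, small_windowset, tmp_path):
        df = extract_features(small_windowset)
        path = tmp_path / "features.csv"
        feature_matrix_to_csv(df, path)
        back = feature_matrix_from_csv(path)
        pd.testing.assert_frame_equal(df, back, check_exact=False, atol=1e-12)

    def test_empty_set_rejected(self):
        ws = WindowSet(windows=[], protocol=desk_protocol(n_subjects=0))
        with pytest.raises(ValueError):
            extract_features(ws)
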