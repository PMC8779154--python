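"""Feature layer: binning arithmetic, WAMP/WL/RMS oracles, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import emgsleeve as es
from emgsleeve import (BinConfig, EmgRecording, GestureClass, extract_features,
                       normalize_features, rms, segment_bins, wamp,
                       waveform_length)
from emgsleeve.features import (FeatureVector, apply_normalization,
                                calibrate_wamp_threshold, read_features,
                                write_features)

windows = arrays(
    np.float64, st.integers(min_value=2, max_value=40),
    elements=st.floats(-100, 100, allow_nan=False, width=32),
)


class TestSegmentation:
    def test_270ms_bins_at_1khz_have_270_samples(self):
        rec = EmgRecording(np.zeros((1000, 1)), 1000.0)
        for w in segment_bins(rec, BinConfig()):
            assert len(w) == 270

    def test_window_count_with_trailing_discard(self):
        rec = EmgRecording(np.zeros((115_000, 1)), 1000.0)
        assert len(segment_bins(rec, BinConfig())) == 425

    def test_short_recording_yields_zero_windows(self):
        rec = EmgRecording(np.zeros((269, 1)), 1000.0)
        assert segment_bins(rec, BinConfig()) == []

    def test_overlap_half_doubles_density(self):
        rec = EmgRecording(np.zeros((2700, 1)), 1000.0)
        n0 = len(segment_bins(rec, BinConfig()))
        n1 = len(segment_bins(rec, BinConfig(overlap=0.5)))
        assert n1 == 2 * n0 - 1


class TestFeatureOracles:
    """Hand-enumerated values on printed toy windows."""

    def test_wamp_counts_strict_exceedances(self):
        assert wamp(np.array([0.0, 1, 0, 1]), 0.5) == 3

    def test_wamp_strict_inequality_at_threshold(self):
        assert wamp(np.array([0.0, 1, 0, 1]), 1.0) == 0

    def test_wamp_constant_window_is_zero(self):
        assert wamp(np.full(10, 3.3), 0.0) == 0

    def test_waveform_length_hand_enumeration(self):
        assert waveform_length(np.array([0.0, 1, 0, 1])) == pytest.approx(3.0)

    def test_waveform_length_constant_is_zero(self):
        assert waveform_length(np.full(7, 2.0)) == 0.0

    def test_rms_constant_magnitude(self):
        assert rms(np.array([3.0, -3, 3, -3])) == pytest.approx(3.0)

    def test_rms_sqrt_mean_square(self):
        assert rms(np.array([1.0, 2, 3])) == pytest.approx(np.sqrt(14 / 3),
                                                           abs=1e-4)

    def test_rms_zero_window(self):
        assert rms(np.zeros(5)) == 0.0

    @pytest.mark.parametrize("func", [wamp, waveform_length])
    def test_short_window_rejected(self, func):
        with pytest.raises(ValueError):
            (func(np.array([1.0]), 0.1) if func is wamp
             else func(np.array([1.0])))


class TestFeatureProperties:
    @given(x=windows, e1=st.floats(0, 50), e2=st.floats(0, 50))
    @settings(derandomize=True, max_examples=50)
    def test_wamp_non_increasing_in_epsilon(self, x, e1, e2):
        lo, hi = sorted((e1, e2))
        assert wamp(x, lo) >= wamp(x, hi)

    @given(x=windows, eps=st.floats(0, 50))
    @settings(derandomize=True, max_examples=50)
    def test_wl_bounds_epsilon_times_wamp(self, x, eps):
        assert waveform_length(x) >= eps * wamp(x, eps) - 1e-9

    @given(x=windows, c=st.floats(-20, 20, allow_nan=False))
    @settings(derandomize=True, max_examples=50)
    def test_scale_equivariance_of_wl_and_rms(self, x, c):
        assert waveform_length(c * x) == pytest.approx(
            abs(c) * waveform_length(x), rel=1e-9, abs=1e-9)
        assert rms(c * x) == pytest.approx(abs(c) * rms(x),
                                           rel=1e-9, abs=1e-9)

    def test_negation_preserves_wl(self, rng):
        x = rng.normal(size=30)
        assert waveform_length(-x) == pytest.approx(waveform_length(x))


class TestExtract:
    def test_seven_channels_give_21_values(self, short_session):
        feats = extract_features(short_session, BinConfig(), epsilon=1.0)
        assert all(len(f.values) == 21 for f in feats)
        assert len(feats) == len(segment_bins(short_session, BinConfig()))

    def test_all_rest_labels_give_rest_bins(self):
        rec = EmgRecording(np.random.default_rng(0).normal(size=(1000, 2)),
                           1000.0, labels=[GestureClass.Rest] * 1000)
        feats = extract_features(rec, BinConfig(), epsilon=1.0)
        assert all(f.label is GestureClass.Rest for f in feats)

    def test_majority_label_with_tie_falls_to_rest(self):
        labels = ([GestureClass.Index] * 135 + [GestureClass.Middle] * 135
                  + [GestureClass.Rest] * 730)
        rec = EmgRecording(np.zeros((1000, 1)), 1000.0, labels=labels)
        feats = extract_features(rec, BinConfig(), epsilon=1.0)
        # bin 0 splits 135/135 between two poses: tie -> Rest
        assert feats[0].label is GestureClass.Rest

    def test_scaling_recording_scales_wl_rms_keeps_wamp_nondecreasing(self, rng):
        x = rng.normal(size=(540, 1))
        rec = EmgRecording(x, 1000.0)
        rec10 = EmgRecording(10 * x, 1000.0)
        f1 = extract_features(rec, BinConfig(), epsilon=0.5)
        f10 = extract_features(rec10, BinConfig(), epsilon=0.5)
        for a, b in zip(f1, f10):
            assert b.values[1] == pytest.approx(10 * a.values[1])  # WL
            assert b.values[2] == pytest.approx(10 * a.values[2])  # RMS
            assert b.values[0] >= a.values[0]                      # WAMP

    def test_calibrated_epsilon_scales_with_signal(self, short_session):
        e1 = calibrate_wamp_threshold(short_session, 4.0)
        doubled = EmgRecording(2 * short_session.samples, short_session.fs)
        assert calibrate_wamp_threshold(doubled, 4.0) == pytest.approx(2 * e1)


class TestNormalization:
    def _feats(self, X):
        return [FeatureVector(i, i * 0.27, row) for i, row in enumerate(X)]

    def test_self_normalization_max_abs_is_one(self, rng):
        feats = self._feats(rng.normal(size=(20, 6)))
        normed, _ = normalize_features(feats)
        X = np.stack([f.values for f in normed])
        np.testing.assert_allclose(np.max(np.abs(X), axis=0), 1.0)

    def test_zero_dimension_passes_through(self):
        X = np.zeros((5, 3))
        X[:, 1] = np.arange(5)
        normed, consts = normalize_features(self._feats(X))
        out = np.stack([f.values for f in normed])
        np.testing.assert_array_equal(out[:, 0], 0.0)
        assert consts[0] == 0.0

    def test_constants_reapply_identically(self, rng):
        train = self._feats(rng.normal(size=(15, 6)))
        other = self._feats(rng.normal(size=(7, 6)))
        normed_a, consts = normalize_features(train, apply_to=other)
        normed_b = apply_normalization(other, consts)
        for a, b in zip(normed_a, normed_b):
            np.testing.assert_array_equal(a.values, b.values)


def test_feature_csv_roundtrip(tmp_path, short_session):
    feats = extract_features(short_session, BinConfig(), epsilon=1.0)
    path = tmp_path / "features.csv"
    write_features(feats, path)
    back = read_features(path)
    assert len(back) == len(feats)
    for a, b in zip(feats, back):
        np.testing.assert_allclose(a.values, b.values, rtol=1e-8)
        assert a.label == b.label and a.bin_index == b.bin_index
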