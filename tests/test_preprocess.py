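"""Unit conversion, calibration, normalization, windowing and splits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from harfusion import (
    NormalizationParams,
    SensorSpec,
    SixAxisRecording,
    SplitSpec,
    WindowSet,
    calibrate_precision,
    convert_raw,
    fit_minmax,
    flatten_window,
    normalize,
    segment,
    split_dataset,
    unflatten_window,
)
from harfusion.preprocess import holdout_verification, split_accounting
from harfusion.signal_io import RecordingMeta


class TestConvertRaw:
    @pytest.mark.parametrize(
        "channel,count,expected",
        [
            (0, 2048, 1.0),  # 2048 counts = 1 g
            (0, -4096, -2.0),  # linearity
            (3, 16.4, 1.0),  # 16.4 counts = 1 deg/s
            (5, -32.8, -2.0),
        ],
    )
    def test_sensitivity_definitions(self, channel, count, expected):
        counts = np.zeros((1, 6))
        counts[0, channel] = count
        out = convert_raw(counts, SensorSpec())
        assert out[0, channel] == pytest.approx(expected)

    def test_accel_and_gyro_columns_use_different_sensitivities(self):
        out = convert_raw(np.full((2, 6), 2048.0))
        np.testing.assert_allclose(out[:, :3], 1.0)
        np.testing.assert_allclose(out[:, 3:], 2048.0 / 16.4)


class TestCalibratePrecision:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.123456789, 0.1234568),
            (1.0, 1.0),
            (0.0, 0.0),
            (-9.87654321e-5, -9.876543e-5),
            (12345678.0, 12345680.0),
        ],
    )
    def test_seven_significant_digits(self, value, expected):
        assert calibrate_precision(np.array([value]))[0] == pytest.approx(
            expected, rel=1e-12
        )

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_idempotent(self, seed):
        x = np.random.default_rng(seed).uniform(-16, 16, size=1000)
        once = calibrate_precision(x)
        np.testing.assert_array_equal(calibrate_precision(once), once)

    def test_non_finite_is_fatal(self):
        with pytest.raises(ValueError, match="index"):
            calibrate_precision(np.array([1.0, np.nan]))


class TestMinMax:
    def test_fit_and_endpoints(self):
        data = np.zeros((1, 3, 6))
        data[0, :, 0] = [0.0, 5.0, 10.0]
        ws = WindowSet(data, np.array([0]))
        p = fit_minmax(ws)
        assert p.mins[0] == 0 and p.maxs[0] == 10
        out = normalize(ws, p)
        np.testing.assert_allclose(out.data[0, :, 0], [-1.0, 0.0, 1.0])

    def test_degenerate_channel_maps_to_zero(self):
        ws = WindowSet(np.full((2, 4, 6), 3.0), np.array([0, 1]))
        p = fit_minmax(ws)
        assert p.degenerate.all()
        out = normalize(ws, p)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_out_of_range_test_value_clipped(self):
        train = WindowSet(
            np.linspace(0, 10, 12).reshape(1, 2, 6), np.array([0])
        )
        p = NormalizationParams(mins=np.zeros(6), maxs=np.full(6, 10.0))
        test = WindowSet(np.full((1, 2, 6), 12.0), np.array([0]))
        out = normalize(test, p)
        np.testing.assert_array_equal(out.data, 1.0)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_train_set_spans_exactly_minus_one_to_one(self, seed):
        rng = np.random.default_rng(seed)
        ws = WindowSet(
            rng.normal(scale=3, size=(5, 7, 6)), rng.integers(0, 6, 5)
        )
        out = normalize(ws, fit_minmax(ws))
        np.testing.assert_allclose(out.data.min(axis=(0, 1)), -1.0, atol=1e-12)
        np.testing.assert_allclose(out.data.max(axis=(0, 1)), 1.0, atol=1e-12)

    def test_params_never_read_test_data(self, random_ws):
        train = random_ws(n=6, L=8, seed=1)
        test = random_ws(n=4, L=8, seed=2)
        before = fit_minmax(train)
        test.data[:] = 1e6  # mutate test: fitted params must not move
        after = fit_minmax(train)
        np.testing.assert_array_equal(before.mins, after.mins)
        np.testing.assert_array_equal(before.maxs, after.maxs)
        assert np.abs(normalize(test, after).data).max() <= 1.0


def _brute_force_starts(N, L, stride):
    return [s for s in range(0, N) if s + L <= N and s % stride == 0]


class TestSegment:
    def test_window_length_of_256s_at_50hz_is_128(self):
        rec = SixAxisRecording(np.zeros((300, 6)), labels=np.zeros(300, int))
        ws = segment(rec, 2.56, 0.5)
        assert ws.window_len == 128

    def test_enumeration_matches_brute_force(self):
        """N=300, L=128, 50% overlap -> stride 64, starts 0/64/128."""
        rec = SixAxisRecording(
            np.arange(300 * 6, dtype=float).reshape(300, 6),
            labels=np.zeros(300, int),
        )
        ws = segment(rec, 2.56, 0.5)
        starts = _brute_force_starts(300, 128, 64)
        assert len(ws) == len(starts) == 3
        for w, s in zip(ws.data, starts):
            np.testing.assert_array_equal(w, rec.samples[s : s + 128])

    @given(
        st.integers(130, 400),
        st.sampled_from([0.0, 0.25, 0.5, 0.75]),
    )
    @settings(max_examples=30, deadline=None)
    def test_window_count_formula(self, N, overlap):
        rec = SixAxisRecording(np.zeros((N, 6)), labels=np.zeros(N, int))
        ws = segment(rec, 2.56, overlap)
        L = 128
        stride = round(L * (1 - overlap))
        assert len(ws) == (N - L) // stride + 1

    def test_three_seconds_at_50hz_flattens_to_900(self):
        rec = SixAxisRecording(np.zeros((200, 6)), labels=np.zeros(200, int))
        ws = segment(rec, 3.0)
        assert ws.window_len == 150
        assert flatten_window(ws.data[0]).shape == (900,)

    def test_straddling_windows_dropped(self):
        labels = np.concatenate([np.zeros(100, int), np.ones(100, int)])
        rec = SixAxisRecording(np.zeros((200, 6)), labels=labels)
        ws = segment(rec, 1.0, 0.0)  # L=50: window at start 50..100 straddles
        assert len(ws) == 4  # starts 0, 50, 100, 150; none straddle
        labels2 = np.concatenate([np.zeros(75, int), np.ones(125, int)])
        rec2 = SixAxisRecording(np.zeros((200, 6)), labels=labels2)
        ws2 = segment(rec2, 1.0, 0.0)
        assert len(ws2) == 3  # window starting at 50 straddles and is dropped

    def test_short_stream_warns_and_is_empty(self):
        rec = SixAxisRecording(np.zeros((10, 6)), labels=np.zeros(10, int))
        with pytest.warns(UserWarning):
            ws = segment(rec, 3.0)
        assert len(ws) == 0


class TestFlatten:
    def test_blocked_layout(self):
        w = np.arange(1, 13, dtype=float).reshape(2, 6)
        flat = flatten_window(w)
        np.testing.assert_array_equal(
            flat, [1, 7, 2, 8, 3, 9, 4, 10, 5, 11, 6, 12]
        )

    @given(st.integers(0, 2**32 - 1), st.integers(1, 40))
    @settings(max_examples=25, deadline=None)
    def test_unflatten_inverts_flatten(self, seed, L):
        w = np.random.default_rng(seed).normal(size=(L, 6))
        np.testing.assert_array_equal(unflatten_window(flatten_window(w), L), w)


class TestSplit:
    def test_published_per_class_counts(self):
        """One balanced 2,310-window class splits 1,293/324/693."""
        acc = split_accounting(2310)
        assert acc == {"train": 1293, "verification": 324, "test": 693}

    def test_ceiling_holdout_reproduces_1471(self):
        n_ver, n_train = holdout_verification(7352, 0.2)
        assert n_ver == 1471 and n_train == 5881

    def test_unstratified_10_items(self):
        ws = WindowSet(
            np.zeros((10, 4, 6)), np.zeros(10, int)
        )
        tr, ver, te = split_dataset(
            ws, SplitSpec(stratified=False, verification_fraction_of_train=0.0)
        )
        assert len(te) == 3 and len(tr) + len(ver) == 7 and len(ver) == 0

    def test_partition_disjoint_exhaustive_deterministic(self, random_ws):
        ws = random_ws(n=60, L=5, seed=3)
        # tag windows so membership can be tracked through the split
        ws.data[:, 0, 0] = np.arange(60)
        spec = SplitSpec(seed=11)
        parts1 = split_dataset(ws, spec)
        parts2 = split_dataset(ws, spec)
        ids1 = [set(p.data[:, 0, 0].astype(int)) for p in parts1]
        ids2 = [set(p.data[:, 0, 0].astype(int)) for p in parts2]
        assert ids1 == ids2  # same seed, same membership
        assert set().union(*ids1) == set(range(60))
        assert sum(len(s) for s in ids1) == 60  # pairwise disjoint

    def test_stratified_tiny_class_is_fatal(self):
        ws = WindowSet(
            np.zeros((5, 4, 6)), np.array([0, 0, 0, 0, 1])
        )
        with pytest.raises(ValueError, match="class"):
            split_dataset(ws, SplitSpec())

    def test_empty_is_fatal(self):
        ws = WindowSet(np.empty((0, 4, 6)), np.empty(0, int))
        with pytest.raises(ValueError):
            split_dataset(ws, SplitSpec())


class TestSpecValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=0.7, test_fraction=0.2)

    def test_sensitivities_positive(self):
        with pytest.raises(ValueError):
            SensorSpec(accel_sensitivity=0)
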