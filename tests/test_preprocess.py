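"""I/O round-trips, Butterworth filtering, magnitudes, events, stride windows."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stridefatigue import SynthConfig, generate_cohort
from stridefatigue.preprocess import (
    CHANNEL_ORDER,
    RAW_CHANNELS,
    FilterSpec,
    RawRecording,
    SchemaError,
    SegmentationWarning,
    add_magnitude_channels,
    detect_foot_strikes,
    filter_recording,
    frame_to_windows,
    lowpass_filter,
    read_recording,
    segment_and_normalize,
    windows_to_frame,
    write_recording,
)


def toy_recording(n=1000, fs=256.0, seed=0) -> RawRecording:
    rng = np.random.default_rng(seed)
    return RawRecording(
        participant_id="P01",
        condition="NF",
        sampling_rate=fs,
        t=np.arange(n) / fs,
        channels={c: rng.normal(size=n) for c in RAW_CHANNELS},
    )


class TestRecordingIO:
    def test_roundtrip_reproduces_values(self, tmp_path):
        rec = toy_recording()
        path = tmp_path / "P01_NF.csv"
        write_recording(rec, path)
        back = read_recording(path)
        assert back.participant_id == "P01" and back.condition == "NF"
        assert back.sampling_rate == rec.sampling_rate
        for c in RAW_CHANNELS:
            assert np.max(np.abs(back.channels[c] - rec.channels[c])) < 1e-9

    def test_missing_column_names_the_column(self, tmp_path):
        rec = toy_recording(n=50)
        path = tmp_path / "P01_NF.csv"
        write_recording(rec, path)
        df = pd.read_csv(path).drop(columns=["gz"])
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="gz"):
            read_recording(path)

    def test_three_row_fixture_parses_exactly(self, tmp_path):
        path = tmp_path / "toy.csv"
        path.write_text(
            "time,ax,ay,az,gx,gy,gz\n"
            "0.0,1.0,2.0,3.0,4.0,5.0,6.0\n"
            "0.5,1.5,2.5,3.5,4.5,5.5,6.5\n"
            "1.0,-1.0,0.0,9.8,0.0,0.0,0.0\n"
        )
        path.with_suffix(".json").write_text(
            '{"participant_id": "P09", "condition": "F", "sampling_rate": 2.0}'
        )
        rec = read_recording(path)
        assert rec.participant_id == "P09" and rec.condition == "F"
        assert np.array_equal(rec.channels["ax"], [1.0, 1.5, -1.0])
        assert np.array_equal(rec.channels["az"], [3.0, 3.5, 9.8])

    def test_non_monotone_time_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "time,ax,ay,az,gx,gy,gz\n0.0,0,0,0,0,0,0\n0.2,0,0,0,0,0,0\n0.1,0,0,0,0,0,0\n"
        )
        path.with_suffix(".json").write_text(
            '{"participant_id": "P01", "condition": "NF", "sampling_rate": 10.0}'
        )
        with pytest.raises(ValueError, match="increasing"):
            read_recording(path)


class TestLowpassFilter:
    FS = 256.0

    def _attenuation(self, freq, fs=FS, spec=FilterSpec()):
        t = np.arange(int(8 * fs)) / fs
        out = lowpass_filter(np.sin(2 * np.pi * freq * t), fs, spec)
        core = out[len(out) // 4 : -len(out) // 4]  # discard edge transients
        return np.max(np.abs(core))

    def test_constant_preserved(self):
        x = np.full(500, 3.3)
        assert np.allclose(lowpass_filter(x, self.FS), 3.3)

    def test_stopband_attenuation_bound(self):
        # analytic single-pass |H(60)| = (1 + (60/20)^8)^-1/2 ~ 1.2e-2; the
        # forward-backward pass squares it, and bilinear warping at 256 Hz
        # only attenuates further, so 1.5e-4 is a hard upper bound.
        assert self._attenuation(60.0) <= 1.5e-4

    def test_passband_unity(self):
        assert self._attenuation(1.0) >= 0.999

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_filter(np.zeros(100), self.FS, FilterSpec(cutoff=128.0))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            lowpass_filter(np.zeros(10), self.FS, FilterSpec(order=4))

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(
        a=st.floats(-5, 5, allow_nan=False),
        b=st.floats(-5, 5, allow_nan=False),
        seed=st.integers(0, 1000),
    )
    def test_linearity(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=300), rng.normal(size=300)
        lhs = lowpass_filter(a * x + b * y, self.FS)
        rhs = a * lowpass_filter(x, self.FS) + b * lowpass_filter(y, self.FS)
        assert np.max(np.abs(lhs - rhs)) < 1e-9


class TestMagnitudes:
    def test_pythagorean_and_zero(self):
        rec = toy_recording(n=3)
        rec.channels["ax"] = np.array([3.0, 0.0, 3.0])
        rec.channels["ay"] = np.array([4.0, 0.0, -4.0])
        rec.channels["az"] = np.array([0.0, 0.0, 0.0])
        out = add_magnitude_channels(rec)
        assert np.array_equal(out.channels["amag"], [5.0, 0.0, 5.0])

    def test_sign_flip_invariance(self):
        rec = toy_recording(n=100)
        flipped = RawRecording(
            rec.participant_id,
            rec.condition,
            rec.sampling_rate,
            rec.t,
            {c: (-v if c == "gy" else v) for c, v in rec.channels.items()},
        )
        assert np.allclose(
            add_magnitude_channels(rec).channels["gmag"],
            add_magnitude_channels(flipped).channels["gmag"],
        )


class TestFootStrikeDetection:
    FS = 256.0

    def test_impulse_train_spacing_and_count(self):
        period = 200
        x = np.zeros(4000)
        centers = np.arange(100, 4000 - 100, period)
        for c in centers:  # narrow Gaussian bumps
            i = np.arange(max(0, c - 30), min(len(x), c + 30))
            x[i] += np.exp(-0.5 * ((i - c) / 6.0) ** 2)
        events = detect_foot_strikes(x, self.FS)
        assert len(events) == len(centers)
        assert np.all(np.abs(events - centers) <= 1)
        assert np.all(np.abs(np.diff(events) - period) <= 1)

    def test_constant_signal_flagged_with_zero_events(self):
        with pytest.warns(SegmentationWarning):
            events = detect_foot_strikes(np.full(1000, 2.0), self.FS)
        assert len(events) == 0

    def test_single_impulse_one_event_flagged(self):
        x = np.zeros(1000)
        i = np.arange(470, 530)
        x[i] = np.exp(-0.5 * ((i - 500) / 5.0) ** 2)
        with pytest.warns(SegmentationWarning):
            events = detect_foot_strikes(x, self.FS)
        assert len(events) == 1


class TestSegmentation:
    def test_event_pairs_make_windows(self):
        rec = toy_recording(n=1000)
        events = np.array([100, 300, 500, 700, 900])
        windows = segment_and_normalize(rec, events, n_points=64)
        assert len(windows) == 4
        assert all(w.n_points == 64 and w.data.shape[1] == len(CHANNEL_ORDER) for w in windows)
        assert [w.stride_index for w in windows] == [0, 1, 2, 3]
        assert windows[0].duration == pytest.approx(200 / 256.0)

    def test_linear_ramp_resamples_exactly(self):
        rec = toy_recording(n=500)
        rec.channels["ax"] = np.arange(500, dtype=float)
        w = segment_and_normalize(rec, np.array([100, 300]), n_points=64)[0]
        ramp = w.channel("ax")
        assert ramp[0] == 100.0
        assert np.allclose(np.diff(ramp), np.diff(ramp)[0])

    def test_smooth_signal_mean_preserved_within_one_percent(self):
        fs = 256.0
        t = np.arange(600) / fs
        rec = toy_recording(n=600)
        rec.channels["az"] = 5.0 + np.sin(2 * np.pi * 4 * t) + 0.5 * np.sin(2 * np.pi * 9 * t)
        w = segment_and_normalize(rec, np.array([50, 562]), n_points=128)[0]
        src = rec.channels["az"][50:562]
        assert w.channel("az").mean() == pytest.approx(src.mean(), rel=0.01)

    def test_short_window_dropped_with_warning(self):
        rec = toy_recording(n=200)
        with pytest.warns(SegmentationWarning, match="dropped"):
            windows = segment_and_normalize(rec, np.array([10, 12, 100]), n_points=32)
        assert len(windows) == 1

    def test_roundtrip_through_long_table(self):
        rec = toy_recording(n=1000)
        windows = segment_and_normalize(rec, np.array([0, 250, 500, 750]), n_points=32)
        back = frame_to_windows(windows_to_frame(windows))
        assert len(back) == len(windows)
        for a, b in zip(windows, back):
            assert np.allclose(a.data, b.data)
            assert a.duration == pytest.approx(b.duration)


class TestSegmentationAgainstGroundTruth:
    def test_noise_free_recall_and_precision_are_perfect(self):
        cfg = SynthConfig(
            n_participants=2,
            strides_per_condition=(20, 20),
            noise_sd=0.0,
            amplitude_drift=0.0,
            stride_gain_noise_sd=0.0,
            seed=13,
        )
        recordings, truth = generate_cohort(cfg)
        for rec in recordings:
            filtered = filter_recording(rec)
            events = detect_foot_strikes(filtered.channels["az"], rec.sampling_rate)
            true_interior = np.round(
                truth.events[(rec.participant_id, rec.condition)] * rec.sampling_rate
            ).astype(int)[1:-1]
            # precision: every detection within 1 sample of a true event
            assert np.all(
                np.min(np.abs(events[:, None] - true_interior[None, :]), axis=1) <= 1
            )
            # recall: every interior true event found
            assert np.all(
                np.min(np.abs(true_interior[:, None] - events[None, :]), axis=1) <= 1
            )
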