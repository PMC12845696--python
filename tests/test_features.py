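"""Moment, spectral and entropy features against hand arithmetic and oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stridefatigue import SynthConfig, generate_cohort
from stridefatigue.features import (
    BandSpec,
    SampEnParams,
    build_feature_table,
    base_feature_columns,
    feature_columns,
    sample_entropy,
    spectral_features,
    time_domain_features,
)
from stridefatigue.preprocess import segment_recording


def sampen_bruteforce(x, m, r):
    """Independent exhaustive template count (ordered pairs, Chebyshev <= r*sd)."""
    x = np.asarray(x, float)
    tol = r * np.std(x)
    nt = len(x) - m
    a = b = 0
    for i in range(nt):
        for j in range(nt):
            if i == j:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= tol:
                b += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= tol:
                a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -np.log(a / b)


class TestTimeDomain:
    def test_hand_example(self):
        f = time_domain_features(np.array([1.0, 2.0, 3.0, 2.0]))
        assert f["mean"] == 2.0
        assert f["std"] ** 2 == pytest.approx(0.5)
        assert f["rms"] == pytest.approx(np.sqrt(4.5))
        assert f["skew"] == pytest.approx(0.0)
        assert f["kurt"] == pytest.approx(2.0)
        assert (f["min"], f["max"], f["energy"]) == (1.0, 3.0, 18.0)

    def test_constant_series_degenerate_policy(self):
        f = time_domain_features(np.full(10, -2.5))
        assert f["std"] == 0.0 and f["rms"] == 2.5
        assert f["min"] == f["max"] == f["mean"] == -2.5
        assert f["skew"] == 0.0 and f["kurt"] == 0.0
        assert f["degenerate"]

    def test_gaussian_kurtosis_tends_to_three(self):
        x = np.random.default_rng(42).standard_normal(100_000)
        assert time_domain_features(x)["kurt"] == pytest.approx(3.0, abs=0.1)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(c=st.floats(0.01, 100), seed=st.integers(0, 500))
    def test_scale_equivariance(self, c, seed):
        x = np.random.default_rng(seed).normal(1.0, 2.0, 64)
        f1, fc = time_domain_features(x), time_domain_features(c * x)
        for key in ("mean", "std", "rms", "min", "max"):
            assert fc[key] == pytest.approx(c * f1[key], rel=1e-9, abs=1e-12)
        assert fc["skew"] == pytest.approx(f1["skew"], rel=1e-7)
        assert fc["kurt"] == pytest.approx(f1["kurt"], rel=1e-7)
        assert fc["energy"] == pytest.approx(c**2 * f1["energy"], rel=1e-9)


class TestSpectral:
    def test_pure_sinusoid_dominant_bin(self):
        t = np.arange(256) / 256.0
        f = spectral_features(np.sin(2 * np.pi * 4 * t), effective_rate=256.0)
        assert f["fdom"] == pytest.approx(4.0)
        assert f["specent"] < 1e-6  # one-hot spectrum

    def test_uniform_four_bin_spectrum_entropy_ln4(self):
        n = 16
        t = np.arange(n)
        x = sum(np.cos(2 * np.pi * k * t / n) for k in range(1, 5))
        f = spectral_features(np.asarray(x), effective_rate=float(n))
        assert f["specent"] == pytest.approx(np.log(4), abs=1e-9)

    def test_bandpower_concentrates_at_tone(self):
        t = np.arange(256) / 256.0
        bands = BandSpec(bands=((3.0, 5.0), (10.0, 20.0)))
        f = spectral_features(np.sin(2 * np.pi * 4 * t), 256.0, bands)
        total = f["bp1"] + f["bp2"]
        assert f["bp1"] / total >= 0.99
        assert f["bp2"] / total <= 0.01

    def test_zero_ac_spectrum_convention(self):
        f = spectral_features(np.full(64, 7.0), effective_rate=64.0)
        assert np.isnan(f["fdom"]) and f["specent"] == 0.0

    def test_scale_invariance_of_spectral_entropy(self):
        x = np.random.default_rng(3).normal(size=128)
        f1 = spectral_features(x, 128.0)
        f2 = spectral_features(10.0 * x, 128.0)
        assert f2["specent"] == pytest.approx(f1["specent"], rel=1e-9)
        assert f2["fdom"] == f1["fdom"]

    def test_invalid_bands_rejected(self):
        with pytest.raises(ValueError):
            BandSpec(bands=((5.0, 3.0),))
        with pytest.raises(ValueError):
            BandSpec(bands=((0.5, 3.0), (2.0, 8.0)))


class TestSampleEntropy:
    def test_constant_series_zero(self):
        assert sample_entropy(np.full(30, 1.7)) == 0.0

    @pytest.mark.parametrize("m", [1, 2, 3])
    @pytest.mark.parametrize("r", [0.1, 0.2, 0.5])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_oracle(self, m, r, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(m + 4, 31))
        x = rng.normal(size=n)
        ours = sample_entropy(x, SampEnParams(m=m, r=r))
        ref = sampen_bruteforce(x, m, r)
        if np.isnan(ref):
            assert np.isnan(ours)
        else:
            assert ours == pytest.approx(ref, rel=1e-12)

    def test_alternating_series_matches_bruteforce(self):
        x = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        params = SampEnParams(m=2, r=0.5)
        assert sample_entropy(x, params) == pytest.approx(sampen_bruteforce(x, 2, 0.5))

    def test_shuffled_not_more_regular_than_sorted(self):
        params = SampEnParams(m=2, r=0.2)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.uniform(size=500)
            shuffled = sample_entropy(x, params)
            sorted_se = sample_entropy(np.sort(x), params)
            assert shuffled >= sorted_se

    def test_scale_invariance(self):
        x = np.random.default_rng(8).normal(size=100)
        assert sample_entropy(5.0 * x) == pytest.approx(sample_entropy(x), rel=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sample_entropy(np.ones(3), SampEnParams(m=2))


@pytest.fixture(scope="module")
def windows():
    cfg = SynthConfig(n_participants=1, strides_per_condition=(12, 12), seed=21)
    recordings, _ = generate_cohort(cfg)
    out = []
    for rec in recordings:
        out.extend(segment_recording(rec))
    return out[:10]


class TestFeatureTable:
    def test_shape_and_base_width(self, windows):
        table = build_feature_table(windows, include_extended=False)
        assert len(table) == 10
        base = base_feature_columns()
        assert len(base) == 64
        assert all(c in table.columns for c in base)
        assert not table[base].isna().any().any()

    def test_published_feature_names_present(self, windows):
        table = build_feature_table(windows, include_extended=False)
        for name in (
            "acc_z_mean", "acc_mag_kurt", "gyro_y_rms", "gyro_y_energy",
            "acc_y_min", "acc_mag_skew", "gyro_z_std", "acc_x_max",
        ):
            assert name in table.columns

    def test_moment_invariants_hold(self, windows):
        table = build_feature_table(windows, include_extended=True)
        for ch in ("acc_z", "gyro_y", "acc_mag"):
            assert (table[f"{ch}_std"] >= 0).all()
            assert (table[f"{ch}_rms"] >= 0).all()
            assert (table[f"{ch}_min"] <= table[f"{ch}_mean"]).all()
            assert (table[f"{ch}_mean"] <= table[f"{ch}_max"]).all()
            assert (table[f"{ch}_specent"] >= 0).all()

    def test_row_order_statelessness(self, windows):
        t1 = build_feature_table(windows, include_extended=False)
        t2 = build_feature_table(list(reversed(windows)), include_extended=False)
        key = ["participant", "condition", "stride_index"]
        merged = t1.set_index(key).sort_index() - t2.set_index(key).sort_index()
        assert np.allclose(merged.to_numpy(float), 0.0)

    def test_feature_set_selector(self, windows):
        table = build_feature_table(windows, include_extended=True)
        base = feature_columns(table, "base")
        extended = feature_columns(table, "extended")
        assert len(base) == 64
        assert set(base) < set(extended)
        assert any(c.endswith("_sampen") for c in extended)
        with pytest.raises(ValueError):
            feature_columns(table, "everything")

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_feature_table([])
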