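"""Handcrafted features: worked examples, oracle equivalence and
shift/scale laws."""

import numpy as np
import pytest

from gaitenc import FEATURE_NAMES, extract_features, feature_frame
from gaitenc.features import (
    autocorrelation, basic_stats, channel_features, order_mean_features,
    percentile_features, shape_features, spectral_features, zero_crossings,
)
from gaitenc.windowing import Window

import oracles


class TestWorkedExamples:
    """Hand-computed values on tiny inputs."""

    def test_basic_stats(self):
        mx, mn, mean, std = basic_stats([1, 2, 3, 4, 5])
        assert (mx, mn, mean) == (5, 1, 3)
        assert std == pytest.approx(np.sqrt(10 / 4))   # 1.5811, n-1 form

    def test_constant_series_std_zero(self):
        assert basic_stats([2, 2, 2])[3] == 0.0

    def test_std_needs_two_samples(self):
        with pytest.raises(ValueError):
            basic_stats([1.0])

    @pytest.mark.parametrize("series,expected", [
        ([1, -1, 1, -1], 3),
        ([1, 2, 3], 0),
        ([1, 0, -1], 1),              # zero adopts the previous sign
        ([1, 0, 1, -1], 1),
        ([0, 0, 1, -1], 1),           # leading zeros carry no sign
    ])
    def test_zero_crossings(self, series, expected):
        assert zero_crossings(np.array(series, float)) == expected

    def test_percentiles(self):
        p20, p50, p80, iqr = percentile_features(np.array([1, 2, 3, 4, 5.0]))
        assert p50 == 3.0
        assert iqr == pytest.approx(2.0)               # p75=4, p25=2
        const = percentile_features(np.full(10, 7.0))
        assert const == (7.0, 7.0, 7.0, 0.0)

    def test_kurtosis_and_skewness_composition(self):
        # sum((m-3)^4) = 34, sigma^2 = 2.5 (n-1 form) => 34 / (5 * 6.25)
        kurt, skew = shape_features(np.array([1, 2, 3, 4, 5.0]))
        assert kurt == pytest.approx(34 / (5 * 6.25))
        assert skew == pytest.approx(0.0, abs=1e-12)   # symmetric input

    def test_skewness_sign_right_tail(self):
        _, skew = shape_features(np.array([0, 0, 0, 1.0]))
        assert skew > 0

    def test_constant_window_degenerate_to_zero(self):
        kurt, skew = shape_features(np.full(8, 3.0))
        assert (kurt, skew) == (0.0, 0.0)
        assert autocorrelation(np.full(8, 3.0), 1) == 0.0

    def test_autocorrelation_limits(self, rng):
        x = rng.standard_normal(50)
        assert autocorrelation(x, 0) == pytest.approx(1.0)
        alternating = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
        assert autocorrelation(alternating, 1) < 0

    def test_order_mean_values(self):
        assert order_mean_features(np.full(5, 2.0)) == (0, 0, 0, 0)
        fom, nfom, som, nsom = order_mean_features(np.array([1, 2, 3, 4.0]))
        assert (som, nsom) == (0.0, 0.0)               # linear ramp
        assert fom == pytest.approx(1.0)
        assert nfom == pytest.approx(3.0)

    def test_sorted_gaps_telescope(self, rng):
        x = rng.standard_normal(30)
        fom, nfom, _, _ = order_mean_features(x)
        assert nfom == pytest.approx(x.max() - x.min())
        assert fom == pytest.approx((x.max() - x.min()) / 29)

    def test_constant_series_spectral_entropy_zero(self):
        # all magnitude in the DC bin: single-support distribution
        sep, se = spectral_features(np.full(16, 5.0))
        assert sep == pytest.approx(0.0, abs=1e-12)
        assert se == pytest.approx((16 * 5.0) ** 2)

    def test_noise_entropy_exceeds_tone_entropy(self):
        n = 128
        t = np.arange(n)
        tone_entropies, noise_entropies = [], []
        for seed in range(20):
            r = np.random.default_rng(seed)
            tone = np.sin(2 * np.pi * 8 * t / n + r.uniform(0, 2 * np.pi))
            noise = r.standard_normal(n)
            tone_entropies.append(spectral_features(tone)[0])
            noise_entropies.append(spectral_features(noise)[0])
        assert min(noise_entropies) > max(tone_entropies)
        assert np.mean(noise_entropies) > 0.7 * np.log(n // 2 + 1)


class TestOracleEquivalence:
    """Every feature matches the independent brute-force implementation."""

    def test_all_features_on_random_windows(self, rng):
        for _ in range(200):
            x = rng.standard_normal(rng.integers(16, 129))
            ours = channel_features(x)
            theirs = oracles.all_features_bf(list(x))
            np.testing.assert_allclose(ours, theirs, rtol=0, atol=1e-9)

    def test_spectral_energy_matches_naive_dft(self, rng):
        for _ in range(5):
            x = rng.standard_normal(64)
            _, se = spectral_features(x)
            assert se == pytest.approx(oracles.spectral_energy_bf(list(x)),
                                       abs=1e-9 * max(1.0, se))

    def test_autocorr_matches_double_loop(self, rng):
        x = rng.standard_normal(100)
        for k in (0, 1, 5, 50):
            assert autocorrelation(x, k) == pytest.approx(
                oracles.autocorr_bf(list(x), k), abs=1e-12
            )


# shift/scale equivariance table: which slots are invariant under
# x -> x + c, and how each slot transforms under x -> lam * x (lam > 0)
SHIFT_INVARIANT = {"std", "iqr", "kurtosis", "skewness", "autocorr",
                   "fom", "norm_fom", "som", "norm_som", "zero_crossings"}
SHIFT_PLUS_C = {"max", "min", "mean", "p20", "p50", "p80"}
SCALE_LINEAR = {"max", "min", "mean", "std", "p20", "p50", "p80", "iqr",
                "fom", "norm_fom", "som", "norm_som"}
SCALE_INVARIANT = {"kurtosis", "skewness", "autocorr", "spectral_entropy",
                   "zero_crossings"}


class TestShiftScaleLaws:
    def _windows(self, rng, n=100):
        # strictly positive offset keeps zero-crossing counts trivially
        # stable under scaling; shift tests exclude the zc slot anyway
        return [rng.standard_normal(128) for _ in range(n)]

    def test_shift_law(self, rng):
        idx = {name: i for i, name in enumerate(FEATURE_NAMES)}
        for x in self._windows(rng, 100):
            base = channel_features(x)
            for c in (-3.0, 0.5, 10.0, 100.0, -0.25):
                shifted = channel_features(x + c)
                for name in SHIFT_INVARIANT - {"zero_crossings"}:
                    assert shifted[idx[name]] == pytest.approx(
                        base[idx[name]], abs=1e-9 * max(1, abs(base[idx[name]]))
                    ), name
                for name in SHIFT_PLUS_C:
                    assert shifted[idx[name]] == pytest.approx(
                        base[idx[name]] + c, abs=1e-9 * max(1, abs(c))
                    ), name

    def test_scale_law(self, rng):
        idx = {name: i for i, name in enumerate(FEATURE_NAMES)}
        for x in self._windows(rng, 100):
            base = channel_features(x)
            for lam in (0.5, 2.0, 10.0, 0.01, 7.5):
                scaled = channel_features(lam * x)
                for name in SCALE_LINEAR:
                    assert scaled[idx[name]] == pytest.approx(
                        lam * base[idx[name]],
                        abs=1e-9 * max(1, abs(lam * base[idx[name]])),
                    ), name
                for name in SCALE_INVARIANT:
                    assert scaled[idx[name]] == pytest.approx(
                        base[idx[name]],
                        abs=1e-9 * max(1, abs(base[idx[name]])),
                    ), name
                assert scaled[idx["spectral_energy"]] == pytest.approx(
                    lam**2 * base[idx["spectral_energy"]],
                    rel=1e-9,
                )


class TestFusion:
    def _window(self, rng, n_channels=9):
        return Window(samples=rng.standard_normal((128, n_channels)),
                      label="walk", subject_id="s1", source_index=("r", 0))

    def test_fused_length_3x3x18(self, rng):
        names = [f"{s}_{a}" for s in ("acc", "gyro", "mag")
                 for a in ("x", "y", "z")]
        fv = extract_features(self._window(rng), names)
        assert fv.values.shape == (162,)
        assert len(fv.feature_names) == 162

    def test_one_sensor_gives_54(self, rng):
        names = [f"acc_{a}" for a in ("x", "y", "z")]
        fv = extract_features(self._window(rng, 3), names)
        assert fv.values.shape == (54,)

    def test_channel_permutation_permutes_blocks(self, rng):
        names = [f"{s}_{a}" for s in ("acc", "gyro", "mag")
                 for a in ("x", "y", "z")]
        win = self._window(rng)
        fv = extract_features(win, names)
        perm = [3, 4, 5, 0, 1, 2, 6, 7, 8]
        win2 = Window(samples=win.samples[:, perm], label="walk",
                      subject_id="s1", source_index=("r", 0))
        fv2 = extract_features(win2, [names[p] for p in perm])
        for new_pos, old_pos in enumerate(perm):
            np.testing.assert_array_equal(
                fv2.values[new_pos * 18:(new_pos + 1) * 18],
                fv.values[old_pos * 18:(old_pos + 1) * 18],
            )

    def test_extraction_is_pure(self, rng):
        win = self._window(rng)
        names = [f"{s}_{a}" for s in ("acc", "gyro", "mag")
                 for a in ("x", "y", "z")]
        a = extract_features(win, names).values
        b = extract_features(win, names).values
        assert np.array_equal(a, b)

    def test_never_emits_nan_on_degenerate_window(self):
        win = Window(samples=np.zeros((128, 9)), label="w", subject_id="s",
                     source_index=("r", 0))
        names = [f"{s}_{a}" for s in ("acc", "gyro", "mag")
                 for a in ("x", "y", "z")]
        fv = extract_features(win, names)
        assert np.isfinite(fv.values).all()

    def test_feature_frame_columns(self, rng):
        names = [f"{s}_{a}" for s in ("acc", "gyro", "mag")
                 for a in ("x", "y", "z")]
        df = feature_frame([self._window(rng) for _ in range(3)], names)
        assert df.shape == (3, 164)                   # 162 + label + subject
        assert "acc_x_spectral_entropy" in df.columns
        assert list(df["label"]) == ["walk"] * 3
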