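import numpy as np
import pytest
from skimage.draw import disk as _disk

from segcomplexity import (
    ValidationError,
    dataset_profile,
    deldensity,
    delentropy,
    make_blob_mask,
    make_spectral_image,
    make_vessel_mask,
    mdf_2d,
    mean_frequency_1d,
    median_frequency_1d,
    mnf_2d,
    perimetric_complexity,
    power_spectrum_1d,
    shannon_entropy,
)
from segcomplexity.complexity_measures import SpectralDensity


# --------------------------------------------------------------------------
# independent oracles


def brute_force_deldensity(img):
    """Tally (dx, dy) of every 2x2 window one window at a time."""
    img = np.asarray(img, float)
    h, w = img.shape
    tally = {}
    for r in range(h - 1):
        for c in range(w - 1):
            dx = 0.5 * ((img[r, c + 1] - img[r, c]) + (img[r + 1, c + 1] - img[r + 1, c]))
            dy = 0.5 * ((img[r + 1, c] - img[r, c]) + (img[r + 1, c + 1] - img[r, c + 1]))
            tally[(dx, dy)] = tally.get((dx, dy), 0) + 1
    n = (h - 1) * (w - 1)
    return {k: v / n for k, v in tally.items()}


def naive_dft_power(x):
    """O(N^2) discrete Fourier sum, one-sided squared amplitudes."""
    x = np.asarray(x, float)
    n = len(x)
    out = []
    for k in range(n // 2 + 1):
        re = sum(x[t] * np.cos(-2 * np.pi * k * t / n) for t in range(n))
        im = sum(x[t] * np.sin(-2 * np.pi * k * t / n) for t in range(n))
        out.append(re**2 + im**2)
    return np.array(out)


def stripes(h=8, w=9):
    """Alternating 0/1 columns; odd width keeps the +1/-1 gradients balanced."""
    return np.tile(np.array([0.0, 1.0]), (h, (w + 1) // 2))[:, :w]


# --------------------------------------------------------------------------
# entropy measures


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "img,n_levels,expected",
        [
            (np.full((8, 8), 3.0), 256, 0.0),
            (np.repeat([[0.0], [1.0]], [4, 4], axis=0) * np.ones((8, 8)), 2, 1.0),
            (np.arange(4).repeat(4).reshape(4, 4).astype(float), 4, 2.0),
        ],
    )
    def test_closed_form_cases(self, img, n_levels, expected):
        assert shannon_entropy(img, n_levels) == pytest.approx(expected, abs=1e-12)

    def test_rejects_degenerate_levels(self):
        with pytest.raises(ValidationError):
            shannon_entropy(np.zeros((4, 4)), n_levels=1)


class TestDeldensity:
    def test_constant_image_single_bin(self):
        dd = deldensity(np.full((6, 6), 5.0))
        assert dd.hist.size == 1 and dd.hist[0, 0] == 1.0

    def test_stripes_two_equiprobable_bins(self):
        dd = deldensity(stripes())
        occupied = dd.hist[dd.hist > 0]
        np.testing.assert_allclose(np.sort(occupied), [0.5, 0.5])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_window_tally(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 16, (8, 8)).astype(float)
        dd = deldensity(img)
        oracle = brute_force_deldensity(img)
        got = {
            (float(x), float(y)): dd.hist[i, j]
            for i, x in enumerate(dd.x_centers)
            for j, y in enumerate(dd.y_centers)
            if dd.hist[i, j] > 0
        }
        assert set(got) == set(oracle)
        for k in oracle:
            assert got[k] == pytest.approx(oracle[k], abs=1e-12)

    def test_checkerboard_matches_tally(self):
        img = np.indices((8, 8)).sum(axis=0) % 2 * 1.0
        dd = deldensity(img)
        oracle = brute_force_deldensity(img)
        assert sum(v > 0 for v in dd.hist.ravel()) == len(oracle)
        assert dd.n_samples == 49


class TestDelentropy:
    def test_constant_is_zero(self):
        assert delentropy(np.full((16, 16), 9.0)) == 0.0

    def test_stripes_half_bit(self):
        assert delentropy(stripes()) == pytest.approx(0.5, abs=1e-12)

    def test_equals_half_entropy_of_brute_force_histogram(self):
        rng = np.random.default_rng(7)
        img = rng.integers(0, 8, (32, 32)).astype(float)
        p = np.array(list(brute_force_deldensity(img).values()))
        expected = -0.5 * (p * np.log2(p)).sum()
        assert delentropy(img) == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_shift_and_transpose(self):
        img = np.random.default_rng(3).integers(0, 32, (12, 17)).astype(float)
        base = delentropy(img)
        assert delentropy(img + 100.0) == pytest.approx(base, abs=1e-12)
        assert delentropy(img.T) == pytest.approx(base, abs=1e-12)


# --------------------------------------------------------------------------
# spectral measures


class TestPowerSpectrum1D:
    def test_constant_signal_all_power_at_dc(self):
        spec = power_spectrum_1d(np.full(16, 2.0), include_dc=True)
        assert spec.power[0] == pytest.approx((16 * 2.0) ** 2)
        np.testing.assert_allclose(spec.power[1:], 0, atol=1e-20)

    def test_on_bin_cosine_single_bin(self):
        n, k = 32, 5
        sig = np.cos(2 * np.pi * k * np.arange(n) / n)
        spec = power_spectrum_1d(sig, include_dc=False)
        idx = np.argmax(spec.power)
        assert spec.freqs[idx] == pytest.approx(k / n)
        others = np.delete(spec.power, idx)
        assert others.max() < 1e-20 * spec.power[idx]

    def test_matches_naive_dft(self):
        x = np.random.default_rng(11).normal(size=16)
        spec = power_spectrum_1d(x, include_dc=True)
        np.testing.assert_allclose(spec.power, naive_dft_power(x), atol=1e-9)
        np.testing.assert_allclose(spec.freqs, np.arange(9) / 16)

    def test_short_signal_rejected(self):
        with pytest.raises(ValidationError):
            power_spectrum_1d([1.0])


class TestFrequencyStatistics:
    def test_single_tone_mean_equals_median(self):
        spec = SpectralDensity(power=np.array([0, 5.0, 0]), freqs=np.array([0.1, 0.2, 0.3]))
        assert mean_frequency_1d(spec) == median_frequency_1d(spec) == pytest.approx(0.2)

    def test_two_equal_tones_mean_is_midpoint(self):
        spec = SpectralDensity(power=np.array([2.0, 2.0]), freqs=np.array([0.1, 0.4]))
        assert mean_frequency_1d(spec) == pytest.approx(0.25)

    def test_flat_spectrum(self):
        freqs = np.arange(1, 9) / 16
        spec = SpectralDensity(power=np.ones(8), freqs=freqs)
        assert mean_frequency_1d(spec) == pytest.approx(freqs.mean())
        assert median_frequency_1d(spec) == pytest.approx(freqs[3])  # ceil(8/2)th bin

    def test_cumulative_rule_prefers_first_crossing(self):
        spec = SpectralDensity(power=np.array([1.0, 3.0]), freqs=np.array([0.1, 0.3]))
        assert median_frequency_1d(spec) == pytest.approx(0.3)

    def test_zero_power_convention(self):
        spec = SpectralDensity(power=np.zeros(4), freqs=np.arange(1, 5) / 10)
        assert mean_frequency_1d(spec) == 0.0
        assert median_frequency_1d(spec) == 0.0


class TestSpectral2D:
    def test_constant_image_zero_both_modes(self):
        img = np.full((16, 16), 3.0)
        for mode in ("literal", "mean"):
            assert mnf_2d(img, mode=mode) == 0.0
            assert mdf_2d(img, mode=mode) == 0.0

    def test_mean_mode_is_column_average(self):
        img = np.random.default_rng(5).normal(size=(16, 16))
        cols = [
            mean_frequency_1d(power_spectrum_1d(img[:, w], include_dc=False))
            for w in range(16)
        ]
        assert mnf_2d(img, mode="mean") == pytest.approx(np.mean(cols), abs=1e-12)

    @pytest.mark.parametrize("fn,stat", [(mnf_2d, mean_frequency_1d), (mdf_2d, median_frequency_1d)])
    def test_literal_mode_is_two_stage_composition(self, fn, stat):
        img = np.random.default_rng(6).normal(size=(16, 16))
        cols = np.array(
            [stat(power_spectrum_1d(img[:, w], include_dc=False)) for w in range(16)]
        )
        expected = stat(power_spectrum_1d(cols, include_dc=False))
        assert fn(img, mode="literal") == pytest.approx(expected, abs=1e-12)

    def test_identical_tone_columns_mean_mode(self):
        n, k = 32, 4
        col = np.cos(2 * np.pi * k * np.arange(n) / n)
        img = np.tile(col[:, None], (1, 12))
        assert mdf_2d(img, mode="mean") == pytest.approx(k / n)

    def test_amplitude_scale_invariance(self):
        img = np.random.default_rng(8).normal(size=(20, 20))
        assert mnf_2d(img * 7.3) == pytest.approx(mnf_2d(img), abs=1e-12)
        assert mdf_2d(img * 7.3) == pytest.approx(mdf_2d(img), abs=1e-12)

    def test_range_bounds(self):
        for seed in range(5):
            img = make_spectral_image((32, 32), beta=float(seed), seed=seed)
            for v in (mnf_2d(img), mdf_2d(img), mnf_2d(img, mode="mean")):
                assert 0.0 <= v <= 0.5

    def test_monotone_in_spectral_exponent(self):
        betas = [0.0, 1.0, 2.0, 3.0, 4.0]
        mdfs = [mdf_2d(make_spectral_image((128, 128), b, seed=11), mode="mean") for b in betas]
        mnfs = [mnf_2d(make_spectral_image((128, 128), b, seed=11), mode="mean") for b in betas]
        assert all(a >= b for a, b in zip(mdfs, mdfs[1:]))
        assert all(a >= b for a, b in zip(mnfs, mnfs[1:]))


# --------------------------------------------------------------------------
# perimetric complexity


def filled_disk(radius, frame):
    m = np.zeros((frame, frame), np.uint8)
    rr, cc = _disk((frame // 2, frame // 2), radius)
    m[rr, cc] = 1
    return m


class TestPerimetricComplexity:
    def test_filled_square_near_four_over_pi(self):
        m = np.zeros((220, 220), np.uint8)
        m[10:210, 10:210] = 1
        assert perimetric_complexity(m) == pytest.approx(4 / np.pi, rel=0.02)

    def test_disk_near_one(self):
        assert perimetric_complexity(filled_disk(50, 128)) == pytest.approx(1.0, rel=0.05)

    def test_two_congruent_disks_double_single(self):
        single = filled_disk(40, 150)
        double = np.zeros((300, 150), np.uint8)
        double[:150] = single
        double[150:] = single
        ratio = perimetric_complexity(double) / perimetric_complexity(single)
        assert ratio == pytest.approx(2.0, rel=0.01)

    def test_translation_invariance(self):
        m = np.zeros((100, 100), np.uint8)
        m[10:40, 10:40] = 1
        assert perimetric_complexity(np.roll(m, (23, 31), (0, 1))) == pytest.approx(
            perimetric_complexity(m), abs=1e-9
        )

    def test_approximate_scale_invariance(self):
        m = make_blob_mask(seed=3)
        up = np.kron(m, np.ones((2, 2), np.uint8))
        assert perimetric_complexity(up) == pytest.approx(
            perimetric_complexity(m), rel=0.05
        )

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError, match="mask"):
            perimetric_complexity(np.zeros((8, 8), np.uint8))

    def test_vessel_exceeds_blob(self):
        assert perimetric_complexity(make_vessel_mask(seed=4)) > 10 * perimetric_complexity(
            make_blob_mask(seed=4)
        )


# --------------------------------------------------------------------------
# aggregation


class TestDatasetProfile:
    def test_single_pair_is_per_image_value(self):
        img = make_spectral_image((64, 64), 1.0, 3)
        msk = make_blob_mask((64, 64), n_blobs=1, radius=12, seed=3)
        prof = dataset_profile([(img, msk)])
        assert prof.de == pytest.approx(delentropy(img))
        assert prof.mdf == pytest.approx(mdf_2d(img))
        assert prof.pc == pytest.approx(perimetric_complexity(msk))
        assert prof.n_images == 1

    def test_pc_is_arithmetic_mean(self):
        img = make_spectral_image((64, 64), 1.0, 3)
        m1 = make_blob_mask((64, 64), n_blobs=1, radius=12, seed=1)
        m2 = make_vessel_mask((64, 64), seed=1)
        prof = dataset_profile([(img, m1), (img, m2)])
        expected = 0.5 * (perimetric_complexity(m1) + perimetric_complexity(m2))
        assert prof.pc == pytest.approx(expected)

    def test_error_identifies_offending_pair(self):
        img = make_spectral_image((64, 64), 1.0, 3)
        with pytest.raises(ValidationError, match="#1"):
            dataset_profile([(img, make_blob_mask((64, 64), n_blobs=1, radius=12, seed=1)),
                             (img, np.zeros((64, 64), np.uint8))])
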