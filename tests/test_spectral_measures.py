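import numpy as np
import pytest

from iqrank import (
    GrayImage,
    power_spectrum_2d,
    reduce_radial,
    reduce_summed,
    tail_stats,
    invert_measure,
    gaussian_blur,
    make_base_image,
)
from iqrank.spectral_measures import PowerSpectrum1D, PowerSpectrum2D
from iqrank.errors import ParameterError


def brute_force_radial(ps: PowerSpectrum2D):
    """Independent O(N^2) loop-based radial binning."""
    h, w = ps.power.shape
    cy, cx = h // 2, w // 2
    r_max = min(cy, cx, h - 1 - cy, w - 1 - cx)
    sums = np.zeros(r_max + 1)
    counts = np.zeros(r_max + 1)
    for i in range(h):
        for j in range(w):
            r = int(round(np.hypot(i - cy, j - cx)))
            if r <= r_max:
                sums[r] += ps.power[i, j]
                counts[r] += 1
    return sums / counts


class TestPowerSpectrum2D:
    def test_constant_image_has_no_ac_power(self):
        ps = power_spectrum_2d(GrayImage(np.full((32, 32), 9.0)))
        dc = ps.power[16, 16]
        assert dc > 0
        ac = ps.power.copy()
        ac[16, 16] = 0
        assert np.allclose(ac, 0, atol=1e-9)

    def test_central_impulse_flat_spectrum(self):
        px = np.zeros((32, 32))
        px[16, 16] = 100.0
        ps = power_spectrum_2d(GrayImage(px))
        assert np.allclose(ps.power, ps.power[0, 0], rtol=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_parseval_identity(self, seed):
        rng = np.random.default_rng(seed)
        g = GrayImage(rng.uniform(0, 255, (64, 64)))
        ps = power_spectrum_2d(g)
        unnormalized = ps.power * ps.mean_gray * ps.n_pixels
        lhs = unnormalized.sum() / g.pixels.size
        rhs = (g.pixels**2).sum()
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_brightness_scales_spectrum_linearly(self, random_image):
        ps1 = power_spectrum_2d(random_image)
        ps2 = power_spectrum_2d(GrayImage(3.0 * random_image.pixels))
        assert np.allclose(ps2.power, 3.0 * ps1.power, rtol=1e-9)

    def test_zero_image_rejected(self):
        with pytest.raises(ParameterError, match="mean"):
            power_spectrum_2d(GrayImage(np.zeros((32, 32))))


class TestReduceRadial:
    @pytest.mark.parametrize("shape", [(32, 32), (33, 33), (48, 64), (64, 48)])
    def test_matches_brute_force_oracle_exactly(self, rng, shape):
        ps = power_spectrum_2d(GrayImage(rng.uniform(0, 255, shape)))
        ps1d = reduce_radial(ps)
        assert np.array_equal(ps1d.power, brute_force_radial(ps))
        assert ps1d.freq_fraction[0] == 0.0 and ps1d.freq_fraction[-1] == 1.0

    def test_constant_image_only_dc(self):
        ps1d = reduce_radial(power_spectrum_2d(GrayImage(np.full((32, 32), 4.0))))
        assert ps1d.power[0] > 0
        assert np.allclose(ps1d.power[1:], 0, atol=1e-10)

    def test_blurred_noise_profile_decays(self, rng):
        img = GrayImage(rng.uniform(0, 255, (64, 64)))
        sm = gaussian_blur(img, 3.0)
        prof = reduce_radial(power_spectrum_2d(sm)).power
        # beyond the lowest radii the isotropically blurred profile decreases,
        # until the attenuated power reaches the floating-point noise floor
        assert np.all(np.diff(prof[2:12]) < 0)
        assert prof[12:].max() < prof[2:12].min()


class TestReduceSummed:
    def test_folding_doubles_symmetric_profile(self, rng):
        # real input -> conjugate-symmetric spectrum; use odd size so every
        # non-DC sample has a negative-frequency twin
        ps = power_spectrum_2d(GrayImage(rng.uniform(0, 255, (33, 33))))
        row = ps.power.sum(axis=0)
        c = 16
        one_sided = row[c:]
        folded = reduce_summed(ps)
        col = ps.power.sum(axis=1)
        expected = np.concatenate(([one_sided[0]], 2 * one_sided[1:]))
        expected += np.concatenate(([col[c]], 2 * col[c + 1 :]))
        assert np.allclose(folded.power, expected, rtol=1e-12)

    def test_constant_image_no_ac(self):
        ps1d = reduce_summed(power_spectrum_2d(GrayImage(np.full((32, 32), 4.0))))
        assert np.allclose(ps1d.power[1:], 0, atol=1e-10)

    def test_nonsquare_interpolated_to_long_axis(self, rng):
        ps1d = reduce_summed(power_spectrum_2d(GrayImage(rng.uniform(0, 255, (32, 64)))))
        assert ps1d.power.size == 33  # long axis: 64 -> 33 folded samples

    def test_blur_ranking_consistent_with_radial(self):
        base = make_base_image("filaments", (64, 64), seed=4)
        means_s, means_r = [], []
        for r in range(0, 11, 2):
            ps = power_spectrum_2d(gaussian_blur(base, r))
            means_s.append(tail_stats(reduce_summed(ps), 0.40).fMean)
            means_r.append(tail_stats(reduce_radial(ps), 0.40).fMean)
        assert np.argsort(means_s).tolist() == np.argsort(means_r).tolist()


class TestTailStats:
    def _spectrum(self, power):
        n = len(power)
        return PowerSpectrum1D(np.linspace(0, 1, n), np.asarray(power, float), "summed")

    def test_constant_tail(self):
        s = tail_stats(self._spectrum([9.0] * 21), threshold=0.40)
        assert s.fMean == 9.0 and s.fSTD == 0.0 and s.skewness == 0.0 and s.MeanBin == 9.0

    def test_meanbin_is_first_five_tail_samples(self):
        power = np.zeros(21)
        power[9:] = np.arange(1, 13)  # tail above 0.40 starts at [1, 2, 3, 4, 5, ...]
        s = tail_stats(self._spectrum(power), threshold=0.40)
        assert s.MeanBin == 3.0

    def test_blur_lowers_fmean(self, filaments_image):
        sharp = tail_stats(reduce_summed(power_spectrum_2d(filaments_image)), 0.40)
        soft = tail_stats(
            reduce_summed(power_spectrum_2d(gaussian_blur(filaments_image, 2.0))), 0.40
        )
        assert soft.fMean < sharp.fMean

    def test_noise_raises_fmean(self):
        base = make_base_image("ramp", (64, 64), seed=0)
        rng = np.random.default_rng(1)
        noisy = GrayImage(np.clip(base.pixels + rng.normal(0, 5, (64, 64)), 0, None))
        s0 = tail_stats(reduce_summed(power_spectrum_2d(base)), 0.40)
        s1 = tail_stats(reduce_summed(power_spectrum_2d(noisy)), 0.40)
        assert s1.fMean > s0.fMean and s1.MeanBin > s0.MeanBin

    def test_cv_relation_and_high90(self, random_image):
        ps1d = reduce_summed(power_spectrum_2d(random_image))
        s = tail_stats(ps1d, 0.40)
        assert s.cv == pytest.approx(s.fSTD / s.fMean, rel=1e-12)
        assert s.high90_power == pytest.approx(
            ps1d.power[ps1d.freq_fraction > 0.90].sum(), rel=1e-12
        )

    def test_short_tail_instructs_lower_threshold(self, random_image):
        ps1d = reduce_summed(power_spectrum_2d(random_image))
        with pytest.raises(ParameterError, match="lower the threshold"):
            tail_stats(ps1d, threshold=0.95)

    @pytest.mark.parametrize("threshold", [0.0, 1.0, -0.2])
    def test_threshold_bounds(self, random_image, threshold):
        ps1d = reduce_summed(power_spectrum_2d(random_image))
        with pytest.raises(ParameterError):
            tail_stats(ps1d, threshold=threshold)


class TestInvertMeasure:
    @pytest.mark.parametrize("value, expected", [(0.0, 1.0), (1.0, 0.0), (0.3, 0.7)])
    def test_arithmetic(self, value, expected):
        assert invert_measure(value) == pytest.approx(expected)

    @pytest.mark.parametrize("value", [-0.1, 1.5])
    def test_only_defined_on_normalized_values(self, value):
        with pytest.raises(ParameterError):
            invert_measure(value)
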