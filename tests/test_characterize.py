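import numpy as np
import pytest

from oracles import fitting_oracle, local_means_oracle
from vsseg.characterize import (build_seed_bank, fitting_functions,
                                gaussian_density, local_feature_means,
                                seed_density_grid)
from vsseg.errors import UnusableSeedsError
from vsseg.features import compute_feature_volume
from vsseg.kernels import make_gaussian_kernel


def _features(rng, shape=(7, 7, 7)):
    arr = rng.uniform(0.0, 200.0, size=shape)
    return compute_feature_volume(arr, sigma=0.5)


def _seed_map(shape, n_fg=6, n_bg=6):
    seeds = np.zeros(shape, dtype=np.uint8)
    seeds[1, 1, 1:1 + n_fg] = 1
    seeds[-2, -2, 1:1 + n_bg] = 2
    return seeds


class TestSeedBank:
    def test_collects_both_classes(self, rng):
        fv = _features(rng)
        bank = build_seed_bank(fv, _seed_map(fv.shape), cap=2000, rng_seed=0)
        assert bank.class_feats(1).shape == (6, 3)
        assert bank.class_feats(2).shape == (6, 3)
        assert bank.floor > 0

    def test_cap_subsampling_is_deterministic(self, rng):
        fv = _features(rng, shape=(9, 9, 9))
        seeds = np.zeros(fv.shape, dtype=np.uint8)
        seeds[1:8, 1:8, 1:8] = 1
        seeds[0, :, :] = 2
        b1 = build_seed_bank(fv, seeds, cap=50, rng_seed=7)
        b2 = build_seed_bank(fv, seeds, cap=50, rng_seed=7)
        assert b1.class_feats(1).shape == (50, 3)
        assert np.array_equal(b1.class_feats(1), b2.class_feats(1))

    def test_auto_background_from_border_shell(self, rng):
        fv = _features(rng)
        seeds = np.zeros(fv.shape, dtype=np.uint8)
        seeds[3, 3, 2:5] = 1
        bank = build_seed_bank(fv, seeds, cap=5000, rng_seed=0)
        assert bank.auto_background
        n = fv.shape[0]
        # full border shell of a cube, none of it overlapping the seeds
        assert bank.class_feats(2).shape[0] == n ** 3 - (n - 2) ** 3

    def test_no_foreground_raises(self, rng):
        fv = _features(rng)
        with pytest.raises(UnusableSeedsError):
            build_seed_bank(fv, np.zeros(fv.shape, dtype=np.uint8))


class TestGaussianDensity:
    def test_standard_normal_origin_value(self):
        val = gaussian_density((0, 0, 0), (1, 1, 1))
        assert val == pytest.approx((2 * np.pi) ** -1.5, rel=1e-12)
        assert val == pytest.approx(0.0635, abs=5e-4)

    def test_even_and_nonnegative(self, rng):
        d = rng.normal(size=3)
        v = rng.uniform(0.5, 2.0, size=3)
        assert gaussian_density(d, v) >= 0
        assert gaussian_density(d, v) == pytest.approx(
            gaussian_density(-d, v), rel=1e-12)


class TestLocalMeans:
    def test_full_foreground_degenerates(self, rng):
        fv = _features(rng)
        k = make_gaussian_kernel(1.0)
        means = local_feature_means(fv, np.ones(fv.shape), k)
        # mu_1 is the kernel-smoothed feature image
        from vsseg.kernels import convolve
        for c in range(3):
            want = convolve(fv.channel(c), k) / convolve(
                np.ones(fv.shape), k)
            assert np.allclose(means.mu1[..., c], want, atol=1e-9)
        # mu_2 collapses to the floored-denominator fallback (~0)
        assert np.all(np.abs(means.mu2) < 1e-4)

    def test_constant_features_give_constant_means(self):
        arr = np.full((6, 6, 6), 80.0)
        fv = compute_feature_volume(arr, 0.5)
        h = np.full(fv.shape, 0.5)
        means = local_feature_means(fv, h, make_gaussian_kernel(1.0))
        assert np.allclose(means.mu1[..., 0], 80.0, atol=1e-9)
        assert np.allclose(means.mu2[..., 0], 80.0, atol=1e-9)

    def test_matches_bruteforce_window_means(self, rng):
        fv = _features(rng)
        h = rng.uniform(0.05, 0.95, size=fv.shape)
        k = make_gaussian_kernel(1.0)
        means = local_feature_means(fv, h, k)
        mu1, mu2 = local_means_oracle(fv.data, h, k)
        assert np.allclose(means.mu1, mu1, atol=1e-9)
        assert np.allclose(means.mu2, mu2, atol=1e-9)


class TestFittingFunctions:
    def test_omega_zero_ignores_the_contour(self, rng):
        fv = _features(rng)
        bank = build_seed_bank(fv, _seed_map(fv.shape))
        k = make_gaussian_kernel(1.5)
        ha = rng.uniform(0, 1, size=fv.shape)
        hb = rng.uniform(0, 1, size=fv.shape)
        fa = fitting_functions(fv, bank, local_feature_means(fv, ha, k),
                               ha, k, omega=0.0)
        fb = fitting_functions(fv, bank, local_feature_means(fv, hb, k),
                               hb, k, omega=0.0)
        assert np.array_equal(fa.p1, fb.p1)
        assert np.array_equal(fa.p2, fb.p2)

    def test_omega_one_never_touches_seed_features(self, rng):
        fv = _features(rng)
        k = make_gaussian_kernel(1.5)
        h = rng.uniform(0, 1, size=fv.shape)
        means = local_feature_means(fv, h, k)
        bank_a = build_seed_bank(fv, _seed_map(fv.shape))
        bank_b = build_seed_bank(fv, _seed_map(fv.shape))
        bank_b.feats = (bank_b.feats[1][::-1].copy(),
                        bank_b.feats[0][::-1].copy())  # scrambled classes
        fa = fitting_functions(fv, bank_a, means, h, k, omega=1.0)
        fb = fitting_functions(fv, bank_b, means, h, k, omega=1.0)
        assert np.array_equal(fa.p1, fb.p1)
        assert np.array_equal(fa.p2, fb.p2)

    @pytest.mark.parametrize("omega", [0.0, 0.4, 1.0])
    def test_matches_double_loop_oracle(self, rng, omega):
        fv = _features(rng)
        bank = build_seed_bank(fv, _seed_map(fv.shape))
        k = make_gaussian_kernel(1.5)
        h = rng.uniform(0, 1, size=fv.shape)
        means = local_feature_means(fv, h, k)
        got = fitting_functions(fv, bank, means, h, k, omega)
        wiv = fv.channel(2)
        p1, p2 = fitting_oracle(fv.data, wiv, bank.floor,
                                bank.class_feats(1), bank.class_feats(2),
                                means.mu1, means.mu2, h, k, omega)
        assert np.allclose(got.p1, p1, atol=1e-9)
        assert np.allclose(got.p2, p2, atol=1e-9)

    def test_convex_blend_bounded_by_terms(self, rng):
        fv = _features(rng)
        bank = build_seed_bank(fv, _seed_map(fv.shape))
        k = make_gaussian_kernel(1.5)
        h = rng.uniform(0, 1, size=fv.shape)
        means = local_feature_means(fv, h, k)
        seed = fitting_functions(fv, bank, means, h, k, 0.0).p1
        local = fitting_functions(fv, bank, means, h, k, 1.0).p1
        mid = fitting_functions(fv, bank, means, h, k, 0.4).p1
        assert np.all(mid >= np.minimum(seed, local) - 1e-12)
        assert np.all(mid <= np.maximum(seed, local) + 1e-12)

    def test_seed_densities_separate_phases_on_phantom(self):
        from vsseg.phantoms import PhantomSpec, make_phantom, \
            make_seed_strokes
        spec = PhantomSpec(size=24, radius=7)
        img, truth = make_phantom(spec)
        seeds = make_seed_strokes(truth, n_strokes=1, stroke_length=4,
                                  rng_seed=2)
        fv = compute_feature_volume(img.data, 0.5)
        bank = build_seed_bank(fv, seeds)
        p1 = seed_density_grid(fv, bank, 1)
        p2 = seed_density_grid(fv, bank, 2)
        assert p1[truth].mean() > p1[~truth].mean()
        assert p2[~truth].mean() > p2[truth].mean()
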