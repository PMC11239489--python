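"""Fourier-shell machinery: FSC, phase randomization, filters, noise."""

import numpy as np
import pytest

from blush.volume_io import Volume
from blush.spectral import (
    FSCCurve,
    GaussianCovariance,
    NoiseSpectrum,
    anisotropic_gaussian_filter,
    apply_shell_filter,
    compute_fsc,
    covariance_from_resolution,
    estimate_rho,
    make_colored_noise,
    make_lowpass,
    randomize_phases,
    shell_counts,
    shell_of_resolution,
    shell_power,
    solvent_corrected_fsc,
)


def noise_volume(seed, n=32, voxel=1.5):
    rng = np.random.default_rng(seed)
    return Volume(rng.standard_normal((n, n, n)).astype(np.float32), voxel)


class TestFSC:
    def test_self_correlation_is_exactly_one(self, small_volume):
        fsc = compute_fsc(small_volume, small_volume)
        assert np.all(fsc.values == 1.0)

    def test_sign_flip_gives_minus_one(self, small_volume):
        neg = small_volume.with_grid(-small_volume.grid)
        fsc = compute_fsc(small_volume, neg)
        assert np.all(fsc.values[1:] == -1.0)

    def test_symmetric_and_scale_invariant(self, small_volume):
        other = noise_volume(5)
        ab = compute_fsc(small_volume, other).values
        ba = compute_fsc(other, small_volume).values
        assert np.array_equal(ab, ba)
        scaled = compute_fsc(
            small_volume.with_grid(small_volume.grid * 7.5), other
        ).values
        assert np.allclose(ab, scaled, atol=1e-9)

    def test_null_distribution_of_independent_noise(self):
        """|FSC| of independent white noise stays within ~3/sqrt(n_s)."""
        n = 32
        counts = shell_counts(n)
        hits = total = 0
        for seed in range(100):
            a = noise_volume(2 * seed + 1000, n)
            b = noise_volume(2 * seed + 1001, n)
            vals = compute_fsc(a, b).values
            for s in range(1, n // 2 + 1):
                total += 1
                if abs(vals[s]) <= 3.0 / np.sqrt(counts[s]):
                    hits += 1
        assert hits / total >= 0.95

    def test_shape_mismatch_rejected(self, small_volume):
        with pytest.raises(ValueError):
            compute_fsc(small_volume, noise_volume(0, n=16))


class TestPhaseRandomization:
    def test_per_shell_power_preserved(self, small_volume, rng):
        out = randomize_phases(small_volume, 8, rng)
        p0 = shell_power(small_volume)
        p1 = shell_power(out)
        assert np.max(np.abs(p1 - p0) / p0) < 1e-5

    def test_parseval_total_power(self, small_volume, rng):
        out = randomize_phases(small_volume, 4, rng)
        t0 = (small_volume.grid.astype(np.float64) ** 2).sum()
        t1 = (out.grid.astype(np.float64) ** 2).sum()
        assert t1 == pytest.approx(t0, rel=1e-6)

    def test_low_shells_untouched(self, small_volume, rng):
        out = randomize_phases(small_volume, 8, rng)
        F0 = np.fft.fftn(small_volume.grid.astype(np.float64))
        F1 = np.fft.fftn(out.grid.astype(np.float64))
        from blush.spectral import shell_index_map

        low = shell_index_map(32) < 8
        ref = np.abs(F0[low]).max()
        assert np.abs(F0[low] - F1[low]).max() / ref < 1e-5

    def test_fsc_one_below_and_zero_mean_beyond(self, small_volume):
        s0 = 8
        beyond = []
        for seed in range(50):
            out = randomize_phases(small_volume, s0,
                                   np.random.default_rng(seed))
            vals = compute_fsc(small_volume, out).values
            assert np.all(vals[1:s0] > 0.999)
            beyond.append(vals[s0 + 1:])
        assert abs(np.mean(beyond)) < 0.05


class TestSolventCorrection:
    def test_noise_pair_corrects_to_zero_beyond(self):
        ones = Volume(np.ones((32, 32, 32), dtype=np.float32), 1.5)
        beyond = []
        for seed in range(12):
            a = noise_volume(3 * seed + 50)
            b = noise_volume(3 * seed + 51)
            fsc = solvent_corrected_fsc(a, b, ones, rand_shell=8,
                                        rng=np.random.default_rng(seed))
            beyond.append(fsc.values[11:])
        assert abs(np.mean(beyond)) < 0.05

    def test_low_shells_equal_masked_fsc(self, phantom_and_mask):
        phantom, mask = phantom_and_mask
        b = phantom.with_grid(phantom.grid
                              + 0.3 * noise_volume(9).grid)
        fsc = solvent_corrected_fsc(phantom, b, mask, rand_shell=8,
                                    rng=np.random.default_rng(0))
        am = phantom.with_grid(phantom.grid * mask.grid)
        bm = b.with_grid(b.grid * mask.grid)
        plain = compute_fsc(am, bm)
        # correction only applies above rand_shell + margin
        assert np.allclose(fsc.values[:11], plain.values[:11], atol=1e-12)

    def test_correction_formula(self):
        # (0.8 - 0.5) / (1 - 0.5) = 0.6
        assert (0.8 - 0.5) / (1 - 0.5) == pytest.approx(0.6)


class TestRhoEstimation:
    def test_first_crossing_rule(self):
        vals = np.array([1, 1, 0.9, 0.5, 0.10, 0.3] + [0.0] * 11)
        fsc = FSCCurve(values=vals, n=32, voxel_size=1.5)
        assert estimate_rho(fsc) == 3

    def test_no_crossing_gives_nyquist(self):
        fsc = FSCCurve(values=np.ones(17), n=32, voxel_size=1.5)
        assert estimate_rho(fsc) == 16

    def test_immediate_crossing_gives_one(self):
        vals = np.ones(17)
        vals[1:] = 0.05
        fsc = FSCCurve(values=vals, n=32, voxel_size=1.5)
        assert estimate_rho(fsc) == 1

    def test_self_fsc_gives_nyquist(self, small_volume):
        assert estimate_rho(compute_fsc(small_volume, small_volume)) == 16


class TestShellFilters:
    def test_constant_volume_unchanged_by_lowpass(self):
        v = Volume(np.full((32, 32, 32), 2.5, dtype=np.float32), 1.0)
        out = apply_shell_filter(v, make_lowpass(4, 32))
        assert np.abs(out.grid - 2.5).max() < 1e-5

    def test_hard_cutoff_zeroes_high_shells(self, small_volume):
        out = apply_shell_filter(small_volume, make_lowpass(6, 32))
        p = shell_power(out)
        assert np.all(p[7:] < 1e-12 * p[:7].max())

    def test_resolution_to_shell_rounds_down(self):
        assert shell_of_resolution(15.0, 64, 1.5) == 6  # 64*1.5/15 = 6.4


class TestGaussianFilter:
    def test_zero_covariance_is_identity(self, small_volume):
        out = anisotropic_gaussian_filter(small_volume,
                                          GaussianCovariance(np.zeros((3, 3))))
        assert np.abs(out.grid - small_volume.grid).max() < 1e-5

    def test_matches_brute_force_spatial_convolution(self):
        """Point source blurred with isotropic C equals periodic real-space
        convolution with the same Gaussian (independent oracle)."""
        n, sig = 16, 2.0
        g = np.zeros((n, n, n), dtype=np.float32)
        g[8, 8, 8] = 1.0
        out = anisotropic_gaussian_filter(Volume(g, 1.0),
                                          GaussianCovariance.isotropic(sig**2))
        z, y, x = np.meshgrid(*(np.arange(n) - 8,) * 3, indexing="ij")
        ker = np.zeros((n, n, n))
        for dz in (-n, 0, n):
            for dy in (-n, 0, n):
                for dx in (-n, 0, n):
                    ker += np.exp(-((z + dz) ** 2 + (y + dy) ** 2
                                    + (x + dx) ** 2) / (2 * sig**2))
        ker /= ker.sum()
        ref = np.fft.ifftn(np.fft.fftn(np.fft.ifftshift(ker))
                           * np.fft.fftn(g.astype(np.float64))).real
        err = np.sqrt(((out.grid - ref) ** 2).mean() / (ref**2).mean())
        assert err < 1e-4

    def test_extreme_axis_variance_flattens_that_axis(self, small_volume):
        C = np.diag([0.0, 0.0, 1e4])  # huge variance along z (C is x,y,z)
        out = anisotropic_gaussian_filter(small_volume, GaussianCovariance(C))
        var_along_z = out.grid.var(axis=0).mean()
        assert var_along_z < 1e-6 * small_volume.grid.var()

    def test_axis_permutation_equivariance(self, small_volume):
        C = np.diag([1.0, 4.0, 9.0])
        out1 = anisotropic_gaussian_filter(small_volume, GaussianCovariance(C))
        # swap x and y in both the volume and the covariance
        swapped = small_volume.with_grid(small_volume.grid.swapaxes(1, 2))
        Cp = np.diag([4.0, 1.0, 9.0])
        out2 = anisotropic_gaussian_filter(swapped, GaussianCovariance(Cp))
        assert np.abs(out1.grid.swapaxes(1, 2) - out2.grid).max() < 1e-5

    def test_covariance_from_resolution_half_gain(self):
        R = 10.0
        cov = covariance_from_resolution(R)
        k = 1.0 / R
        gain = np.exp(-2 * np.pi**2 * cov.C[0, 0] * k**2)
        assert gain == pytest.approx(0.5, rel=1e-12)


class TestColoredNoise:
    def test_zero_spectrum_gives_zero_volume(self, rng):
        out = make_colored_noise(16, NoiseSpectrum(np.zeros(9)), rng)
        assert np.all(out.grid == 0)

    def test_seed_determinism(self):
        sp = NoiseSpectrum.flat(16)
        a = make_colored_noise(16, sp, np.random.default_rng(3))
        b = make_colored_noise(16, sp, np.random.default_rng(3))
        assert np.array_equal(a.grid, b.grid)

    def test_flat_spectrum_power_is_flat(self):
        """Per-shell mean power of flat-spectrum noise is flat within
        3 standard errors (Monte-Carlo spectrum estimator)."""
        n, draws = 16, 1000
        sp = NoiseSpectrum.flat(n)
        counts = shell_counts(n)
        acc = np.zeros(n // 2 + 1)
        acc2 = np.zeros(n // 2 + 1)
        for seed in range(draws):
            v = make_colored_noise(n, sp, np.random.default_rng(seed))
            p = shell_power(v) / counts
            acc += p
            acc2 += p**2
        mean = acc / draws
        se = np.sqrt((acc2 / draws - mean**2) / draws)
        overall = mean[1:-1].mean()
        dev = np.abs(mean[1:-1] - overall)
        assert np.all(dev <= 3.0 * se[1:-1] + 1e-9)
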