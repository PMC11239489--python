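"""Projection/backprojection, alignment, spectral trailing and the
refinement loop's reduction properties."""

import numpy as np
import pytest

from blush.volume_io import Volume
from blush.spectral import FSCCurve, compute_fsc, shell_index_map, shell_power
from blush.synthetic import (
    NoiseModel,
    ParticleDataset,
    PhantomSpec,
    make_orientation_grid,
    make_particle_dataset,
    make_phantom,
)
from blush.denoiser import DenoiserConfig, build_model
from blush.reconstruct import (
    RefinementConfig,
    TrailingState,
    align_particles,
    backproject_halfset,
    classify_denoise_hook,
    fourier_slice_project,
    refine,
    trailing_filter,
    wiener_filter_final,
    wiener_weights,
)


@pytest.fixture(scope="module")
def phantom32():
    spec = PhantomSpec(n=32, voxel_size=1.5, n_blobs=8,
                       blob_radius_range=(2.0, 5.0), seed=2)
    return make_phantom(spec)


@pytest.fixture(scope="module")
def noiseless_data(phantom32):
    phantom, _ = phantom32
    grid = make_orientation_grid(768)
    data = make_particle_dataset(phantom, 1024, grid,
                                 NoiseModel.white(32, 0.0),
                                 np.random.default_rng(0))
    return data, grid


class TestBackprojection:
    def test_dense_noiseless_reconstruction_fidelity(self, phantom32,
                                                     noiseless_data):
        """Exact projections over a dense orientation set reconstruct the
        phantom with FSC > 0.95 up to 80% of Nyquist."""
        phantom, _ = phantom32
        data, _ = noiseless_data
        rec = backproject_halfset(data, 0)
        fsc = compute_fsc(rec, phantom)
        limit = int(0.8 * 16)
        assert fsc.values[1:limit + 1].min() > 0.95

    def test_zero_images_give_zero_volume(self, noiseless_data):
        data, _ = noiseless_data
        zeroed = ParticleDataset(
            images=np.zeros_like(data.images),
            rotations=data.rotations, shifts=data.shifts,
            half_labels=data.half_labels, pixel_size=data.pixel_size)
        rec = backproject_halfset(zeroed, 0)
        assert np.abs(rec.grid).max() < 1e-10

    def test_linearity_under_intensity_doubling(self, noiseless_data):
        data, _ = noiseless_data
        doubled = ParticleDataset(
            images=data.images * 2.0,
            rotations=data.rotations, shifts=data.shifts,
            half_labels=data.half_labels, pixel_size=data.pixel_size)
        a = backproject_halfset(data, 0).grid
        b = backproject_halfset(doubled, 0).grid
        assert np.abs(b - 2 * a).max() < 1e-4 * np.abs(a).max()

    def test_empty_halfset_rejected(self, phantom32):
        phantom, _ = phantom32
        grid = make_orientation_grid(4)
        data = make_particle_dataset(phantom, 4, grid,
                                     NoiseModel.white(32, 0.0),
                                     np.random.default_rng(0))
        data.half_labels[:] = 0
        with pytest.raises(ValueError):
            backproject_halfset(data, 1)

    def test_identity_projection_is_z_sum(self, phantom32):
        phantom, _ = phantom32
        proj = fourier_slice_project(phantom.grid, np.eye(3))
        zsum = phantom.grid.sum(axis=0)
        assert np.abs(proj - zsum).max() < 1e-4 * np.abs(zsum).max()


class TestAlignment:
    def test_noiseless_particles_recover_true_orientations(self, phantom32):
        phantom, _ = phantom32
        grid = make_orientation_grid(64)
        data = make_particle_dataset(phantom, 64, grid,
                                     NoiseModel.white(32, 0.0),
                                     np.random.default_rng(0))
        assign = align_particles(data, phantom, phantom, grid)
        assert np.array_equal(assign, data.grid_indices)

    def test_zero_reference_breaks_ties_to_lowest_index(self, phantom32):
        phantom, _ = phantom32
        grid = make_orientation_grid(16)
        data = make_particle_dataset(phantom, 8, grid,
                                     NoiseModel.white(32, 0.0),
                                     np.random.default_rng(0))
        zeros = Volume(np.zeros_like(phantom.grid), phantom.voxel_size)
        assign = align_particles(data, zeros, zeros, grid)
        assert np.all(assign == 0)

    def test_per_particle_independence(self, phantom32):
        phantom, _ = phantom32
        grid = make_orientation_grid(32)
        data = make_particle_dataset(phantom, 16, grid,
                                     NoiseModel.white(32, 0.0),
                                     np.random.default_rng(0))
        base = align_particles(data, phantom, phantom, grid)
        noisy = ParticleDataset(
            images=data.images.copy(), rotations=data.rotations,
            shifts=data.shifts, half_labels=data.half_labels,
            pixel_size=data.pixel_size, grid_indices=data.grid_indices)
        noisy.images[3] += 50.0 * np.random.default_rng(1).standard_normal(
            (32, 32)).astype(np.float32)
        perturbed = align_particles(noisy, phantom, phantom, grid)
        others = np.arange(16) != 3
        assert np.array_equal(base[others], perturbed[others])


class TestTrailingFilter:
    def test_zeroes_power_above_trail_shell(self, small_volume):
        ts = TrailingState.from_rho(10, 32, 1.5)  # trail 8, nyquist 16
        assert ts.trail_shell == 8
        out = trailing_filter(small_volume, small_volume, ts)
        p = shell_power(out)
        assert np.all(p[9:] < 1e-10 * p[:9].max())

    def test_fallback_bit_equal_above_denoiser_nyquist(self, rng):
        # voxel 1.2 A: denoiser Nyquist shell = floor(32*1.2/3) = 12 < 16
        den = Volume(rng.standard_normal((32, 32, 32)).astype(np.float32), 1.2)
        fb = Volume(rng.standard_normal((32, 32, 32)).astype(np.float32), 1.2)
        ts = TrailingState.from_rho(14, 32, 1.2)
        assert ts.nyquist_shell == 12 and ts.rho > ts.nyquist_shell
        out = trailing_filter(den, fb, ts)
        s = shell_index_map(32)
        Fo = np.fft.fftn(out.grid.astype(np.float64))
        Ff = np.fft.fftn(fb.grid.astype(np.float64))
        hand = s > 12
        assert np.abs(Fo[hand] - Ff[hand]).max() < 1e-3 * np.abs(Ff[hand]).max()
        # between trail (12) and nyquist (12): empty here; below trail from den
        Fd = np.fft.fftn(den.grid.astype(np.float64))
        low = s <= ts.trail_shell
        assert np.abs(Fo[low] - Fd[low]).max() < 1e-3 * np.abs(Fd[low]).max()

    def test_gap_between_trail_and_nyquist_is_zeroed(self, rng):
        den = Volume(rng.standard_normal((32, 32, 32)).astype(np.float32), 1.2)
        fb = Volume(rng.standard_normal((32, 32, 32)).astype(np.float32), 1.2)
        ts = TrailingState.from_rho(13, 32, 1.2)  # trail 11 < nyquist 12 < rho
        out = trailing_filter(den, fb, ts)
        s = shell_index_map(32)
        Fo = np.fft.fftn(out.grid.astype(np.float64))
        gap = (s > 11) & (s <= 12)
        assert np.abs(Fo[gap]).max() < 1e-6 * np.abs(Fo).max()

    def test_shape_mismatch_rejected(self, small_volume, rng):
        other = Volume(rng.standard_normal((16, 16, 16)).astype(np.float32), 1.5)
        ts = TrailingState.from_rho(8, 32, 1.5)
        with pytest.raises(ValueError):
            trailing_filter(small_volume, other, ts)

    def test_trail_state_invariants(self):
        ts = TrailingState.from_rho(1, 32, 1.5)
        assert ts.trail_shell == 1  # clamped to >= 1
        with pytest.raises(ValueError):
            TrailingState(rho=4, trail_shell=6, nyquist_shell=16)


class TestWienerFilter:
    def test_unit_fsc_returns_plain_average(self, rng):
        a = Volume(rng.standard_normal((32, 32, 32)).astype(np.float32), 1.5)
        b = Volume(rng.standard_normal((32, 32, 32)).astype(np.float32), 1.5)
        fsc = FSCCurve(values=np.ones(17), n=32, voxel_size=1.5)
        out = wiener_filter_final(a, b, fsc)
        avg = 0.5 * (a.grid + b.grid)
        assert np.abs(out.grid - avg).max() < 1e-5

    def test_weight_values(self):
        fsc = FSCCurve(values=np.array([1.0, 1.0, 1 / 3, 0.0] + [0.5] * 13),
                       n=32, voxel_size=1.5)
        w = wiener_weights(fsc)
        assert w[1] == pytest.approx(1.0)
        assert w[2] == pytest.approx(0.5)   # 2*(1/3)/(1+1/3)
        assert w[3] == pytest.approx(0.0)

    def test_zero_fsc_shell_is_zeroed(self, rng):
        a = Volume(rng.standard_normal((32, 32, 32)).astype(np.float32), 1.5)
        vals = np.ones(17)
        vals[5] = 0.0
        fsc = FSCCurve(values=vals, n=32, voxel_size=1.5)
        out = wiener_filter_final(a, a, fsc)
        p = shell_power(out)
        assert p[5] < 1e-10 * p[1]


@pytest.fixture(scope="module")
def high_snr_data():
    spec = PhantomSpec(n=32, voxel_size=1.5, n_blobs=8,
                       blob_radius_range=(2.0, 5.0), seed=2)
    phantom, mask = make_phantom(spec)
    grid = make_orientation_grid(96)
    data = make_particle_dataset(phantom, 256, grid,
                                 NoiseModel.colored(32, 1.0),
                                 np.random.default_rng(1))
    return phantom, mask, grid, data


class TestRefinementReduction:

    def test_identity_denoiser_reduces_to_baseline_below_cutoff(
            self, high_snr_data):
        phantom, mask, grid, data = high_snr_data
        ident = build_model(DenoiserConfig(base_channels=(4, 8),
                                           dropout_rate=0.0))
        base = refine(data, None,
                      RefinementConfig(iterations=3, mode="baseline",
                                       seed=0, mask=mask), grid, 16, 8)
        blush = refine(data, ident,
                       RefinementConfig(iterations=3, mode="blush",
                                        seed=0, mask=mask), grid, 16, 8)
        ts = TrailingState.from_rho(blush.rho_trace[-1], 32, 1.5)
        s = shell_index_map(32)
        low = s <= ts.trail_shell
        for rb, rB in zip(base.references, blush.references):
            Fb = np.fft.fftn(rb.grid.astype(np.float64))
            FB = np.fft.fftn(rB.grid.astype(np.float64))
            assert np.abs(Fb[low] - FB[low]).max() < 1e-5 * np.abs(Fb[low]).max()
        assert np.array_equal(base.assignments, blush.assignments)

    def test_identity_denoiser_full_band_gives_identical_assignments(
            self, high_snr_data):
        phantom, mask, grid, data = high_snr_data
        ident = build_model(DenoiserConfig(base_channels=(4, 8),
                                           dropout_rate=0.0))
        base = refine(data, None,
                      RefinementConfig(iterations=3, mode="baseline",
                                       seed=0, mask=mask), grid, 16, 8)
        blush = refine(data, ident,
                       RefinementConfig(iterations=3, mode="blush", seed=0,
                                        mask=mask, trailing_override=16),
                       grid, 16, 8)
        assert np.array_equal(base.assignments, blush.assignments)

    def test_resolution_safety_trail_below_rho(self, high_snr_data):
        """Shells at the reported rho were never populated from the
        denoiser: trail_shell < rho at every iteration."""
        phantom, mask, grid, data = high_snr_data
        ident = build_model(DenoiserConfig(base_channels=(4, 8),
                                           dropout_rate=0.0))
        blush = refine(data, ident,
                       RefinementConfig(iterations=3, mode="blush",
                                        seed=0, mask=mask), grid, 16, 8)
        for rho in blush.rho_trace:
            ts = TrailingState.from_rho(rho, 32, 1.5)
            assert ts.trail_shell < rho or rho == 1

    def test_high_snr_baseline_recovers_phantom(self):
        """Self-consistency: many high-SNR particles over a dense grid
        refine to a map matching the phantom to half-Nyquist."""
        spec = PhantomSpec(n=32, voxel_size=1.5, n_blobs=8,
                           blob_radius_range=(2.0, 5.0), seed=2)
        phantom, mask = make_phantom(spec)
        grid = make_orientation_grid(768)
        data = make_particle_dataset(phantom, 1024, grid,
                                     NoiseModel.colored(32, 0.5),
                                     np.random.default_rng(1))
        res = refine(data, None,
                     RefinementConfig(iterations=3, mode="baseline",
                                      seed=0, mask=mask), grid, 16, 8)
        fsc = compute_fsc(res.volume, phantom)
        assert fsc.values[1:9].min() > 0.9  # up to half-Nyquist

    def test_blush_mode_requires_model(self, high_snr_data):
        phantom, mask, grid, data = high_snr_data
        with pytest.raises(ValueError):
            refine(data, None,
                   RefinementConfig(iterations=1, mode="blush"), grid)


class TestClassificationHook:
    def test_identity_model_preserves_map(self, rng):
        ident = build_model(DenoiserConfig(base_channels=(4, 8),
                                           dropout_rate=0.0))
        v = Volume(rng.standard_normal((32, 32, 32)).astype(np.float32), 1.5)
        out = classify_denoise_hook(v, ident, patch_edge=16, overlap=8)
        assert out.grid.shape == v.grid.shape
        assert out.voxel_size == v.voxel_size
        assert np.abs(out.grid - v.grid).max() < 1e-5

    def test_nonfinite_map_rejected(self, rng):
        ident = build_model(DenoiserConfig(base_channels=(4, 8),
                                           dropout_rate=0.0))
        g = rng.standard_normal((32, 32, 32)).astype(np.float32)
        v = Volume(g, 1.5)
        v.grid[0, 0, 0] = np.inf
        with pytest.raises(ValueError):
            classify_denoise_hook(v, ident)
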