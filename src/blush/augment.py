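"""Training-pair construction for noise2noise denoiser training.

A half-map pair shares signal but carries independent noise.  A training
example is built from one pair by a shared augmentation: the *input* patch
is the OTHER half-map plus fresh colored noise, passed through an
augmentation operator H (anisotropic Gaussian filter with covariance C,
affine transform A, crop to a cubic patch, voxel standardization); the
*target* patch is this half-map — blended with its 15-A low-pass inside the
complement of the molecule mask, so disordered regions keep plausible
smooth density rather than being zeroed — passed through H with its own
covariance C-bar but the SAME A and crop.  Cross-half input/target indexing
is what makes this noise2noise: the network never sees a clean map.

The input-side covariance C never cuts at higher resolution than the
target-side C-bar, so the network is never asked to sharpen — a deliberate
guard against hallucinated high-resolution features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import affine_transform
from scipy.spatial.transform import Rotation

from .volume_io import Volume
from .spectral import (
    GaussianCovariance,
    NoiseSpectrum,
    anisotropic_gaussian_filter,
    apply_shell_filter,
    covariance_from_resolution,
    make_colored_noise,
    make_lowpass,
    shell_of_resolution,
)

__all__ = [
    "HalfMapPair",
    "AffineTransform",
    "AugmentationSpec",
    "AugmentationPolicy",
    "TrainingExample",
    "apply_H",
    "make_input_y",
    "make_target_ybar",
    "sample_spec",
    "build_example",
    "ZeroVariancePatch",
]

STANDARDIZATION_TOL = 1e-6


class ZeroVariancePatch(ValueError):
    """Raised when a crop has (near-)zero variance and cannot be standardized."""


@dataclass
class HalfMapPair:
    """Two independently reconstructed volumes sharing signal, plus an
    optional smooth molecule mask (values in [0, 1])."""

    x0: Volume
    x1: Volume
    mask: Volume | None = None
    identifier: str = ""

    def __post_init__(self) -> None:
        self._blend_cache: dict = {}
        self._fft_cache: dict = {}
        if self.x0.grid.shape != self.x1.grid.shape:
            raise ValueError("half-maps must share shape")
        if not np.isclose(self.x0.voxel_size, self.x1.voxel_size, rtol=1e-6):
            raise ValueError("half-maps must share voxel size")
        if self.mask is not None:
            if self.mask.grid.shape != self.x0.grid.shape:
                raise ValueError("mask shape mismatch")
            if self.mask.grid.min() < -1e-6 or self.mask.grid.max() > 1 + 1e-6:
                raise ValueError("mask values must lie in [0, 1]")

    def half(self, k: int) -> Volume:
        if k not in (0, 1):
            raise ValueError("half index must be 0 or 1")
        return self.x0 if k == 0 else self.x1


@dataclass
class AffineTransform:
    """Rigid transform: rotation about the volume center plus a translation
    in voxels.  Rotation must be a proper orthonormal matrix."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3, translation length 3")
        RtR = self.rotation.T @ self.rotation
        if not np.allclose(RtR, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-6):
            raise ValueError("rotation must have determinant +1")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class AugmentationSpec:
    """One fully drawn augmentation: input/target covariances, shared
    affine transform and crop corner, noise spectrum, recycle count."""

    C: GaussianCovariance
    C_bar: GaussianCovariance
    A: AffineTransform
    noise: NoiseSpectrum
    noise_scale: float
    crop_corner: tuple[int, int, int]
    r: int
    # base resolution cutoffs (A) the covariances were built from; the
    # input-side cutoff is never finer than the target-side one
    resolution_input: float | None = None
    resolution_target: float | None = None

    def __post_init__(self) -> None:
        if not (isinstance(self.r, (int, np.integer)) and 0 <= self.r <= 5):
            raise ValueError(f"recycle count r must be an integer in [0, 5], got {self.r}")


@dataclass
class TrainingExample:
    """An (input, target) patch pair, both standardized to mean 0 / std 1."""

    y: np.ndarray
    y_bar: np.ndarray
    r: int
    identifier: str = ""

    def __post_init__(self) -> None:
        for name, p in (("y", self.y), ("y_bar", self.y_bar)):
            mu = float(p.mean(dtype=np.float64))
            sd = float(p.std(dtype=np.float64))
            if abs(mu) > STANDARDIZATION_TOL or abs(sd - 1.0) > STANDARDIZATION_TOL:
                raise ValueError(f"{name} violates the standardization contract")


@dataclass
class AugmentationPolicy:
    """Sampling ranges for the augmentation draw.

    Resolution cutoffs are in Angstrom (the covariance gives gain 0.5 at the
    cutoff frequency); anisotropy multiplies per-axis sigma; translations are
    in voxels; rotations are uniform over SO(3); the recycle count r is
    uniform over {0, ..., 5}.
    """

    patch_edge: int = 64
    resolution_range: tuple[float, float] = (4.0, 20.0)
    anisotropy_range: tuple[float, float] = (0.7, 1.4)
    translation_range: float = 2.0
    noise_scale_range: tuple[float, float] = (0.0, 1.0)
    noise_knee_shell: float = 4.0
    lowpass_fill_resolution: float = 15.0
    r_max: int = 5
    max_retries: int = 10

    def __post_init__(self) -> None:
        lo, hi = self.resolution_range
        if not (0 < lo <= hi):
            raise ValueError("empty resolution range")
        if self.noise_scale_range[0] > self.noise_scale_range[1]:
            raise ValueError("empty noise range")


def _standardize(patch: np.ndarray) -> np.ndarray:
    p = np.asarray(patch, dtype=np.float64)
    std = float(p.std())
    if std < 1e-9:
        raise ZeroVariancePatch("patch has (near-)zero variance")
    return ((p - p.mean()) / std).astype(np.float32)


def _resample_affine(grid: np.ndarray, A: AffineTransform) -> np.ndarray:
    """Resample so that out(x) = in(R^-1 (x - c) + c - t), i.e. the volume
    is rotated by R about its center and shifted by t, with trilinear
    interpolation and volume-mean fill outside the source grid."""
    n = grid.shape[0]
    center = (np.array(grid.shape, dtype=float) - 1.0) / 2.0
    Rinv = A.rotation.T
    offset = center - Rinv @ (center + A.translation)
    return affine_transform(
        grid, Rinv, offset=offset, order=1,
        mode="constant", cval=float(grid.mean()),
    )


def _transform_crop_standardize(grid: np.ndarray, A: AffineTransform,
                                crop_corner: tuple[int, int, int],
                                patch_edge: int) -> np.ndarray:
    n = grid.shape[0]
    cz, cy, cx = crop_corner
    e = patch_edge
    if min(cz, cy, cx) < 0 or max(cz, cy, cx) + e > n:
        raise ValueError(
            f"crop corner {crop_corner} (+{e}) outside grid of edge {n}")
    moved = _resample_affine(grid, A)
    return _standardize(moved[cz:cz + e, cy:cy + e, cx:cx + e])


def apply_H(v: Volume, C: GaussianCovariance, A: AffineTransform,
            crop_corner: tuple[int, int, int],
            patch_edge: int = 64) -> np.ndarray:
    """The augmentation operator H: Gaussian filter, affine resample, crop,
    standardize — in that order."""
    filtered = anisotropic_gaussian_filter(v, C)
    return _transform_crop_standardize(filtered.grid, A, crop_corner,
                                       patch_edge)


def _half_fft(pair: HalfMapPair, idx: int) -> np.ndarray:
    F = pair._fft_cache.get(idx)
    if F is None:
        F = np.fft.fftn(pair.half(idx).grid.astype(np.float64))
        pair._fft_cache[idx] = F
    return F


def make_input_y(pair: HalfMapPair, k: int, spec: AugmentationSpec,
                 rng: np.random.Generator,
                 patch_edge: int = 64) -> np.ndarray:
    """Input patch for target half ``k``: the OTHER half-map plus fresh
    colored noise, through H with covariance C.

    Works on cached Fourier transforms: the noise draw, the addition and
    the Gaussian filter all compose in Fourier space, so only one inverse
    transform is needed per example.
    """
    from .spectral import colored_noise_fft, gaussian_transfer

    source = pair.half(1 - k)
    F = _half_fft(pair, 1 - k)
    if spec.noise_scale > 0:
        F = F + spec.noise_scale * colored_noise_fft(source.n, spec.noise, rng)
    H = gaussian_transfer(source.n, source.voxel_size, spec.C)
    filtered = np.fft.ifftn(F * H).real.astype(np.float32)
    return _transform_crop_standardize(filtered, spec.A, spec.crop_corner,
                                       patch_edge)


def make_target_ybar(pair: HalfMapPair, k: int, spec: AugmentationSpec,
                     patch_edge: int = 64,
                     lowpass_fill_resolution: float = 15.0) -> np.ndarray:
    """Target patch for half ``k``: the half-map blended with its low-pass
    outside the mask, through H with covariance C-bar and the SAME A/crop.

    The blended volume's Fourier transform is cached per pair, so each
    example costs one transfer multiplication and one inverse transform.
    """
    from .spectral import gaussian_transfer

    x = pair.half(k)
    key = (k, round(lowpass_fill_resolution, 6))
    F = pair._blend_cache.get(key)
    if F is None:
        if pair.mask is None:
            blended = x.grid.astype(np.float64)
        else:
            cut = shell_of_resolution(lowpass_fill_resolution, x.n,
                                      x.voxel_size)
            lp = apply_shell_filter(x, make_lowpass(max(1, cut), x.n))
            m = pair.mask.grid
            blended = (x.grid * m + lp.grid * (1.0 - m)).astype(np.float64)
        F = np.fft.fftn(blended)
        pair._blend_cache[key] = F
    H = gaussian_transfer(x.n, x.voxel_size, spec.C_bar)
    filtered = np.fft.ifftn(F * H).real.astype(np.float32)
    return _transform_crop_standardize(filtered, spec.A, spec.crop_corner,
                                       patch_edge)


def sample_spec(rng: np.random.Generator, policy: AugmentationPolicy,
                n: int) -> AugmentationSpec:
    """Draw one augmentation.  The input-side cutoff is constrained to be at
    or below (coarser than) the target-side cutoff so the network is never
    trained to sharpen."""
    lo, hi = policy.resolution_range
    res_a, res_b = rng.uniform(lo, hi, size=2)
    res_target = min(res_a, res_b)
    res_input = max(res_a, res_b)  # coarser or equal

    def _aniso_cov(resolution: float) -> GaussianCovariance:
        base = covariance_from_resolution(resolution).C[0, 0]
        scales = rng.uniform(*policy.anisotropy_range, size=3) ** 2
        R = Rotation.random(random_state=rng).as_matrix()
        return GaussianCovariance(R @ np.diag(base * scales) @ R.T)

    C = _aniso_cov(res_input)
    C_bar = _aniso_cov(res_target)
    rot = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-policy.translation_range, policy.translation_range, size=3)
    A = AffineTransform(rot, t)
    e = policy.patch_edge
    if e > n:
        raise ValueError(f"patch_edge {e} exceeds volume edge {n}")
    corner = tuple(int(c) for c in rng.integers(0, n - e + 1, size=3))
    noise_scale = float(rng.uniform(*policy.noise_scale_range))
    spectrum = NoiseSpectrum.lorentzian(n, 1.0, policy.noise_knee_shell)
    r = int(rng.integers(0, policy.r_max + 1))
    return AugmentationSpec(C=C, C_bar=C_bar, A=A, noise=spectrum,
                            noise_scale=noise_scale, crop_corner=corner, r=r,
                            resolution_input=res_input,
                            resolution_target=res_target)


def resolution_cutoff_of(cov: GaussianCovariance) -> float:
    """Geometric-mean resolution at which the Gaussian transfer reaches 0.5
    (inverse of :func:`covariance_from_resolution` for isotropic C)."""
    sigma2 = float(np.linalg.eigvalsh(cov.C).mean())
    return float(np.sqrt(sigma2 * 2.0 * np.pi**2 / np.log(2.0)))


def build_example(pair: HalfMapPair, k: int, rng: np.random.Generator,
                  policy: AugmentationPolicy) -> TrainingExample:
    """Draw one spec and build the (y, y_bar) pair with shared A and crop.

    Zero-variance crops are resampled up to ``policy.max_retries`` times.
    """
    last_err: Exception | None = None
    for _ in range(policy.max_retries):
        spec = sample_spec(rng, policy, pair.x0.n)
        try:
            y = make_input_y(pair, k, spec, rng, policy.patch_edge)
            y_bar = make_target_ybar(pair, k, spec, policy.patch_edge,
                                     policy.lowpass_fill_resolution)
        except ZeroVariancePatch as err:
            last_err = err
            continue
        return TrainingExample(y=y, y_bar=y_bar, r=spec.r,
                               identifier=f"{pair.identifier}:k{k}")
    raise ZeroVariancePatch(
        f"no usable crop after {policy.max_retries} draws: {last_err}"
    )
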