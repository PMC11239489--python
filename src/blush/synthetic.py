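"""Synthetic phantoms, half-map pairs and particle stacks.

Everything the rest of the package consumes can be generated here without
downloads: Gaussian-blob phantoms standing in for macromolecular density,
smooth molecule masks with optional "disordered" sub-regions (the analogue
of detergent micelles — dense but unstructured texture the mask excludes),
half-map pairs sharing signal but carrying independent colored noise (the
statistical contract noise2noise training relies on), and stacks of noisy
2D projections with ground-truth orientations for toy refinements.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .volume_io import Volume
from .spectral import (
    NoiseSpectrum,
    make_colored_noise,
    make_lowpass,
    apply_shell_filter,
    shell_of_resolution,
)
from .augment import HalfMapPair

__all__ = [
    "PhantomSpec",
    "NoiseModel",
    "ParticleDataset",
    "make_phantom",
    "make_halfmap_pair",
    "make_particle_dataset",
    "make_training_corpus",
    "make_disorder_volumes",
    "randomize_dataset_phases",
    "make_orientation_grid",
    "project_volume",
]


@dataclass
class PhantomSpec:
    """Recipe for a blob phantom.

    Blobs are anisotropic 3D Gaussians — deliberately not atomic models, so
    the synthetic corpus carries smooth plausible density without implying
    atomic realism.  ``disorder_region``, when set, is a sub-box (corner and
    edge, voxels) filled with band-limited (>= ``disorder_resolution`` A)
    random texture and excluded from the mask, emulating micelle-like
    density.
    """

    n: int = 32
    voxel_size: float = 1.5
    n_blobs: int = 8
    blob_radius_range: tuple[float, float] = (3.0, 7.0)  # Angstrom
    blob_weight_range: tuple[float, float] = (0.5, 1.5)
    disorder_region: tuple[tuple[int, int, int], int] | None = None
    disorder_resolution: float = 20.0
    disorder_amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n % 2:
            raise ValueError("n must be even")
        if self.disorder_region is not None:
            (cz, cy, cx), e = self.disorder_region
            for c in (cz, cy, cx):
                if not 0 <= c <= self.n - e:
                    raise ValueError("disorder region outside grid")


@dataclass
class NoiseModel:
    """Noise recipe: a per-shell amplitude spectrum and a scale factor.
    Draws are independent per half-set / per particle by construction
    (each consumes fresh values from the caller's seeded stream)."""

    spectrum: NoiseSpectrum
    scale: float = 1.0

    @classmethod
    def colored(cls, n: int, scale: float = 1.0,
                knee_shell: float = 4.0) -> "NoiseModel":
        return cls(NoiseSpectrum.lorentzian(n, 1.0, knee_shell), scale)

    @classmethod
    def white(cls, n: int, scale: float = 1.0) -> "NoiseModel":
        return cls(NoiseSpectrum.flat(n, 1.0), scale)

    def draw(self, n: int, voxel_size: float,
             rng: np.random.Generator) -> np.ndarray:
        noise = make_colored_noise(n, self.spectrum, rng, voxel_size)
        return noise.grid * self.scale


@dataclass
class ParticleDataset:
    """Stack of noisy 2D projections with orientation metadata.

    ``rotations`` are the ground-truth/current rotation matrices (object
    rotation; images are projections of the rotated volume along z).
    ``half_labels`` assign each particle to half-set 0 or 1.
    """

    images: np.ndarray  # (n_particles, n, n)
    rotations: np.ndarray  # (n_particles, 3, 3)
    shifts: np.ndarray  # (n_particles, 2) in Angstrom (y, x)
    half_labels: np.ndarray  # (n_particles,) in {0, 1}
    pixel_size: float
    snr: float | None = None
    grid_indices: np.ndarray | None = None  # ground-truth grid index, if any

    def __post_init__(self) -> None:
        npart = len(self.images)
        if not (len(self.rotations) == len(self.half_labels)
                == len(self.shifts) == npart):
            raise ValueError("metadata length mismatch")
        labels = set(np.unique(self.half_labels).tolist())
        if not labels <= {0, 1}:
            raise ValueError("half labels must be 0/1")
        if 0 not in labels or 1 not in labels:
            raise ValueError("both half-sets must be nonempty")

    @property
    def n_particles(self) -> int:
        return len(self.images)

    def half_indices(self, half: int) -> np.ndarray:
        return np.nonzero(self.half_labels == half)[0]


def _blob_field(n: int, voxel: float, centers, radii, weights,
                aniso) -> np.ndarray:
    z, y, x = np.meshgrid(*(np.arange(n, dtype=np.float64),) * 3, indexing="ij")
    out = np.zeros((n, n, n))
    for c, r, w, a in zip(centers, radii, weights, aniso):
        sig = (r / voxel) * a  # per-axis sigma, voxels
        d2 = ((z - c[0]) / sig[0]) ** 2 + ((y - c[1]) / sig[1]) ** 2 \
            + ((x - c[2]) / sig[2]) ** 2
        out += w * np.exp(-0.5 * d2)
    return out


def make_phantom(spec: PhantomSpec) -> tuple[Volume, Volume]:
    """Build a blob phantom and its smooth molecule mask.

    The mask is a soft-edged indicator of the blob region, values in [0, 1],
    ~1 at blob centers; the disordered sub-region is excluded from the mask
    but filled with low-frequency random texture in the density.
    """
    rng = np.random.default_rng(spec.seed)
    n, voxel = spec.n, spec.voxel_size
    margin = max(2.0, spec.blob_radius_range[1] / voxel)
    if spec.n_blobs > 0:
        centers = rng.uniform(margin, n - 1 - margin, size=(spec.n_blobs, 3))
        radii = rng.uniform(*spec.blob_radius_range, size=spec.n_blobs)
        weights = rng.uniform(*spec.blob_weight_range, size=spec.n_blobs)
        aniso = rng.uniform(0.7, 1.4, size=(spec.n_blobs, 3))
        density = _blob_field(n, voxel, centers, radii, weights, aniso)
        # soft mask: normalized blob support, squashed to [0, 1]
        support = _blob_field(n, voxel, centers,
                              radii * 1.6, np.ones(spec.n_blobs), aniso)
        peak_floor = 0.15
        mask = np.clip(support / peak_floor, 0.0, 1.0)
    else:
        density = np.zeros((n, n, n))
        mask = np.zeros((n, n, n))
    if spec.disorder_region is not None:
        (cz, cy, cx), e = spec.disorder_region
        tex = make_colored_noise(n, NoiseSpectrum.flat(n), rng, voxel)
        cut = shell_of_resolution(spec.disorder_resolution, n, voxel)
        tex = apply_shell_filter(tex, make_lowpass(max(1, cut), n))
        t = tex.grid / (np.std(tex.grid) + 1e-12) * spec.disorder_amplitude
        box = np.s_[cz:cz + e, cy:cy + e, cx:cx + e]
        density[box] += np.abs(t[box])
        mask[box] = np.minimum(mask[box], 0.05)
    return (
        Volume(density.astype(np.float32), voxel),
        Volume(mask.astype(np.float32), voxel),
    )


def make_halfmap_pair(phantom: Volume, mask: Volume | None, noise: NoiseModel,
                      rng: np.random.Generator,
                      identifier: str = "synthetic") -> HalfMapPair:
    """Two volumes sharing the phantom's signal with independent noise."""
    n0 = noise.draw(phantom.n, phantom.voxel_size, rng)
    n1 = noise.draw(phantom.n, phantom.voxel_size, rng)
    x0 = phantom.with_grid(phantom.grid + n0)
    x1 = phantom.with_grid(phantom.grid + n1)
    return HalfMapPair(x0=x0, x1=x1, mask=mask, identifier=identifier)


def make_orientation_grid(n_orientations: int, seed: int = 7) -> np.ndarray:
    """Deterministic quasi-uniform set of rotation matrices over SO(3)."""
    rng = np.random.default_rng(seed)
    return Rotation.random(n_orientations, random_state=rng).as_matrix()


def project_volume(vol: Volume, rotation: np.ndarray) -> np.ndarray:
    """Central-slice projection of the rotated volume along z.

    Implemented in Fourier space (slice extraction with trilinear
    interpolation), the exact adjoint of the gridded insertion used by
    backprojection.
    """
    from .reconstruct import fourier_slice_project  # local import: cycle

    return fourier_slice_project(vol.grid, rotation)


def make_particle_dataset(phantom: Volume, n_particles: int,
                          orientation_grid: np.ndarray, noise: NoiseModel,
                          rng: np.random.Generator,
                          disorder_volumes: list[Volume] | None = None,
                          ) -> ParticleDataset:
    """Noisy central-slice projections at grid orientations.

    Orientations are drawn from ``orientation_grid`` (recorded as ground
    truth), noise is independent per particle, and half-set labels
    alternate so the two halves differ in size by at most one.

    ``disorder_volumes`` emulates structurally disordered density (a
    detergent micelle, flexible domains): each particle's image additionally
    carries the projection of one randomly chosen texture volume, so this
    density is present in every image but inconsistent between particles —
    pseudo-structure that averages into a smooth blob in reconstructions.
    """
    if n_particles < 2:
        raise ValueError("need at least 2 particles (one per half-set)")
    n = phantom.n
    n_orient = len(orientation_grid)
    idx = rng.integers(0, n_orient, size=n_particles)
    images = np.empty((n_particles, n, n), dtype=np.float32)
    clean_var = 0.0
    noise_var = 0.0
    from .reconstruct import FourierProjector

    projector = FourierProjector(phantom.grid)
    projections = {int(i): projector.project(orientation_grid[i])
                   for i in np.unique(idx)}
    dis_projectors = None
    dis_choice = None
    if disorder_volumes:
        dis_projectors = [FourierProjector(v.grid) for v in disorder_volumes]
        dis_choice = rng.integers(0, len(disorder_volumes), size=n_particles)
    for p in range(n_particles):
        clean = projections[int(idx[p])]
        if dis_projectors is not None:
            clean = clean + dis_projectors[int(dis_choice[p])].project(
                orientation_grid[int(idx[p])]
            )
        noise2d = _draw_noise_2d(n, phantom.voxel_size, noise, rng)
        images[p] = clean + noise2d
        clean_var += float(np.var(clean))
        noise_var += float(np.var(noise2d))
    snr = clean_var / noise_var if noise_var > 0 else None
    labels = np.arange(n_particles) % 2
    return ParticleDataset(
        images=images,
        rotations=orientation_grid[idx].copy(),
        shifts=np.zeros((n_particles, 2)),
        half_labels=labels,
        pixel_size=phantom.voxel_size,
        snr=snr,
        grid_indices=idx,
    )


def _draw_noise_2d(n: int, pixel: float, noise: NoiseModel,
                   rng: np.random.Generator) -> np.ndarray:
    """2D colored noise with the model's radial amplitude spectrum."""
    w = rng.standard_normal((n, n))
    f = np.fft.fftfreq(n) * n
    ky, kx = np.meshgrid(f, f, indexing="ij")
    s = np.minimum(np.rint(np.hypot(ky, kx)).astype(int), n // 2)
    F = np.fft.fft2(w) * noise.spectrum.amplitude[s]
    return np.fft.ifft2(F).real.astype(np.float32) * noise.scale


def make_disorder_volumes(spec: PhantomSpec, count: int,
                          rng: np.random.Generator) -> list[Volume]:
    """Independent micelle-like texture volumes for ``spec.disorder_region``.

    Each volume holds a fresh band-limited (>= ``disorder_resolution`` A)
    random texture confined to the disordered box — the per-particle
    realizations of structurally disordered density."""
    if spec.disorder_region is None:
        raise ValueError("spec has no disorder_region")
    (cz, cy, cx), e = spec.disorder_region
    n, voxel = spec.n, spec.voxel_size
    cut = shell_of_resolution(spec.disorder_resolution, n, voxel)
    box = np.s_[cz:cz + e, cy:cy + e, cx:cx + e]
    out = []
    for _ in range(count):
        tex = make_colored_noise(n, NoiseSpectrum.flat(n), rng, voxel)
        tex = apply_shell_filter(tex, make_lowpass(max(1, cut), n))
        t = tex.grid / (np.std(tex.grid) + 1e-12) * spec.disorder_amplitude
        g = np.zeros((n, n, n), dtype=np.float32)
        g[box] = np.abs(t[box])
        out.append(Volume(g, voxel))
    return out


def randomize_dataset_phases(data: ParticleDataset, shell_start: int,
                             rng: np.random.Generator) -> ParticleDataset:
    """Phase-randomize every particle image beyond a 2D Fourier shell,
    preserving amplitudes (the input side of the overfitting guard: any
    apparent half-map correlation beyond ``shell_start`` after refinement
    is spurious)."""
    n = data.images.shape[1]
    f = np.fft.fftfreq(n) * n
    ky, kx = np.meshgrid(f, f, indexing="ij")
    s = np.rint(np.hypot(ky, kx)).astype(int)
    beyond = s >= shell_start
    images = np.empty_like(data.images)
    for p in range(data.n_particles):
        F = np.fft.fft2(data.images[p].astype(np.float64))
        W = np.fft.fft2(rng.standard_normal((n, n)))
        mag = np.abs(W)
        phase = np.where(mag > 0, W / mag, 1.0)
        F[beyond] = np.abs(F[beyond]) * phase[beyond]
        images[p] = np.fft.ifft2(F).real
    return ParticleDataset(
        images=images,
        rotations=data.rotations.copy(),
        shifts=data.shifts.copy(),
        half_labels=data.half_labels.copy(),
        pixel_size=data.pixel_size,
        snr=data.snr,
        grid_indices=None if data.grid_indices is None
        else data.grid_indices.copy(),
    )


def make_training_corpus(n_pairs: int, template: PhantomSpec,
                         noise: NoiseModel, rng: np.random.Generator,
                         noise_scale_range: tuple[float, float] | None = None,
                         ) -> list[HalfMapPair]:
    """A list of distinct half-map pairs with masks, varying blob layout per
    pair (the desk-scale stand-in for a curated training corpus).

    With ``noise_scale_range`` the noise amplitude is drawn per pair from
    that range, so the corpus spans a range of map qualities the way a real
    archive of deposited half-maps does.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    corpus = []
    for i in range(n_pairs):
        if noise_scale_range is not None:
            noise = NoiseModel(noise.spectrum,
                               float(rng.uniform(*noise_scale_range)))
        region = template.disorder_region
        if region is not None:
            # jitter the disordered box per pair so its placement is not
            # a learnable constant
            e = region[1]
            corner = tuple(int(c) for c in
                           rng.integers(0, template.n - e + 1, size=3))
            region = (corner, e)
        spec = PhantomSpec(
            n=template.n,
            voxel_size=template.voxel_size,
            n_blobs=max(1, template.n_blobs + int(rng.integers(-2, 3))),
            blob_radius_range=template.blob_radius_range,
            blob_weight_range=template.blob_weight_range,
            disorder_region=region,
            disorder_resolution=template.disorder_resolution,
            disorder_amplitude=template.disorder_amplitude,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        phantom, mask = make_phantom(spec)
        corpus.append(
            make_halfmap_pair(phantom, mask, noise, rng, identifier=f"pair{i:03d}")
        )
    return corpus
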