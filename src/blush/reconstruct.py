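"""Iterative half-set refinement with denoiser regularization and spectral
trailing, plus the Wiener-filtered baseline it is compared against.

The expectation step here is deliberately minimal plumbing: exhaustive
projection matching by normalized cross-correlation over a fixed orientation
grid, with hard assignment.  Reconstruction is direct Fourier inversion —
central-slice insertion with trilinear gridding weights and per-Fourier-voxel
weight normalization — the exact adjoint of the slice-extraction projector.
The contribution this package exists for sits on top of that plumbing:

* per iteration, each half-set is aligned against its own reference and
  backprojected; the solvent-corrected half-map FSC gives the resolution
  cutoff ``rho`` (first shell run below FSC 0.143);
* in ``blush`` mode the half-maps pass through the denoiser and a trailing
  filter keeps denoised Fourier shells only up to ``rho - 2`` (two one-voxel
  shells below the cutoff), zeroes the rest, and — when ``rho`` exceeds the
  denoiser's own 3 A Nyquist — hands shells above that limit back to the
  standard per-shell Wiener regularization;
* in ``baseline`` mode each half's reference is simply its Wiener-weighted
  reconstruction;
* the final iteration never sees the denoiser: the output is the average of
  the last half-maps under the gold-standard per-shell weight
  ``2 FSC / (1 + FSC)``.

Because shells at and above ``rho - 2`` are never populated from the
denoiser, the reported resolution cannot be inflated by it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .volume_io import Volume, rescale_voxel_size
from .spectral import (
    FSCCurve,
    estimate_rho,
    shell_index_map,
    solvent_corrected_fsc,
)
from .synthetic import ParticleDataset
from .denoiser import DenoiserModel, denoise_volume

__all__ = [
    "TrailingState",
    "RefinementConfig",
    "RefinementResult",
    "fourier_slice_project",
    "backproject_halfset",
    "align_particles",
    "trailing_filter",
    "wiener_filter_final",
    "wiener_weights",
    "refine",
    "classify_denoise_hook",
    "DENOISER_NYQUIST_A",
]

DENOISER_NYQUIST_A = 3.0  # the denoiser's own band limit (1.5 A voxels)
DENOISER_VOXEL_A = 1.5


@dataclass
class TrailingState:
    """Spectral-trailing bookkeeping for one iteration."""

    rho: int
    trail_shell: int
    nyquist_shell: int

    @classmethod
    def from_rho(cls, rho: int, n: int, voxel_size: float) -> "TrailingState":
        half = n // 2
        trail = min(max(1, rho - 2), half)
        nyq = min(half, int(n * voxel_size / DENOISER_NYQUIST_A))
        nyq = max(1, nyq)
        return cls(rho=rho, trail_shell=trail, nyquist_shell=nyq)

    def __post_init__(self) -> None:
        if not 1 <= self.trail_shell:
            raise ValueError("trail_shell must be >= 1")
        if self.trail_shell > self.rho:
            raise ValueError("trail_shell must not exceed rho")


@dataclass
class RefinementConfig:
    iterations: int = 4
    mode: str = "blush"  # "blush" | "baseline"
    mask: Volume | None = None
    rand_shell: int | None = None  # default n//4
    n_rand: int = 2
    seed: int = 0
    soft_trailing_edge: int = 0  # shells; 0 = hard cutoff
    fsc_threshold: float = 0.143
    initial_lowpass_shell: int | None = None  # default n//8; None -> default
    trailing_override: int | None = None  # force trail_shell (validation knob)

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.mode not in ("blush", "baseline"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class RefinementResult:
    volume: Volume
    half_maps: tuple[Volume, Volume]
    fsc_trace: list[FSCCurve]
    rho_trace: list[int]
    assignments: np.ndarray  # final per-particle orientation grid indices
    references: tuple[Volume, Volume] | None = None


# ---------------------------------------------------------------------------
# Fourier-slice projection / backprojection (adjoint pair)

OVERSAMPLE = 2  # Fourier oversampling factor for slice extraction/insertion


def _centered_fft3(grid: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(grid)))


def _centered_ifft3(F: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(F))).real


def _slice_coords(n: int, rotation: np.ndarray,
                  os: int = OVERSAMPLE) -> np.ndarray:
    """Fractional (z, y, x) coordinates in the centered, ``os``-times
    oversampled 3D FFT grid for the central slice of the volume rotated by
    ``rotation`` (projection along z)."""
    f = np.arange(n) - n // 2
    ky, kx = np.meshgrid(f, f, indexing="ij")
    # image FT at (kx, ky) samples the volume FT at R^-1 (kx, ky, 0)
    Rinv = np.asarray(rotation).T
    pts = np.stack([kx.ravel(), ky.ravel(), np.zeros(kx.size)])  # (3, m)
    q = Rinv @ pts * os  # (x, y, z) frequency coordinates, oversampled units
    c = (n * os) // 2
    return np.stack([q[2] + c, q[1] + c, q[0] + c])  # (z, y, x) indices


class FourierProjector:
    """Central-slice projector with a cached oversampled transform.

    The volume is zero-padded by the oversampling factor and transformed
    once; each projection is then a trilinear slice interpolation plus a 2D
    inverse transform, so projecting many orientations of one reference is
    cheap.
    """

    def __init__(self, grid: np.ndarray, os: int = OVERSAMPLE):
        grid = np.asarray(grid, dtype=np.float64)
        self.n = grid.shape[0]
        self.os = os
        N = self.n * os
        big = np.zeros((N, N, N))
        lo = (N - self.n) // 2
        big[lo:lo + self.n, lo:lo + self.n, lo:lo + self.n] = grid
        F = _centered_fft3(big)
        self._re = np.ascontiguousarray(F.real)
        self._im = np.ascontiguousarray(F.imag)

    def slice_transform(self, rotation: np.ndarray) -> np.ndarray:
        coords = _slice_coords(self.n, rotation, self.os)
        re = map_coordinates(self._re, coords, order=1, mode="constant", cval=0.0)
        im = map_coordinates(self._im, coords, order=1, mode="constant", cval=0.0)
        return (re + 1j * im).reshape(self.n, self.n)

    def project(self, rotation: np.ndarray) -> np.ndarray:
        P = self.slice_transform(rotation)
        img = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(P))).real
        return img.astype(np.float32)


def fourier_slice_project(grid: np.ndarray, rotation: np.ndarray) -> np.ndarray:
    """Central-slice projection along z of the volume rotated by
    ``rotation``.  One-shot convenience wrapper over
    :class:`FourierProjector`."""
    return FourierProjector(grid).project(rotation)


def _trilinear_scatter(acc: np.ndarray, wacc: np.ndarray,
                       coords: np.ndarray, values: np.ndarray) -> None:
    """Scatter complex ``values`` at fractional (z, y, x) coords into ``acc``
    with trilinear weights; accumulate the weights in ``wacc``.

    Accumulation is done with bincount over flattened indices (much faster
    than indexed in-place addition for many scattered points)."""
    n = acc.shape[0]
    size = acc.size
    base = np.floor(coords).astype(np.int64)  # (3, m)
    frac = coords - base
    # drop points whose 2x2x2 neighborhood leaves the grid (image-corner
    # frequencies beyond the Nyquist sphere)
    ok = ((base >= 0) & (base < n - 1)).all(axis=0)
    if not np.all(ok):
        base = base[:, ok]
        frac = frac[:, ok]
        values = values[ok]
    flat_base = (base[0] * n + base[1]) * n + base[2]
    fz, fy, fx = frac
    gz, gy, gx = 1.0 - fz, 1.0 - fy, 1.0 - fx
    # weights for the 8 corners, ordered by (dz, dy, dx) bits
    w8 = np.stack([
        gz * gy * gx, gz * gy * fx, gz * fy * gx, gz * fy * fx,
        fz * gy * gx, fz * gy * fx, fz * fy * gx, fz * fy * fx,
    ])
    off = np.array([(dz * n + dy) * n + dx
                    for dz in (0, 1) for dy in (0, 1) for dx in (0, 1)])
    flat = (flat_base[None, :] + off[:, None]).ravel()
    w_all = w8.ravel()
    v_all = (values[None, :] * w8).ravel()
    br = np.bincount(flat, weights=v_all.real, minlength=size)
    bi = np.bincount(flat, weights=v_all.imag, minlength=size)
    acc += (br + 1j * bi).reshape(acc.shape)
    wacc += np.bincount(flat, weights=w_all, minlength=size).reshape(wacc.shape)


def backproject_halfset(data: ParticleDataset, half: int,
                        rotations: np.ndarray | None = None) -> Volume:
    """Direct Fourier reconstruction of one half-set.

    Each image's 2D transform is inserted as a central slice with trilinear
    gridding; the accumulated grid is normalized per Fourier voxel by the
    accumulated weights and Hermitian-symmetrized before inversion.
    """
    idx = data.half_indices(half)
    if len(idx) == 0:
        raise ValueError(f"half-set {half} is empty")
    if rotations is None:
        rotations = data.rotations
    n = data.images.shape[1]
    os = OVERSAMPLE
    N = n * os
    c = N // 2
    acc = np.zeros((N, N, N), dtype=np.complex128)
    wacc = np.zeros((N, N, N), dtype=np.float64)
    all_coords = []
    all_values = []
    for p in idx:
        img = np.asarray(data.images[p], dtype=np.float64)
        P = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img))).ravel()
        coords = _slice_coords(n, rotations[p], os)
        all_coords.append(coords)
        all_values.append(P)
        # Friedel mate: conj at the point-mirrored coordinates
        all_coords.append(2 * c - coords)
        all_values.append(np.conj(P))
    _trilinear_scatter(acc, wacc, np.concatenate(all_coords, axis=1),
                       np.concatenate(all_values))
    F = np.zeros_like(acc)
    ok = wacc > 1e-8
    F[ok] = acc[ok] / wacc[ok]
    # decimate the oversampled grid back to the n-grid Fourier samples
    sel = (np.arange(n) - n // 2) * os + c
    Fd = F[np.ix_(sel, sel, sel)]
    # Hermitian symmetrization about the centered origin keeps the map real
    Fc = np.roll(np.conj(Fd[::-1, ::-1, ::-1]), 1, axis=(0, 1, 2))
    Fd = 0.5 * (Fd + Fc)
    vol = _centered_ifft3(Fd)
    return Volume(vol.astype(np.float32), data.pixel_size)


def align_particles(data: ParticleDataset, ref0: Volume, ref1: Volume,
                    orientation_grid: np.ndarray) -> np.ndarray:
    """Exhaustive projection matching: per particle, the grid orientation
    maximizing normalized cross-correlation with the reference of its own
    half-set.  Ties break to the lowest grid index."""
    for ref in (ref0, ref1):
        if not np.all(np.isfinite(ref.grid)):
            raise ValueError("non-finite reference")
    n_orient = len(orientation_grid)
    templates = {}
    for h, ref in ((0, ref0), (1, ref1)):
        projector = FourierProjector(ref.grid)
        t = np.empty((n_orient, ref.n * ref.n))
        for j, R in enumerate(orientation_grid):
            proj = projector.project(R).ravel().astype(np.float64)
            proj = proj - proj.mean()
            norm = np.linalg.norm(proj)
            t[j] = proj / norm if norm > 1e-12 else 0.0
        templates[h] = t
    out = np.empty(data.n_particles, dtype=np.int64)
    for h in (0, 1):
        idx = data.half_indices(h)
        imgs = data.images[idx].reshape(len(idx), -1).astype(np.float64)
        imgs = imgs - imgs.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(imgs, axis=1, keepdims=True)
        norms[norms < 1e-12] = 1.0
        imgs /= norms
        scores = imgs @ templates[h].T  # (n_idx, n_orient)
        out[idx] = np.argmax(scores, axis=1)  # argmax takes the lowest index
    return out


# ---------------------------------------------------------------------------
# spectral trailing and Wiener filtering


def trailing_filter(denoised: Volume, fallback: Volume,
                    ts: TrailingState, soft_edge: int = 0) -> Volume:
    """Compose the next reference from the denoised map below the trailing
    cutoff and (above the denoiser's Nyquist, when ``rho`` exceeds it) the
    standard-regularized fallback.

    Shells <= ``trail_shell`` come from ``denoised``; shells above it are
    zero, except that when ``rho > nyquist_shell`` the shells above
    ``nyquist_shell`` are taken bit-for-bit from ``fallback``.
    """
    if denoised.grid.shape != fallback.grid.shape:
        raise ValueError("shape mismatch between denoised and fallback maps")
    n = denoised.n
    s = shell_index_map(n)
    Fd = np.fft.fftn(denoised.grid.astype(np.float64))
    out = np.where(s <= ts.trail_shell, Fd, 0.0)
    if soft_edge > 0 and ts.trail_shell > soft_edge:
        ramp = (s > ts.trail_shell - soft_edge) & (s <= ts.trail_shell)
        t = (ts.trail_shell - s[ramp] + 1) / (soft_edge + 1)
        out[ramp] = Fd[ramp] * 0.5 * (1.0 - np.cos(np.pi * t))
    if ts.rho > ts.nyquist_shell:
        Ff = np.fft.fftn(fallback.grid.astype(np.float64))
        hand = s > ts.nyquist_shell
        out[hand] = Ff[hand]
    return denoised.with_grid(np.fft.ifftn(out).real)


def wiener_weights(fsc: FSCCurve) -> np.ndarray:
    """Gold-standard per-shell signal weight 2 FSC / (1 + FSC), clamped to
    [0, 1]."""
    f = fsc.values
    w = np.zeros_like(f)
    ok = f > 0
    w[ok] = 2.0 * f[ok] / (1.0 + f[ok])
    return np.clip(w, 0.0, 1.0)


def _apply_per_shell(v: Volume, weights: np.ndarray) -> Volume:
    n = v.n
    s = np.minimum(shell_index_map(n), n // 2)
    F = np.fft.fftn(v.grid.astype(np.float64)) * weights[s]
    return v.with_grid(np.fft.ifftn(F).real)


def wiener_filter_final(half0: Volume, half1: Volume,
                        fsc: FSCCurve) -> Volume:
    """Average of the half-maps under the per-shell Wiener weight."""
    avg = half0.with_grid(0.5 * (half0.grid + half1.grid))
    return _apply_per_shell(avg, wiener_weights(fsc))


def _denoise_at_native_scale(model: DenoiserModel, v: Volume,
                             patch_edge: int, overlap: int) -> Volume:
    """Denoise at the network's 1.5 A training scale, rescaling there and
    back when the refinement grid differs."""
    if abs(v.voxel_size - DENOISER_VOXEL_A) < 1e-3:
        return denoise_volume(model, v, patch_edge, overlap)
    native = rescale_voxel_size(v, DENOISER_VOXEL_A)
    den = denoise_volume(model, native, patch_edge, overlap)
    back = rescale_voxel_size(den, v.voxel_size)
    if back.n != v.n:  # rounding can move the edge by one even step
        raise ValueError(
            f"voxel-size round trip changed the grid ({v.n} -> {back.n})"
        )
    return back


def refine(data: ParticleDataset, model: DenoiserModel | None,
           cfg: RefinementConfig, orientation_grid: np.ndarray,
           patch_edge: int = 64, overlap: int = 32) -> RefinementResult:
    """Iterative two-half-set refinement.

    Per iteration: align each half-set against its own reference,
    backproject, estimate ``rho`` from the solvent-corrected FSC, then build
    the next references — denoised + trailing-filtered in ``blush`` mode,
    Wiener-weighted in ``baseline`` mode.  The final iteration skips the
    denoiser entirely and returns the Wiener-filtered average.
    """
    if cfg.mode == "blush" and model is None:
        raise ValueError("blush mode requires a denoiser model")
    n = data.images.shape[1]
    rand_shell = cfg.rand_shell if cfg.rand_shell is not None else max(2, n // 4)
    rng = np.random.default_rng(cfg.seed)
    # initial references: strongly low-passed reconstructions at the
    # recorded orientations (a consensus low-resolution starting model);
    # alignment is re-estimated from scratch against them each iteration
    ini = cfg.initial_lowpass_shell
    if ini is None:
        ini = max(2, n // 8)
    from .spectral import make_lowpass, apply_shell_filter

    lp = make_lowpass(min(ini, n // 2), n)
    ref0 = apply_shell_filter(backproject_halfset(data, 0), lp)
    ref1 = apply_shell_filter(backproject_halfset(data, 1), lp)
    fsc_trace: list[FSCCurve] = []
    rho_trace: list[int] = []
    assignments = data.grid_indices if data.grid_indices is not None \
        else np.zeros(data.n_particles, dtype=np.int64)
    half0 = ref0
    half1 = ref1
    for it in range(cfg.iterations):
        assignments = align_particles(data, ref0, ref1, orientation_grid)
        rots = orientation_grid[assignments]
        half0 = backproject_halfset(data, 0, rots)
        half1 = backproject_halfset(data, 1, rots)
        if not (np.all(np.isfinite(half0.grid)) and np.all(np.isfinite(half1.grid))):
            raise FloatingPointError(f"non-finite reconstruction at iteration {it}")
        fsc = solvent_corrected_fsc(half0, half1, cfg.mask, rand_shell,
                                    n_rand=cfg.n_rand, rng=rng)
        rho = estimate_rho(fsc, cfg.fsc_threshold)
        fsc_trace.append(fsc)
        rho_trace.append(rho)
        if it == cfg.iterations - 1:
            break
        w = wiener_weights(fsc)
        if cfg.mode == "baseline":
            ref0 = _apply_per_shell(half0, w)
            ref1 = _apply_per_shell(half1, w)
        else:
            ts = TrailingState.from_rho(rho, n, data.pixel_size)
            if cfg.trailing_override is not None:
                ts = TrailingState(rho=max(ts.rho, cfg.trailing_override),
                                   trail_shell=cfg.trailing_override,
                                   nyquist_shell=ts.nyquist_shell)
            new_refs = []
            for half in (half0, half1):
                # the denoiser sees the SSNR-filtered map (as in the
                # classification contract); with an identity denoiser the
                # reference reduces exactly to the baseline's below the
                # trailing cutoff
                filtered = _apply_per_shell(half, w)
                den = _denoise_at_native_scale(model, filtered,
                                               patch_edge, overlap)
                new_refs.append(
                    trailing_filter(den, filtered, ts, cfg.soft_trailing_edge)
                )
            ref0, ref1 = new_refs
    final = wiener_filter_final(half0, half1, fsc_trace[-1])
    return RefinementResult(
        volume=final,
        half_maps=(half0, half1),
        fsc_trace=fsc_trace,
        rho_trace=rho_trace,
        assignments=assignments,
        references=(ref0, ref1),
    )


def classify_denoise_hook(filtered_class_map: Volume,
                          model: DenoiserModel,
                          patch_edge: int = 64,
                          overlap: int = 32) -> Volume:
    """Per-class reference update for classification-style runs: a single
    denoiser pass on the regularized-likelihood filtered map, with no
    trailing filter; applied at every iteration including the last."""
    if not np.all(np.isfinite(filtered_class_map.grid)):
        raise ValueError("non-finite class map")
    return _denoise_at_native_scale(model, filtered_class_map,
                                    patch_edge, overlap)
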