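"""Fourier-shell machinery: FSC, solvent correction, phase randomization,
shell filters, anisotropic Gaussian filters and colored-noise synthesis.

Every operation shares one shell convention: the Fourier voxel at integer
frequency vector ``k`` (in grid units, i.e. cycles per box) belongs to shell
``round(|k|)``, so each shell is one Fourier voxel wide and shell ``s`` on an
``n``-grid with voxel size ``v`` corresponds to a resolution of ``n * v / s``
Angstrom.  Shells run from 0 (DC) to ``n // 2`` (Nyquist); corner voxels
beyond Nyquist exist in the 3D transform and are handled explicitly by each
operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np

from .volume_io import Volume

__all__ = [
    "FSCCurve",
    "ShellFilter",
    "GaussianCovariance",
    "NoiseSpectrum",
    "shell_index_map",
    "shell_counts",
    "compute_fsc",
    "randomize_phases",
    "solvent_corrected_fsc",
    "estimate_rho",
    "make_lowpass",
    "apply_shell_filter",
    "anisotropic_gaussian_filter",
    "covariance_from_resolution",
    "make_colored_noise",
    "shell_of_resolution",
    "resolution_of_shell",
    "shell_power",
]

logger = logging.getLogger(__name__)

_shell_cache: dict[int, np.ndarray] = {}


def shell_index_map(n: int) -> np.ndarray:
    """Integer shell index ``round(|k|)`` for every voxel of an n^3 FFT grid."""
    got = _shell_cache.get(n)
    if got is not None:
        return got
    f = np.fft.fftfreq(n) * n
    kz, ky, kx = np.meshgrid(f, f, f, indexing="ij")
    s = np.rint(np.sqrt(kz**2 + ky**2 + kx**2)).astype(np.int32)
    _shell_cache[n] = s
    return s


def shell_counts(n: int) -> np.ndarray:
    """Number of Fourier voxels in each shell 0 .. n//2."""
    s = shell_index_map(n)
    return np.bincount(s.ravel(), minlength=n // 2 + 1)[: n // 2 + 1]


def shell_of_resolution(resolution: float, n: int, voxel_size: float) -> int:
    """Shell index of a resolution in Angstrom, rounded down (conservative:
    never passes frequencies beyond the stated resolution)."""
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    return min(n // 2, int(n * voxel_size / resolution))


def resolution_of_shell(s: int, n: int, voxel_size: float) -> float:
    if s < 1:
        raise ValueError("shell must be >= 1 for a finite resolution")
    return n * voxel_size / s


@dataclass
class FSCCurve:
    """Per-shell correlation between two volumes.

    ``values[s]`` is the FSC at integer shell ``s`` for ``s = 0 .. n // 2``.
    """

    values: np.ndarray
    n: int
    voxel_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) != self.n // 2 + 1:
            raise ValueError(
                f"FSC length {len(self.values)} != n/2+1 = {self.n // 2 + 1}"
            )

    def resolution_at(self, s: int) -> float:
        return resolution_of_shell(s, self.n, self.voxel_size)

    def to_text(self) -> str:
        """Two-column text: resolution (A), FSC. DC row reports 'inf'."""
        lines = ["# resolution_A\tfsc"]
        for s, v in enumerate(self.values):
            res = "inf" if s == 0 else f"{self.resolution_at(s):.4f}"
            lines.append(f"{res}\t{v:.6f}")
        return "\n".join(lines) + "\n"


@dataclass
class ShellFilter:
    """Multiplicative per-shell gain, indexed by shell 0 .. n//2.

    When applied, voxels beyond Nyquist (grid corners) use the Nyquist gain.
    """

    transfer: np.ndarray

    def __post_init__(self) -> None:
        self.transfer = np.asarray(self.transfer, dtype=np.float64)
        if not np.all(np.isfinite(self.transfer)) or np.any(self.transfer < 0):
            raise ValueError("filter gains must be finite and >= 0")


@dataclass
class GaussianCovariance:
    """Symmetric PSD 3x3 covariance (squared lengths, A^2) of a real-space
    Gaussian kernel; the Fourier transfer function is exp(-2 pi^2 k^T C k)."""

    C: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=np.float64)
        if self.C.shape != (3, 3):
            raise ValueError("C must be 3x3")
        if not np.allclose(self.C, self.C.T, atol=1e-10):
            raise ValueError("C must be symmetric")
        if np.linalg.eigvalsh(self.C).min() < -1e-10:
            raise ValueError("C must be positive semi-definite")

    @classmethod
    def isotropic(cls, sigma2: float) -> "GaussianCovariance":
        return cls(np.eye(3) * sigma2)


def covariance_from_resolution(resolution: float) -> GaussianCovariance:
    """Isotropic Gaussian covariance whose Fourier gain is 0.5 at frequency
    1/resolution: exp(-2 pi^2 sigma^2 / R^2) = 1/2."""
    sigma2 = np.log(2.0) * resolution**2 / (2.0 * np.pi**2)
    return GaussianCovariance.isotropic(sigma2)


@dataclass
class NoiseSpectrum:
    """Target per-shell RMS Fourier amplitude for colored-noise synthesis."""

    amplitude: np.ndarray
    label: str = "noise"

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=np.float64)
        if np.any(self.amplitude < 0) or not np.all(np.isfinite(self.amplitude)):
            raise ValueError("amplitudes must be finite and >= 0")

    @classmethod
    def flat(cls, n: int, amplitude: float = 1.0) -> "NoiseSpectrum":
        return cls(np.full(n // 2 + 1, amplitude), label="white")

    @classmethod
    def lorentzian(cls, n: int, amplitude: float = 1.0,
                   knee_shell: float = 4.0) -> "NoiseSpectrum":
        """Falling spectrum, power ~ 1/(1 + (s/s0)^2), emulating the decaying
        spectral SNR of experimental maps."""
        s = np.arange(n // 2 + 1, dtype=float)
        return cls(amplitude / np.sqrt(1.0 + (s / knee_shell) ** 2),
                   label="lorentzian")


# ---------------------------------------------------------------------------


def _check_same_geometry(a: Volume, b: Volume) -> None:
    if a.grid.shape != b.grid.shape:
        raise ValueError(f"shape mismatch: {a.grid.shape} vs {b.grid.shape}")
    if not np.isclose(a.voxel_size, b.voxel_size, rtol=1e-6):
        raise ValueError(
            f"voxel size mismatch: {a.voxel_size} vs {b.voxel_size}"
        )


def compute_fsc(a: Volume, b: Volume) -> FSCCurve:
    """Fourier shell correlation between two volumes.

    ``FSC(s) = Re(sum A conj(B)) / sqrt(sum |A|^2 sum |B|^2)`` over the
    voxels of shell ``s``; shells with zero power in either input give 0.
    """
    _check_same_geometry(a, b)
    n = a.n
    A = np.fft.fftn(a.grid)
    B = np.fft.fftn(b.grid)
    s = shell_index_map(n).ravel()
    nshell = n // 2 + 1
    # power computed with the same expression as the cross term so that
    # FSC(v, v) is exactly 1 at every populated shell
    cross = np.bincount(s, weights=(A * np.conj(B)).real.ravel())[:nshell]
    pa = np.bincount(s, weights=(A * np.conj(A)).real.ravel())[:nshell]
    pb = np.bincount(s, weights=(B * np.conj(B)).real.ravel())[:nshell]
    denom = np.sqrt(pa * pb)
    values = np.zeros(nshell)
    ok = denom > 0
    values[ok] = cross[ok] / denom[ok]
    np.clip(values, -1.0, 1.0, out=values)
    return FSCCurve(values=values, n=n, voxel_size=a.voxel_size)


def shell_power(v: Volume) -> np.ndarray:
    """Total Fourier power per shell 0 .. n//2."""
    n = v.n
    F = np.fft.fftn(v.grid)
    s = shell_index_map(n).ravel()
    return np.bincount(s, weights=(np.abs(F) ** 2).ravel())[: n // 2 + 1]


def randomize_phases(v: Volume, shell_start: int,
                     rng: np.random.Generator) -> Volume:
    """Replace Fourier phases at shells >= ``shell_start`` by random phases.

    Amplitudes are preserved at every voxel and the output stays real:
    the random phases are taken from the transform of a real white-noise
    field, which is Hermitian-symmetric by construction.
    """
    n = v.n
    if not 1 <= shell_start <= n // 2:
        raise ValueError(f"need 1 <= shell_start <= {n // 2}, got {shell_start}")
    F = np.fft.fftn(v.grid)
    W = np.fft.fftn(rng.standard_normal(v.grid.shape))
    mag_w = np.abs(W)
    phase = np.where(mag_w > 0, W / mag_w, 1.0)
    s = shell_index_map(n)
    rand = s >= shell_start
    out = F.copy()
    out[rand] = np.abs(F[rand]) * phase[rand]
    g = np.fft.ifftn(out).real
    return v.with_grid(g)


def solvent_corrected_fsc(a: Volume, b: Volume, mask: Volume | None,
                          rand_shell: int, n_rand: int = 3,
                          rng: np.random.Generator | None = None,
                          margin: int = 2) -> FSCCurve:
    """Masked FSC corrected for mask-induced correlation by phase
    randomization.

    The correction ``(FSC_t - FSC_n) / (1 - FSC_n)`` is applied at shells
    above ``rand_shell + margin``; ``FSC_n`` is the masked FSC of both
    volumes phase-randomized beyond ``rand_shell``, averaged over ``n_rand``
    randomization seeds.
    """
    _check_same_geometry(a, b)
    if rng is None:
        rng = np.random.default_rng(0)
    if mask is not None:
        mg = mask.grid
        if mg.min() < -1e-6 or mg.max() > 1 + 1e-6:
            raise ValueError("mask values must lie in [0, 1]")
        am = a.with_grid(a.grid * mg)
        bm = b.with_grid(b.grid * mg)
    else:
        mg = None
        am, bm = a, b
    fsc_t = compute_fsc(am, bm).values
    acc = np.zeros_like(fsc_t)
    for _ in range(n_rand):
        ar = randomize_phases(a, rand_shell, rng)
        br = randomize_phases(b, rand_shell, rng)
        if mg is not None:
            ar = ar.with_grid(ar.grid * mg)
            br = br.with_grid(br.grid * mg)
        acc += compute_fsc(ar, br).values
    fsc_n = acc / n_rand
    corrected = fsc_t.copy()
    hi = np.arange(len(fsc_t)) > rand_shell + margin
    denom = 1.0 - fsc_n
    bad = hi & (denom <= 1e-6)
    if np.any(bad):
        logger.warning(
            "solvent correction: FSC_n >= 1 at shells %s; clamping to 0",
            np.nonzero(bad)[0].tolist(),
        )
    good = hi & ~bad
    corrected[good] = (fsc_t[good] - fsc_n[good]) / denom[good]
    corrected[bad] = 0.0
    np.clip(corrected, -1.0, 1.0, out=corrected)
    return FSCCurve(values=corrected, n=a.n, voxel_size=a.voxel_size)


def estimate_rho(fsc: FSCCurve, threshold: float = 0.143) -> int:
    """First-crossing resolution shell: the largest ``s`` such that the FSC
    stays >= ``threshold`` at every shell 1 .. s.

    Returns 1 if shell 1 is already below threshold, n//2 if no shell ever
    drops below.
    """
    half = fsc.n // 2
    for s in range(1, half + 1):
        if fsc.values[s] < threshold:
            return max(1, s - 1)
    return half


def make_lowpass(cutoff_shell: int, n: int, edge_width: int = 0) -> ShellFilter:
    """Low-pass shell filter: gain 1 up to ``cutoff_shell - edge_width``,
    raised-cosine ramp reaching 0 at ``cutoff_shell``, 0 beyond.
    ``edge_width = 0`` gives a hard cutoff (gain 1 at the cutoff shell)."""
    half = n // 2
    if not 1 <= cutoff_shell <= half:
        raise ValueError(f"need 1 <= cutoff_shell <= {half}")
    if edge_width < 0:
        raise ValueError("edge_width must be >= 0")
    gain = np.zeros(half + 1)
    s = np.arange(half + 1)
    if edge_width == 0:
        gain[s <= cutoff_shell] = 1.0
    else:
        gain[s <= cutoff_shell - edge_width] = 1.0
        ramp = (s > cutoff_shell - edge_width) & (s < cutoff_shell)
        t = (cutoff_shell - s[ramp]) / edge_width
        gain[ramp] = 0.5 * (1.0 - np.cos(np.pi * t))
    return ShellFilter(gain)


def apply_shell_filter(v: Volume, filt: ShellFilter) -> Volume:
    """Multiply each Fourier voxel by its shell gain (corners beyond Nyquist
    use the Nyquist gain)."""
    n = v.n
    if len(filt.transfer) != n // 2 + 1:
        raise ValueError("filter length does not match volume Nyquist")
    s = np.minimum(shell_index_map(n), n // 2)
    F = np.fft.fftn(v.grid) * filt.transfer[s]
    return v.with_grid(np.fft.ifftn(F).real)


_freq_cache: dict[tuple[int, float], tuple[np.ndarray, ...]] = {}


def _freq_grids(n: int, voxel_size: float):
    key = (n, round(voxel_size, 9))
    got = _freq_cache.get(key)
    if got is None:
        f = np.fft.fftfreq(n, d=voxel_size)  # cycles/A
        got = np.meshgrid(f, f, f, indexing="ij")
        _freq_cache[key] = got
    return got


def gaussian_transfer(n: int, voxel_size: float,
                      cov: GaussianCovariance) -> np.ndarray:
    """Fourier transfer function ``exp(-2 pi^2 k^T C k)`` on an n^3 FFT
    grid, ``k`` in cycles per Angstrom."""
    kz, ky, kx = _freq_grids(n, voxel_size)
    C = cov.C
    # quadratic form with axes ordered (z, y, x): map C's (x, y, z) indexing
    q = (
        C[0, 0] * kx**2 + C[1, 1] * ky**2 + C[2, 2] * kz**2
        + 2 * C[0, 1] * kx * ky + 2 * C[0, 2] * kx * kz + 2 * C[1, 2] * ky * kz
    )
    return np.exp(-2.0 * np.pi**2 * q)


def anisotropic_gaussian_filter(v: Volume, cov: GaussianCovariance) -> Volume:
    """Convolve with an anisotropic Gaussian via Fourier multiplication by
    ``exp(-2 pi^2 k^T C k)``, ``k`` in cycles per Angstrom."""
    H = gaussian_transfer(v.n, v.voxel_size, cov)
    return v.with_grid(np.fft.ifftn(np.fft.fftn(v.grid) * H).real)


def colored_noise_fft(n: int, spectrum: NoiseSpectrum,
                      rng: np.random.Generator) -> np.ndarray:
    """Fourier transform of a colored real Gaussian field (see
    :func:`make_colored_noise`); useful when the caller works in Fourier
    space anyway."""
    if len(spectrum.amplitude) != n // 2 + 1:
        raise ValueError("spectrum length must be n//2 + 1")
    w = rng.standard_normal((n, n, n))
    s = np.minimum(shell_index_map(n), n // 2)
    return np.fft.fftn(w) * spectrum.amplitude[s]


def make_colored_noise(n: int, spectrum: NoiseSpectrum,
                       rng: np.random.Generator,
                       voxel_size: float = 1.0) -> Volume:
    """Real Gaussian random field whose expected per-voxel Fourier RMS
    amplitude follows ``spectrum`` (indexed by shell; corners beyond Nyquist
    continue with the Nyquist amplitude)."""
    F = colored_noise_fft(n, spectrum, rng)
    g = np.fft.ifftn(F).real
    return Volume(g.astype(np.float32), voxel_size)
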