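"""Volumes on cubic grids: MRC reading/writing, Fourier rescaling, patch tiling.

The whole pipeline moves 3D density maps around as :class:`Volume` objects —
a cubic, even-edged grid of float32 densities with an isotropic voxel size in
Angstrom.  Cubic/even grids keep the Nyquist shell unambiguous at ``n // 2``,
which the spectral machinery relies on throughout.

MRC2014 files are handled through :mod:`gemmi`; on read the grid is
canonicalized to ``(z, y, x)`` slowest-to-fastest axis order regardless of the
axis-order words in the header, and written files are always mode-2 (32-bit
float) with the cell encoding the voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "Volume",
    "PatchGrid",
    "read_mrc",
    "write_mrc",
    "rescale_voxel_size",
    "tile_volume",
    "stitch_patches",
    "pad_to_cube",
]

MIN_EDGE = 16


@dataclass
class Volume:
    """Cubic 3D density grid.

    Parameters
    ----------
    grid : ndarray
        Density values, axis order ``(z, y, x)``.  Stored as float32.
    voxel_size : float
        Isotropic voxel size in Angstrom.
    origin : tuple of float
        Physical offset of the grid corner in Angstrom, ``(z, y, x)``.
    """

    grid: np.ndarray
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3:
            raise ValueError(f"grid must be 3D, got ndim={self.grid.ndim}")
        nz, ny, nx = self.grid.shape
        if not (nz == ny == nx):
            raise ValueError(
                f"grid must be cubic, got shape {self.grid.shape}; "
                "use pad_to_cube() for non-cubic maps"
            )
        if nz < MIN_EDGE or nz % 2 != 0:
            raise ValueError(
                f"grid edge must be even and >= {MIN_EDGE}, got {nz}"
            )
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid contains non-finite values")

    @property
    def n(self) -> int:
        """Grid edge length in voxels."""
        return self.grid.shape[0]

    @property
    def extent(self) -> float:
        """Physical edge length in Angstrom."""
        return self.n * self.voxel_size

    def copy(self) -> "Volume":
        return Volume(self.grid.copy(), self.voxel_size, self.origin)

    def with_grid(self, grid: np.ndarray) -> "Volume":
        """Same metadata, new density values (shape must match)."""
        if grid.shape != self.grid.shape:
            raise ValueError("replacement grid has different shape")
        return Volume(np.asarray(grid, dtype=np.float32), self.voxel_size, self.origin)


def read_mrc(path, allow_noncubic: bool = False) -> Volume:
    """Read an MRC2014 volume.

    Voxel size is taken as cell length / grid samples; axis order is
    canonicalized to ``(z, y, x)``.  Non-cubic or odd-edged maps are rejected
    unless ``allow_noncubic`` is set, in which case they are padded to the
    enclosing even cube with edge-value fill.
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise ValueError(f"not a readable MRC2014 map: {path}: {exc}") from exc
    # reorder axes per MAPC/MAPR/MAPS and fill the full cell
    m.setup(float("nan"))
    arr = np.array(m.grid, copy=True)  # indexed (x, y, z)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{path}: map data incomplete or non-finite after setup")
    grid = np.ascontiguousarray(arr.T)  # -> (z, y, x)
    sp = m.grid.spacing
    if not np.allclose(sp, sp[0], rtol=1e-3):
        raise ValueError(
            f"{path}: anisotropic voxel size {sp} unsupported (CELLA/NX..NZ)"
        )
    voxel = float(sp[0])
    origin = (
        float(m.header_float(52)),
        float(m.header_float(51)),
        float(m.header_float(50)),
    )
    nz, ny, nx = grid.shape
    if not (nz == ny == nx and nz % 2 == 0):
        if not allow_noncubic:
            raise ValueError(
                f"{path}: grid {nx} x {ny} x {nz} (header NX/NY/NZ) is not an "
                "even cube; pass allow_noncubic=True to pad"
            )
        grid = _pad_grid_to_even_cube(grid)
    return Volume(grid, voxel, origin)


def write_mrc(vol: Volume, path) -> None:
    """Write ``vol`` as a mode-2 (float32) MRC2014 file."""
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(vol.grid.T))  # (x, y, z)
    ext = vol.extent
    m.grid.unit_cell = gemmi.UnitCell(ext, ext, ext, 90.0, 90.0, 90.0)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    oz, oy, ox = vol.origin
    m.set_header_float(50, float(ox))
    m.set_header_float(51, float(oy))
    m.set_header_float(52, float(oz))
    m.write_ccp4_map(str(path))


def pad_to_cube(grid: np.ndarray) -> np.ndarray:
    """Pad an arbitrary 3D array to the enclosing even cube (edge-value fill)."""
    return _pad_grid_to_even_cube(np.asarray(grid, dtype=np.float32))


def _pad_grid_to_even_cube(grid: np.ndarray) -> np.ndarray:
    edge = max(max(grid.shape), MIN_EDGE)
    if edge % 2:
        edge += 1
    pads = []
    for s in grid.shape:
        before = (edge - s) // 2
        pads.append((before, edge - s - before))
    return np.pad(grid, pads, mode="edge")


def rescale_voxel_size(vol: Volume, target: float) -> Volume:
    """Resample ``vol`` onto a grid with voxel size ``target`` by Fourier
    cropping/padding.

    The output edge is ``round(n * voxel_size / target)`` rounded down to
    even, so the physical extent is preserved within one voxel.  Band
    limitation is exact (no interpolation kernel) and the physical integral
    of the density (mean x volume) is preserved exactly.
    """
    if not target > 0:
        raise ValueError(f"target voxel size must be > 0, got {target}")
    n = vol.n
    m = int(round(n * vol.voxel_size / target))
    m -= m % 2
    if m < MIN_EDGE:
        raise ValueError(
            f"target {target} A would give edge {m} < {MIN_EDGE} voxels"
        )
    if m == n:
        return vol.copy()
    F = np.fft.fftshift(np.fft.fftn(vol.grid))
    c_in, c_out = n // 2, m // 2
    if m < n:
        lo, hi = c_in - c_out, c_in + c_out
        F = F[lo:hi, lo:hi, lo:hi]
    else:
        G = np.zeros((m, m, m), dtype=complex)
        lo, hi = c_out - c_in, c_out + c_in
        G[lo:hi, lo:hi, lo:hi] = F
        F = G
    out = np.fft.ifftn(np.fft.ifftshift(F)).real
    # crop/pad + ifftn preserves the grid sum, so scaling by the voxel-volume
    # ratio preserves the physical integral (mean density x volume) exactly
    out *= vol.voxel_size**3 / target**3
    new_extent = m * target
    eff_voxel = target
    # keep origin: the grids share the same physical center
    shift = (vol.extent - new_extent) / 2.0
    origin = tuple(o + shift for o in vol.origin)
    return Volume(out.astype(np.float32), eff_voxel, origin)


# ---------------------------------------------------------------------------
# patch tiling


@dataclass
class PatchGrid:
    """Tiling of a cubic volume into overlapping cubic patches.

    ``axis_weights`` holds, per axis, one 1D blend profile per patch origin;
    the 3D blend weight of a patch is the outer product of its three
    profiles.  The profiles are raised-cosine ramps over overlap regions,
    normalized per coordinate so the weights form an exact partition of
    unity.
    """

    n: int
    patch_edge: int
    overlap: int
    origins_1d: np.ndarray  # shape (p,)
    axis_weights: np.ndarray  # shape (p, patch_edge), same for all 3 axes
    patch_origins: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.patch_origins:
            self.patch_origins = [
                (int(a), int(b), int(c))
                for a in self.origins_1d
                for b in self.origins_1d
                for c in self.origins_1d
            ]

    @property
    def n_patches(self) -> int:
        return len(self.patch_origins)

    def blend_weight(self, index: int) -> np.ndarray:
        """Full 3D blend-weight field for patch ``index``."""
        pz, py, px = self._axis_indices(index)
        wz = self.axis_weights[pz]
        wy = self.axis_weights[py]
        wx = self.axis_weights[px]
        return wz[:, None, None] * wy[None, :, None] * wx[None, None, :]

    def _axis_indices(self, index: int) -> tuple[int, int, int]:
        p = len(self.origins_1d)
        return index // (p * p), (index // p) % p, index % p

    def extract(self, grid: np.ndarray, index: int) -> np.ndarray:
        oz, oy, ox = self.patch_origins[index]
        e = self.patch_edge
        return grid[oz : oz + e, oy : oy + e, ox : ox + e]


def _axis_origins(n: int, patch_edge: int, overlap: int) -> np.ndarray:
    stride = patch_edge - overlap
    if patch_edge == n:
        return np.array([0])
    origins = list(range(0, n - patch_edge, stride))
    origins.append(n - patch_edge)
    return np.array(sorted(set(origins)))


def _raised_cosine_ramp(width: int) -> np.ndarray:
    # half-cosine from 0 to 1 over `width` samples (endpoints interior)
    t = (np.arange(width) + 0.5) / width
    return 0.5 * (1.0 - np.cos(np.pi * t))


def tile_volume(vol_or_n, patch_edge: int = 64, overlap: int = 32) -> PatchGrid:
    """Tile a volume (or a bare edge length) into overlapping patches.

    Raised-cosine ramps over each overlap region are normalized per
    coordinate so that, at every voxel, contributing blend weights sum to 1.
    """
    n = vol_or_n.n if isinstance(vol_or_n, Volume) else int(vol_or_n)
    if patch_edge > n:
        raise ValueError(f"patch_edge {patch_edge} exceeds volume edge {n}")
    if not 0 <= overlap < patch_edge:
        raise ValueError(f"need 0 <= overlap < patch_edge, got {overlap}")
    origins = _axis_origins(n, patch_edge, overlap)
    p = len(origins)
    raw = np.ones((p, patch_edge))
    for i, o in enumerate(origins):
        if i > 0:  # ramp up over the overlap with the previous patch
            ov = origins[i - 1] + patch_edge - o
            raw[i, :ov] = _raised_cosine_ramp(ov)
        if i < p - 1:  # ramp down over the overlap with the next patch
            ov = o + patch_edge - origins[i + 1]
            raw[i, patch_edge - ov :] = _raised_cosine_ramp(ov)[::-1]
    # normalize per coordinate -> exact partition of unity even for the
    # irregular final-patch overlap
    total = np.zeros(n)
    for i, o in enumerate(origins):
        total[o : o + patch_edge] += raw[i]
    for i, o in enumerate(origins):
        raw[i] /= total[o : o + patch_edge]
    return PatchGrid(n=n, patch_edge=patch_edge, overlap=overlap,
                     origins_1d=origins, axis_weights=raw)


def stitch_patches(patches, grid: PatchGrid,
                   voxel_size: float = 1.0,
                   origin: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> Volume:
    """Recombine patches by their partition-of-unity blend weights."""
    if len(patches) != grid.n_patches:
        raise ValueError(
            f"got {len(patches)} patches for a grid of {grid.n_patches}"
        )
    out = np.zeros((grid.n,) * 3, dtype=np.float64)
    e = grid.patch_edge
    for idx, patch in enumerate(patches):
        patch = np.asarray(patch)
        if patch.shape != (e, e, e):
            raise ValueError(
                f"patch {idx} has shape {patch.shape}, expected {(e, e, e)}"
            )
        oz, oy, ox = grid.patch_origins[idx]
        out[oz : oz + e, oy : oy + e, ox : ox + e] += patch * grid.blend_weight(idx)
    return Volume(out.astype(np.float32), voxel_size, origin)
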