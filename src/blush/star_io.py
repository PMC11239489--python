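"""Particle metadata (STAR) and image-stack (MRC) persistence.

The STAR file is a minimal single-block loop with one row per particle:
image index, ZYZ Euler angles (degrees), in-plane shifts (Angstrom) and the
half-set label (1/2, the gold-standard convention).  Image stacks are
written as 32-bit float MRC with the particle index as the slow axis.
"""

from __future__ import annotations

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .synthetic import ParticleDataset

__all__ = ["save_particles", "load_particles"]

_COLUMNS = [
    "ImageIndex",
    "AngleRot",
    "AngleTilt",
    "AnglePsi",
    "OriginXAngst",
    "OriginYAngst",
    "RandomSubset",
]


def _write_stack(images: np.ndarray, pixel_size: float, path: str) -> None:
    npart, ny, nx = images.shape
    m = gemmi.Ccp4Map()
    # gemmi grid is (u, v, w) = (x, y, z); particle index goes on z
    m.grid = gemmi.FloatGrid(
        np.ascontiguousarray(images.transpose(2, 1, 0).astype(np.float32))
    )
    m.grid.unit_cell = gemmi.UnitCell(
        nx * pixel_size, ny * pixel_size, npart * pixel_size, 90, 90, 90
    )
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(path)


def _read_stack(path: str) -> tuple[np.ndarray, float]:
    m = gemmi.read_ccp4_map(path)
    arr = np.array(m.grid, copy=True)  # (x, y, z)
    images = np.ascontiguousarray(arr.transpose(2, 1, 0))
    pixel = float(m.grid.unit_cell.a / arr.shape[0])
    return images, pixel


def save_particles(data: ParticleDataset, star_path, stack_path) -> None:
    """Write orientation metadata as STAR and images as an MRC stack."""
    doc = gemmi.cif.Document()
    block = doc.add_new_block("particles")
    loop = block.init_loop("_rln", _COLUMNS)
    angles = Rotation.from_matrix(data.rotations).as_euler("ZYZ", degrees=True)
    for p in range(data.n_particles):
        rot, tilt, psi = angles[p]
        sy, sx = data.shifts[p]
        loop.add_row([
            str(p),
            f"{rot:.4f}", f"{tilt:.4f}", f"{psi:.4f}",
            f"{sx:.4f}", f"{sy:.4f}",
            str(int(data.half_labels[p]) + 1),
        ])
    doc.write_file(str(star_path))
    _write_stack(data.images, data.pixel_size, str(stack_path))


def load_particles(star_path, stack_path) -> ParticleDataset:
    doc = gemmi.cif.read_file(str(star_path))
    block = doc.sole_block()
    cols = {c: np.array(list(block.find_loop(f"_rln{c}")), dtype=float)
            for c in _COLUMNS}
    if any(len(v) == 0 for v in cols.values()):
        raise ValueError(f"{star_path}: missing required _rln columns")
    images, pixel = _read_stack(str(stack_path))
    order = np.argsort(cols["ImageIndex"].astype(int))
    angles = np.stack([cols["AngleRot"], cols["AngleTilt"],
                       cols["AnglePsi"]], axis=1)[order]
    rotations = Rotation.from_euler("ZYZ", angles, degrees=True).as_matrix()
    shifts = np.stack([cols["OriginYAngst"], cols["OriginXAngst"]],
                      axis=1)[order]
    labels = cols["RandomSubset"].astype(int)[order] - 1
    return ParticleDataset(
        images=images,
        rotations=rotations,
        shifts=shifts,
        half_labels=labels,
        pixel_size=pixel,
    )
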