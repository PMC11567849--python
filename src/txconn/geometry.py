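"""Voxel-grid geometry helpers shared across the imaging stages.

All volumes in this package are plain ``numpy`` arrays indexed ``(i, j, k)``
together with a 4x4 affine mapping voxel indices to scanner/MNI millimetre
coordinates, the same convention ``nibabel`` uses.  NIfTI I/O lives in the
CLI layer; the library operates on ``(array, affine)`` pairs.
"""

from __future__ import annotations

import numpy as np


def voxel_to_mm(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    """Map voxel indices (..., 3) to mm coordinates (..., 3)."""
    ijk = np.asarray(ijk, dtype=float)
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def mm_to_voxel(affine: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    """Map mm coordinates (..., 3) to (fractional) voxel indices (..., 3)."""
    inv = np.linalg.inv(affine)
    xyz = np.asarray(xyz, dtype=float)
    return xyz @ inv[:3, :3].T + inv[:3, 3]


def grid_coordinates_mm(shape: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    """mm coordinates of every voxel centre, shape ``(*shape, 3)``."""
    idx = np.indices(shape).reshape(3, -1).T
    return voxel_to_mm(affine, idx).reshape(*shape, 3)


def voxel_volume_mm3(affine: np.ndarray) -> float:
    """Volume of one voxel in mm^3 (absolute determinant of the linear part)."""
    return float(abs(np.linalg.det(affine[:3, :3])))


def voxel_sizes_mm(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel edge lengths in mm (column norms of the linear part)."""
    return np.sqrt((affine[:3, :3] ** 2).sum(axis=0))


def ellipsoid_mask(shape: tuple[int, int, int], margin: int = 1) -> np.ndarray:
    """Axis-aligned ellipsoid inscribed in the grid, used as a synthetic brain mask.

    ``margin`` voxels of padding are left outside along every axis so that the
    grid carries out-of-brain voxels, as real normalized images do.
    """
    shape = tuple(int(s) for s in shape)
    centre = (np.asarray(shape) - 1) / 2.0
    radii = np.maximum((np.asarray(shape) - 1) / 2.0 - margin, 1.0)
    idx = np.indices(shape).reshape(3, -1).T
    u = (idx - centre) / radii
    return ((u**2).sum(axis=1) <= 1.0).reshape(shape)


def default_affine(
    shape: tuple[int, int, int],
    voxel_size_mm: float,
    anchor_mni: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Isotropic affine placing the centre voxel of ``shape`` at ``anchor_mni``.

    Synthetic cohorts use this so that a physically meaningful seed coordinate
    (e.g. the left angular gyrus at MNI -45, -67, 38) falls on a voxel centre
    in the middle of the simulated grid.
    """
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = float(voxel_size_mm)
    centre_voxel = np.asarray(shape) // 2
    affine[:3, 3] = np.asarray(anchor_mni, dtype=float) - centre_voxel * float(voxel_size_mm)
    return affine
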