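"""Voxel-grid geometry helpers: affines, world coordinates, resampling."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "affine_from_voxel_size",
    "voxel_size_from_affine",
    "world_coordinates",
    "resample_to_grid",
]


def affine_from_voxel_size(voxel_size, shape=None, centered: bool = True) -> np.ndarray:
    """Diagonal RAS affine for an axis-aligned grid.

    With ``centered=True`` (and a shape given) the world origin sits at the
    grid centre, which is convenient for phantoms whose fields are defined in
    normalised coordinates.
    """
    voxel_size = np.asarray(voxel_size, dtype=float)
    aff = np.eye(4)
    aff[:3, :3] = np.diag(voxel_size)
    if centered and shape is not None:
        aff[:3, 3] = -voxel_size * (np.asarray(shape[:3], dtype=float) - 1) / 2.0
    return aff


def voxel_size_from_affine(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel size in mm (column norms of the linear part)."""
    return np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)


def world_coordinates(shape, affine: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """World (mm) coordinate volumes for every voxel of a 3-D grid."""
    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    lin = np.asarray(affine)[:3, :3]
    off = np.asarray(affine)[:3, 3]
    x = lin[0, 0] * ii + lin[0, 1] * jj + lin[0, 2] * kk + off[0]
    y = lin[1, 0] * ii + lin[1, 1] * jj + lin[1, 2] * kk + off[1]
    z = lin[2, 0] * ii + lin[2, 1] * jj + lin[2, 2] * kk + off[2]
    return x, y, z


def resample_to_grid(
    data: np.ndarray,
    src_affine: np.ndarray,
    dst_shape,
    dst_affine: np.ndarray,
    order: int = 1,
) -> np.ndarray:
    """Resample a 3-D volume onto a target grid via the two affines.

    Trilinear interpolation by default (``order=1``).  Voxels of the target
    grid that fall outside the source extent are returned as NaN so that
    downstream stages can mark them invalid.

    Raises
    ------
    ValueError
        If either affine is singular (orientation cannot be established).
    """
    data = np.asarray(data, dtype=float)
    src_affine = np.asarray(src_affine, dtype=float)
    dst_affine = np.asarray(dst_affine, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {data.shape}")
    try:
        src_inv = np.linalg.inv(src_affine)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError("source affine is singular") from exc
    # voxel-to-voxel mapping: dst index -> world -> src index
    m = src_inv @ dst_affine
    ii, jj, kk = np.meshgrid(
        np.arange(dst_shape[0]), np.arange(dst_shape[1]), np.arange(dst_shape[2]),
        indexing="ij",
    )
    coords = np.stack(
        [
            m[0, 0] * ii + m[0, 1] * jj + m[0, 2] * kk + m[0, 3],
            m[1, 0] * ii + m[1, 1] * jj + m[1, 2] * kk + m[1, 3],
            m[2, 0] * ii + m[2, 1] * jj + m[2, 2] * kk + m[2, 3],
        ]
    )
    out = ndimage.map_coordinates(
        data, coords, order=order, mode="constant", cval=np.nan, prefilter=order > 1
    )
    return out.reshape(dst_shape)
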