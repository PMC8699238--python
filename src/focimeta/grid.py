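"""Voxel grids and brain masks.

A :class:`VoxelGrid` is an isotropic lattice in MNI millimetre space
(right-anterior-superior axes) with a binary brain mask.  The default mask is
an axis-aligned ellipsoid with semi-axes (72, 90, 65) mm centred at
(0, -16, 11) mm - a coarse stand-in for an MNI brain volume (which is
posterior- and superior-shifted relative to the origin) that keeps the
package free of external templates while containing the coordinate ranges
reported meta-analyses actually span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .exceptions import ConfigError

DEFAULT_SEMI_AXES = (72.0, 90.0, 65.0)
DEFAULT_CENTER = (0.0, -16.0, 11.0)


@dataclass(frozen=True)
class EllipsoidMask:
    """Axis-aligned ellipsoid in mm, centred at ``center``."""

    semi_axes: tuple[float, float, float] = DEFAULT_SEMI_AXES
    center: tuple[float, float, float] = DEFAULT_CENTER

    def __post_init__(self):
        if min(self.semi_axes) <= 0:
            raise ConfigError("ellipsoid semi-axes must be positive")

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        rel = (pts - np.asarray(self.center)) / np.asarray(self.semi_axes)
        return (rel ** 2).sum(axis=1) <= 1.0

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center)
        s = np.asarray(self.semi_axes)
        return c - s, c + s


@dataclass
class VoxelGrid:
    """Isotropic voxel lattice with a world affine and a binary mask.

    ``origin`` is the mm position of the centre of voxel (0, 0, 0); world
    coordinates are ``origin + index * voxel_size``.
    """

    voxel_size: float
    origin: np.ndarray
    shape: tuple[int, int, int]
    mask: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ConfigError("voxel_size must be positive")
        self.origin = np.asarray(self.origin, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != tuple(self.shape):
            raise ConfigError("mask shape does not match grid shape")
        if not self.mask.any():
            raise ConfigError("brain mask is empty")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        aff[:3, 3] = self.origin
        return aff

    @property
    def voxel_volume(self) -> float:
        return float(self.voxel_size ** 3)

    def voxel_centers_mm(self, indices: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(indices, dtype=float) * self.voxel_size

    def mm_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Nearest voxel index; exact half-way ties break toward negative
        indices (ceil(u - 1/2))."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        u = (pts - self.origin) / self.voxel_size
        return np.ceil(u - 0.5).astype(int)

    def in_bounds(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(indices)
        return ((idx >= 0) & (idx < np.asarray(self.shape))).all(axis=1)

    @classmethod
    def from_mask_fn(cls, contains, lower_mm, upper_mm, voxel_size: float = 2.0):
        """Build a grid whose lattice spans [lower_mm, upper_mm] and rasterize
        ``contains`` (a vectorized mm-point predicate) at the voxel centres."""
        lower = np.asarray(lower_mm, dtype=float)
        upper = np.asarray(upper_mm, dtype=float)
        shape = tuple(np.floor((upper - lower) / voxel_size).astype(int) + 1)
        idx = np.indices(shape).reshape(3, -1).T
        centers = lower + idx * voxel_size
        mask = contains(centers).reshape(shape)
        return cls(voxel_size=voxel_size, origin=lower, shape=shape, mask=mask)


def default_grid(voxel_size: float = 2.0,
                 semi_axes: tuple[float, float, float] = DEFAULT_SEMI_AXES,
                 center: tuple[float, float, float] = DEFAULT_CENTER,
                 margin_mm: float = 2.0) -> VoxelGrid:
    """Ellipsoid-masked grid covering the default brain stand-in."""
    ell = EllipsoidMask(semi_axes=semi_axes, center=center)
    lo, hi = ell.bounding_box
    return VoxelGrid.from_mask_fn(ell.contains, lo - margin_mm, hi + margin_mm,
                                  voxel_size)


def save_nifti(volume: np.ndarray, grid: VoxelGrid, path) -> None:
    """Write a volume on this grid as NIfTI-1 (float32, grid affine)."""
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), grid.affine)
    nib.save(img, str(path))
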