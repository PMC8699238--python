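"""Cluster-centred cubic regions of interest.

For each discriminative cluster the per-axis dispersion of its member foci
(centroid +/- one sample standard deviation) is reported as a diagnostic, and
the final ROI is a fixed-edge axis-aligned cube (default 18 mm) centred on the
centroid.  Per-condition ROIs are the voxelwise union of their cubes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ValidationError
from .grid import VoxelGrid


def sigma_range(cluster_coords) -> pd.DataFrame:
    """Per-axis centroid, sample sd, and centroid +/- 1 sigma bounds.

    Needs at least two foci; an axis with zero spread is flagged degenerate.
    ``lower_int``/``upper_int`` give the integer display rounding; full
    precision is kept in ``lower``/``upper``.
    """
    coords = np.asarray(cluster_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValidationError("cluster_coords must be an (n, 3) array")
    if len(coords) < 2:
        raise ValidationError("dispersion needs at least two foci")
    centroid = coords.mean(axis=0)
    sigma = coords.std(axis=0, ddof=1)
    lower = centroid - sigma
    upper = centroid + sigma
    return pd.DataFrame({
        "axis": ["x", "y", "z"],
        "centroid": centroid, "sigma": sigma,
        "lower": lower, "upper": upper,
        "lower_int": np.rint(lower).astype(int),
        "upper_int": np.rint(upper).astype(int),
        "degenerate": sigma == 0.0,
    }).set_index("axis")


@dataclass(frozen=True)
class RoiCube:
    """Axis-aligned cube: ``center`` mm, ``edge`` mm on every axis."""

    center: tuple[float, float, float]
    edge: float = 18.0

    def __post_init__(self):
        if self.edge <= 0:
            raise ConfigError("cube edge must be positive")

    @property
    def bounds(self) -> np.ndarray:
        """(3, 2) array of per-axis [min, max] = center -/+ edge/2."""
        c = np.asarray(self.center, dtype=float)
        h = self.edge / 2.0
        return np.stack([c - h, c + h], axis=1)

    @property
    def volume_mm3(self) -> float:
        return float(self.edge ** 3)

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        """Inclusive containment of mm points."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        b = self.bounds
        return ((pts >= b[:, 0]) & (pts <= b[:, 1])).all(axis=1)


def build_cube(center, edge: float = 18.0) -> RoiCube:
    """Fixed-edge cube centred on a cluster centroid."""
    return RoiCube(center=tuple(float(v) for v in np.asarray(center, float)), edge=edge)


def rasterize_union(cubes, grid: VoxelGrid) -> np.ndarray:
    """Binary mask volume: a voxel is in iff its centre lies in any cube
    (inclusive bounds)."""
    cubes = list(cubes)
    if not cubes:
        raise ValidationError("no cubes to rasterize")
    out = np.zeros(grid.shape, dtype=bool)
    idx = np.indices(grid.shape).reshape(3, -1).T
    centers = grid.voxel_centers_mm(idx)
    for cube in cubes:
        out |= cube.contains(centers).reshape(grid.shape)
    if not out.any():
        raise ValidationError("union is empty: no voxel centre falls in any cube")
    return out
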