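"""Activation likelihood estimation (ALE) with permutation thresholding.

The ALE statistic treats each study's reported peaks as centres of spatial
uncertainty: a study's *modelled activation* (MA) map smooths its foci with an
isotropic 3-D Gaussian (voxelwise max across the study's own foci, so a study
cannot reinforce itself), and the ALE map is the probabilistic union across
studies,

    ALE(v) = 1 - prod_studies (1 - MA_study(v)),

the voxelwise probability that at least one study truly activates there.
Significance comes from a Monte-Carlo null in which every study's foci are
relocated uniformly over the brain-mask voxels (per-study focus counts
preserved): the pooled null values give the voxel-level cluster-forming
cutoff, and the per-permutation maximum suprathreshold cluster size gives the
cluster-level family-wise-error cutoff.

Kernel width: when a study's subject count is known the FWHM follows the
empirical uncertainty model of the ALE literature (a fixed between-template
term plus a between-subject term shrinking as 1/sqrt(n)); otherwise a
configurable fixed default (10 mm) is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import ConfigError, EmptyInputError, ValidationError
from .grid import VoxelGrid

_FWHM_TO_SD = 1.0 / np.sqrt(8.0 * np.log(2.0))
# empirical localisation uncertainty (mm FWHM): between-template term and
# between-subject term at n = 1
_TEMPLATE_FWHM = 5.7 / (2.0 * np.sqrt(2.0 / np.pi)) * np.sqrt(8.0 * np.log(2.0))
_SUBJECT_FWHM = 11.6 / (2.0 * np.sqrt(2.0 / np.pi)) * np.sqrt(8.0 * np.log(2.0))

DEFAULT_FWHM_MM = 10.0


def kernel_fwhm(n_subjects: int) -> float:
    """Sample-size-based smoothing width (mm FWHM)."""
    if n_subjects < 1:
        raise ConfigError("n_subjects must be >= 1")
    return float(np.sqrt(_TEMPLATE_FWHM ** 2 + (_SUBJECT_FWHM / np.sqrt(n_subjects)) ** 2))


def build_kernel(n_subjects: int | None = None, fwhm_override: float | None = None,
                 voxel_size: float = 2.0,
                 default_fwhm: float = DEFAULT_FWHM_MM) -> np.ndarray:
    """Discretized isotropic Gaussian, truncated at +/-3 sd, sum-normalised.

    The returned odd-sided cube holds per-voxel probabilities (sums to 1);
    the peak sits at the central voxel.
    """
    if voxel_size <= 0:
        raise ConfigError("voxel_size must be positive")
    if fwhm_override is not None:
        fwhm = fwhm_override
    elif n_subjects is not None:
        fwhm = kernel_fwhm(n_subjects)
    else:
        fwhm = default_fwhm
    if fwhm <= 0:
        raise ConfigError("FWHM must be positive")
    sd = fwhm * _FWHM_TO_SD
    radius = int(np.ceil(3.0 * sd / voxel_size))
    ax = np.arange(-radius, radius + 1) * voxel_size
    sq = ax ** 2
    dist2 = sq[:, None, None] + sq[None, :, None] + sq[None, None, :]
    kern = np.exp(-dist2 / (2.0 * sd * sd))
    kern[dist2 > (3.0 * sd) ** 2] = 0.0
    return kern / kern.sum()


def _stamp_max(volume: np.ndarray, kernel: np.ndarray, centers: np.ndarray) -> None:
    """Max-combine ``kernel`` into ``volume`` at each voxel-index centre,
    clipping at the grid edges."""
    r = kernel.shape[0] // 2
    shape = volume.shape
    for c in centers:
        lo = np.maximum(c - r, 0)
        hi = np.minimum(c + r + 1, shape)
        klo = lo - (c - r)
        khi = klo + (hi - lo)
        view = volume[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        np.maximum(view, kernel[klo[0]:khi[0], klo[1]:khi[1], klo[2]:khi[2]],
                   out=view)


def compute_ma_map(coords_mm: np.ndarray, kernel: np.ndarray,
                   grid: VoxelGrid) -> np.ndarray:
    """One study's modelled-activation map.

    Each focus is stamped at its nearest voxel centre; within the study the
    voxelwise combination is the maximum, so several nearby foci from the
    same experiment do not inflate convergence.  Foci outside the grid
    bounding box are excluded with a warning count in the module log.
    """
    coords = np.atleast_2d(np.asarray(coords_mm, dtype=float))
    if coords.size == 0:
        raise EmptyInputError("a study must contribute at least one focus")
    idx = grid.mm_to_voxel(coords)
    inside = grid.in_bounds(idx)
    if not inside.all():
        import logging
        logging.getLogger(__name__).warning(
            "%d focus/foci outside the grid bounding box excluded",
            int((~inside).sum()))
    idx = idx[inside]
    vol = np.zeros(grid.shape, dtype=float)
    if len(idx):
        _stamp_max(vol, kernel, idx)
    vol[~grid.mask] = 0.0
    return vol


def compute_ale_map(ma_maps) -> np.ndarray:
    """Probabilistic union of MA maps: 1 - prod(1 - MA)."""
    ma_maps = list(ma_maps)
    if not ma_maps:
        raise EmptyInputError("need at least one MA map")
    shape = ma_maps[0].shape
    anti = np.ones(shape, dtype=float)
    for ma in ma_maps:
        if ma.shape != shape:
            raise ValidationError("MA maps are not on a common grid")
        anti *= 1.0 - ma
    return 1.0 - anti


def _structure(connectivity: int) -> np.ndarray:
    try:
        rank = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ConfigError("connectivity must be 6, 18 or 26") from None
    return ndimage.generate_binary_structure(3, rank)


@dataclass
class NullDistribution:
    """Monte-Carlo null summaries from uniform relocation of all foci.

    ``voxel_values`` pools, per permutation, the null ALE value of every mask
    voxel; ``max_cluster_sizes`` is the largest suprathreshold component (in
    voxels, at ``cluster_forming_p``) of each permutation.
    """

    voxel_values: np.ndarray = field(repr=False)   # (n_perm, n_mask_voxels)
    max_cluster_sizes: np.ndarray                  # (n_perm,)
    n_perm: int
    seed: int
    cluster_forming_p: float
    connectivity: int

    def voxel_threshold(self, cluster_forming_p: float | None = None) -> float:
        p = self.cluster_forming_p if cluster_forming_p is None else p_check(cluster_forming_p)
        return float(np.quantile(self.voxel_values.ravel(), 1.0 - p, method="higher"))

    def cluster_size_threshold(self, cluster_fwe_p: float = 0.05) -> float:
        return float(np.quantile(self.max_cluster_sizes, 1.0 - cluster_fwe_p,
                                 method="higher"))


def p_check(p: float) -> float:
    if not 0.0 < p < 0.5:
        raise ConfigError(f"threshold p {p} outside (0, 0.5)")
    return p


def sample_null(foci_counts, kernel, grid: VoxelGrid, n_perm: int = 1000,
                seed: int = 0, cluster_forming_p: float = 1e-4,
                connectivity: int = 26) -> NullDistribution:
    """Build the permutation null by relocating every study's foci uniformly
    over the mask voxels.

    Parameters
    ----------
    foci_counts : sequence of int
        Number of foci per study (counts are preserved under relocation).
    kernel : ndarray or sequence of ndarray
        A shared kernel, or one kernel per study.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    p_check(cluster_forming_p)
    counts = [int(c) for c in foci_counts]
    if not counts or min(counts) < 1:
        raise ValidationError("every study needs at least one focus")
    kernels = ([kernel] * len(counts) if isinstance(kernel, np.ndarray)
               else list(kernel))
    if len(kernels) != len(counts):
        raise ValidationError("one kernel per study required")
    mask_idx = np.argwhere(grid.mask)
    n_mask = len(mask_idx)
    values = np.empty((n_perm, n_mask), dtype=np.float32)
    seeds = np.random.SeedSequence(seed).spawn(n_perm)
    anti = np.empty(grid.shape, dtype=float)
    ma = np.empty(grid.shape, dtype=float)
    for p in range(n_perm):
        rng = np.random.default_rng(seeds[p])
        anti.fill(1.0)
        for count, kern in zip(counts, kernels):
            ma.fill(0.0)
            pick = mask_idx[rng.integers(n_mask, size=count)]
            _stamp_max(ma, kern, pick)
            anti *= 1.0 - ma
        values[p] = (1.0 - anti)[grid.mask]
    thr = np.quantile(values.ravel(), 1.0 - cluster_forming_p, method="higher")
    structure = _structure(connectivity)
    max_sizes = np.zeros(n_perm, dtype=int)
    vol = np.zeros(grid.shape, dtype=bool)
    for p in range(n_perm):
        vol[grid.mask] = values[p] > thr
        labels, n_comp = ndimage.label(vol, structure=structure)
        if n_comp:
            max_sizes[p] = int(np.bincount(labels.ravel())[1:].max())
    return NullDistribution(voxel_values=values, max_cluster_sizes=max_sizes,
                            n_perm=n_perm, seed=seed,
                            cluster_forming_p=cluster_forming_p,
                            connectivity=connectivity)


@dataclass
class ClusterReportRow:
    """One surviving cluster of the thresholded ALE map."""

    cluster_index: int
    peak_mm: tuple[float, float, float]
    peak_ale: float
    size_voxels: int
    size_mm3: float
    subpeaks: list = field(default_factory=list)  # [(mm, ale), ...] incl. the peak


def _subpeaks(ale, cluster_mask, grid, min_dist_mm=8.0):
    local = ndimage.maximum_filter(np.where(cluster_mask, ale, -np.inf), size=3)
    cand = np.argwhere(cluster_mask & (ale >= local))
    vals = ale[tuple(cand.T)]
    order = np.argsort(-vals)
    kept, kept_mm = [], []
    for i in order:
        mm = grid.voxel_centers_mm(cand[i])
        if all(np.linalg.norm(mm - k) >= min_dist_mm for k in kept_mm):
            kept_mm.append(mm)
            kept.append((tuple(float(v) for v in mm), float(vals[i])))
    return kept


def threshold_ale(ale: np.ndarray, null: NullDistribution, grid: VoxelGrid,
                  cluster_forming_p: float = 1e-4, cluster_fwe_p: float = 0.05,
                  connectivity: int = 26
                  ) -> tuple[np.ndarray, list[ClusterReportRow]]:
    """Voxel-level cluster-forming threshold + cluster-level FWE correction.

    A voxel survives if its ALE exceeds the (1 - cluster_forming_p) quantile
    of the pooled null; connected components (default 26-connectivity)
    survive if their size exceeds the (1 - cluster_fwe_p) quantile of the
    null maximum-cluster-size distribution.  Returns the thresholded map and
    report rows sorted by size descending, each with local maxima at least
    8 mm apart as subpeaks.
    """
    p_check(cluster_forming_p)
    if not 0.0 < cluster_fwe_p < 1.0:
        raise ConfigError("cluster_fwe_p must be in (0, 1)")
    thr = null.voxel_threshold(cluster_forming_p)
    supra = (ale > thr) & grid.mask
    labels, n_comp = ndimage.label(supra, structure=_structure(connectivity))
    size_cut = null.cluster_size_threshold(cluster_fwe_p)
    rows: list[ClusterReportRow] = []
    out = np.zeros_like(ale)
    if n_comp:
        sizes = np.bincount(labels.ravel())[1:]
        surviving = np.flatnonzero(sizes > size_cut) + 1
        for lab in surviving:
            cmask = labels == lab
            out[cmask] = ale[cmask]
            peaks = _subpeaks(ale, cmask, grid)
            rows.append(ClusterReportRow(
                cluster_index=0,
                peak_mm=peaks[0][0],
                peak_ale=peaks[0][1],
                size_voxels=int(cmask.sum()),
                size_mm3=float(cmask.sum() * grid.voxel_volume),
                subpeaks=peaks,
            ))
        rows.sort(key=lambda r: -r.size_voxels)
        for i, row in enumerate(rows, start=1):
            row.cluster_index = i
    return out, rows


def report_to_frame(rows: list[ClusterReportRow]) -> pd.DataFrame:
    """Cluster report as a table (one row per cluster, peak coordinates split
    into x/y/z columns)."""
    return pd.DataFrame([
        {"cluster": r.cluster_index,
         "peak_x": r.peak_mm[0], "peak_y": r.peak_mm[1], "peak_z": r.peak_mm[2],
         "peak_ale": r.peak_ale, "size_voxels": r.size_voxels,
         "size_mm3": r.size_mm3, "n_subpeaks": len(r.subpeaks)}
        for r in rows
    ])
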