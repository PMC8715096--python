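"""Voxel-height thresholding and permutation cluster-extent FWE control.

Group maps are thresholded at a one-tailed voxel p (default 0.001, converted
to a t quantile at the group's df).  Cluster-extent family-wise error is then
controlled nonparametrically: under the one-sample null the subject Fisher-z
maps are sign-symmetric, so random sign-flips of whole subjects generate the
null distribution of the maximum supra-threshold cluster size.  A cluster's
FWE p-value is (1 + #{null max >= observed size}) / (n_perm + 1), the +1
accounting for the always-included identity permutation; clusters with
fwe_p <= alpha survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from .core import BinaryMask, StatMap, VolumeGrid, connectivity_structure
from .fc import GroupMap, SubjectFcMap, group_onesample
from .rois import ClusterRecord, find_clusters, locate_peak

__all__ = ["InferenceResult", "height_threshold", "permutation_cluster_fwe"]

logger = logging.getLogger(__name__)


def height_threshold(group: GroupMap, voxel_p: float = 0.001, sign: str = "positive") -> BinaryMask:
    """Voxels whose one-tailed p in the requested direction beats ``voxel_p``.

    The cutoff is applied on the t scale: t* = t-quantile(1 - voxel_p, df).
    """
    if not 0 < voxel_p <= 1:
        raise ValueError("voxel_p must lie in (0, 1]")
    t_star = stats.t.ppf(1.0 - voxel_p, group.df)
    if sign == "positive":
        data = group.t > t_star
    elif sign == "negative":
        data = group.t < -t_star
    else:
        raise ValueError("sign must be 'positive' or 'negative'")
    data &= group.valid
    return BinaryMask(group.grid, data)


@dataclass
class InferenceResult:
    """Outcome of one sign's permutation cluster-extent test."""

    sign: str
    voxel_p: float
    alpha: float
    clusters: list[ClusterRecord]  # all supra-threshold clusters, fwe_p filled
    n_permutations: int
    rng_seed: int
    t_threshold: float
    df: int
    n_subjects: int
    grid: VolumeGrid
    stat_map: StatMap = field(repr=False, default=None)  # group t map
    method_note: str = (
        "cluster-level FWE by sign-flip permutation of subject z-maps "
        "(max-cluster-size null), not parametric random-field theory"
    )

    @property
    def surviving(self) -> list[ClusterRecord]:
        return [c for c in self.clusters if c.cluster_fwe_p is not None and c.cluster_fwe_p <= self.alpha]

    def surviving_mask(self) -> BinaryMask:
        data = np.zeros(self.grid.shape, dtype=bool)
        for c in self.surviving:
            data[tuple(c.voxel_indices.T)] = True
        return BinaryMask(self.grid, data)


def _perm_t(Z: np.ndarray, signs: np.ndarray, ss: np.ndarray) -> np.ndarray:
    """t statistics after sign-flipping rows of Z; exploits sum(Z^2) invariance."""
    n = Z.shape[0]
    mean = signs @ Z / n
    var = (ss - n * mean**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    t[~np.isfinite(t)] = 0.0
    return t


def permutation_cluster_fwe(
    z_maps: Sequence[SubjectFcMap],
    voxel_p: float = 0.001,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    sign: str = "positive",
    connectivity: int = 26,
) -> InferenceResult:
    """Max-cluster-size permutation test for one correlation direction.

    The permutation stream is counter-based (numpy Philox), so extending
    ``n_perm`` with the same seed reuses the earlier draws as a prefix.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if len(z_maps) < 2:
        raise ValueError("need at least 2 subjects")
    if len(z_maps) < 8:
        logger.warning("only %d subjects: permutation null is coarse below 8", len(z_maps))
    group = group_onesample(z_maps)
    t_star = float(stats.t.ppf(1.0 - voxel_p, group.df))
    structure = connectivity_structure(connectivity)

    observed_mask = height_threshold(group, voxel_p, sign)
    clusters = find_clusters(observed_mask, min_size=1, connectivity=connectivity)
    for rec in clusters:
        rec.peak_value, rec.peak_mni_mm = locate_peak(
            rec, StatMap(group.grid, group.t), sign=sign
        )

    Z = np.stack([m.z_values.reshape(-1) for m in z_maps])
    n = Z.shape[0]
    ss = (Z**2).sum(axis=0)
    rng = np.random.Generator(np.random.Philox(seed))
    signs = rng.choice(np.array([-1.0, 1.0]), size=(n_perm, n))
    shape = group.grid.shape
    valid = group.valid.reshape(-1)
    null_max = np.zeros(n_perm, dtype=int)
    for p in range(n_perm):
        t = _perm_t(Z, signs[p], ss)
        t[~valid] = 0.0
        supra = (t > t_star) if sign == "positive" else (t < -t_star)
        labeled, nlab = ndimage.label(supra.reshape(shape), structure=structure)
        if nlab:
            null_max[p] = int(np.bincount(labeled.reshape(-1))[1:].max())

    for rec in clusters:
        exceed = int(np.sum(null_max >= rec.size_voxels))
        rec.cluster_fwe_p = (1 + exceed) / (n_perm + 1)
    result = InferenceResult(
        sign=sign,
        voxel_p=voxel_p,
        alpha=alpha,
        clusters=clusters,
        n_permutations=n_perm,
        rng_seed=seed,
        t_threshold=t_star,
        df=group.df,
        n_subjects=n,
        grid=group.grid,
        stat_map=StatMap(group.grid, group.t),
    )
    logger.info(
        "%s-sign inference: %d supra-threshold cluster(s), %d surviving at alpha=%.3g",
        sign, len(clusters), len(result.surviving), alpha,
    )
    return result
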