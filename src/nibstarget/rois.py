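"""From a thresholded meta-analytic map to refined spherical seed regions.

The extraction recipe: label the supra-threshold support, keep clusters above
a size cutoff, take each cluster's peak coordinate, grow a 6 mm sphere around
it, and intersect the sphere with the original map support.  The resulting
refined masks are the seeds for the connectivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import BinaryMask, StatMap, VolumeGrid, connectivity_structure

__all__ = [
    "ClusterRecord",
    "RoiSet",
    "find_clusters",
    "locate_peak",
    "sphere_mask",
    "refine_rois",
    "extract_rois",
    "clusters_to_table",
]

logger = logging.getLogger(__name__)


@dataclass
class ClusterRecord:
    """One connected component of a statistical map.

    ``peak_value``/``peak_mni_mm`` may be unset for clusters whose values are
    flat by construction (overlap-count level sets); ``centroid_mni_mm`` is
    always available as a fallback anchor.
    """

    cluster_id: int
    size_voxels: int
    voxel_indices: np.ndarray = field(repr=False)  # (n, 3) int
    peak_value: float | None = None
    peak_mni_mm: tuple[float, float, float] | None = None
    centroid_mni_mm: tuple[float, float, float] | None = None
    anatomical_label: str | None = None
    scalp_label: str | None = None
    cluster_fwe_p: float | None = None

    def mask(self, grid: VolumeGrid) -> BinaryMask:
        data = np.zeros(grid.shape, dtype=bool)
        data[tuple(self.voxel_indices.T)] = True
        return BinaryMask(grid, data)


@dataclass
class RoiSet:
    """Named seed regions on a shared grid."""

    grid: VolumeGrid
    rois: list[tuple[str, BinaryMask, tuple[float, float, float]]]

    def __post_init__(self) -> None:
        names = [n for n, _, _ in self.rois]
        if len(set(names)) != len(names):
            raise ValueError("ROI names must be unique")
        for _, mask, _ in self.rois:
            self.grid.require_match(mask.grid)

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    @property
    def names(self) -> list[str]:
        return [n for n, _, _ in self.rois]


def find_clusters(
    mask: BinaryMask,
    min_size: int = 0,
    connectivity: int = 26,
    strict: bool = False,
) -> list[ClusterRecord]:
    """Connected components of a binary mask, size-filtered.

    With ``strict=True`` only components larger than ``min_size`` survive
    (the meta-analysis convention "larger than 50 voxels"); otherwise
    components of at least ``min_size`` voxels are kept.  Components are
    ordered by size descending, ties broken by smallest linear voxel index.
    An empty mask yields an empty list.
    """
    structure = connectivity_structure(connectivity)
    labeled, n = ndimage.label(mask.data, structure=structure)
    records = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labeled == lab)
        size = len(idx)
        keep = size > min_size if strict else size >= min_size
        if not keep:
            continue
        records.append(ClusterRecord(cluster_id=0, size_voxels=size, voxel_indices=idx))

    def linear_index(rec: ClusterRecord) -> int:
        lin = np.ravel_multi_index(rec.voxel_indices.T, mask.grid.shape)
        return int(lin.min())

    records.sort(key=lambda r: (-r.size_voxels, linear_index(r)))
    for i, rec in enumerate(records, start=1):
        rec.cluster_id = i
        rec.centroid_mni_mm = tuple(
            np.asarray(mask.grid.voxel_to_mm(rec.voxel_indices.mean(axis=0)), dtype=float)
        )
    return records


def locate_peak(
    cluster: ClusterRecord | np.ndarray,
    stat_map: StatMap,
    sign: str = "positive",
) -> tuple[float, tuple[float, float, float]]:
    """Peak value and MNI-mm coordinate of a cluster under a sign convention.

    ``sign``: "positive" takes the arg-max of the signed value, "negative"
    the arg-min (returning the signed value), "absolute" the arg-max of |v|.
    Ties break at the smallest linear voxel index.
    """
    idx = cluster.voxel_indices if isinstance(cluster, ClusterRecord) else np.asarray(cluster)
    if len(idx) == 0:
        raise ValueError("cluster is empty")
    vals = stat_map.data[tuple(idx.T)]
    if sign == "positive":
        key = vals
    elif sign == "negative":
        key = -vals
    elif sign == "absolute":
        key = np.abs(vals)
    else:
        raise ValueError("sign must be positive, negative or absolute")
    lin = np.ravel_multi_index(idx.T, stat_map.grid.shape)
    order = np.lexsort((lin, -key))  # max key, then smallest linear index
    best = order[0]
    mm = stat_map.grid.voxel_to_mm(idx[best])
    return float(vals[best]), tuple(float(v) for v in np.asarray(mm))


def sphere_mask(
    grid: VolumeGrid, center_mm: Sequence[float], radius_mm: float = 6.0
) -> BinaryMask:
    """Voxels whose centers lie within ``radius_mm`` (inclusive) of a point."""
    if radius_mm < 0:
        raise ValueError("radius must be nonnegative")
    center = np.asarray(center_mm, dtype=float)
    centers = grid.voxel_centers_mm()
    d2 = np.sum((centers - center) ** 2, axis=1)
    if radius_mm == 0:
        data = np.zeros(grid.n_voxels, dtype=bool)
        data[np.argmin(d2)] = True
    else:
        data = d2 <= radius_mm**2
    if not data.any():
        raise ValueError(f"sphere at {tuple(center)} lies entirely outside the grid")
    return BinaryMask(grid, data.reshape(grid.shape))


def refine_rois(spheres: RoiSet, source_mask: BinaryMask) -> RoiSet:
    """Intersect each spherical ROI with the source-map support.

    Spheres that fall entirely outside the support are dropped with a
    warning; if nothing survives the refinement is an error.
    """
    spheres.grid.require_match(source_mask.grid)
    kept = []
    for name, mask, center in spheres:
        refined = mask.intersect(source_mask)
        if refined.is_empty():
            logger.warning("ROI %r empty after refinement against the source map; dropped", name)
            continue
        kept.append((name, refined, center))
    if not kept:
        raise ValueError("all ROIs empty after refinement")
    return RoiSet(spheres.grid, kept)


def extract_rois(
    meta_map: StatMap,
    min_cluster_voxels: int = 50,
    radius_mm: float = 6.0,
    connectivity: int = 26,
    strict: bool = True,
    name_prefix: str = "ROI",
) -> tuple[RoiSet, list[ClusterRecord]]:
    """Full extraction: clusters of the (already thresholded) map's support,
    peaks, 6 mm spheres, refinement against the support.

    Returns the refined ROI set and the cluster table records (with peaks
    filled) in matching order.
    """
    support = BinaryMask(meta_map.grid, meta_map.data != 0)
    clusters = find_clusters(support, min_cluster_voxels, connectivity, strict=strict)
    spheres = []
    for rec in clusters:
        rec.peak_value, rec.peak_mni_mm = locate_peak(rec, meta_map, sign="absolute")
        spheres.append(
            (f"{name_prefix}{rec.cluster_id:02d}", sphere_mask(meta_map.grid, rec.peak_mni_mm, radius_mm), rec.peak_mni_mm)
        )
    if not spheres:
        raise ValueError("no clusters survive the size filter; nothing to extract")
    refined = refine_rois(RoiSet(meta_map.grid, spheres), support)
    kept_names = set(refined.names)
    clusters = [
        rec for rec in clusters if f"{name_prefix}{rec.cluster_id:02d}" in kept_names
    ]
    return refined, clusters


def clusters_to_table(clusters: Sequence[ClusterRecord]) -> pd.DataFrame:
    """Cluster records as a table with peak value and MNI coordinates."""
    rows = []
    for rec in clusters:
        peak = rec.peak_mni_mm or (np.nan, np.nan, np.nan)
        rows.append(
            {
                "cluster_id": rec.cluster_id,
                "size_voxels": rec.size_voxels,
                "peak_value": np.nan if rec.peak_value is None else rec.peak_value,
                "peak_x": peak[0],
                "peak_y": peak[1],
                "peak_z": peak[2],
                "brain_region": rec.anatomical_label or "",
                "location_10_20": rec.scalp_label or "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "size_voxels", "peak_value",
            "peak_x", "peak_y", "peak_z", "brain_region", "location_10_20",
        ],
    )
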