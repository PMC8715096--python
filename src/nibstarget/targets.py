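"""Three pipelines for selecting brain-surface stimulation-target clusters.

All pipelines restrict candidates to a brain-surface mask (the union of
cortical regions a stimulation coil can reach):

1. clusters taken directly from the meta-analytic map;
2. surviving clusters of the disease-network seed's group correlation map,
   positive and negative directions separately, top clusters by |peak|;
3. an overlap ("third-level") map counting, per voxel, how many single-ROI
   group maps include it; clusters are cut from descending level sets of the
   count and ranked by (count level, size).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import BinaryMask, StatMap, VolumeGrid
from .inference import InferenceResult
from .rois import ClusterRecord, clusters_to_table, find_clusters, locate_peak
from .synth import Parcellation

__all__ = [
    "SurfaceMask",
    "OverlapMap",
    "TargetReport",
    "build_surface_mask",
    "pipeline1",
    "pipeline2",
    "binarize_map",
    "overlap_sum",
    "pipeline3",
    "annotate_anatomy",
]

logger = logging.getLogger(__name__)


@dataclass
class SurfaceMask:
    """Brain-surface mask with the provenance list of included region names."""

    mask: BinaryMask
    region_names: list[str]

    def __post_init__(self) -> None:
        if self.mask.is_empty():
            raise ValueError("surface mask is empty")


@dataclass
class OverlapMap:
    """Voxelwise count of source masks containing each voxel."""

    grid: VolumeGrid
    data: np.ndarray
    n_sources: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=int)
        if self.data.shape != self.grid.shape:
            raise ValueError("overlap data shape inconsistent with grid")
        if self.data.max(initial=0) > self.n_sources or self.data.min(initial=0) < 0:
            raise ValueError("overlap values must lie in [0, n_sources]")

    def to_stat_map(self) -> StatMap:
        return StatMap(self.grid, self.data.astype(float))


@dataclass
class TargetReport:
    """Ranked surface clusters from one pipeline and sign."""

    pipeline: int
    sign: str  # positive | negative | none
    clusters: list[ClusterRecord]
    params: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return clusters_to_table(self.clusters)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")


def build_surface_mask(parcellation: Parcellation, region_names: Sequence[str]) -> SurfaceMask:
    """Union of the named parcellation labels."""
    names = list(dict.fromkeys(region_names))  # dedupe, keep order
    known = set(parcellation.table["name"])
    unknown = [n for n in names if n not in known]
    if unknown:
        raise ValueError(f"unknown region name(s): {unknown}")
    data = np.zeros(parcellation.grid.shape, dtype=bool)
    for n in names:
        data |= parcellation.region_mask(n).data
    return SurfaceMask(BinaryMask(parcellation.grid, data), names)


def pipeline1(
    meta_map: StatMap,
    surface: SurfaceMask,
    min_cluster: int = 50,
    strict: bool = True,
    connectivity: int = 26,
) -> TargetReport:
    """Surface clusters picked directly from the thresholded meta-analytic map."""
    meta_map.grid.require_match(surface.mask.grid)
    support = BinaryMask(meta_map.grid, (meta_map.data != 0) & surface.mask.data)
    clusters = find_clusters(support, min_cluster, connectivity, strict=strict)
    for rec in clusters:
        rec.peak_value, rec.peak_mni_mm = locate_peak(rec, meta_map, sign="absolute")
    clusters.sort(key=lambda r: (-abs(r.peak_value), r.cluster_id))
    for i, rec in enumerate(clusters, start=1):
        rec.cluster_id = i
    if not clusters:
        logger.warning("pipeline 1: no surface clusters survive the size filter")
    return TargetReport(1, "none", clusters, {"min_cluster": min_cluster, "strict": strict})


def _surface_clusters_from_result(
    result: InferenceResult,
    surface: SurfaceMask,
    min_cluster: int,
    connectivity: int,
) -> list[ClusterRecord]:
    mask = result.surviving_mask().intersect(surface.mask)
    clusters = find_clusters(mask, min_cluster, connectivity, strict=False)
    for rec in clusters:
        rec.peak_value, rec.peak_mni_mm = locate_peak(rec, result.stat_map, sign=result.sign)
    return clusters


def pipeline2(
    result_pos: InferenceResult,
    result_neg: InferenceResult,
    surface: SurfaceMask,
    min_cluster: int = 20,
    k_min: int = 4,
    k_max: int = 6,
    connectivity: int = 26,
) -> tuple[TargetReport, TargetReport]:
    """Top surface clusters of the network-seed map, per correlation sign.

    Surviving clusters are intersected with the surface, re-labeled as
    components, size-filtered (clusters smaller than ``min_cluster`` voxels
    are excluded), and the top-k by |peak| are reported with
    k = min(k_max, #available); fewer than ``k_min`` triggers a warning.
    """
    reports = []
    params = {"min_cluster": min_cluster, "k_min": k_min, "k_max": k_max}
    for result in (result_pos, result_neg):
        clusters = _surface_clusters_from_result(result, surface, min_cluster, connectivity)
        clusters.sort(key=lambda r: (-abs(r.peak_value), r.cluster_id))
        clusters = clusters[:k_max]
        for i, rec in enumerate(clusters, start=1):
            rec.cluster_id = i
        if len(clusters) < k_min:
            logger.warning(
                "pipeline 2 (%s): only %d surface cluster(s) available (wanted >= %d)",
                result.sign, len(clusters), k_min,
            )
        reports.append(TargetReport(2, result.sign, clusters, dict(params)))
    return reports[0], reports[1]


def binarize_map(result: InferenceResult) -> BinaryMask:
    """Union of a result's surviving clusters as a 0/1 mask."""
    return result.surviving_mask()


def overlap_sum(masks: Sequence[BinaryMask]) -> OverlapMap:
    """Voxelwise integer sum of binary masks (order-invariant)."""
    if len(masks) == 0:
        raise ValueError("need at least one mask")
    grid = masks[0].grid
    total = np.zeros(grid.shape, dtype=int)
    for m in masks:
        grid.require_match(m.grid)
        total += m.data.astype(int)
    return OverlapMap(grid, total, len(masks))


def _levelset_clusters(
    counts: np.ndarray,
    grid: VolumeGrid,
    surface: SurfaceMask,
    min_cluster: int,
    k_max: int,
    connectivity: int,
) -> list[ClusterRecord]:
    """Descending level-set clustering of an integer count map.

    For each count level c from the maximum down to 1, components of
    {count >= c} inside the surface with >= min_cluster voxels are collected
    unless they contain a cluster already collected at a higher level; a
    reported cluster's intensity is the level at which it first reached the
    size cutoff, so every voxel in it carries at least that count.
    """
    collected: list[tuple[int, ClusterRecord]] = []
    taken = np.zeros(grid.shape, dtype=bool)
    cmax = int(counts.max(initial=0))
    for c in range(cmax, 0, -1):
        mask = BinaryMask(grid, (counts >= c) & surface.mask.data)
        for comp in find_clusters(mask, min_cluster, connectivity, strict=False):
            comp_mask = np.zeros(grid.shape, dtype=bool)
            comp_mask[tuple(comp.voxel_indices.T)] = True
            if np.any(comp_mask & taken):
                continue
            comp.peak_value = float(c)
            comp.peak_mni_mm = None  # level sets are flat; no meaningful peak
            taken |= comp_mask
            collected.append((c, comp))
            if len(collected) >= k_max:
                break
        if len(collected) >= k_max:
            break
    collected.sort(key=lambda cc: (-cc[0], -cc[1].size_voxels))
    clusters = [rec for _, rec in collected]
    for i, rec in enumerate(clusters, start=1):
        rec.cluster_id = i
    return clusters


def pipeline3(
    overlap_pos: OverlapMap,
    overlap_neg: OverlapMap,
    surface: SurfaceMask,
    min_cluster: int = 20,
    k_min: int = 4,
    k_max: int = 6,
    connectivity: int = 26,
    rule: str = "levelset",
    threshold_level: int = 1,
) -> tuple[TargetReport, TargetReport]:
    """Top surface clusters of the per-sign overlap maps.

    ``rule='levelset'`` (default) cuts clusters from descending level sets of
    the count map and ranks them by (count level, size); ``rule='threshold'``
    instead thresholds at ``threshold_level`` and ranks by size.  Reported
    intensities are count levels; peak coordinates are omitted because voxels
    within a level-set cluster share the same thresholded intensity.
    """
    if rule not in ("levelset", "threshold"):
        raise ValueError("rule must be 'levelset' or 'threshold'")
    reports = []
    params = {
        "min_cluster": min_cluster, "k_min": k_min, "k_max": k_max,
        "rule": rule, "threshold_level": threshold_level,
    }
    for overlap, sign in ((overlap_pos, "positive"), (overlap_neg, "negative")):
        overlap.grid.require_match(surface.mask.grid)
        if overlap.data.max(initial=0) == 0:
            logger.warning("pipeline 3 (%s): overlap map is all zero", sign)
            reports.append(TargetReport(3, sign, [], dict(params)))
            continue
        if rule == "levelset":
            clusters = _levelset_clusters(
                overlap.data, overlap.grid, surface, min_cluster, k_max, connectivity
            )
        else:
            mask = BinaryMask(overlap.grid, (overlap.data >= threshold_level) & surface.mask.data)
            clusters = find_clusters(mask, min_cluster, connectivity, strict=False)[:k_max]
            for rec in clusters:
                rec.peak_value = float(threshold_level)
                rec.peak_mni_mm = None
        if len(clusters) < k_min:
            logger.warning(
                "pipeline 3 (%s): only %d surface cluster(s) available (wanted >= %d)",
                sign, len(clusters), k_min,
            )
        reports.append(TargetReport(3, sign, clusters, dict(params)))
    return reports[0], reports[1]


def annotate_anatomy(report: TargetReport, parcellation: Parcellation) -> TargetReport:
    """Fill each cluster's anatomical label from the parcellation (in place)."""
    for rec in report.clusters:
        anchor = rec.peak_mni_mm or rec.centroid_mni_mm
        if anchor is not None:
            rec.anatomical_label = parcellation.region_at(np.asarray(anchor))
    return report
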