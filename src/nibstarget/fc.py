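"""Seed-to-voxel functional connectivity and the group-level one-sample test.

For each subject, the mean time course of a seed region is correlated with
every voxel (Pearson r), the correlations are variance-stabilized with the
Fisher transform z = atanh(r), and the subject z-maps enter a voxelwise
one-sample t-test (t = mean(z) / (sd(z)/sqrt(n)), df = n-1) with one-tailed
p-values in each direction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .core import BinaryMask, BoldSeries, StatMap, VolumeGrid
from .rois import RoiSet

__all__ = [
    "SubjectFcMap",
    "GroupMap",
    "roi_timeseries",
    "network_seed",
    "seed_to_voxel",
    "group_onesample",
    "fisher_z",
]

logger = logging.getLogger(__name__)

# keeps atanh finite at |r| = 1 while preserving ordering
R_CLIP = 1e-7


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing Fisher transform, z = atanh(r)."""
    return np.arctanh(r)


def roi_timeseries(bold: BoldSeries, roi: BinaryMask) -> np.ndarray:
    """Unweighted mean BOLD time course over the ROI voxels."""
    bold.grid.require_match(roi.grid)
    if roi.is_empty():
        raise ValueError("ROI is empty")
    return bold.data[roi.data].mean(axis=0)


def network_seed(rois: RoiSet) -> BinaryMask:
    """Union of all ROI masks: the disease network treated as one seed."""
    if len(rois) == 0:
        raise ValueError("need at least one ROI")
    data = np.zeros(rois.grid.shape, dtype=bool)
    for _, mask, _ in rois:
        data |= mask.data
    return BinaryMask(rois.grid, data)


@dataclass
class SubjectFcMap:
    """One subject's seed-to-voxel correlation map (r and Fisher z)."""

    grid: VolumeGrid
    r_values: np.ndarray
    z_values: np.ndarray
    seed_name: str
    subject_id: str
    constant_voxels: np.ndarray = field(repr=False, default=None)
    seed_mask: BinaryMask | None = None


def seed_to_voxel(
    bold: BoldSeries,
    seed_series: np.ndarray,
    seed_name: str = "seed",
    subject_id: str = "",
    seed_mask: BinaryMask | None = None,
) -> SubjectFcMap:
    """Pearson correlation of every voxel with a seed time course.

    Constant voxels get r = 0 and are flagged; |r| is clipped to 1 - 1e-7
    before the Fisher transform so z stays finite.
    """
    s = np.asarray(seed_series, dtype=float)
    if s.ndim != 1 or len(s) != bold.n_volumes:
        raise ValueError("seed series length must equal the number of volumes")
    if len(s) < 3:
        raise ValueError("need at least 3 time points")
    s_c = s - s.mean()
    s_norm = np.sqrt((s_c**2).sum())
    if s_norm == 0:
        raise ValueError("seed series is constant")
    Y = bold.data.reshape(-1, bold.n_volumes)
    Y_c = Y - Y.mean(axis=1, keepdims=True)
    y_norm = np.sqrt((Y_c**2).sum(axis=1))
    # numerically constant: variation at the rounding floor of the voxel scale
    constant = y_norm <= np.abs(Y).max(axis=1) * 1e-12
    denom = np.where(constant, 1.0, y_norm * s_norm)
    r = (Y_c @ s_c) / denom
    r[constant] = 0.0
    r = np.clip(r, -1.0, 1.0)
    z = np.arctanh(np.clip(r, -1.0 + R_CLIP, 1.0 - R_CLIP))
    shape = bold.grid.shape
    return SubjectFcMap(
        bold.grid,
        r.reshape(shape),
        z.reshape(shape),
        seed_name,
        subject_id,
        constant_voxels=constant.reshape(shape),
        seed_mask=seed_mask,
    )


@dataclass
class GroupMap:
    """Voxelwise one-sample t statistics over subject Fisher-z maps."""

    grid: VolumeGrid
    t: np.ndarray
    df: int
    mean_z: np.ndarray
    p_positive: np.ndarray
    p_negative: np.ndarray
    n_subjects: int
    valid: np.ndarray = field(repr=False, default=None)  # False where sd == 0
    seed_name: str = ""

    def save(self, out_dir: str | Path, prefix: str = "group") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        StatMap(self.grid, self.t).save(out / f"{prefix}_t.nii.gz")
        StatMap(self.grid, self.mean_z).save(out / f"{prefix}_meanz.nii.gz")
        meta = {"seed_name": self.seed_name, "n_subjects": self.n_subjects, "df": self.df}
        (out / f"{prefix}_meta.json").write_text(json.dumps(meta, indent=2))


def group_onesample(z_maps: Sequence[SubjectFcMap]) -> GroupMap:
    """Voxelwise one-sample t-test across subjects' Fisher-z maps.

    Voxels with zero across-subject variance are masked out (t undefined);
    their count is logged.  One-tailed p-values are computed per direction
    from the t distribution at df = n - 1.
    """
    if len(z_maps) < 2:
        raise ValueError("need at least 2 subjects")
    grid = z_maps[0].grid
    for m in z_maps[1:]:
        grid.require_match(m.grid)
    Z = np.stack([m.z_values.reshape(-1) for m in z_maps])  # (n, voxels)
    n = Z.shape[0]
    mean = Z.mean(axis=0)
    sd = Z.std(axis=0, ddof=1)
    valid = sd > 0
    if (~valid).sum():
        logger.info("masking %d voxel(s) with zero variance across subjects", int((~valid).sum()))
    t = np.zeros_like(mean)
    t[valid] = mean[valid] / (sd[valid] / np.sqrt(n))
    df = n - 1
    p_pos = np.ones_like(mean)
    p_neg = np.ones_like(mean)
    p_pos[valid] = stats.t.sf(t[valid], df)
    p_neg[valid] = stats.t.cdf(t[valid], df)
    shape = grid.shape
    return GroupMap(
        grid,
        t.reshape(shape),
        df,
        mean.reshape(shape),
        p_pos.reshape(shape),
        p_neg.reshape(shape),
        n,
        valid=valid.reshape(shape),
        seed_name=z_maps[0].seed_name,
    )
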