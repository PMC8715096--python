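"""Synthetic study inputs with planted ground truth.

The real study drew on two inputs this package cannot ship: a meta-analytic
uniformity map distilled from hundreds of fMRI experiments, and resting-state
scans from a patient cohort.  This module generates stand-ins for both on a
desk-scale grid, with known blob locations and known seed-to-target couplings,
so that every downstream stage can be tested against planted truth.

Signal model
------------
Each simulated network has one latent AR(1) time series s(t),

    s_t = phi * s_{t-1} + e_t,   e_t ~ N(0, 1 - phi^2),

normalized to unit stationary variance.  The latent enters every seed-region
voxel with weight 1 and every target-region voxel with weight equal to the
coupling c in [-1, 1]; independent N(0, noise_sd^2) noise is added everywhere.
Without spatial smoothing, the expected Pearson correlation between the
seed-region mean and the target-region mean over n_seed and n_target voxels is

    r = c / sqrt((1 + sigma^2 / n_seed) * (c^2 + sigma^2 / n_target))

with sigma = noise_sd (see :func:`expected_seed_target_correlation`); tests
hold the generator to this closed form.  Smoothing mixes neighboring voxels
and is not covered by the formula.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import BinaryMask, BoldSeries, MotionTrace, StatMap, VolumeGrid

__all__ = [
    "Blob",
    "NetworkSpec",
    "Parcellation",
    "simulate_meta_map",
    "simulate_group_bold",
    "simulate_motion",
    "make_toy_parcellation",
    "expected_seed_target_correlation",
]

logger = logging.getLogger(__name__)

FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548


@dataclass(frozen=True)
class Blob:
    """A Gaussian bump in a statistical map."""

    center_mm: tuple[float, float, float]
    peak_z: float
    fwhm_mm: float


@dataclass
class NetworkSpec:
    """One planted connectivity network: a seed region coupled to targets.

    targets is a sequence of (region, coupling) with |coupling| <= 1; all
    regions (seed and targets) must be pairwise disjoint.
    """

    seed_region: BinaryMask
    targets: Sequence[tuple[BinaryMask, float]]
    ar_coefficient: float = 0.4
    noise_sd: float = 1.0
    smooth_fwhm_mm: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.smooth_fwhm_mm < 0:
            raise ValueError("smooth_fwhm_mm must be nonnegative")
        regions = [self.seed_region] + [r for r, _ in self.targets]
        for i in range(len(regions)):
            for j in range(i + 1, len(regions)):
                if not regions[i].disjoint(regions[j]):
                    raise ValueError(f"regions {i} and {j} of a NetworkSpec overlap")
        for _, c in self.targets:
            if abs(c) > 1:
                raise ValueError(f"|coupling| must be <= 1, got {c}")


def expected_seed_target_correlation(
    coupling: float, noise_sd: float, n_seed: int, n_target: int
) -> float:
    """Closed-form expected seed-mean to target-mean Pearson correlation.

    Valid for the unsmoothed generator: the seed mean is s + noise of variance
    sigma^2/n_seed and the target mean is c*s + noise of variance
    sigma^2/n_target, with s the unit-variance latent.
    """
    s2 = noise_sd**2
    return coupling / np.sqrt((1.0 + s2 / n_seed) * (coupling**2 + s2 / n_target))


def simulate_meta_map(
    grid: VolumeGrid,
    blobs: Sequence[Blob | tuple],
    floor_z: float = 3.0,
    seed: int | None = None,
) -> StatMap:
    """Blob-cluster statistical map emulating a thresholded meta-analytic map.

    The map is zero except inside Gaussian blobs truncated at ``floor_z``;
    overlapping blobs combine by voxelwise maximum so each stated peak value
    is attained exactly at the voxel nearest its center.  The map is a
    deterministic function of the blob list; ``seed`` is accepted for
    interface symmetry with the other generators and unused.
    """
    blobs = [b if isinstance(b, Blob) else Blob(*b) for b in blobs]
    for b in blobs:
        if b.peak_z <= floor_z:
            raise ValueError(f"peak_z ({b.peak_z}) must exceed floor_z ({floor_z})")
        if floor_z <= 0:
            raise ValueError("floor_z must be positive")
        if not grid.contains_mm(b.center_mm):
            raise ValueError(f"blob center {b.center_mm} lies outside the grid")
    data = np.zeros(grid.shape)
    if blobs:
        centers = grid.voxel_centers_mm()
        for b in blobs:
            sd = b.fwhm_mm / FWHM_TO_SD
            d2 = np.sum((centers - np.asarray(b.center_mm)) ** 2, axis=1)
            vals = b.peak_z * np.exp(-d2 / (2.0 * sd**2))
            # snap the peak onto the voxel nearest the center so the stated
            # maximum is attained exactly
            vals[np.argmin(d2)] = b.peak_z
            data = np.maximum(data, vals.reshape(grid.shape))
    data[data < floor_z] = 0.0
    return StatMap(grid, data)


def _ar1_series(n: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance AR(1) series with stationary initialization."""
    if phi == 0:
        return rng.standard_normal(n)
    innov_sd = np.sqrt(1.0 - phi**2)
    s = np.empty(n)
    s[0] = rng.standard_normal()
    eps = rng.standard_normal(n - 1) * innov_sd
    for t in range(1, n):
        s[t] = phi * s[t - 1] + eps[t - 1]
    return s


def simulate_group_bold(
    grid: VolumeGrid,
    n_subjects: int,
    n_volumes: int,
    tr_s: float,
    spec: NetworkSpec | Sequence[NetworkSpec],
    seed: int,
    motion_baseline_mm: float | Sequence[float] = 0.05,
    motion_spikes: dict[int, tuple[Sequence[int], float]] | None = None,
) -> list[tuple[BoldSeries, MotionTrace]]:
    """Per-subject 4-D BOLD with planted couplings, plus motion traces.

    ``spec`` may be a single :class:`NetworkSpec` or several; multiple
    networks carry independent latents and their contributions add.  Motion
    traces are random walks with per-subject step size ``motion_baseline_mm``
    (scalar or one value per subject); ``motion_spikes`` maps a subject index
    to (spike volume indices, spike magnitude in mm) to plant high-motion
    subjects.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if n_volumes <= 20:
        raise ValueError("n_volumes must be > 20")
    specs = [spec] if isinstance(spec, NetworkSpec) else list(spec)
    for sp in specs:
        grid.require_match(sp.seed_region.grid)
    baselines = (
        [float(motion_baseline_mm)] * n_subjects
        if np.isscalar(motion_baseline_mm)
        else [float(b) for b in motion_baseline_mm]
    )
    if len(baselines) != n_subjects:
        raise ValueError("motion_baseline_mm must be scalar or one value per subject")
    motion_spikes = motion_spikes or {}

    root = np.random.SeedSequence(seed)
    subject_seeds = root.spawn(n_subjects)
    out: list[tuple[BoldSeries, MotionTrace]] = []
    for subj in range(n_subjects):
        rng = np.random.default_rng(subject_seeds[subj])
        data = None
        for sp in specs:
            s = _ar1_series(n_volumes, sp.ar_coefficient, rng)
            signal = np.zeros((*grid.shape, n_volumes))
            signal[sp.seed_region.data] += s
            for region, coupling in sp.targets:
                signal[region.data] += coupling * s
            data = signal if data is None else data + signal
        if data is None:
            data = np.zeros((*grid.shape, n_volumes))
        noise_sd = specs[0].noise_sd if specs else 1.0
        data = data + noise_sd * rng.standard_normal(data.shape)
        fwhm = specs[0].smooth_fwhm_mm if specs else 0.0
        if fwhm > 0:
            from .preprocess import smooth_gaussian  # local import avoids a cycle

            data = smooth_gaussian(BoldSeries(grid, data, tr_s), fwhm).data
        spikes, spike_mm = motion_spikes.get(subj, ((), 0.0))
        trace = simulate_motion(
            n_volumes,
            baselines[subj],
            spike_volumes=spikes,
            spike_mm=spike_mm,
            seed=int(rng.integers(2**31)),
        )
        out.append((BoldSeries(grid, data, tr_s), trace))
    return out


def simulate_motion(
    n_volumes: int,
    baseline_mm: float,
    spike_volumes: Sequence[int] = (),
    spike_mm: float = 0.0,
    seed: int = 0,
) -> MotionTrace:
    """Random-walk head-motion trace with optional planted spikes.

    Translations take Gaussian steps of sd ``baseline_mm``; rotations take
    steps of sd ``baseline_mm``/50 rad so their displacement on the 50 mm QC
    sphere is commensurate.  A spike adds ``spike_mm`` to the x-translation of
    the listed volumes only (a transient jerk).
    """
    if baseline_mm < 0 or spike_mm < 0:
        raise ValueError("motion magnitudes must be nonnegative")
    for v in spike_volumes:
        if not 0 <= v < n_volumes:
            raise ValueError(f"spike volume {v} out of range [0, {n_volumes})")
    rng = np.random.default_rng(seed)
    steps = np.zeros((n_volumes, 6))
    if baseline_mm > 0:
        steps[1:, :3] = rng.standard_normal((n_volumes - 1, 3)) * baseline_mm
        steps[1:, 3:] = rng.standard_normal((n_volumes - 1, 3)) * (baseline_mm / 50.0)
    params = np.cumsum(steps, axis=0)
    for v in spike_volumes:
        params[v, 0] += spike_mm
    return MotionTrace(params)


@dataclass
class Parcellation:
    """Integer label image with a (label_id, name, is_surface) lookup table."""

    grid: VolumeGrid
    labels: np.ndarray
    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.shape != self.grid.shape:
            raise ValueError("label image shape inconsistent with grid")
        required = {"label_id", "name", "is_surface"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"lookup table must have columns {sorted(required)}")

    def region_mask(self, name: str) -> BinaryMask:
        row = self.table[self.table["name"] == name]
        if row.empty:
            raise KeyError(f"unknown region name: {name!r}")
        return BinaryMask(self.grid, self.labels == int(row["label_id"].iloc[0]))

    @property
    def surface_names(self) -> list[str]:
        return list(self.table.loc[self.table["is_surface"].astype(bool), "name"])

    def region_at(self, mm: np.ndarray) -> str | None:
        """Region name at an MNI-mm point, or None outside all regions."""
        try:
            idx = self.grid.mm_to_index(mm)
        except ValueError:
            return None
        label = int(self.labels[idx])
        if label == 0:
            return None
        row = self.table[self.table["label_id"] == label]
        return str(row["name"].iloc[0]) if not row.empty else None

    def save(self, label_path: str | Path, table_path: str | Path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), self.grid.affine), str(label_path))
        self.table.to_csv(table_path, sep="\t", index=False)

    @classmethod
    def load(cls, label_path: str | Path, table_path: str | Path) -> "Parcellation":
        import nibabel as nib

        img = nib.load(str(label_path))
        grid = VolumeGrid(tuple(img.shape[:3]), np.asarray(img.affine))
        table = pd.read_csv(table_path, sep="\t")
        table["is_surface"] = table["is_surface"].astype(bool)
        return cls(grid, np.asarray(img.dataobj).astype(np.int32), table)


def make_toy_parcellation(
    grid: VolumeGrid,
    regions: Sequence[tuple[str, BinaryMask]],
    surface_names: Sequence[str],
) -> Parcellation:
    """Build a label image from named, disjoint region masks.

    ``surface_names`` marks which regions enter the brain-surface mask used
    for target selection (they stand in for the cortical regions a
    stimulation coil can reach).
    """
    names = [n for n, _ in regions]
    if len(set(names)) != len(names):
        raise ValueError("region names must be unique")
    unknown = set(surface_names) - set(names)
    if unknown:
        raise ValueError(f"surface_names not among regions: {sorted(unknown)}")
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            if not regions[i][1].disjoint(regions[j][1]):
                raise ValueError(
                    f"regions {regions[i][0]!r} and {regions[j][0]!r} overlap"
                )
    labels = np.zeros(grid.shape, dtype=np.int32)
    rows = []
    for k, (name, mask) in enumerate(regions, start=1):
        grid.require_match(mask.grid)
        labels[mask.data] = k
        rows.append({"label_id": k, "name": name, "is_surface": name in set(surface_names)})
    return Parcellation(grid, labels, pd.DataFrame(rows))
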