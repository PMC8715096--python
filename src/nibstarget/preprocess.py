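"""Denoising and motion quality control applied to template-space BOLD.

The chain mirrors a standard resting-state toolbox pipeline: drop the first
volumes, exclude high-motion subjects, flag outlier volumes for scrubbing,
regress nuisance signals (motion + derivatives, tissue principal components,
outlier indicators, linear trend), then band-pass filter.  Spatial smoothing
is available for the connectivity inputs and can run before or after the
regression step.

Motion arithmetic convention: a volume's position is the 6-parameter vector
(tx, ty, tz, 50*rx, 50*ry, 50*rz) — rotations in radians converted to mm of
displacement on a 50 mm sphere.  "Mean relative RMS" is the mean over volumes
of the Euclidean frame-to-frame displacement of that vector; "maximum head
motion" is the largest displacement from the first (reference) volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import BinaryMask, BoldSeries, MotionTrace, StatMap, VolumeGrid

__all__ = [
    "MotionQC",
    "drop_initial_volumes",
    "motion_qc",
    "detect_outlier_volumes",
    "compcor_components",
    "build_confounds",
    "regress_confounds",
    "bandpass",
    "smooth_gaussian",
    "preprocess_subject",
    "PreprocessConfig",
    "PreprocessedSubject",
]

logger = logging.getLogger(__name__)

ROTATION_RADIUS_MM = 50.0
FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _displacement_vectors(trace: MotionTrace) -> np.ndarray:
    """6-parameter positions with rotations scaled to mm on the 50 mm sphere."""
    p = trace.params.copy()
    p[:, 3:] *= ROTATION_RADIUS_MM
    return p


def framewise_displacement(trace: MotionTrace) -> np.ndarray:
    """Euclidean frame-to-frame displacement per volume (first volume: 0)."""
    p = _displacement_vectors(trace)
    fd = np.zeros(trace.n_volumes)
    fd[1:] = np.linalg.norm(np.diff(p, axis=0), axis=1)
    return fd


def drop_initial_volumes(
    bold: BoldSeries, trace: MotionTrace, k: int = 5
) -> tuple[BoldSeries, MotionTrace]:
    """Remove the first ``k`` volumes from a BOLD series and its motion trace."""
    if bold.n_volumes != trace.n_volumes:
        raise ValueError("BOLD and motion trace volume counts differ")
    if k >= bold.n_volumes:
        raise ValueError(f"cannot drop {k} of {bold.n_volumes} volumes")
    if k == 0:
        return bold, trace
    return (
        BoldSeries(bold.grid, bold.data[..., k:], bold.tr_s),
        MotionTrace(trace.params[k:]),
    )


@dataclass(frozen=True)
class MotionQC:
    passed: bool
    mean_rms_mm: float
    max_displacement_mm: float
    n_volumes: int


def motion_qc(
    trace: MotionTrace, mean_rms_mm: float = 0.2, max_mm: float = 3.0
) -> MotionQC:
    """Subject-level motion screen.

    Fails if the mean relative RMS (mean frame-to-frame displacement) exceeds
    ``mean_rms_mm`` or the maximum displacement from the first volume exceeds
    ``max_mm``.
    """
    if trace.n_volumes < 2:
        raise ValueError("motion QC needs at least 2 volumes")
    fd = framewise_displacement(trace)
    mean_rms = float(np.mean(fd[1:]))
    p = _displacement_vectors(trace)
    max_disp = float(np.max(np.linalg.norm(p - p[0], axis=1)))
    passed = mean_rms <= mean_rms_mm and max_disp <= max_mm
    return MotionQC(passed, mean_rms, max_disp, trace.n_volumes)


def detect_outlier_volumes(
    bold: BoldSeries,
    trace: MotionTrace,
    global_sd: float = 3.0,
    fd_mm: float = 0.5,
    logic: str = "or",
) -> list[int]:
    """Volumes flagged for scrubbing.

    A volume is an outlier when its global mean signal deviates more than
    ``global_sd`` standard deviations from the series mean, or its framewise
    displacement exceeds ``fd_mm``.  ``logic`` switches between the
    either-criterion ("or", the artifact-detection tool convention) and the
    strict conjunction ("and").
    """
    if bold.n_volumes != trace.n_volumes:
        raise ValueError("BOLD and motion trace volume counts differ")
    if logic not in ("or", "and"):
        raise ValueError("logic must be 'or' or 'and'")
    g = bold.data.reshape(-1, bold.n_volumes).mean(axis=0)
    sd = g.std(ddof=1)
    z = np.zeros_like(g) if sd == 0 else (g - g.mean()) / sd
    intensity_out = np.abs(z) > global_sd
    motion_out = framewise_displacement(trace) > fd_mm
    flagged = (intensity_out | motion_out) if logic == "or" else (intensity_out & motion_out)
    return sorted(int(i) for i in np.flatnonzero(flagged))


def compcor_components(
    bold: BoldSeries, tissue_mask: BinaryMask, n_components: int
) -> np.ndarray:
    """Top principal-component time series of a tissue mask (aCompCor).

    The masked voxel x time matrix is demeaned and variance-normalized per
    voxel; components are the leading right singular vectors, ordered by
    explained variance and unit-normalized, with a deterministic sign
    convention (largest-magnitude element positive).  Returns (n_components,
    n_volumes).
    """
    bold.grid.require_match(tissue_mask.grid)
    if tissue_mask.is_empty():
        raise ValueError("tissue mask is empty")
    X = bold.data[tissue_mask.data]  # (n_voxels, n_volumes)
    limit = min(X.shape[0], bold.n_volumes - 1)
    if n_components > limit:
        raise ValueError(f"n_components={n_components} exceeds limit {limit}")
    X = X - X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1)
    keep = sd > 0
    X = X[keep] / sd[keep, None]
    if X.shape[0] == 0:
        raise ValueError("all mask voxels are constant")
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    comps = vt[:n_components]
    for row in comps:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1
    norms = np.linalg.norm(comps, axis=1, keepdims=True)
    return comps / norms


def build_confounds(
    trace: MotionTrace,
    wm_components: np.ndarray | None = None,
    csf_components: np.ndarray | None = None,
    outlier_volumes: Sequence[int] = (),
) -> pd.DataFrame:
    """Assemble the nuisance design: 6 motion parameters, their first-order
    temporal derivatives, tissue components, one indicator per outlier volume,
    and a linear trend."""
    n = trace.n_volumes
    cols: dict[str, np.ndarray] = {}
    names = ["tx", "ty", "tz", "rx", "ry", "rz"]
    for i, nm in enumerate(names):
        cols[f"motion_{nm}"] = trace.params[:, i]
    deriv = np.vstack([np.zeros((1, 6)), np.diff(trace.params, axis=0)])
    for i, nm in enumerate(names):
        cols[f"motion_d{nm}"] = deriv[:, i]
    for label, comps in (("wm", wm_components), ("csf", csf_components)):
        if comps is not None:
            comps = np.atleast_2d(comps)
            if comps.shape[1] != n:
                raise ValueError(f"{label} component length != n_volumes")
            for i, row in enumerate(comps):
                cols[f"{label}_comp{i + 1}"] = row
    for v in sorted(set(int(v) for v in outlier_volumes)):
        if not 0 <= v < n:
            raise ValueError(f"outlier volume {v} out of range")
        ind = np.zeros(n)
        ind[v] = 1.0
        cols[f"outlier_{v}"] = ind
    cols["linear_trend"] = np.linspace(-1.0, 1.0, n)
    return pd.DataFrame(cols)


def regress_confounds(
    bold: BoldSeries, confounds: pd.DataFrame | np.ndarray | None
) -> BoldSeries:
    """Per-voxel OLS residuals against the confound columns plus an intercept.

    Rank-deficient designs are repaired by dropping linearly dependent columns
    (logged).  With an empty confound set the demeaned input is returned.
    """
    n = bold.n_volumes
    if confounds is None or (hasattr(confounds, "shape") and confounds.shape[-1] == 0) or (
        isinstance(confounds, pd.DataFrame) and confounds.shape[1] == 0
    ):
        X = np.ones((n, 1))
        names: list[str] = []
        C = np.empty((n, 0))
    else:
        if isinstance(confounds, pd.DataFrame):
            names = list(confounds.columns)
            C = confounds.to_numpy(dtype=float)
        else:
            C = np.asarray(confounds, dtype=float)
            if C.ndim == 1:
                C = C[:, None]
            names = [f"c{i}" for i in range(C.shape[1])]
        if C.shape[0] != n:
            raise ValueError("confound rows != BOLD volumes")
        # greedy rank repair: keep columns that increase design rank
        keep: list[int] = []
        base = np.ones((n, 1))
        for j in range(C.shape[1]):
            cand = np.hstack([base] + [C[:, [k]] for k in keep] + [C[:, [j]]])
            if np.linalg.matrix_rank(cand) > 1 + len(keep):
                keep.append(j)
        if len(keep) < C.shape[1]:
            dropped = [names[j] for j in range(C.shape[1]) if j not in keep]
            logger.warning("dropping %d dependent confound column(s): %s", len(dropped), dropped)
        C = C[:, keep]
        X = np.hstack([np.ones((n, 1)), C])
    Y = bold.data.reshape(-1, n).T  # (time, voxels)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = (Y - X @ beta).T.reshape(bold.data.shape)
    return BoldSeries(bold.grid, resid, bold.tr_s)


def bandpass(bold: BoldSeries, low_hz: float = 0.01, high_hz: float = 0.1) -> BoldSeries:
    """Ideal (boxcar) frequency-domain band-pass filter after demeaning.

    Frequencies f with ``low_hz <= f <= high_hz`` pass; everything else,
    including the DC component, is zeroed.
    """
    nyquist = 1.0 / (2.0 * bold.tr_s)
    if not (0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) must satisfy 0 < low < high < Nyquist ({nyquist:.4g})"
        )
    n = bold.n_volumes
    Y = bold.data.reshape(-1, n)
    F = np.fft.rfft(Y - Y.mean(axis=1, keepdims=True), axis=1)
    freqs = np.fft.rfftfreq(n, d=bold.tr_s)
    F[:, ~((freqs >= low_hz) & (freqs <= high_hz))] = 0.0
    out = np.fft.irfft(F, n=n, axis=1).reshape(bold.data.shape)
    return BoldSeries(bold.grid, out, bold.tr_s)


def smooth_gaussian(obj, fwhm_mm: float = 6.0):
    """Separable Gaussian smoothing with per-axis sd = fwhm / 2.3548 in mm.

    Accepts a StatMap, BinaryMask (returns a StatMap of smoothed membership),
    or BoldSeries (smoothed volume by volume); fwhm 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be nonnegative")
    if fwhm_mm == 0:
        return obj
    grid: VolumeGrid = obj.grid
    sigma_vox = (fwhm_mm / FWHM_TO_SD) / grid.voxel_size_mm
    if isinstance(obj, BoldSeries):
        out = ndimage.gaussian_filter(
            obj.data, sigma=(*sigma_vox, 0.0), mode="constant", cval=0.0
        )
        return BoldSeries(grid, out, obj.tr_s)
    data = obj.data.astype(float)
    out = ndimage.gaussian_filter(data, sigma=tuple(sigma_vox), mode="constant", cval=0.0)
    return StatMap(grid, out)


@dataclass(frozen=True)
class PreprocessConfig:
    drop_volumes: int = 5
    mean_rms_mm: float = 0.2
    max_motion_mm: float = 3.0
    outlier_global_sd: float = 3.0
    outlier_fd_mm: float = 0.5
    outlier_logic: str = "or"
    n_wm_components: int = 10
    n_csf_components: int = 5
    low_hz: float = 0.01
    high_hz: float = 0.1
    smooth_fwhm_mm: float = 6.0
    smooth_order: str = "before"  # before | after confound regression | off


@dataclass
class PreprocessedSubject:
    subject_id: str
    qc: MotionQC
    outlier_volumes: list[int]
    bold: BoldSeries | None  # None when QC fails
    n_confounds: int = 0


def preprocess_subject(
    subject_id: str,
    bold: BoldSeries,
    trace: MotionTrace,
    wm_mask: BinaryMask | None = None,
    csf_mask: BinaryMask | None = None,
    config: PreprocessConfig = PreprocessConfig(),
) -> PreprocessedSubject:
    """Full single-subject chain: drop -> QC -> outliers -> regression -> band-pass.

    Smoothing runs before or after confound regression per
    ``config.smooth_order``.  Returns ``bold=None`` when the subject fails
    motion QC.
    """
    bold, trace = drop_initial_volumes(bold, trace, config.drop_volumes)
    qc = motion_qc(trace, config.mean_rms_mm, config.max_motion_mm)
    if not qc.passed:
        logger.info("subject %s excluded by motion QC (mean RMS %.3f mm, max %.2f mm)",
                    subject_id, qc.mean_rms_mm, qc.max_displacement_mm)
        return PreprocessedSubject(subject_id, qc, [], None)
    outliers = detect_outlier_volumes(
        bold, trace, config.outlier_global_sd, config.outlier_fd_mm, config.outlier_logic
    )
    if config.smooth_order == "before" and config.smooth_fwhm_mm > 0:
        bold = smooth_gaussian(bold, config.smooth_fwhm_mm)
    wm = (
        compcor_components(bold, wm_mask, config.n_wm_components)
        if wm_mask is not None and config.n_wm_components > 0
        else None
    )
    csf = (
        compcor_components(bold, csf_mask, config.n_csf_components)
        if csf_mask is not None and config.n_csf_components > 0
        else None
    )
    confounds = build_confounds(trace, wm, csf, outliers)
    bold = regress_confounds(bold, confounds)
    bold = bandpass(bold, config.low_hz, config.high_hz)
    if config.smooth_order == "after" and config.smooth_fwhm_mm > 0:
        bold = smooth_gaussian(bold, config.smooth_fwhm_mm)
    logger.info("subject %s preprocessed: %d volumes, %d outliers, %d confounds",
                subject_id, bold.n_volumes, len(outliers), confounds.shape[1])
    return PreprocessedSubject(subject_id, qc, outliers, bold, confounds.shape[1])
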