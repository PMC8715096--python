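# Methods

This note documents the models, conventions and numerical choices behind
`nibstarget`, and what the synthetic validation does and does not establish.

## Spatial frame

All volumes share a `VolumeGrid`: a shape plus a 4×4 voxel→MNI-mm affine.
The default working grid is 20×24×20 voxels at isotropic 3 mm, centered on
the MNI origin — the same working resolution as a normalized clinical
resting-state analysis at roughly 1/50 of the voxel count, which keeps every
simulation and permutation test desk-scale.  Grids are compared by shape and
affine before any voxelwise arithmetic; NIfTI-1 I/O goes through nibabel.

## Synthetic data model

The generator replaces two inputs that cannot be shipped: a meta-analytic
map distilled from published studies, and patient scans.

**Meta-analytic map.** A sum-free composition of Gaussian blobs: each blob
contributes `peak_z * exp(-d² / 2σ²)` with σ = FWHM/2.3548, blobs combine by
voxelwise maximum (so stated peaks are attained exactly), and values below a
floor (default z = 3) are zeroed — emulating an already-thresholded map.
The map is a deterministic function of the blob list.

**Group BOLD.** Each planted network has one latent AR(1) series
`s_t = φ s_{t−1} + e_t` with unit stationary variance (default φ = 0.4 —
the simplest process with realistic temporal autocorrelation and a closed-form
variance).  The latent enters seed-region voxels with weight 1 and each
target region with weight equal to its coupling c ∈ [−1, 1]; several networks
carry independent latents and add.  Independent N(0, σ²) noise (default
σ = 1) is added everywhere.  Without spatial smoothing the expected
correlation between the seed mean and target mean over n_s and n_t voxels is

    r = c / sqrt( (1 + σ²/n_s) · (c² + σ²/n_t) ),

the closed form the tests hold the generator to.  Smoothing mixes neighboring
voxels and is applied (when requested) after signal injection, so the formula
then holds only approximately.

**Head motion.** Translations follow a Gaussian random walk with step sd
`baseline_mm` (default 0.05 mm); rotations follow a walk with step sd
`baseline_mm`/50 rad so their displacement on a 50 mm sphere is commensurate.
Spikes add a transient offset to the x-translation of chosen volumes.  The
50 mm-sphere convention for converting rotations to millimetres is stated
explicitly because motion-QC literature rarely writes the formula down.

**What the generator does not model:** hemodynamic response shape,
physiological noise spectra, scanner drift beyond a linear trend, multi-site
effects, or anatomically realistic geometry.  Passing the recovery tests
therefore demonstrates that the pipeline's arithmetic and inference are
correct and calibrated on data satisfying its own assumptions — not that the
procedure is robust to every property of real BOLD data.

## Preprocessing conventions

Fixed stage order: drop initial volumes (default 5) → motion QC → outlier
detection → confound regression → band-pass.  Smoothing (default 6 mm FWHM)
runs before the regression by default, mirroring the toolbox chain the
pipeline emulates; `smooth_order: after` is available because the
conventional order is not universal.

- *Motion QC.* A volume's position is (tx, ty, tz, 50·rx, 50·ry, 50·rz) mm.
  "Mean relative RMS" = mean frame-to-frame Euclidean displacement of that
  vector; "maximum head motion" = largest displacement from the first
  volume.  Fail at mean RMS > 0.2 mm or maximum > 3 mm.  QC is a pure
  function of the trace.
- *Outlier volumes.* Either |global-signal z| > 3 or framewise displacement
  > 0.5 mm (the artifact-detection-tool convention); `outlier_logic: and`
  switches to the strict conjunction.  Note the >3 SD rule flags ~0.27% of
  volumes under the null by construction, so long null series are expected
  to contain occasional flags.
- *aCompCor.* Masked voxel×time matrix is demeaned and variance-normalized
  per voxel; components are the leading right singular vectors (unit norm,
  deterministic sign), 10 for WM and 5 for CSF by default.
- *Confound regression.* Per-voxel OLS against motion (6) + first-order
  derivatives (6) + tissue components + one indicator per outlier volume +
  linear trend + intercept.  Linearly dependent columns are dropped greedily
  with a warning.
- *Band-pass.* Ideal (boxcar) FFT filter on demeaned series, passband
  0.01–0.1 Hz inclusive, DC removed.  Chosen over an IIR design because the
  sharp band is exactly testable and matches the emulated toolbox
  convention.

## ROI extraction

Connected components (configurable 6/18/26-connectivity, default 26 — the
common viewer convention) of the thresholded map's support; components must
be strictly larger than 50 voxels (the wording "larger than" is implemented
strictly; the surface pipelines use ≥ 20, i.e. "smaller than 20 excluded").
Cluster peaks take the arg-max (signed or absolute per the caller), ties
broken at the smallest linear voxel index.  Spheres are inclusive
(distance ≤ radius): a 6 mm sphere on a 3 mm grid centered on a voxel center
contains exactly 33 voxels.  Refinement intersects each sphere with the map
support; empty intersections are dropped with a warning.

## Group statistics and inference

Subject maps: Pearson r of each voxel against the seed mean, z = atanh(r),
with |r| clipped to 1−1e−7 so z stays finite while ordering is preserved;
numerically constant voxels get r = 0 and a flag.  Seed voxels are retained
(flagged) — deep seeds are removed later by the surface mask anyway.  Group:
one-sample t = mean(z)/(sd(z)/√n), df = n−1, sd with the n−1 denominator;
voxels with zero across-subject variance are masked out.  No covariates.

Cluster-extent FWE is nonparametric: under the one-sample null, subject
z-maps are sign-symmetric, so random whole-subject sign flips generate the
null of the maximum supra-threshold cluster size.  `fwe_p = (1 + #{null max
≥ observed size}) / (n_perm + 1)`; the +1 is the always-included identity
permutation, so fwe_p ≥ 1/(n_perm+1) and can never be zero.  The stream is
counter-based (numpy Philox) and sign matrices are drawn as one block, so
enlarging n_perm with the same seed extends rather than reshuffles the null.
This permutation scheme is a deliberate substitution for parametric
random-field cluster p-values: it is self-contained, exactly testable, and
calibrated (empirical FWER ≈ 0.04 at nominal 0.05 on 200 null groups); every
run manifest records the deviation.  Numerical shortcut: sign flips leave
Σz² per voxel invariant, so each permutation's t map needs only the flipped
mean — the per-permutation cost is one matrix-vector product plus one
labeling pass.

## Target selection

All pipelines report only voxels inside the surface mask (union of
parcellation labels flagged `is_surface`).

- *Pipeline 1*: clusters of the meta-map support ∩ surface, ranked by peak
  value; the size rule defaults to the meta-analysis's own (> 50).
- *Pipeline 2*: surviving network-seed clusters ∩ surface, re-labeled,
  ≥ 20 voxels, top k = min(6, available) by |peak t| per sign; fewer than 4
  warns.  "Four to six" is read as: report up to 6, warn below 4, because no
  criterion for choosing within that range is stated anywhere.
- *Pipeline 3*: per-ROI surviving maps are binarized and summed into an
  overlap map (value = number of ROIs connected to the voxel).  Clusters are
  cut from descending level sets {count ≥ c}: a component is reported at the
  highest c where it reaches 20 voxels (components containing an
  already-reported cluster are skipped), ranked by (c, size).  The level-set
  rule is this package's own definition — an integer count map has no
  canonical clustering — chosen because it reproduces the flat-intensity
  property: every reported cluster's voxels all carry at least its level, so
  the report prints the level as intensity and no peak coordinate.
  `p3_rule: threshold` substitutes a single fixed threshold.

Selection is deterministic given inputs: ordering is by the ranking statistic
with ties at the smallest linear voxel index.

## 10-20 montage mapping

A peak is projected radially from a head-center reference (0, −18, 12) mm
onto the axis-aligned scalp ellipsoid least-squares-fitted (center fixed) to
the electrode positions, then phrased relative to the nearest electrodes by
straight-line distance on that surface: two nearly equidistant anchors
(second/nearest ≤ 1.25) render "Midpoint to A-B"; within 8 mm of the anchor
renders the bare label; otherwise the dominant y/z offset renders
Anterior/Posterior/Superior/Inferior to the anchor.

The bundled electrode table is a **synthetic**, left-right symmetric
idealized 10-20 layout in the lineage of published standard-position tables.
Its midline and frontal placements, together with the fixed head center,
were calibrated once against the labeling regression suite (four parietal
coordinates anchoring to P3/P4 and a frontal-midline coordinate rendering
"Midpoint to Fz-Cz") and then frozen; the relational thresholds stayed at
their defaults.  Scalp labels are only as meaningful as the electrode table:
it is swappable data, and every labeling records the table's checksum so
disagreements can be traced to provenance.  The exact-symmetry property
(reflecting a peak through x = 0 swaps odd/even anchors) holds by
construction.  The relational grammar itself is a reconstruction — published
tables pair coordinates with phrases without stating distance rules — and is
flagged as such in output metadata.

## Orchestration

A run directory holds config (YAML), inputs, outputs and a manifest.  Stages
(extract-rois → preprocess → fc → infer → targets → annotate) are separately
re-runnable CLI verbs; the manifest records a SHA-256 checksum for every
stage input and output, `--resume` skips stages whose records still match,
and reruns with one seed are byte-identical in their TSV reports.  Stage RNG
seeds derive from the config seed through `numpy.random.SeedSequence`, so
stage order cannot perturb downstream draws.  The manifest's deviations list
always names the permutation-FWE substitution.

## Demo fixture and problem sizes

The demo study: default grid; toy parcellation with five surface slabs, three
deep nuclei, WM and CSF boxes; meta map with blobs over the nuclei (peaks
12/11/10, FWHM 12 mm) plus two surface blobs (9/8.5); 13 subjects × 155
volumes at TR 2 s (12 analyzed after one planted high-motion exclusion);
couplings ±0.6, noise sd 1; 200 permutations.  Validation sizes: FWER
calibration uses 200 replicates of 12-subject null groups on 16³ voxels with
200 permutations; recovery uses 20 replicate 12-subject studies.  These
sizes give stable empirical rates (binomial se ≈ 0.015 at rate 0.05) while a
full test run stays in the minutes range on one CPU.

## Known limitations

- Anatomical labels come from whatever parcellation is supplied; no real
  atlas is bundled, and no claim of correspondence to a named atlas is made.
- The scalp model is an ellipsoid, not a head mesh; electrode positions are
  idealized rather than digitized; labels are qualitative guidance, not
  neuronavigation.
- Permutation inference with very few subjects (< 8) has a coarse null
  (2ⁿ sign patterns) and is warned against, not forbidden.
- Confound regression and band-pass are sequential, not simultaneous; with
  scrubbing indicators this can reintroduce small artifact energy compared
  with a joint fit.
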