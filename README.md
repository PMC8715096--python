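# nibstarget

Connectivity-based localization of non-invasive brain-stimulation (NIBS)
targets from resting-state fMRI.

## The problem

Repetitive TMS and tDCS protocols for psychiatric disorders are usually aimed
at scalp sites chosen by convention (for example "F3" for the left dlPFC),
even though the cortical regions most consistently implicated in a disorder —
and the surface regions most strongly connected to them — may lie elsewhere.
`nibstarget` implements a targeting strategy that chains together:

1. **Meta-analytic seeding.** A thresholded meta-analytic z-map is broken
   into clusters (>50 voxels), each cluster peak becomes a 6-mm-radius
   spherical region of interest (ROI), and every sphere is trimmed back to
   the map's own support.
2. **Seed-to-voxel functional connectivity.** For each subject, BOLD data are
   denoised (motion QC at mean relative RMS ≤ 0.2 mm and maximum displacement
   ≤ 3 mm; scrubbing of volumes with >3 SD global-signal deviation or >0.5 mm
   framewise displacement; regression of 6 motion parameters + derivatives,
   10 white-matter and 5 CSF aCompCor components, outlier indicators and a
   linear trend; 0.01–0.1 Hz band-pass; 6 mm FWHM smoothing).  The mean ROI
   time course is correlated with every voxel, r is Fisher-transformed
   (z = atanh r), and subject maps enter a voxelwise one-sample t-test.
3. **Cluster inference.** Group maps are thresholded at one-tailed voxel
   p < 0.001 and cluster extent is tested against a sign-flip permutation
   null of the maximum supra-threshold cluster size (family-wise error
   α = 0.05), separately for positive and negative correlations.
4. **Three target-selection pipelines**, all restricted to a brain-surface
   mask: (1) surface clusters taken directly from the meta-analytic map;
   (2) top 4–6 surface clusters (≥20 voxels) of the network-seed map, by
   |peak|, per sign; (3) top surface clusters of the "third-level" overlap
   map that counts, per voxel, how many single-ROI maps include it.
5. **10–20 montage mapping.** Each selected cluster's peak (or centroid) is
   projected radially onto a scalp ellipsoid fitted to a bundled synthetic
   10-20 electrode table and rendered as a relational label such as
   "Posterior to F3" or "Midpoint to Fz-Cz".

Real patient scans and the meta-analytic database are replaced by a
first-class synthetic-data module that plants known seed→target couplings
(AR(1) latent dynamics, Gaussian noise, controllable head motion), so every
stage is verifiable offline against ground truth.

## Worked example

```bash
nibstarget demo  run1 --seed 1     # write a miniature synthetic study
nibstarget run-all run1            # ROIs -> QC -> FC -> inference -> targets -> 10-20
```

The demo plants three deep "nuclei", each coupled at ±0.6 to one positive and
one negative surface target, plus one deliberately high-motion subject.  The
run log shows the QC exclusion:

```
INFO nibstarget.preprocess: subject sub-12 excluded by motion QC (mean RMS 0.250 mm, max 5.53 mm)
```

and `run1/outputs/targets/pipeline2_positive.tsv` contains the ranked surface
clusters (values from the run above):

```
cluster_id  size_voxels  peak_value  peak_x  peak_y  peak_z  brain_region  location_10_20
1           100          21.235      22.5    13.5    -1.5    Cortex_R      Anterior to F8
2           70           18.5769     -7.5    7.5     16.5    Cortex_Sup    Midpoint to Fz-Fp1
3           25           17.0911     -16.5   -10.5   -4.5    Cortex_L      Midpoint to F7-T3
...
```

Each row is one candidate stimulation site: its cluster size in voxels, peak
group t value, peak MNI coordinate, the toy-parcellation region under the
peak, and the 10-20 scalp phrase a clinician would position a coil by.  The
planted positive targets at (±22.5, 16.5, 0) and (−7.5, 7.5, 22.5) head the
list; `pipeline2_negative.tsv` holds their negative counterparts, and the
pipeline-3 reports rank surface clusters by how many ROIs they are connected
to (their `peak_value` column is that count level, with no peak coordinate
because level-set clusters are flat).  `manifest.json` records per-stage
input/output checksums and the method deviation note for the permutation FWE.

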