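"""Orchestration: run configuration, demo fixture, staged pipeline, manifest.

A *run directory* holds everything for one analysis::

    rundir/
      config.yaml
      inputs/    meta_map, parcellation (labels + TSV), subjects.tsv,
                 per-subject BOLD + motion, optional electrode TSV
      outputs/   rois/, qc/, fc/, inference/, targets/
      manifest.json

Stages run in a fixed order (ROI extraction -> preprocessing/QC -> FC ->
inference -> target pipelines -> montage annotation); each stage reads its
inputs from the directory and records checksums of everything it consumed and
produced in the manifest, so stages can be re-run individually and a
completed stage with unchanged inputs can be skipped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import fc as fc_mod
from . import montage as montage_mod
from . import preprocess as pp
from . import rois as rois_mod
from . import synth
from . import targets as targets_mod
from .core import BinaryMask, MotionTrace, StatMap, VolumeGrid, load_binary_mask, load_bold, load_stat_map
from .inference import InferenceResult, permutation_cluster_fwe

__all__ = ["RunConfig", "StageError", "make_demo", "run_all", "STAGES"]

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

METHOD_DEVIATION = (
    "cluster-level FWE computed by sign-flip permutation (max-cluster-size null) "
    "rather than parametric random-field theory"
)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated settings for one pipeline run; defaults encode the study's
    printed thresholds."""

    seed: int = 0
    tr_s: float = 2.0
    # paths relative to the run directory
    meta_map: str = "inputs/meta_map.nii.gz"
    parcellation_labels: str = "inputs/parcellation.nii.gz"
    parcellation_table: str = "inputs/parcellation.tsv"
    subjects: str = "inputs/subjects.tsv"
    electrodes: str = "builtin"
    # ROI extraction
    min_cluster_meta: int = 50
    roi_radius_mm: float = 6.0
    connectivity: int = 26
    # inference
    voxel_p: float = 0.001
    cluster_alpha: float = 0.05
    n_perm: int = 200
    # target selection
    min_cluster_surface: int = 20
    k_min: int = 4
    k_max: int = 6
    p3_rule: str = "levelset"
    # preprocessing
    drop_volumes: int = 5
    mean_rms_mm: float = 0.2
    max_motion_mm: float = 3.0
    outlier_logic: str = "or"
    n_wm_components: int = 10
    n_csf_components: int = 5
    wm_region: str = ""
    csf_region: str = ""
    low_hz: float = 0.01
    high_hz: float = 0.1
    smooth_fwhm_mm: float = 6.0
    smooth_order: str = "before"

    def preprocess_config(self) -> pp.PreprocessConfig:
        return pp.PreprocessConfig(
            drop_volumes=self.drop_volumes,
            mean_rms_mm=self.mean_rms_mm,
            max_motion_mm=self.max_motion_mm,
            outlier_logic=self.outlier_logic,
            n_wm_components=self.n_wm_components,
            n_csf_components=self.n_csf_components,
            low_hz=self.low_hz,
            high_hz=self.high_hz,
            smooth_fwhm_mm=self.smooth_fwhm_mm,
            smooth_order=self.smooth_order,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def validate(self, rundir: Path) -> None:
        for name in ("min_cluster_meta", "min_cluster_surface", "k_min", "k_max",
                     "n_perm", "roi_radius_mm", "voxel_p", "cluster_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        if not 0 < self.voxel_p < 1 or not 0 < self.cluster_alpha < 1:
            raise ValueError("voxel_p and cluster_alpha must lie in (0, 1)")
        for rel in (self.meta_map, self.parcellation_labels, self.parcellation_table, self.subjects):
            if not (rundir / rel).exists():
                raise FileNotFoundError(f"configured input missing: {rel}")
        if self.electrodes != "builtin" and not (rundir / self.electrodes).exists():
            raise FileNotFoundError(f"electrode table missing: {self.electrodes}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


class Manifest:
    """Per-stage input/output checksums plus warnings and method deviations."""

    def __init__(self, rundir: Path):
        self.rundir = rundir
        self.path = rundir / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {
                "version": __version__,
                "config": {},
                "stages": {},
                "warnings": [],
                "deviations": [METHOD_DEVIATION],
            }

    def record_stage(self, stage: str, inputs: Sequence[Path], outputs: Sequence[Path]) -> None:
        self.data["stages"][stage] = {
            "inputs": {str(p.relative_to(self.rundir)): _sha256(p) for p in inputs},
            "outputs": {str(p.relative_to(self.rundir)): _sha256(p) for p in outputs},
        }
        self.save()

    def warn(self, message: str) -> None:
        if message not in self.data["warnings"]:
            self.data["warnings"].append(message)
        logger.warning(message)

    def stage_current(self, stage: str) -> bool:
        """True when the stage already ran and every recorded input and output
        file still matches its checksum (the skip/resume test)."""
        rec = self.data["stages"].get(stage)
        if rec is None:
            return False
        for group in ("inputs", "outputs"):
            for rel, checksum in rec[group].items():
                p = self.rundir / rel
                if not p.exists() or _sha256(p) != checksum:
                    return False
        return True

    def save(self) -> None:
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


# --------------------------------------------------------------------------
# demo fixture

def make_demo(
    out_dir: str | Path,
    seed: int = 0,
    n_subjects: int = 13,
    n_volumes: int = 155,
    coupling: float = 0.6,
    noise_sd: float = 1.0,
    n_perm: int = 200,
    high_motion_subject: int | None = 12,
) -> Path:
    """Write a complete miniature study into ``out_dir``.

    The fixture plants 3 deep seed nuclei, each coupled (+coupling /
    -coupling) to two disjoint surface target spheres; a meta-analytic map
    with blobs over the deep nuclei plus two surface blobs; a toy
    parcellation with surface slabs and WM/CSF boxes; and per-subject BOLD
    with motion traces, optionally including one high-motion subject that the
    QC stage must exclude.
    """
    out = Path(out_dir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    grid = VolumeGrid.default()

    regions, surface_names, deep_centers, target_specs, surf_blobs = _demo_geometry(grid)
    parc = synth.make_toy_parcellation(grid, regions, surface_names)
    parc.save(out / "inputs/parcellation.nii.gz", out / "inputs/parcellation.tsv")

    blobs = [synth.Blob(c, z, 12.0) for c, z in zip(deep_centers, (12.0, 11.0, 10.0))]
    blobs += [synth.Blob(c, z, 12.0) for c, z in surf_blobs]
    meta = synth.simulate_meta_map(grid, blobs, floor_z=3.0)
    meta.save(out / "inputs/meta_map.nii.gz")

    specs = [
        synth.NetworkSpec(
            seed_region=rois_mod.sphere_mask(grid, center, 6.0),
            targets=[
                (rois_mod.sphere_mask(grid, pos, 6.0), coupling),
                (rois_mod.sphere_mask(grid, neg, 6.0), -coupling),
            ],
            noise_sd=noise_sd,
        )
        for center, (pos, neg) in zip(deep_centers, target_specs)
    ]
    spikes = (
        {high_motion_subject: ([60, 120], 5.0)}
        if high_motion_subject is not None and high_motion_subject < n_subjects
        else {}
    )
    subjects = synth.simulate_group_bold(
        grid, n_subjects, n_volumes, 2.0, specs, seed=seed, motion_spikes=spikes
    )
    rows = []
    for i, (bold, trace) in enumerate(subjects):
        sid = f"sub-{i:02d}"
        bold_path = out / f"inputs/{sid}_bold.nii"
        motion_path = out / f"inputs/{sid}_motion.txt"
        bold.save(bold_path)
        trace.save(motion_path)
        rows.append({"subject_id": sid, "bold": f"inputs/{sid}_bold.nii", "motion": f"inputs/{sid}_motion.txt"})
    pd.DataFrame(rows).to_csv(out / "inputs/subjects.tsv", sep="\t", index=False)

    config = RunConfig(seed=seed, n_perm=n_perm, wm_region="WhiteMatter", csf_region="CSF")
    config.to_yaml(out / "config.yaml")
    return out


def _demo_geometry(grid: VolumeGrid):
    """Disjoint toy anatomy: surface slabs, deep nuclei, WM/CSF boxes."""

    def box(i0, i1, j0, j1, k0, k1):
        data = np.zeros(grid.shape, dtype=bool)
        data[i0:i1 + 1, j0:j1 + 1, k0:k1 + 1] = True
        return BinaryMask(grid, data)

    surface = {
        "Cortex_L": box(0, 4, 0, 23, 0, 19),
        "Cortex_R": box(15, 19, 0, 23, 0, 19),
        "Cortex_Ant": box(5, 14, 19, 23, 0, 19),
        "Cortex_Post": box(5, 14, 0, 4, 0, 19),
        "Cortex_Sup": box(5, 14, 5, 18, 15, 19),
    }
    deep_centers = [(-10.5, -13.5, -4.5), (10.5, -13.5, -4.5), (0.0, 13.5, -4.5)]
    deep = {
        name: rois_mod.sphere_mask(grid, c, 6.0)
        for name, c in zip(("Nucleus_A", "Nucleus_B", "Nucleus_C"), deep_centers)
    }
    wm = box(8, 11, 6, 9, 2, 5)
    csf = box(8, 11, 12, 15, 2, 5)
    # deep spheres may graze the boxes: carve the boxes out of the spheres
    for name in deep:
        deep[name] = BinaryMask(grid, deep[name].data & ~wm.data & ~csf.data)
    for name in surface:
        for d in deep.values():
            surface[name] = BinaryMask(grid, surface[name].data & ~d.data)
    regions = [*surface.items(), *deep.items(), ("WhiteMatter", wm), ("CSF", csf)]
    target_specs = [
        ((-22.5, 16.5, 0.0), (-22.5, -16.5, 0.0)),   # in Cortex_L
        ((22.5, 16.5, 0.0), (22.5, -16.5, 0.0)),     # in Cortex_R
        ((-7.5, 7.5, 22.5), (7.5, -7.5, 22.5)),      # in Cortex_Sup
    ]
    surf_blobs = [((-24.0, 0.0, 0.0), 9.0), ((24.0, 0.0, 0.0), 8.5)]
    return regions, list(surface.keys()), deep_centers, target_specs, surf_blobs


# --------------------------------------------------------------------------
# stages

def _load_common(rundir: Path, config: RunConfig):
    parc = synth.Parcellation.load(
        rundir / config.parcellation_labels, rundir / config.parcellation_table
    )
    return parc


def _stage_seed(config: RunConfig, k: int) -> int:
    return int(np.random.SeedSequence((config.seed, k)).generate_state(1)[0] % (2**31))


def stage_extract_rois(rundir: Path, config: RunConfig, manifest: Manifest) -> None:
    meta = load_stat_map(rundir / config.meta_map)
    roiset, clusters = rois_mod.extract_rois(
        meta, config.min_cluster_meta, config.roi_radius_mm, config.connectivity, strict=True
    )
    out = rundir / "outputs/rois"
    out.mkdir(parents=True, exist_ok=True)
    outputs = []
    meta_rows = []
    for name, mask, center in roiset:
        p = out / f"{name}.nii.gz"
        mask.save(p)
        outputs.append(p)
        meta_rows.append({"name": name, "center": [float(c) for c in center]})
    table = rois_mod.clusters_to_table(clusters)
    table_path = out / "cluster_table.tsv"
    table.to_csv(table_path, sep="\t", index=False, float_format="%.6g")
    roi_json = out / "rois.json"
    roi_json.write_text(json.dumps(meta_rows, indent=2))
    manifest.record_stage(
        "extract-rois", [rundir / config.meta_map], outputs + [table_path, roi_json]
    )


def _read_subjects(rundir: Path, config: RunConfig) -> pd.DataFrame:
    return pd.read_csv(rundir / config.subjects, sep="\t")


def stage_preprocess(rundir: Path, config: RunConfig, manifest: Manifest) -> None:
    parc = _load_common(rundir, config)
    wm = parc.region_mask(config.wm_region) if config.wm_region else None
    csf = parc.region_mask(config.csf_region) if config.csf_region else None
    subjects = _read_subjects(rundir, config)
    out = rundir / "outputs/preprocessed"
    out.mkdir(parents=True, exist_ok=True)
    pconf = config.preprocess_config()
    qc_rows = []
    inputs = [rundir / config.subjects]
    outputs = []
    n_passed = 0
    for _, row in subjects.iterrows():
        bold = load_bold(rundir / row["bold"], tr_s=config.tr_s)
        trace = MotionTrace.load(rundir / row["motion"])
        inputs += [rundir / row["bold"], rundir / row["motion"]]
        result = pp.preprocess_subject(str(row["subject_id"]), bold, trace, wm, csf, pconf)
        qc_rows.append(
            {
                "subject": result.subject_id,
                "mean_rms": result.qc.mean_rms_mm,
                "max_disp": result.qc.max_displacement_mm,
                "n_outliers": len(result.outlier_volumes),
                "pass": result.qc.passed,
            }
        )
        if result.bold is not None:
            n_passed += 1
            p = out / f"{result.subject_id}_clean.nii"
            result.bold.save(p)
            outputs.append(p)
        else:
            manifest.warn(f"subject {result.subject_id} excluded by motion QC")
    if n_passed == 0:
        raise StageError("preprocess", "motion QC excluded every subject")
    qc_path = rundir / "outputs/qc_report.tsv"
    pd.DataFrame(qc_rows).to_csv(qc_path, sep="\t", index=False, float_format="%.6g")
    manifest.record_stage("preprocess", inputs, outputs + [qc_path])


def _load_rois(rundir: Path) -> rois_mod.RoiSet:
    out = rundir / "outputs/rois"
    meta = json.loads((out / "rois.json").read_text())
    entries = []
    grid = None
    for rec in meta:
        mask = load_binary_mask(out / f"{rec['name']}.nii.gz")
        grid = mask.grid
        entries.append((rec["name"], mask, tuple(rec["center"])))
    if not entries:
        raise StageError("fc", "no extracted ROIs found; run extract-rois first")
    return rois_mod.RoiSet(grid, entries)


def _passed_subjects(rundir: Path) -> list[tuple[str, Path]]:
    out = rundir / "outputs/preprocessed"
    paths = sorted(out.glob("*_clean.nii"))
    if not paths:
        raise StageError("fc", "no preprocessed subjects found; run preprocess first")
    return [(p.name.replace("_clean.nii", ""), p) for p in paths]


def stage_fc(rundir: Path, config: RunConfig, manifest: Manifest) -> None:
    roiset = _load_rois(rundir)
    seeds: list[tuple[str, BinaryMask]] = [("network", fc_mod.network_seed(roiset))]
    seeds += [(name, mask) for name, mask, _ in roiset]
    subjects = _passed_subjects(rundir)
    out = rundir / "outputs/fc"
    inputs = [p for _, p in subjects]
    outputs = []
    for seed_name, seed_mask in seeds:
        seed_dir = out / seed_name
        seed_dir.mkdir(parents=True, exist_ok=True)
        for sid, path in subjects:
            bold = load_bold(path, tr_s=config.tr_s)
            series = fc_mod.roi_timeseries(bold, seed_mask)
            fcmap = fc_mod.seed_to_voxel(bold, series, seed_name, sid, seed_mask)
            p = seed_dir / f"{sid}_z.nii.gz"
            StatMap(bold.grid, fcmap.z_values).save(p)
            outputs.append(p)
        sidecar = seed_dir / "seed.json"
        sidecar.write_text(
            json.dumps({"seed_name": seed_name, "n_subjects": len(subjects)}, indent=2)
        )
        outputs.append(sidecar)
    manifest.record_stage("fc", inputs, outputs)


def _load_zmaps(rundir: Path, seed_name: str) -> list[fc_mod.SubjectFcMap]:
    seed_dir = rundir / "outputs/fc" / seed_name
    maps = []
    for p in sorted(seed_dir.glob("*_z.nii.gz")):
        sm = load_stat_map(p)
        z = sm.data
        maps.append(
            fc_mod.SubjectFcMap(sm.grid, np.tanh(z), z, seed_name, p.name.replace("_z.nii.gz", ""))
        )
    if len(maps) < 2:
        raise StageError("infer", f"fewer than 2 z-maps for seed {seed_name!r}")
    return maps


def _seed_names(rundir: Path) -> list[str]:
    fc_dir = rundir / "outputs/fc"
    if not fc_dir.exists():
        raise StageError("infer", "no FC outputs found; run fc first")
    return sorted(d.name for d in fc_dir.iterdir() if d.is_dir())


def _save_inference(result: InferenceResult, out_dir: Path) -> list[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    mask_path = out_dir / "surviving.nii.gz"
    result.surviving_mask().save(mask_path)
    table = rois_mod.clusters_to_table(result.clusters)
    table["fwe_p"] = [c.cluster_fwe_p for c in result.clusters]
    table_path = out_dir / "clusters.tsv"
    table.to_csv(table_path, sep="\t", index=False, float_format="%.6g")
    t_path = out_dir / "group_t.nii.gz"
    result.stat_map.save(t_path)
    meta_path = out_dir / "meta.json"
    meta_path.write_text(
        json.dumps(
            {
                "sign": result.sign,
                "voxel_p": result.voxel_p,
                "alpha": result.alpha,
                "n_permutations": result.n_permutations,
                "rng_seed": result.rng_seed,
                "t_threshold": result.t_threshold,
                "df": result.df,
                "n_subjects": result.n_subjects,
                "n_surviving": len(result.surviving),
                "method_note": result.method_note,
            },
            indent=2,
        )
    )
    return [mask_path, table_path, t_path, meta_path]


def stage_infer(rundir: Path, config: RunConfig, manifest: Manifest) -> None:
    inputs: list[Path] = []
    outputs: list[Path] = []
    for k, seed_name in enumerate(_seed_names(rundir)):
        zmaps = _load_zmaps(rundir, seed_name)
        inputs += sorted((rundir / "outputs/fc" / seed_name).glob("*_z.nii.gz"))
        for s, sign in enumerate(("positive", "negative")):
            result = permutation_cluster_fwe(
                zmaps,
                voxel_p=config.voxel_p,
                alpha=config.cluster_alpha,
                n_perm=config.n_perm,
                seed=_stage_seed(config, 1000 + 2 * k + s),
                sign=sign,
                connectivity=config.connectivity,
            )
            outputs += _save_inference(result, rundir / "outputs/inference" / f"{seed_name}_{sign}")
    manifest.record_stage("infer", inputs, outputs)


def _load_inference(rundir: Path, seed_name: str, sign: str, config: RunConfig) -> InferenceResult:
    d = rundir / "outputs/inference" / f"{seed_name}_{sign}"
    if not d.exists():
        raise StageError("targets", f"missing inference output {d.name}; run infer first")
    meta = json.loads((d / "meta.json").read_text())
    mask = load_binary_mask(d / "surviving.nii.gz")
    tmap = load_stat_map(d / "group_t.nii.gz")
    clusters = rois_mod.find_clusters(mask, min_size=1, connectivity=config.connectivity)
    for rec in clusters:
        rec.cluster_fwe_p = 0.0  # members of the saved mask already survived
        rec.peak_value, rec.peak_mni_mm = rois_mod.locate_peak(rec, tmap, sign=sign)
    return InferenceResult(
        sign=sign,
        voxel_p=meta["voxel_p"],
        alpha=meta["alpha"],
        clusters=clusters,
        n_permutations=meta["n_permutations"],
        rng_seed=meta["rng_seed"],
        t_threshold=meta["t_threshold"],
        df=meta["df"],
        n_subjects=meta["n_subjects"],
        grid=mask.grid,
        stat_map=tmap,
    )


REPORT_FILES = {
    ("1", "none"): "pipeline1.tsv",
    ("2", "positive"): "pipeline2_positive.tsv",
    ("2", "negative"): "pipeline2_negative.tsv",
    ("3", "positive"): "pipeline3_positive.tsv",
    ("3", "negative"): "pipeline3_negative.tsv",
}


def stage_targets(rundir: Path, config: RunConfig, manifest: Manifest) -> None:
    parc = _load_common(rundir, config)
    surface_names = parc.surface_names
    if not surface_names:
        raise StageError("targets", "parcellation marks no surface regions")
    surface = targets_mod.build_surface_mask(parc, surface_names)
    meta = load_stat_map(rundir / config.meta_map)
    reports = [targets_mod.pipeline1(meta, surface, config.min_cluster_meta, strict=True,
                                     connectivity=config.connectivity)]
    res_pos = _load_inference(rundir, "network", "positive", config)
    res_neg = _load_inference(rundir, "network", "negative", config)
    r2p, r2n = targets_mod.pipeline2(
        res_pos, res_neg, surface, config.min_cluster_surface,
        config.k_min, config.k_max, config.connectivity,
    )
    reports += [r2p, r2n]
    roi_names = [n for n in _seed_names(rundir) if n != "network"]
    overlaps = {}
    for sign in ("positive", "negative"):
        masks = [
            targets_mod.binarize_map(_load_inference(rundir, name, sign, config))
            for name in roi_names
        ]
        overlaps[sign] = targets_mod.overlap_sum(masks)
    r3p, r3n = targets_mod.pipeline3(
        overlaps["positive"], overlaps["negative"], surface,
        config.min_cluster_surface, config.k_min, config.k_max,
        config.connectivity, rule=config.p3_rule,
    )
    reports += [r3p, r3n]

    out = rundir / "outputs/targets"
    out.mkdir(parents=True, exist_ok=True)
    outputs = []
    state = {}
    for report in reports:
        targets_mod.annotate_anatomy(report, parc)
        fname = REPORT_FILES[(str(report.pipeline), report.sign)]
        # the TSV belongs to the annotate stage's manifest record (it fills
        # the 10-20 column in place); this stage records the label volumes
        report.to_tsv(out / fname)
        # companion label volume: voxel value = cluster_id
        labels = np.zeros(parc.grid.shape, dtype=np.int16)
        for rec in report.clusters:
            labels[tuple(rec.voxel_indices.T)] = rec.cluster_id
        label_path = out / fname.replace(".tsv", "_labels.nii.gz")
        StatMap(parc.grid, labels.astype(float)).save(label_path)
        outputs.append(label_path)
        state[fname] = [
            {
                "cluster_id": rec.cluster_id,
                "peak_mni_mm": rec.peak_mni_mm,
                "centroid_mni_mm": rec.centroid_mni_mm,
            }
            for rec in report.clusters
        ]
    for sign in ("positive", "negative"):
        p = out / f"overlap_{sign}.nii.gz"
        overlaps[sign].to_stat_map().save(p)
        outputs.append(p)
    state_path = out / "anchors.json"
    state_path.write_text(json.dumps(state, indent=2))
    outputs.append(state_path)
    manifest.record_stage("targets", [rundir / config.meta_map], outputs)


def stage_annotate(rundir: Path, config: RunConfig, manifest: Manifest) -> None:
    electrodes = montage_mod.load_electrodes(
        "builtin" if config.electrodes == "builtin" else rundir / config.electrodes
    )
    out = rundir / "outputs/targets"
    state_path = out / "anchors.json"
    if not state_path.exists():
        raise StageError("annotate", "no target reports found; run targets first")
    state = json.loads(state_path.read_text())
    outputs = []
    for fname, anchors in state.items():
        path = out / fname
        table = pd.read_csv(path, sep="\t")
        labels = []
        for rec in anchors:
            anchor = rec["peak_mni_mm"] or rec["centroid_mni_mm"]
            labels.append(
                montage_mod.scalp_label(np.asarray(anchor, dtype=float), electrodes).rendered
                if anchor is not None
                else ""
            )
        table["location_10_20"] = labels
        table.to_csv(path, sep="\t", index=False, float_format="%.6g")
        outputs.append(path)
    manifest.data.setdefault("electrode_table_checksum", electrodes.checksum)
    manifest.record_stage("annotate", [state_path], outputs)


def demo_truth(grid: VolumeGrid | None = None) -> list[tuple[tuple[float, float, float], str]]:
    """Planted surface-target centers of the demo fixture with their coupling sign."""
    grid = grid or VolumeGrid.default()
    _, _, _, target_specs, _ = _demo_geometry(grid)
    truth = []
    for pos, neg in target_specs:
        truth.append((pos, "positive"))
        truth.append((neg, "negative"))
    return truth


def verify_demo_recovery(rundir: str | Path) -> dict:
    """Check planted-target recovery of a completed demo run.

    A target counts as recovered by a pipeline when its center voxel lies
    inside one of that pipeline's selected clusters of the matching sign; a
    sign violation is a target center appearing in the opposite-sign report.
    """
    rundir = Path(rundir)
    truth = demo_truth()
    out = rundir / "outputs/targets"
    labels = {}
    for (pipe, sign), fname in REPORT_FILES.items():
        if pipe == "1":
            continue
        sm = load_stat_map(out / fname.replace(".tsv", "_labels.nii.gz"))
        labels[(pipe, sign)] = sm
    result = {"n_targets": len(truth), "recovered": {"2": 0, "3": 0}, "sign_violations": 0}
    opposite = {"positive": "negative", "negative": "positive"}
    for center, sign in truth:
        for pipe in ("2", "3"):
            sm = labels[(pipe, sign)]
            idx = sm.grid.mm_to_index(np.asarray(center))
            if sm.data[idx] > 0:
                result["recovered"][pipe] += 1
            if labels[(pipe, opposite[sign])].data[idx] > 0:
                result["sign_violations"] += 1
    result["all_recovered"] = all(
        result["recovered"][p] == len(truth) for p in ("2", "3")
    )
    return result


STAGES = {
    "extract-rois": stage_extract_rois,
    "preprocess": stage_preprocess,
    "fc": stage_fc,
    "infer": stage_infer,
    "targets": stage_targets,
    "annotate": stage_annotate,
}


def run_all(rundir: str | Path, config: RunConfig | None = None, resume: bool = False) -> Manifest:
    """Execute every stage in order; abort with the failing stage's name."""
    rundir = Path(rundir)
    if config is None:
        config = RunConfig.from_yaml(rundir / "config.yaml")
    config.validate(rundir)
    manifest = Manifest(rundir)
    manifest.data["config"] = dataclasses.asdict(config)
    manifest.save()
    for name, fn in STAGES.items():
        if resume and manifest.stage_current(name):
            logger.info("stage %s up to date; skipped", name)
            continue
        try:
            fn(rundir, config, manifest)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, str(exc)) from exc
        logger.info("stage %s complete", name)
    return manifest
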