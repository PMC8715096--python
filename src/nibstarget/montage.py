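"""Mapping peak MNI coordinates to international 10-20 scalp locations.

A cortical peak is projected radially from a head-center reference onto the
scalp ellipsoid least-squares-fitted to the electrode positions, then labeled
relative to the nearest electrode: "at" the electrode when very close, a
midpoint of the two nearest when they are nearly equidistant, otherwise a
directional phrase (anterior/posterior/superior/inferior to the anchor) from
the dominant offset axis.

The bundled electrode table is a synthetic, left-right symmetric idealized
10-20 layout (see data/electrodes_1020_synthetic.tsv); label agreement
depends on this table, so every labeling records its checksum and an
alternative table can be supplied as a TSV (label, x, y, z).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .targets import TargetReport

__all__ = [
    "ElectrodeSet",
    "ScalpLocation",
    "load_electrodes",
    "scalp_project",
    "scalp_label",
    "annotate_report",
    "DEFAULT_HEAD_CENTER",
]

logger = logging.getLogger(__name__)

DEFAULT_HEAD_CENTER = (0.0, -18.0, 12.0)
# relational thresholds: calibrated once against the labeling regression
# suite and frozen
MIDPOINT_RATIO = 1.25
RELATION_MIN_MM = 8.0


@dataclass
class ElectrodeSet:
    """10-20 electrode labels with MNI scalp coordinates."""

    labels: list[str]
    positions: np.ndarray  # (n, 3) mm
    head_center: np.ndarray
    checksum: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.head_center = np.asarray(self.head_center, dtype=float)
        if len(self.labels) != len(self.positions):
            raise ValueError("labels and positions length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("electrode labels must be unique")

    def position(self, label: str) -> np.ndarray:
        return self.positions[self.labels.index(label)]

    def fit_ellipsoid(self) -> np.ndarray:
        """Semi-axes of the axis-aligned scalp ellipsoid centered on
        head_center, least-squares fitted to the electrode positions."""
        D2 = (self.positions - self.head_center) ** 2
        w, *_ = np.linalg.lstsq(D2, np.ones(len(self.positions)), rcond=None)
        if np.any(w <= 0):
            raise ValueError("degenerate electrode configuration: ellipsoid fit failed")
        return 1.0 / np.sqrt(w)

    def fit_residual_rms(self) -> float:
        axes = self.fit_ellipsoid()
        res = [
            np.linalg.norm(_project(p, self.head_center, axes) - p)
            for p in self.positions
        ]
        return float(np.sqrt(np.mean(np.square(res))))

    def save(self, path: str | Path) -> None:
        lines = ["label\tx\ty\tz"]
        for lab, pos in zip(self.labels, self.positions):
            lines.append(f"{lab}\t{pos[0]:.10g}\t{pos[1]:.10g}\t{pos[2]:.10g}")
        Path(path).write_text("\n".join(lines) + "\n")


def _parse_table(text: str) -> tuple[list[str], np.ndarray]:
    labels: list[str] = []
    coords: list[list[float]] = []
    header_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if not header_seen:
            if [p.lower() for p in parts[:4]] != ["label", "x", "y", "z"]:
                raise ValueError(f"row {lineno}: expected header 'label x y z'")
            header_seen = True
            continue
        if len(parts) < 4:
            raise ValueError(f"row {lineno}: expected 4 columns, got {len(parts)}")
        label = parts[0]
        if label in labels:
            raise ValueError(f"row {lineno}: duplicate label {label!r}")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError as exc:
            raise ValueError(f"row {lineno}: non-numeric coordinate") from exc
        labels.append(label)
        coords.append(xyz)
    if not labels:
        raise ValueError("electrode table contains no rows")
    return labels, np.asarray(coords)


def load_electrodes(
    source: str | Path = "builtin",
    head_center: Sequence[float] = DEFAULT_HEAD_CENTER,
) -> ElectrodeSet:
    """Load an electrode table from the builtin synthetic 10-20 layout or a
    TSV file with columns (label, x, y, z)."""
    if source == "builtin":
        text = (
            resources.files("nibstarget").joinpath("data/electrodes_1020_synthetic.tsv").read_text()
        )
    else:
        text = Path(source).read_text()
    labels, coords = _parse_table(text)
    checksum = hashlib.sha256(text.encode()).hexdigest()[:16]
    return ElectrodeSet(labels, coords, np.asarray(head_center, dtype=float), checksum)


def _project(p: np.ndarray, center: np.ndarray, axes: np.ndarray) -> np.ndarray:
    d = np.asarray(p, dtype=float) - center
    norm2 = np.sum((d / axes) ** 2)
    if norm2 == 0:
        raise ValueError("point coincides with the head center: projection direction undefined")
    return center + d / np.sqrt(norm2)


def scalp_project(peak_mm: Sequence[float], electrodes: ElectrodeSet) -> np.ndarray:
    """Radial projection of a point onto the fitted scalp ellipsoid."""
    axes = electrodes.fit_ellipsoid()
    return _project(np.asarray(peak_mm, dtype=float), electrodes.head_center, axes)


@dataclass(frozen=True)
class ScalpLocation:
    """A 10-20 description of a projected peak."""

    nearest: str
    distance_mm: float
    relation: str  # at | anterior | posterior | superior | inferior | midpoint
    second_label: str | None
    rendered: str
    table_checksum: str = ""


def _render(relation: str, nearest: str, second: str | None) -> str:
    if relation == "at":
        return nearest
    if relation == "midpoint":
        return f"Midpoint to {nearest}-{second}"
    return f"{relation.capitalize()} to {nearest}"


def scalp_label(
    peak_mm: Sequence[float],
    electrodes: ElectrodeSet,
    midpoint_ratio: float = MIDPOINT_RATIO,
    relation_min_mm: float = RELATION_MIN_MM,
) -> ScalpLocation:
    """10-20 label of a peak: nearest electrode plus a relational phrase.

    The projected point's two nearest electrodes decide the phrasing: nearly
    equidistant (ratio <= ``midpoint_ratio``) renders "Midpoint to A-B";
    within ``relation_min_mm`` of the anchor renders the bare label; otherwise
    the dominant y/z offset renders anterior/posterior/superior/inferior.
    """
    projected = scalp_project(peak_mm, electrodes)
    d = np.linalg.norm(electrodes.positions - projected, axis=1)
    order = np.argsort(d)
    i1, i2 = order[0], order[1]
    nearest, second = electrodes.labels[i1], electrodes.labels[i2]
    d1, d2 = float(d[i1]), float(d[i2])
    if d1 > 0 and d2 / d1 <= midpoint_ratio:
        relation: str = "midpoint"
        second_label: str | None = second
    elif d1 <= relation_min_mm:
        relation, second_label = "at", None
    else:
        offset = projected - electrodes.positions[i1]
        if abs(offset[1]) >= abs(offset[2]):
            relation = "anterior" if offset[1] > 0 else "posterior"
        else:
            relation = "superior" if offset[2] > 0 else "inferior"
        second_label = None
    return ScalpLocation(
        nearest=nearest,
        distance_mm=d1,
        relation=relation,
        second_label=second_label,
        rendered=_render(relation, nearest, second_label),
        table_checksum=electrodes.checksum,
    )


def annotate_report(report: TargetReport, electrodes: ElectrodeSet) -> TargetReport:
    """Fill the 10-20 scalp label of every cluster in a target report.

    Clusters without a peak coordinate (flat level-set clusters) are anchored
    at their voxel centroid.  Annotation preserves ordering and is idempotent.
    """
    for rec in report.clusters:
        anchor = rec.peak_mni_mm if rec.peak_mni_mm is not None else rec.centroid_mni_mm
        if anchor is None:
            continue
        rec.scalp_label = scalp_label(np.asarray(anchor), electrodes).rendered
    return report
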