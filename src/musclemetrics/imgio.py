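"""Calibrated multi-channel image I/O and every on-disk output artifact.

Images are TIFF / OME-TIFF, carried in memory as an :class:`ImageRecord`
(channel-first array plus a µm/pixel calibration and a role → channel map).
Result files follow fixed batch conventions:

* ``<ImageFolderName>_GlobalResults_<abbrev-list>.txt`` — one tab-delimited
  row per processed image, rewritten atomically after every image so an
  interrupted batch loses at most the in-flight image;
* per-image detail tables (``FiberDetails``, ``CapillaryDetails``,
  ``SpecificDetails_<marker>``, ``SatCellDetails``,
  ``PeriMyoNucleiDetails``);
* a ``<image>_xxROI.zip`` archive of ImageJ polygon ROIs;
* a timestamped ``BATCH_LOG`` text file per run.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

CHANNEL_ROLES = (
    "section_shape",
    "laminin",
    "dna",
    "type_I",
    "type_IIA",
    "type_IIB",
    "type_IIX",
    "endothelial",
    "cell_marker",
    "myonuclei_marker",
    "intensity_target",
    "cartography_base",
)

#: Abbreviations appended to the GlobalResults file name, one per analysis.
ANALYSIS_ABBREV = {
    "morphology": "Morph",
    "ecm": "ECM",
    "vascularization": "Vasc",
    "capillaries": "Cap",
    "typing": "Typ",
    "centro_myonuclei": "CMN",
    "peri_myonuclei": "PMN",
    "satellite_cells": "SC",
    "fiber_intensity": "Int",
    "specific_cells": "Cells",
}


class ImageReadError(IOError):
    """Raised when a file cannot be read as a calibrated TIFF/OME-TIFF."""


@dataclass
class ImageRecord:
    """A multi-channel image with physical calibration.

    ``pixels`` is channel-first: ``(C, Y, X)`` for a single plane or
    ``(C, Z, Y, X)`` for a stack.  ``channel_roles`` maps role names (see
    :data:`CHANNEL_ROLES`) to channel indices; distinct roles may not share
    nothing — the map must be injective on indices per role name, but one
    physical channel may legitimately serve several roles (e.g. laminin as
    both boundary stain and section shape), so injectivity is enforced on
    role names only.
    """

    pixels: np.ndarray
    um_per_px: float
    channel_roles: Mapping[str, int]
    source_path: str = ""

    def __post_init__(self):
        if self.um_per_px is None or self.um_per_px <= 0:
            raise ValueError("um_per_px must be > 0")
        if self.pixels.ndim not in (3, 4):
            raise ValueError("pixels must be (C, Y, X) or (C, Z, Y, X)")
        n_ch = self.pixels.shape[0]
        for role, idx in self.channel_roles.items():
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {role!r}")
            if not 0 <= int(idx) < n_ch:
                raise ValueError(f"role {role!r} maps to invalid channel {idx}")

    @property
    def has_z(self) -> bool:
        return self.pixels.ndim == 4

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixels.shape[-2], self.pixels.shape[-1]

    def channel(self, role: str) -> np.ndarray:
        """2-D plane for a role (stacks must be projected first)."""
        if role not in self.channel_roles:
            raise KeyError(f"no channel mapped to role {role!r}")
        if self.has_z:
            raise ValueError("Z-stack record: call max_project() first")
        return self.pixels[self.channel_roles[role]]

    def has_role(self, role: str) -> bool:
        return role in self.channel_roles


@dataclass
class RunConfig:
    """User choices for one batch run (one image folder)."""

    pathophysiology: str = "Healthy"  # Healthy | Damaged
    anatomy: str = "Limb"  # Limb | Diaphragm
    scanned_area: str = "EntireSection"  # EntireSection | Crop
    volume: str = "SingleZ"  # SingleZ | ZStack
    artifact_min_fiber_pct: float = 0.0
    enabled_analyses: set = field(default_factory=lambda: {"morphology"})
    marker_name: str = "marker"
    channel_roles: dict = field(default_factory=dict)
    um_per_px: float | None = None
    legend: bool = False
    scalebar_position: str = "none"
    montage: bool = False
    cartographies: list = field(default_factory=list)
    output_dir: str = "results"

    def __post_init__(self):
        if not 0.0 <= self.artifact_min_fiber_pct <= 100.0:
            raise ValueError("artifact_min_fiber_pct must be in [0, 100]")
        if self.pathophysiology not in ("Healthy", "Damaged"):
            raise ValueError("pathophysiology must be Healthy or Damaged")
        if self.anatomy not in ("Limb", "Diaphragm"):
            raise ValueError("anatomy must be Limb or Diaphragm")
        self.enabled_analyses = set(self.enabled_analyses)
        unknown = self.enabled_analyses - set(ANALYSIS_ABBREV)
        if unknown:
            raise ValueError(f"unknown analyses: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class BatchLog:
    """Metadata snapshot for one batch run."""

    image_folder: str
    config: RunConfig
    timestamp: _dt.datetime = field(default_factory=_dt.datetime.now)
    lines: list = field(default_factory=list)

    def add(self, line: str) -> None:
        self.lines.append(str(line))


@dataclass
class AnalysisResults:
    """Everything produced for one image: the GlobalResults row plus the
    per-object detail tables (any of which may be absent)."""

    image_name: str
    global_row: dict = field(default_factory=dict)
    fiber_details: pd.DataFrame | None = None
    capillary_details: pd.DataFrame | None = None
    specific_details: pd.DataFrame | None = None
    satcell_details: pd.DataFrame | None = None
    perimyonuclei_details: pd.DataFrame | None = None
    marker_name: str = "marker"


# ---------------------------------------------------------------------------
# reading / writing images
# ---------------------------------------------------------------------------


def _parse_ome_pixel_size(ome_xml: str) -> float | None:
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return None
    for el in root.iter():
        if el.tag.endswith("Pixels") and "PhysicalSizeX" in el.attrib:
            return float(el.attrib["PhysicalSizeX"])
    return None


def read_image(
    path,
    channel_roles: Mapping[str, int],
    um_per_px_override: float | None = None,
) -> ImageRecord:
    """Read a TIFF/OME-TIFF into an :class:`ImageRecord`.

    Calibration comes from OME ``PhysicalSizeX`` metadata; an explicit
    override wins.  A file with neither is rejected rather than silently
    analysed in pixel units.
    """
    path = str(path)
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            data = series.asarray()
            axes = series.axes
            ome = tf.ome_metadata
    except Exception as exc:  # noqa: BLE001 - normalized to one error type
        raise ImageReadError(f"cannot read {path}: {exc}") from exc

    um_per_px = um_per_px_override
    if um_per_px is None and ome:
        um_per_px = _parse_ome_pixel_size(ome)
    if um_per_px is None:
        raise ImageReadError(
            f"{path}: no pixel-size metadata and no um_per_px override given"
        )

    # Normalize axes to C(Z)YX.
    axes = axes.replace("S", "C")
    if data.ndim == 2:
        data = data[None]
        axes = "CYX"
    order = [axes.index(a) for a in ("C", "Z", "Y", "X") if a in axes]
    data = np.transpose(data, order)
    if "C" not in axes:
        data = data[None]
    return ImageRecord(
        pixels=np.ascontiguousarray(data),
        um_per_px=float(um_per_px),
        channel_roles=dict(channel_roles),
        source_path=path,
    )


def write_image(record: ImageRecord, path) -> str:
    """Write an :class:`ImageRecord` as OME-TIFF with its calibration."""
    axes = "CZYX" if record.has_z else "CYX"
    tifffile.imwrite(
        str(path),
        record.pixels,
        ome=True,
        metadata={
            "axes": axes,
            "PhysicalSizeX": record.um_per_px,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": record.um_per_px,
            "PhysicalSizeYUnit": "µm",
        },
    )
    return str(path)


def max_project(record: ImageRecord) -> ImageRecord:
    """Maximum-intensity projection over Z; identity for single-plane input."""
    if not record.has_z:
        return record
    return dataclasses.replace(record, pixels=record.pixels.max(axis=1))


# ---------------------------------------------------------------------------
# result files
# ---------------------------------------------------------------------------


def global_results_filename(folder_name: str, analyses: Iterable[str]) -> str:
    ordered = [a for a in ANALYSIS_ABBREV if a in set(analyses)]
    abbrevs = "-".join(ANALYSIS_ABBREV[a] for a in ordered) or "None"
    return f"{folder_name}_GlobalResults_{abbrevs}.txt"


def write_global_results(
    rows: Sequence[Mapping],
    out_dir,
    folder_name: str,
    analyses: Iterable[str],
) -> str:
    """(Re)write the GlobalResults table atomically.

    Called once per processed image with the rows accumulated so far, so the
    file on disk is always a complete, parseable table.  With zero rows a
    header-only file is produced.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / global_results_filename(folder_name, analyses)
    if rows:
        df = pd.DataFrame(list(rows))
    else:
        df = pd.DataFrame(columns=["Image"])
    tmp = path.with_suffix(".txt.tmp")
    df.to_csv(tmp, sep="\t", index=False)
    os.replace(tmp, path)
    return str(path)


def write_detail_tables(results: AnalysisResults, out_dir) -> list[str]:
    """Write one tab-delimited detail file per cell type present."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    marker = results.marker_name.replace("/", "-").replace(" ", "_")
    mapping = [
        (results.fiber_details, f"{results.image_name}_FiberDetails.txt"),
        (results.capillary_details, f"{results.image_name}_CapillaryDetails.txt"),
        (results.specific_details, f"{results.image_name}_SpecificDetails_{marker}.txt"),
        (results.satcell_details, f"{results.image_name}_SatCellDetails.txt"),
        (results.perimyonuclei_details, f"{results.image_name}_PeriMyoNucleiDetails.txt"),
    ]
    paths = []
    for df, name in mapping:
        if df is None:
            continue
        p = out_dir / name
        df.to_csv(p, sep="\t", index=False)
        paths.append(str(p))
    return paths


def write_roi_archive(
    named_polygons: Sequence[tuple[str, np.ndarray]],
    image_name: str,
    out_dir,
    log: BatchLog | None = None,
) -> str:
    """Write polygons (section shape, fibers, cells) to ``<image>_xxROI.zip``.

    Polygons with fewer than 3 vertices are skipped with a log line instead
    of aborting the batch.
    """
    from . import roi_format

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{image_name}_xxROI.zip"
    keep = []
    for name, verts in named_polygons:
        v = np.asarray(verts)
        n = len(v) - 1 if len(v) > 1 and np.allclose(v[0], v[-1]) else len(v)
        if n < 3:
            msg = f"skipped degenerate ROI {name!r} ({n} vertices)"
            if log is not None:
                log.add(msg)
            continue
        keep.append((name, v))
    roi_format.write_roi_zip(path, keep)
    return str(path)


def write_batch_log(log: BatchLog, out_dir) -> str:
    """Write ``YYYYMMDD_HHMMSS_<imagefoldername>_BATCH_LOG.txt``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = log.timestamp.strftime("%Y%m%d_%H%M%S")
    path = out_dir / f"{stamp}_{log.image_folder}_BATCH_LOG.txt"
    cfg = log.config
    lines = [
        f"Batch started: {log.timestamp.isoformat(sep=' ', timespec='seconds')}",
        f"Image folder: {log.image_folder}",
        f"Pathophysiology: {cfg.pathophysiology}",
        f"Anatomy: {cfg.anatomy}",
        f"Scanned area: {cfg.scanned_area}",
        f"Volume: {cfg.volume}",
        f"Artifact minimum fiber %: {cfg.artifact_min_fiber_pct}",
        f"Analyses: {', '.join(sorted(cfg.enabled_analyses))}",
        f"Marker name: {cfg.marker_name}",
        "Channel attribution: "
        + ", ".join(f"{r}->{c}" for r, c in sorted(cfg.channel_roles.items())),
    ]
    lines.extend(log.lines)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return str(path)
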