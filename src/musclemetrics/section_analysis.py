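"""Whole-section analyses that need no fiber segmentation.

Three measurements relate staining to the total tissue surface:

* **ECM area** — moment-preserving (Tsai) threshold of the ECM channel
  inside the section, one light erosion pass, reported in µm² and as a
  percentage of the section;
* **vascularization** — endothelial staining segmented after histogram-mode
  background subtraction, with *no* morphological size/shape criterion
  (arteries and veins count too); reports % surface covered and vessels/mm²;
* **specific cells** — arbitrary-marker blobs anywhere in the section,
  cross-checked against DNA spots so debris without a nucleus is reported
  but flagged as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from ._primitives import (
    object_measurements,
    segment_blobs,
    segment_nuclei_mask,
    subtract_background,
    triangle_cut,
)
from .imgio import ImageRecord
from .section import SectionMask


@dataclass
class ECMResult:
    ecm_area_um2: float
    ecm_pct_of_section: float
    mask: np.ndarray | None = None


@dataclass
class VesselObject:
    label: int
    centroid_um: tuple[float, float]
    area_um2: float
    circularity: float
    feret_min_um: float
    feret_max_um: float
    intensity_mean: float


@dataclass
class VascResult:
    vasc_surface_pct: float
    vessels_per_mm2: float
    vessels: list = field(default_factory=list)
    label_image: np.ndarray | None = None


@dataclass
class SpecificCellResult:
    n_cells: int
    n_cells_with_nuclei: int
    pct_cell_area: float
    intensity_mean: float
    area_mean_um2: float
    details: list = field(default_factory=list)
    label_image: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Tsai moment-preserving threshold
# ---------------------------------------------------------------------------


def moments_threshold(histogram: np.ndarray) -> int | None:
    """Moment-preserving (Tsai) threshold of an intensity histogram.

    ``histogram[i]`` is the count of pixels at gray level ``i``.  The method
    finds the two-level image preserving the first three gray-level moments
    of the input; the below-class mass fraction ``p0`` follows in closed
    form, and the returned cut ``t`` is the smallest level for which the
    cumulative histogram below ``t`` best matches ``p0``.  Foreground is
    ``level >= t``.  A constant image has no threshold → ``None``.
    """
    h = np.asarray(histogram, dtype=float)
    if h.ndim != 1 or h.sum() <= 0:
        raise ValueError("histogram must be a 1-D array of counts")
    if np.count_nonzero(h) < 2:
        return None
    p = h / h.sum()
    levels = np.arange(len(p), dtype=float)
    m1 = float((levels * p).sum())
    m2 = float((levels**2 * p).sum())
    m3 = float((levels**3 * p).sum())
    cd = m2 - m1 * m1
    if cd <= 0:
        return None
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        return None
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 == z0:
        return None
    p0 = (z1 - m1) / (z1 - z0)
    cdf = np.cumsum(p)
    # cut t classifies levels < t as background: pick the t whose below-mass
    # is closest to p0 (first such t on ties)
    t = int(np.argmin(np.abs(cdf[:-1] - p0))) + 1
    return t


def _channel_for_ecm(record: ImageRecord) -> np.ndarray:
    for role in ("laminin", "section_shape"):
        if record.has_role(role):
            return record.channel(role).astype(float)
    raise ValueError("no ECM-capable channel (laminin/section_shape) present")


def detect_ecm(record: ImageRecord, section_mask: SectionMask, bins: int = 256) -> ECMResult:
    """ECM area inside the section: Tsai threshold then one erosion pass.

    The erosion uses a radius-1 cross element — the minimal "low erosion"
    that still removes single-pixel speckle.
    """
    if not section_mask.mask.any():
        raise ValueError("empty section mask")
    ch = _channel_for_ecm(record)
    inside = section_mask.mask
    vals = ch[inside]
    vmax = float(vals.max())
    if vmax <= 0 or np.unique(vals).size < 2:
        return ECMResult(0.0, 0.0, np.zeros_like(inside))
    scaled = np.clip(ch / vmax * (bins - 1), 0, bins - 1).astype(int)
    hist = np.bincount(scaled[inside].ravel(), minlength=bins)
    t = moments_threshold(hist)
    if t is None:
        return ECMResult(0.0, 0.0, np.zeros_like(inside))
    mask = (scaled >= t) & inside
    mask = ndi.binary_erosion(mask, structure=ndi.generate_binary_structure(2, 1))
    area = float(mask.sum()) * record.um_per_px**2
    pct = 100.0 * mask.sum() / inside.sum()
    return ECMResult(ecm_area_um2=area, ecm_pct_of_section=pct, mask=mask)


# ---------------------------------------------------------------------------
# vascularization
# ---------------------------------------------------------------------------


def segment_vessels(record: ImageRecord, section_mask: SectionMask) -> tuple[np.ndarray, list[VesselObject]]:
    """Endothelial objects inside the section (shared with the capillary
    classifier): mode-background subtraction, triangle threshold, connected
    components — deliberately no size or shape criterion here."""
    if not record.has_role("endothelial"):
        raise ValueError("no endothelial channel present")
    ch = record.channel("endothelial")
    lbl = segment_blobs(ch, section_mask.mask, min_area_px=2)
    residual = subtract_background(ch, section_mask.mask)
    vessels = [
        VesselObject(
            label=m["label"],
            centroid_um=(m["centroid_x_um"], m["centroid_y_um"]),
            area_um2=m["area_um2"],
            circularity=m["circularity"],
            feret_min_um=m["feret_min_um"],
            feret_max_um=m["feret_max_um"],
            intensity_mean=m["intensity_mean"],
        )
        for m in object_measurements(lbl, residual, record.um_per_px)
    ]
    return lbl, vessels


def detect_vessels(record: ImageRecord, section_mask: SectionMask) -> VascResult:
    """Total vascularization: % of section surface covered and vessels/mm²."""
    if not section_mask.mask.any():
        raise ValueError("empty section mask")
    lbl, vessels = segment_vessels(record, section_mask)
    covered_px = int((lbl > 0).sum())
    pct = 100.0 * covered_px / section_mask.mask.sum()
    section_mm2 = section_mask.total_area_um2 / 1e6
    per_mm2 = len(vessels) / section_mm2 if section_mm2 > 0 else 0.0
    return VascResult(vasc_surface_pct=pct, vessels_per_mm2=per_mm2, vessels=vessels, label_image=lbl)


# ---------------------------------------------------------------------------
# specific cells
# ---------------------------------------------------------------------------


def detect_specific_cells(
    record: ImageRecord,
    section_mask: SectionMask,
    marker_name: str = "marker",
    min_overlap_fraction: float = 0.0,
) -> SpecificCellResult:
    """Detect marker-positive cells anywhere in the section.

    Blobs are segmented with no shape prior (both round and irregular cells
    count).  A blob "has a nucleus" when its mask overlaps a DNA spot by at
    least one pixel (or by ``min_overlap_fraction`` of its area when set).
    Mean intensity and mean area are reported over nucleus-bearing cells
    only; the total count includes nucleus-free blobs, each of which gets a
    detail row without nucleus coordinates.
    """
    if not record.has_role("dna"):
        raise ValueError("specific-cell detection requires a DNA channel")
    if not record.has_role("cell_marker"):
        raise ValueError("no cell-marker channel present")
    inside = section_mask.mask
    upp = record.um_per_px
    marker = record.channel("cell_marker")
    lbl = segment_blobs(marker, inside, min_area_px=4)
    if lbl.max() == 0:
        return SpecificCellResult(0, 0, 0.0, 0.0, 0.0, [], lbl)

    nuc_lbl = segment_nuclei_mask(record.channel("dna"), inside, upp)
    nuc_mask = nuc_lbl > 0
    residual = subtract_background(marker, inside)
    measures = object_measurements(lbl, residual, upp)

    from skimage.measure import regionprops

    nuc_centroids = {rp.label: rp.centroid for rp in regionprops(nuc_lbl)}
    details = []
    n_with = 0
    for m in measures:
        obj = lbl == m["label"]
        overlap = obj & nuc_mask
        frac = overlap.sum() / obj.sum()
        has_nucleus = overlap.any() and frac >= min_overlap_fraction
        row = {
            "marker": marker_name,
            "area_um2": m["area_um2"],
            "feret_min_um": m["feret_min_um"],
            "feret_max_um": m["feret_max_um"],
            "cell_gc_x_um": m["centroid_x_um"],
            "cell_gc_y_um": m["centroid_y_um"],
            "intensity_mean": m["intensity_mean"],
            "nucleus_gc_x_um": np.nan,
            "nucleus_gc_y_um": np.nan,
        }
        if has_nucleus:
            n_with += 1
            nlab = int(np.bincount(nuc_lbl[overlap]).argmax())
            cy, cx = nuc_centroids[nlab]
            row["nucleus_gc_x_um"] = cx * upp
            row["nucleus_gc_y_um"] = cy * upp
        details.append(row)

    with_nuc = [d for d in details if np.isfinite(d["nucleus_gc_x_um"])]
    pct_area = 100.0 * (lbl > 0).sum() / inside.sum()
    return SpecificCellResult(
        n_cells=len(details),
        n_cells_with_nuclei=n_with,
        pct_cell_area=pct_area,
        intensity_mean=float(np.mean([d["intensity_mean"] for d in with_nuc])) if with_nuc else 0.0,
        area_mean_um2=float(np.mean([d["area_um2"] for d in with_nuc])) if with_nuc else 0.0,
        details=details,
        label_image=lbl,
    )
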