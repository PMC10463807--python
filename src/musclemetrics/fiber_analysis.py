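"""Per-fiber analyses: nuclei classes, capillaries, typing, ROI intensity.

All operations here consume the per-fiber :class:`~musclemetrics.fibers.ROIBands`
and classify detected objects by centroid membership:

* a nucleus is **central** when its centroid falls in ``roi_cnf`` (no marker
  colabel needed — central position suffices);
* a **peripheral myonucleus** must sit in ``roi_mb`` *and* be positive for
  the myonuclei marker (colabel with the DNA stain is mandatory);
* a **satellite cell** is a marker+/DNA+ object whose centroid lies in a
  fiber's ``roi_sc`` band;
* a **capillary** is an endothelial object with area ≤ 100 µm² and
  circularity ≥ 0.45; its *sharing factor* is the number of fibers whose
  ``roi_cap`` band its mask touches, and the transposed count per fiber is
  the fiber's *capillary contacts* (the two totals are equal by
  construction);
* **fiber typing** thresholds each myosin-heavy-chain channel at
  mean + SD (types I and IIA) or at the mean (types IIB and IIX) of the
  per-fiber mean intensities, with inclusive comparisons; fibers positive
  on several channels get a hybrid label, on none "undetermined".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._primitives import otsu_cut, segment_blobs, segment_nuclei_mask, subtract_background, triangle_cut
from .fibers import ROIBands
from .imgio import ImageRecord
from .section import SectionMask
from .section_analysis import VesselObject

CAPILLARY_MAX_AREA_UM2 = 100.0
CAPILLARY_MIN_CIRCULARITY = 0.45
TYPE_ORDER = ("I", "IIA", "IIB", "IIX")
TYPE_RULES = {"I": "mean_plus_sd", "IIA": "mean_plus_sd", "IIB": "mean", "IIX": "mean"}
ROI_NAMES = ("roi_f", "roi_cnf", "roi_mb", "roi_sc", "roi_cap")


@dataclass
class NucleusRecord:
    label: int
    centroid_um: tuple[float, float]
    area_um2: float
    marker_positive: bool | None = None


@dataclass
class NucleiResult:
    records: list
    label_image: np.ndarray


@dataclass
class CapillaryRecord:
    label: int
    centroid_um: tuple[float, float]
    area_um2: float
    circularity: float
    feret_min_um: float
    feret_max_um: float
    intensity_mean: float
    sharing_factor: int = 0


@dataclass
class TypingThresholds:
    """Per-channel positivity thresholds reported in GlobalResults."""

    per_channel: dict = field(default_factory=dict)  # type -> dict(mean, sd, threshold, rule)


# ---------------------------------------------------------------------------
# nuclei
# ---------------------------------------------------------------------------


def detect_nuclei(record: ImageRecord, section_mask: SectionMask) -> NucleiResult:
    """Segment DNA spots inside the section and split touching nuclei."""
    if not record.has_role("dna"):
        raise ValueError("nucleus detection requires a DNA channel")
    upp = record.um_per_px
    lbl = segment_nuclei_mask(record.channel("dna"), section_mask.mask, upp)
    from skimage.measure import regionprops

    records = []
    for rp in regionprops(lbl):
        cy, cx = rp.centroid
        records.append(
            NucleusRecord(
                label=rp.label,
                centroid_um=(cx * upp, cy * upp),
                area_um2=rp.area * upp**2,
            )
        )
    return NucleiResult(records=records, label_image=lbl)


def _owning_fiber(bands: list[ROIBands], which: str, row: float, col: float) -> int | None:
    """Fiber whose band contains the point; ties go to the smaller fiber id."""
    for b in sorted(bands, key=lambda b: b.fiber_id):
        if b.contains_point(which, row, col):
            return b.fiber_id
    return None


def count_centronuclei(bands: list[ROIBands], nuclei: NucleiResult, um_per_px: float) -> dict[int, int]:
    """Central-nucleus count per fiber (centroid inside ``roi_cnf``)."""
    counts = {b.fiber_id: 0 for b in bands}
    for nuc in nuclei.records:
        x, y = nuc.centroid_um
        fid = _owning_fiber(bands, "roi_cnf", y / um_per_px, x / um_per_px)
        if fid is not None:
            counts[fid] += 1
    return counts


def count_peri_myonuclei(
    bands: list[ROIBands],
    nuclei: NucleiResult,
    record: ImageRecord,
) -> tuple[dict[int, int], list[dict]]:
    """Peripheral myonuclei per fiber: in ``roi_mb`` and marker-positive.

    Marker positivity is decided per nucleus by Otsu over the nucleus-wise
    mean intensities of the myonuclei channel (inclusive ≥; a degenerate
    one-level distribution counts everything positive).
    """
    if not record.has_role("myonuclei_marker"):
        raise ValueError("peri-myonuclei counting requires a myonuclei marker channel")
    upp = record.um_per_px
    marker = record.channel("myonuclei_marker").astype(float)
    lbl = nuclei.label_image
    means = {}
    for nuc in nuclei.records:
        means[nuc.label] = float(marker[lbl == nuc.label].mean()) if (lbl == nuc.label).any() else 0.0
    cut = otsu_cut(np.array(list(means.values()))) if means else None
    counts = {b.fiber_id: 0 for b in bands}
    details = []
    for nuc in nuclei.records:
        positive = means[nuc.label] >= cut if cut is not None else True
        nuc.marker_positive = bool(positive)
        if not positive:
            continue
        x, y = nuc.centroid_um
        fid = _owning_fiber(bands, "roi_mb", y / upp, x / upp)
        if fid is None:
            continue
        counts[fid] += 1
        details.append(
            {
                "fiber": fid,
                "nucleus_x_um": x,
                "nucleus_y_um": y,
                "area_um2": nuc.area_um2,
                "marker_intensity": means[nuc.label],
            }
        )
    return counts, details


def detect_satellite_cells(
    bands: list[ROIBands],
    nuclei: NucleiResult,
    record: ImageRecord,
    section_mask: SectionMask,
    marker_role: str = "cell_marker",
) -> tuple[dict[int, int], list[dict]]:
    """Satellite cells: marker+/DNA+ objects with centroid in ``roi_sc``."""
    if not record.has_role(marker_role):
        raise ValueError(f"satellite-cell detection requires a {marker_role} channel")
    upp = record.um_per_px
    lbl = segment_blobs(record.channel(marker_role), section_mask.mask, min_area_px=4)
    nuc_mask = nuclei.label_image > 0
    counts = {b.fiber_id: 0 for b in bands}
    details = []
    from skimage.measure import regionprops

    for rp in regionprops(lbl):
        obj = lbl == rp.label
        if not (obj & nuc_mask).any():  # colabel is mandatory
            continue
        cy, cx = rp.centroid
        fid = _owning_fiber(bands, "roi_sc", cy, cx)
        if fid is None:
            continue
        counts[fid] += 1
        details.append(
            {
                "fiber": fid,
                "cell_x_um": cx * upp,
                "cell_y_um": cy * upp,
                "area_um2": rp.area * upp**2,
            }
        )
    return counts, details


# ---------------------------------------------------------------------------
# capillaries
# ---------------------------------------------------------------------------


def classify_capillaries(vessels: list[VesselObject]) -> list[CapillaryRecord]:
    """Keep endothelial objects small and round enough to be capillaries.

    Both bounds are inclusive: area ≤ 100 µm² and circularity ≥ 0.45.
    Larger or elongated objects stay "vessels" for the vascularization
    analysis but are not capillaries.
    """
    return [
        CapillaryRecord(
            label=v.label,
            centroid_um=v.centroid_um,
            area_um2=v.area_um2,
            circularity=v.circularity,
            feret_min_um=v.feret_min_um,
            feret_max_um=v.feret_max_um,
            intensity_mean=v.intensity_mean,
        )
        for v in vessels
        if v.area_um2 <= CAPILLARY_MAX_AREA_UM2 and v.circularity >= CAPILLARY_MIN_CIRCULARITY
    ]


def capillary_fiber_adjacency(
    capillaries: list[CapillaryRecord],
    vessel_labels: np.ndarray,
    bands: list[ROIBands],
) -> np.ndarray:
    """Boolean (capillary × fiber) matrix: capillary mask ∩ ``roi_cap`` ≥ 1 px.

    Sharing factors and capillary contacts are row and column sums of this
    one matrix, which makes their totals equal by construction.
    """
    adj = np.zeros((len(capillaries), len(bands)), dtype=bool)
    cap_index = {c.label: i for i, c in enumerate(capillaries)}
    for j, b in enumerate(bands):
        window = b.window(vessel_labels)
        present = np.unique(window[b.roi_cap[: window.shape[0], : window.shape[1]]])
        for lab in present:
            if lab in cap_index:
                adj[cap_index[lab], j] = True
    return adj


def sharing_factor(adjacency: np.ndarray) -> np.ndarray:
    """Number of fibers around each capillary (row sums)."""
    return adjacency.sum(axis=1).astype(int)


def capillary_contacts(adjacency: np.ndarray) -> np.ndarray:
    """Number of capillaries around each fiber (column sums)."""
    return adjacency.sum(axis=0).astype(int)


# ---------------------------------------------------------------------------
# fiber typing
# ---------------------------------------------------------------------------


def fiber_typing(
    bands: list[ROIBands],
    record: ImageRecord,
) -> tuple[TypingThresholds, dict[int, str], dict[int, dict]]:
    """Type every fiber from the myosin-heavy-chain channels present.

    Returns the thresholds (for GlobalResults), a fiber → label map, and the
    raw per-fiber per-channel mean intensities (for FiberDetails, so users
    can re-threshold manually).  Statistics are single-pass over all fibers.
    """
    present = [t for t in TYPE_ORDER if record.has_role(f"type_{t}")]
    if not present:
        raise ValueError("fiber typing requires at least one type channel")
    intensities: dict[int, dict] = {b.fiber_id: {} for b in bands}
    for t in present:
        ch = record.channel(f"type_{t}").astype(float)
        for b in bands:
            mean, _ = b.stats("roi_f", ch)
            intensities[b.fiber_id][t] = mean
    thresholds = TypingThresholds()
    for t in present:
        vals = np.array([intensities[b.fiber_id][t] for b in bands], dtype=float)
        mean = float(np.nanmean(vals)) if len(vals) else 0.0
        sd = float(np.nanstd(vals)) if len(vals) else 0.0
        rule = TYPE_RULES[t]
        thr = mean + sd if rule == "mean_plus_sd" else mean
        thresholds.per_channel[t] = {"mean": mean, "sd": sd, "threshold": thr, "rule": rule}
    labels: dict[int, str] = {}
    for b in bands:
        pos = [
            t
            for t in present
            if intensities[b.fiber_id][t] >= thresholds.per_channel[t]["threshold"]
        ]
        labels[b.fiber_id] = "-".join(pos) if pos else "undetermined"
    return thresholds, labels, intensities


# ---------------------------------------------------------------------------
# intensity by ROI
# ---------------------------------------------------------------------------


def fiber_intensity_by_roi(
    bands: list[ROIBands],
    record: ImageRecord,
    section_mask: SectionMask,
    threshold: float | None = None,
) -> tuple[dict[int, dict], dict]:
    """Mean intensity and % positive pixels per fiber for all five ROIs.

    The channel is background-subtracted (histogram mode) and a single
    per-image positivity threshold is derived from the residual histogram
    (triangle method) unless one is supplied.  Empty ROIs report NaN.
    Returns per-fiber results and the per-ROI global mean/SD summary.
    """
    if not record.has_role("intensity_target"):
        raise ValueError("intensity analysis requires an intensity_target channel")
    residual = subtract_background(record.channel("intensity_target"), section_mask.mask)
    if threshold is None:
        threshold = triangle_cut(residual, section_mask.mask)
    per_fiber: dict[int, dict] = {}
    for b in bands:
        row = {}
        win = b.window(residual)
        for name in ROI_NAMES:
            roi = getattr(b, name)[: win.shape[0], : win.shape[1]]
            n = int(roi.sum())
            if n == 0:
                row[f"{name}_intensity_mean"] = np.nan
                row[f"{name}_pct_positive"] = np.nan
                continue
            vals = win[roi]
            row[f"{name}_intensity_mean"] = float(vals.mean())
            if threshold is None:
                row[f"{name}_pct_positive"] = 0.0
            else:
                row[f"{name}_pct_positive"] = 100.0 * float((vals >= threshold).sum()) / n
        per_fiber[b.fiber_id] = row
    summary = {}
    for name in ROI_NAMES:
        means = np.array([per_fiber[b.fiber_id][f"{name}_intensity_mean"] for b in bands])
        valid = means[np.isfinite(means)]
        summary[f"{name}_intensity_mean"] = float(valid.mean()) if valid.size else np.nan
        summary[f"{name}_intensity_sd"] = float(valid.std(ddof=0)) if valid.size else np.nan
    summary["positivity_threshold"] = threshold
    return per_fiber, summary
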