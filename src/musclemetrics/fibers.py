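"""Fiber segmentation, shape morphometry, CSA filtering, and ROI bands.

Candidate fibers are the connected regions enclosed by the laminin boundary
network inside the section.  Each candidate carries polygon-based shape
measures (CSA, perimeter, circularity, min/max Feret); the pathophysiology
filter then keeps fibers with circularity in [0.45, 1] and CSA between a
fixed lower bound and ``mean + k·SD`` of all candidates — (100 µm², k=3)
for healthy muscle, (50 µm², k=4) for damaged muscle, where the fiber-size
distribution is much wider.  All comparisons are inclusive, so a uniform
population (SD = 0) is kept in full.

Each kept fiber is decomposed into five regions used by the downstream
analyses:

* ``roi_f``   — the fiber interior;
* ``roi_mb``  — the membrane band: the space inside the fiber within
  one-twentieth of the min Feret diameter of the boundary;
* ``roi_cnf`` — the central region used for centronucleation calls
  (interior eroded by max(2 µm, minFeret/10));
* ``roi_sc`` / ``roi_cap`` — thin bands outside the fiber where satellite
  cells and capillaries are looked up (3 µm outward by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import Polygon
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import approximate_polygon, find_contours
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

from ._primitives import feret_diameters
from .imgio import ImageRecord
from .section import SectionMask

#: (lower CSA bound µm², SD multiplier) per pathophysiology mode
FILTER_BOUNDS = {"Healthy": (100.0, 3.0), "Damaged": (50.0, 4.0)}
CIRCULARITY_MIN = 0.45
CIRCULARITY_MAX = 1.0
MEMBRANE_BAND_FRACTION = 1.0 / 20.0  # of min Feret diameter
CNF_MARGIN_MIN_UM = 2.0
CNF_MARGIN_FRACTION = 1.0 / 10.0
OUTER_BAND_UM = 3.0  # default width of roi_sc and roi_cap


@dataclass
class FiberROI:
    """One candidate fiber: its outline polygon (pixel coordinates, 0-based)
    and physical shape measures in µm."""

    id: int
    polygon: np.ndarray
    area_um2: float
    perimeter_um: float
    circularity: float
    feret_min_um: float
    feret_max_um: float
    centroid: tuple[float, float]  # µm


@dataclass
class ROIBands:
    """The five per-fiber regions, stored as masks on a cropped window.

    ``offset`` is the (row, col) of the window's top-left pixel in the full
    image; helper methods translate between the two frames.
    """

    fiber_id: int
    offset: tuple[int, int]
    roi_f: np.ndarray
    roi_cnf: np.ndarray
    roi_mb: np.ndarray
    roi_sc: np.ndarray
    roi_cap: np.ndarray

    def _local(self, row: float, col: float) -> tuple[int, int] | None:
        r, c = int(round(row)) - self.offset[0], int(round(col)) - self.offset[1]
        if 0 <= r < self.roi_f.shape[0] and 0 <= c < self.roi_f.shape[1]:
            return r, c
        return None

    def contains_point(self, which: str, row: float, col: float) -> bool:
        """Membership of a full-image (row, col) point in one of the bands."""
        loc = self._local(row, col)
        return bool(getattr(self, which)[loc]) if loc is not None else False

    def window(self, image: np.ndarray) -> np.ndarray:
        r0, c0 = self.offset
        h, w = self.roi_f.shape
        return image[r0 : r0 + h, c0 : c0 + w]

    def stats(self, which: str, image: np.ndarray) -> tuple[float, int]:
        """(mean intensity, pixel count) of a band over a full-frame image."""
        band = getattr(self, which)
        n = int(band.sum())
        if n == 0:
            return float("nan"), 0
        return float(self.window(image)[band].mean()), n


@dataclass
class FilterReport:
    mode: str
    csa_mean_um2: float
    csa_sd_um2: float
    lower_bound_um2: float
    upper_bound_um2: float
    kept_ids: list = field(default_factory=list)
    excluded_ids: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# shape measures
# ---------------------------------------------------------------------------


def shape_metrics(polygon: np.ndarray, um_per_px: float):
    """(area µm², perimeter µm, circularity, feret_min µm, feret_max µm).

    Area is the shoelace polygon area, perimeter the polygon arc length, and
    circularity ``4π·A/P²`` clipped to 1; Feret extremes come from rotating
    calipers on the convex hull.  Self-intersecting outlines are rejected.
    """
    pts = np.asarray(polygon, dtype=float)
    if len(pts) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    poly = Polygon(pts)
    if not poly.is_valid:
        raise ValueError("self-intersecting polygon")
    area = poly.area * um_per_px**2
    perim = poly.length * um_per_px
    circ = min(4.0 * np.pi * area / perim**2, 1.0) if perim > 0 else 1.0
    fmin, fmax = feret_diameters(pts)
    return area, perim, circ, fmin * um_per_px, fmax * um_per_px


def fiber_from_polygon(fid: int, polygon: np.ndarray, um_per_px: float) -> FiberROI:
    area, perim, circ, fmin, fmax = shape_metrics(polygon, um_per_px)
    cx, cy = np.asarray(Polygon(polygon).centroid.coords)[0]
    return FiberROI(
        id=fid,
        polygon=np.asarray(polygon, dtype=float),
        area_um2=area,
        perimeter_um=perim,
        circularity=circ,
        feret_min_um=fmin,
        feret_max_um=fmax,
        centroid=(cx * um_per_px, cy * um_per_px),
    )


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def _split_watershed(mask: np.ndarray) -> np.ndarray:
    """Distance-transform watershed of one region; deterministic tie-breaks
    come from scan-ordered peak labeling."""
    dist = ndi.distance_transform_edt(mask)
    min_dist = max(3, int(round(np.sqrt(mask.sum()) / 4)))
    peaks = peak_local_max(dist, min_distance=min_dist, labels=mask, exclude_border=False)
    if len(peaks) < 2:
        return mask.astype(np.int32)
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    return watershed(-dist, markers, mask=mask)


def _region_polygon(mask: np.ndarray, origin: tuple[int, int], tolerance: float = 0.75):
    """Trace the outer contour of a region crop into an (n, 2) x/y polygon."""
    padded = np.pad(mask, 1)
    contours = find_contours(padded.astype(float), 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)
    contour = approximate_polygon(contour, tolerance=tolerance)
    rows = contour[:, 0] - 1 + origin[0]
    cols = contour[:, 1] - 1 + origin[1]
    poly = np.stack([cols, rows], axis=1)
    if len(poly) > 1 and np.allclose(poly[0], poly[-1]):
        poly = poly[:-1]
    return poly if len(poly) >= 3 else None


def segment_fibers(
    record: ImageRecord,
    section_mask: SectionMask,
    min_area_um2: float = 30.0,
    convexity_deficiency_split: float = 0.2,
) -> list[FiberROI]:
    """Segment candidate fibers from the laminin boundary network.

    Chain: morphological background flattening → Gaussian σ=1 → Otsu on the
    boundary channel → candidate interiors are the non-boundary connected
    components inside the section.  Components whose convexity deficiency
    exceeds ``convexity_deficiency_split`` (fused neighbors) are split by a
    distance-transform watershed.  No randomness anywhere: identical input
    gives identical candidates.
    """
    if not record.has_role("laminin"):
        raise ValueError("segment_fibers requires a laminin channel")
    lam = record.channel("laminin").astype(float)
    upp = record.um_per_px

    background = ndi.grey_opening(lam, size=51)
    sub = np.clip(lam - background, 0, None)
    sm = gaussian(sub, sigma=1, preserve_range=True)
    inside = section_mask.mask
    if not inside.any():
        return []
    vals = sm[inside]
    if np.unique(vals).size < 2:
        return []
    boundary = sm >= threshold_otsu(vals)
    interior = inside & ~boundary

    min_px = max(4, int(round(min_area_um2 / upp**2)))
    lbl = sk_label(interior, connectivity=1)
    fibers: list[FiberROI] = []
    fid = 0
    for rp in regionprops(lbl):
        if rp.area < min_px:
            continue
        r0, c0, r1, c1 = rp.bbox
        crop = lbl[r0:r1, c0:c1] == rp.label
        deficiency = 1.0 - rp.area / rp.area_convex if rp.area_convex > 0 else 0.0
        pieces = _split_watershed(crop) if deficiency > convexity_deficiency_split else crop.astype(np.int32)
        for k in range(1, pieces.max() + 1):
            sub_mask = pieces == k
            if sub_mask.sum() < min_px:
                continue
            poly = _region_polygon(sub_mask, (r0, c0))
            if poly is None:
                continue
            try:
                fiber = fiber_from_polygon(fid, poly, upp)
            except ValueError:
                continue
            if fiber.area_um2 <= 0:
                continue
            fibers.append(fiber)
            fid += 1
    return fibers


# ---------------------------------------------------------------------------
# pathophysiology filter
# ---------------------------------------------------------------------------


def filter_fibers(candidates: list[FiberROI], mode: str = "Healthy") -> FilterReport:
    """Apply the CSA/circularity filter over the full candidate population.

    Mean and SD are taken over *all* candidates (population SD), then a
    candidate is kept iff its circularity lies in [0.45, 1] and its CSA in
    ``[lower, mean + k·SD]`` with inclusive bounds.  Excluded fibers stay
    available for cartography (rendered black there).
    """
    if mode not in FILTER_BOUNDS:
        raise ValueError(f"mode must be one of {sorted(FILTER_BOUNDS)}")
    if not candidates:
        raise ValueError("filter_fibers needs at least one candidate")
    lower, k = FILTER_BOUNDS[mode]
    areas = np.array([f.area_um2 for f in candidates])
    mean = float(areas.mean())
    sd = float(areas.std(ddof=0))
    upper = mean + k * sd
    report = FilterReport(
        mode=mode,
        csa_mean_um2=mean,
        csa_sd_um2=sd,
        lower_bound_um2=lower,
        upper_bound_um2=upper,
    )
    for f in candidates:
        ok = (
            CIRCULARITY_MIN <= f.circularity <= CIRCULARITY_MAX
            and lower <= f.area_um2 <= upper
        )
        (report.kept_ids if ok else report.excluded_ids).append(f.id)
    return report


# ---------------------------------------------------------------------------
# ROI bands
# ---------------------------------------------------------------------------


def derive_rois(
    fiber: FiberROI,
    image_shape: tuple[int, int],
    um_per_px: float,
    sc_band_um: float = OUTER_BAND_UM,
    cap_band_um: float = OUTER_BAND_UM,
) -> ROIBands:
    """Derive the five per-fiber regions from the fiber outline.

    Distances are Euclidean distance-transform values on the rasterized
    outline, so the membrane band is exactly the set of interior pixels
    within minFeret/20 of the boundary; the central region starts at
    max(2 µm, minFeret/10), strictly beyond the membrane band, and the two
    outer bands extend ``sc_band_um`` / ``cap_band_um`` outward.  A fiber
    too small for the central erosion simply yields an empty ``roi_cnf``.
    """
    from skimage.draw import polygon as draw_polygon

    poly = np.asarray(fiber.polygon, dtype=float)
    pad = int(np.ceil(max(sc_band_um, cap_band_um) / um_per_px)) + 2
    c0 = max(int(np.floor(poly[:, 0].min())) - pad, 0)
    r0 = max(int(np.floor(poly[:, 1].min())) - pad, 0)
    c1 = min(int(np.ceil(poly[:, 0].max())) + pad + 1, image_shape[1])
    r1 = min(int(np.ceil(poly[:, 1].max())) + pad + 1, image_shape[0])
    shape = (r1 - r0, c1 - c0)

    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_polygon(poly[:, 1] - r0, poly[:, 0] - c0, shape=shape)
    mask[rr, cc] = True

    dist_in = ndi.distance_transform_edt(mask) * um_per_px
    dist_out = ndi.distance_transform_edt(~mask) * um_per_px

    w_mb = MEMBRANE_BAND_FRACTION * fiber.feret_min_um
    w_cnf = max(CNF_MARGIN_MIN_UM, CNF_MARGIN_FRACTION * fiber.feret_min_um)
    return ROIBands(
        fiber_id=fiber.id,
        offset=(r0, c0),
        roi_f=mask,
        roi_mb=mask & (dist_in <= w_mb),
        roi_cnf=mask & (dist_in > w_cnf),
        roi_sc=~mask & (dist_out <= sc_band_um),
        roi_cap=~mask & (dist_out <= cap_band_um),
    )
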