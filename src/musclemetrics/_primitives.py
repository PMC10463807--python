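"""Shared low-level image primitives used by several analysis modules.

These are deliberately small, deterministic building blocks: histogram-mode
background estimation, auto-thresholding of residual signal, spot/blob
segmentation, and convex-hull Feret measures.  Nothing here depends on the
higher-level analysis modules, so both the per-section and per-fiber layers
can import from this module without cycles.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu, threshold_triangle
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.segmentation import watershed


def histogram_mode(values: np.ndarray, bins: int = 256) -> float:
    """Most frequent intensity, used as the background level.

    Integer arrays use an exact bincount; float arrays fall back to a
    ``bins``-bin histogram over the data range.
    """
    v = np.asarray(values).ravel()
    if v.size == 0:
        return 0.0
    if np.issubdtype(v.dtype, np.integer):
        return float(np.bincount(v.astype(np.int64)).argmax())
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return lo
    counts, edges = np.histogram(v, bins=bins, range=(lo, hi))
    i = int(counts.argmax())
    return float(0.5 * (edges[i] + edges[i + 1]))


def subtract_background(channel: np.ndarray, within: np.ndarray | None = None) -> np.ndarray:
    """Subtract the histogram-mode background level, clipping at zero."""
    ch = np.asarray(channel, dtype=float)
    sel = ch[within] if within is not None and within.any() else ch
    return np.clip(ch - histogram_mode(sel), 0.0, None)


def triangle_cut(residual: np.ndarray, within: np.ndarray | None = None) -> float | None:
    """Triangle auto-threshold on background-subtracted signal.

    Returns ``None`` when the residual carries no signal at all (constant
    image), which callers treat as an empty foreground.
    """
    vals = residual[within] if within is not None else residual
    vals = np.asarray(vals, dtype=float).ravel()
    if vals.size == 0 or float(vals.max()) <= 0.0:
        return None
    if np.unique(vals).size < 2:
        return None
    return float(threshold_triangle(vals))


def otsu_cut(values: np.ndarray) -> float | None:
    vals = np.asarray(values, dtype=float).ravel()
    if vals.size == 0 or np.unique(vals).size < 2:
        return None
    return float(threshold_otsu(vals))


def segment_blobs(
    channel: np.ndarray,
    within: np.ndarray,
    min_area_px: int = 4,
    threshold: str = "triangle",
) -> np.ndarray:
    """Generic marker-blob segmentation: mode background subtraction,
    auto-threshold, connected components restricted to ``within``.

    Returns an int label image (0 = background).  No shape prior is applied.
    """
    residual = subtract_background(channel, within)
    if threshold == "triangle":
        cut = triangle_cut(residual, within)
    else:
        cut = otsu_cut(residual[within])
    if cut is None or cut <= 0:
        return np.zeros(channel.shape, dtype=np.int32)
    mask = (residual >= cut) & within
    lbl = sk_label(mask, connectivity=1)
    if min_area_px > 1 and lbl.max() > 0:
        counts = np.bincount(lbl.ravel())
        small = np.flatnonzero(counts < min_area_px)
        if small.size:
            lbl[np.isin(lbl, small)] = 0
        lbl, _, _ = relabel_sequential(lbl)
    return lbl


def relabel_sequential(lbl: np.ndarray):
    from skimage.segmentation import relabel_sequential as _rs

    return _rs(lbl)


def segment_nuclei_mask(
    dna: np.ndarray,
    within: np.ndarray,
    um_per_px: float,
    min_area_px: int = 4,
    split_distance_um: float = 2.0,
) -> np.ndarray:
    """Segment DNA spots and split touching nuclei.

    Otsu threshold on the background-subtracted DNA channel, hole filling,
    then a distance-transform watershed seeded at local maxima at least
    ``split_distance_um`` apart; ties are resolved by scan order so the
    result is deterministic.  Returns an int label image.
    """
    residual = subtract_background(dna, within)
    cut = otsu_cut(residual[within]) if within.any() else None
    if cut is None or cut <= 0:
        return np.zeros(dna.shape, dtype=np.int32)
    mask = (residual >= cut) & within
    if not mask.any():
        return np.zeros(dna.shape, dtype=np.int32)
    mask = ndi.binary_fill_holes(mask)
    dist = ndi.distance_transform_edt(mask)
    min_dist = max(2, int(round(split_distance_um / um_per_px)))
    peaks = peak_local_max(dist, min_distance=min_dist, labels=mask, exclude_border=False)
    if len(peaks) == 0:
        lbl = sk_label(mask, connectivity=1)
    else:
        markers = np.zeros(mask.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        lbl = watershed(-dist, markers, mask=mask)
    if min_area_px > 1 and lbl.max() > 0:
        counts = np.bincount(lbl.ravel())
        small = np.flatnonzero(counts < min_area_px)
        if small.size:
            lbl[np.isin(lbl, small)] = 0
    lbl, _, _ = relabel_sequential(lbl)
    return lbl.astype(np.int32)


def feret_diameters(points: np.ndarray) -> tuple[float, float]:
    """Min and max Feret (caliper) diameters of a point set, in the input
    units, via rotating calipers on the convex hull.

    ``feret_max`` is the largest pairwise hull distance; ``feret_min`` is the
    smallest width over hull-edge directions.
    """
    from scipy.spatial import ConvexHull

    pts = np.asarray(points, dtype=float)
    pts = np.unique(pts, axis=0)
    if len(pts) == 1:
        return 0.0, 0.0
    if len(pts) == 2 or np.linalg.matrix_rank(pts - pts[0]) < 2:
        d = np.linalg.norm(pts.max(axis=0) - pts.min(axis=0))
        return 0.0, float(d)
    hull = ConvexHull(pts)
    hp = pts[hull.vertices]
    diffs = hp[:, None, :] - hp[None, :, :]
    feret_max = float(np.sqrt((diffs**2).sum(-1)).max())
    edges = np.roll(hp, -1, axis=0) - hp
    lengths = np.linalg.norm(edges, axis=1)
    keep = lengths > 0
    normals = np.stack([-edges[keep][:, 1], edges[keep][:, 0]], axis=1) / lengths[keep, None]
    proj = hp @ normals.T  # (nverts, nedges)
    widths = proj.max(axis=0) - proj.min(axis=0)
    feret_min = float(widths.min())
    return feret_min, feret_max


def object_measurements(lbl: np.ndarray, intensity: np.ndarray, um_per_px: float) -> list[dict]:
    """Area/shape/intensity measures per labeled object, in physical units."""
    out = []
    for rp in regionprops(lbl, intensity_image=intensity):
        area = rp.area * um_per_px**2
        perim = rp.perimeter * um_per_px
        circ = 4.0 * np.pi * area / perim**2 if perim > 0 else 1.0
        fmin, fmax = feret_diameters(rp.coords[:, ::-1].astype(float))
        cy, cx = rp.centroid
        out.append(
            {
                "label": rp.label,
                "area_um2": float(area),
                "circularity": float(min(circ, 1.0)),
                "feret_min_um": fmin * um_per_px,
                "feret_max_um": fmax * um_per_px,
                "centroid_x_um": float(cx * um_per_px),
                "centroid_y_um": float(cy * um_per_px),
                "intensity_mean": float(rp.intensity_mean),
            }
        )
    return out


def polygon_mask(polygon_px: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize an (n, 2) array of (x, y) pixel vertices into a bool mask."""
    from skimage.draw import polygon as draw_polygon

    poly = np.asarray(polygon_px, dtype=float)
    rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask
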