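"""Synthetic muscle-section phantoms with exhaustive ground truth.

The generator emulates a transverse immunofluorescence section of skeletal
muscle: a roughly circular piece of tissue tiled by polygonal fibers
(Poisson-disc seeds + Voronoi tessellation), a bright extracellular-matrix
lattice along the fiber boundaries (the laminin/WGA compartment), DAPI-like
nuclear spots in central / peripheral / interstitial positions, small round
capillary profiles at fiber junctions, irregular marker-positive cells in
the interstitium, myosin-heavy-chain type channels, and a membrane-localized
staining channel (dystrophin-like).  Every placed object is recorded in a
:class:`PhantomGroundTruth`, so each analysis stage of the package can be
tested for parameter recovery without any real data.

Determinism: for a fixed :class:`PhantomSpec` (which includes the seed) the
generator is a pure function — repeated calls return bit-identical pixel
arrays and ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import Voronoi
from shapely.geometry import MultiPolygon, Point, Polygon
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .imgio import ImageRecord, write_image

FULL_SCALE = 65535.0
BACKGROUND = 0.05 * FULL_SCALE  # base level of every channel, 16-bit scale
FOREGROUND = 0.60 * FULL_SCALE
NUCLEUS_SIGMA_UM = 2.0
NUCLEUS_AMPLITUDE = 0.50 * FULL_SCALE
CAPILLARY_RADIUS_UM = 2.0
CAPILLARY_ADJACENCY_UM = 3.0  # matches the default outer capillary band
PERI_NUCLEUS_DEPTH_UM = 1.5
MIN_FIBER_SPACING_UM = 8.0  # adult fibers are never thinner than this
MYONUCLEI_SPOT_RADIUS_UM = 2.5
MEMBRANE_RING_UM = 2.0

FIBER_TYPES = ("I", "IIA", "IIB", "IIX")

#: channel layout of every generated phantom
PHANTOM_CHANNELS = {
    "laminin": 0,
    "dna": 1,
    "type_I": 2,
    "type_IIA": 3,
    "type_IIB": 4,
    "type_IIX": 5,
    "endothelial": 6,
    "cell_marker": 7,
    "myonuclei_marker": 8,
    "intensity_target": 9,
}


class PhantomPlacementError(RuntimeError):
    """Raised when the requested objects cannot be placed on the canvas."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic section.

    Defaults describe a small but realistic mouse-limb field of view:
    ~40 fibers of mixed type at 1 µm/px, one central nucleus in 20% of
    fibers, four peripheral myonuclei per fiber, capillaries apposed to
    the fiber junctions, and a thin endomysial ECM lattice covering 8%
    of the section.
    """

    width_px: int = 512
    height_px: int = 512
    um_per_px: float = 1.0
    n_fibers: int = 40
    boundary_width_um: float = 4.0
    type_fractions: dict = field(
        default_factory=lambda: {"I": 0.3, "IIA": 0.3, "IIB": 0.2, "IIX": 0.15, "hybrid": 0.05}
    )
    centro_fraction: float = 0.2
    peri_nuclei_per_fiber: int = 4
    n_capillaries: int = 30
    n_specific_cells: int = 10
    ecm_fraction_target: float | None = 0.08
    specific_nucleus_fraction: float = 0.7
    noise_sd: float = 150.0
    annular_section: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be > 0")
        for name in ("n_fibers", "peri_nuclei_per_fiber", "n_capillaries", "n_specific_cells"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("centro_fraction", "specific_nucleus_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.ecm_fraction_target is not None and not 0.0 < self.ecm_fraction_target < 1.0:
            raise ValueError("ecm_fraction_target must be in (0, 1)")
        bad_keys = set(self.type_fractions) - set(FIBER_TYPES) - {"hybrid"}
        if bad_keys:
            raise ValueError(f"unknown fiber types: {sorted(bad_keys)}")
        vals = list(self.type_fractions.values())
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ValueError("type fractions must be in [0, 1]")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError("type_fractions must sum to 1")


@dataclass
class PhantomGroundTruth:
    """Exact record of everything the generator placed.

    Coordinates are in µm with the origin at the image's top-left corner
    (x along columns, y along rows).  ``nucleus_centers`` rows are
    ``(x, y, class, fiber_index)`` with class in
    ``{central, peripheral, interstitial}`` and fiber index ``-1`` for
    interstitial nuclei.  ``specific_cell_masks`` entries hold the blob's
    pixel coordinates (row, col) and whether a DNA spot was planted on it.
    """

    fiber_polygons: list
    fiber_types: list
    nucleus_centers: list
    capillary_centers: list
    capillary_adjacent: list
    specific_cell_masks: list
    ecm_mask: np.ndarray
    section_polygon: Polygon


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _section_polygon(spec: PhantomSpec) -> Polygon:
    r = 0.45 * min(spec.width_px, spec.height_px) * spec.um_per_px
    cx = 0.5 * spec.width_px * spec.um_per_px
    cy = 0.5 * spec.height_px * spec.um_per_px
    disc = Point(cx, cy).buffer(r, quad_segs=24)
    if spec.annular_section:
        return disc.difference(Point(cx, cy).buffer(0.5 * r, quad_segs=24))
    return disc


def _poisson_disc(rng: np.random.Generator, region: Polygon, n: int, radius: float) -> np.ndarray:
    """Dart-throwing Poisson-disc sampling of ``n`` seeds inside ``region``."""
    minx, miny, maxx, maxy = region.bounds
    pts: list[tuple[float, float]] = []
    attempts = 0
    budget = 400 * max(n, 1)
    while len(pts) < n:
        if attempts >= budget:
            raise PhantomPlacementError(
                f"cannot place fibers: {len(pts)}/{n} seeds at Poisson radius "
                f"{radius:.1f} µm"
            )
        attempts += 1
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if not region.contains(Point(x, y)):
            continue
        if pts:
            d2 = np.min((np.array(pts) - (x, y)) ** 2 @ np.ones(2))
            if d2 < radius * radius:
                continue
        pts.append((x, y))
    return np.asarray(pts)


def _largest_polygon(geom) -> Polygon:
    if isinstance(geom, MultiPolygon):
        return max(geom.geoms, key=lambda g: g.area)
    return geom


def _voronoi_cells(seeds: np.ndarray, section: Polygon) -> list[Polygon]:
    """Bounded Voronoi cells of the seeds, clipped to the section."""
    cx, cy = section.centroid.x, section.centroid.y
    span = max(section.bounds[2] - section.bounds[0], section.bounds[3] - section.bounds[1])
    ang = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    ghosts = np.stack([cx + 3 * span * np.cos(ang), cy + 3 * span * np.sin(ang)], axis=1)
    vor = Voronoi(np.vstack([seeds, ghosts]))
    cells = []
    for i in range(len(seeds)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:
            raise PhantomPlacementError("unbounded Voronoi cell (seed outside ghost ring)")
        cell = Polygon(vor.vertices[region]).intersection(section)
        cells.append(_largest_polygon(cell))
    return cells, vor


def _fiber_polygons(cells: list[Polygon], section: Polygon, spec: PhantomSpec) -> tuple[list[Polygon], float]:
    """Shrink each Voronoi cell to leave an ECM lattice between fibers.

    The half-width of the negative buffer is calibrated by bisection so the
    polygonal ECM fraction matches ``ecm_fraction_target``; with no target,
    ``boundary_width_um`` is used directly.
    """

    def shrunk(w: float) -> list[Polygon]:
        return [_largest_polygon(c.buffer(-0.5 * w)) for c in cells]

    def ecm_fraction(w: float) -> float:
        return 1.0 - sum(p.area for p in shrunk(w)) / section.area

    if spec.ecm_fraction_target is None:
        width = spec.boundary_width_um
    else:
        lo, hi = 0.05, 30.0
        target = spec.ecm_fraction_target
        for _ in range(48):
            mid = 0.5 * (lo + hi)
            if ecm_fraction(mid) < target:
                lo = mid
            else:
                hi = mid
        width = 0.5 * (lo + hi)
    polys = shrunk(width)
    if any(p.is_empty or p.area <= 0 for p in polys):
        raise PhantomPlacementError("cannot place fibers: ECM band annihilates a fiber")
    return polys, width


def _poly_mask(poly, shape: tuple[int, int], upp: float) -> np.ndarray:
    """Rasterize a shapely polygon given in µm into a boolean pixel mask."""
    mask = np.zeros(shape, dtype=bool)
    geoms = poly.geoms if isinstance(poly, MultiPolygon) else [poly]
    for g in geoms:
        if g.is_empty:
            continue
        ext = np.asarray(g.exterior.coords)
        rr, cc = draw_polygon(ext[:, 1] / upp, ext[:, 0] / upp, shape=shape)
        mask[rr, cc] = True
        for ring in g.interiors:
            hole = np.asarray(ring.coords)
            rr, cc = draw_polygon(hole[:, 1] / upp, hole[:, 0] / upp, shape=shape)
            mask[rr, cc] = False
    return mask


def _allocate_types(rng: np.random.Generator, spec: PhantomSpec) -> list[str]:
    """Exact per-type counts by largest remainder, shuffled, hybrids paired."""
    names = [t for t in (*FIBER_TYPES, "hybrid") if spec.type_fractions.get(t, 0) > 0]
    fracs = np.array([spec.type_fractions[t] for t in names])
    n = spec.n_fibers
    counts = np.floor(fracs * n).astype(int)
    remainder = fracs * n - counts
    for i in np.argsort(-remainder, kind="stable")[: n - counts.sum()]:
        counts[i] += 1
    labels: list[str] = []
    for name, c in zip(names, counts):
        for _ in range(c):
            if name == "hybrid":
                pair = sorted(rng.choice(len(FIBER_TYPES), size=2, replace=False))
                labels.append("-".join(FIBER_TYPES[i] for i in pair))
            else:
                labels.append(name)
    order = rng.permutation(n)
    return [labels[i] for i in order]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_phantom(spec: PhantomSpec) -> tuple[ImageRecord, PhantomGroundTruth]:
    """Generate one phantom image and its exhaustive ground truth."""
    rng = np.random.default_rng(spec.seed)
    upp = spec.um_per_px
    shape = (spec.height_px, spec.width_px)
    section = _section_polygon(spec)

    # fiber mosaic
    radius = max(0.6 * math.sqrt(section.area / max(spec.n_fibers, 1)), MIN_FIBER_SPACING_UM)
    seed_region = section.buffer(-min(2.0, 0.45 * radius))
    seeds = _poisson_disc(rng, seed_region, spec.n_fibers, radius)
    cells, vor = _voronoi_cells(seeds, section) if spec.n_fibers else ([], None)
    fibers, _band_w = _fiber_polygons(cells, section, spec) if cells else ([], 0.0)

    fiber_types = _allocate_types(rng, spec) if spec.n_fibers else []

    # nuclei: central (exact count), peripheral, interstitial added later
    nuclei: list[tuple[float, float, str, int]] = []
    n_central = int(round(spec.centro_fraction * spec.n_fibers))
    central_ids = set()
    if n_central:
        central_ids = set(int(i) for i in rng.choice(spec.n_fibers, n_central, replace=False))
    for i in sorted(central_ids):
        c = fibers[i].centroid
        nuclei.append((c.x, c.y, "central", i))
    # nuclei of real fibers do not overlap: keep a minimum spacing so DNA
    # spots stay resolvable
    min_spacing = 2.5 * NUCLEUS_SIGMA_UM
    placed = [np.array([x, y]) for x, y, _c, _f in nuclei]
    for i, poly in enumerate(fibers):
        ring_poly = poly.buffer(-PERI_NUCLEUS_DEPTH_UM)
        if ring_poly.is_empty:
            continue
        ring = _largest_polygon(ring_poly).exterior
        for _ in range(spec.peri_nuclei_per_fiber):
            for _try in range(30):
                p = ring.interpolate(rng.uniform(0.0, ring.length))
                if not placed or min(
                    float(np.hypot(*(q - (p.x, p.y)))) for q in placed
                ) >= min_spacing:
                    break
            placed.append(np.array([p.x, p.y]))
            nuclei.append((p.x, p.y, "peripheral", i))

    # capillaries at fiber junctions (Voronoi vertices of the kept cells)
    cap_centers: list[tuple[float, float]] = []
    cap_adjacent: list[set[int]] = []
    if spec.n_capillaries:
        vidx = sorted(
            {v for i in range(spec.n_fibers) for v in vor.regions[vor.point_region[i]] if v != -1}
        )
        inner = section.buffer(-2.0)
        candidates = [tuple(vor.vertices[v]) for v in vidx if inner.contains(Point(*vor.vertices[v]))]
        if len(candidates) < spec.n_capillaries:
            raise PhantomPlacementError(
                f"cannot place capillaries: {len(candidates)} junctions < "
                f"{spec.n_capillaries} requested"
            )
        chosen = rng.choice(len(candidates), spec.n_capillaries, replace=False)
        reach = CAPILLARY_ADJACENCY_UM + CAPILLARY_RADIUS_UM
        for k in sorted(int(c) for c in chosen):
            pt = Point(*candidates[k])
            cap_centers.append((pt.x, pt.y))
            cap_adjacent.append({i for i, f in enumerate(fibers) if f.distance(pt) <= reach})

    # rasters
    label_img = np.zeros(shape, dtype=np.int32)
    for i, poly in enumerate(fibers):
        label_img[_poly_mask(poly, shape, upp)] = i + 1
    section_raster = _poly_mask(section, shape, upp)
    ecm_mask = section_raster & (label_img == 0)

    # specific cells: irregular blobs living in the ECM compartment
    cell_masks: list[dict] = []
    ecm_pix = np.argwhere(ecm_mask)
    if spec.n_specific_cells:
        if len(ecm_pix) == 0:
            raise PhantomPlacementError("cannot place specific cells: no ECM pixels")
        n_with = math.ceil(spec.specific_nucleus_fraction * spec.n_specific_cells)
        nuc_xy = np.array([[x, y] for x, y, _c, _f in nuclei]) if nuclei else np.empty((0, 2))
        for j in range(spec.n_specific_cells):
            # stay clear of planted nuclei so the has_nucleus flag reflects
            # actual DNA overlap, not the skirt of a neighboring myonucleus
            for _try in range(200):
                r0, c0 = ecm_pix[int(rng.integers(0, len(ecm_pix)))]
                xy = np.array([c0 * upp, r0 * upp])
                if len(nuc_xy) == 0 or np.hypot(*(nuc_xy - xy).T).min() >= 8.0:
                    break
            blob = np.zeros(shape, dtype=bool)
            centers = [(float(r0), float(c0))]
            centers += [
                (r0 + rng.normal(0, 1.5 / upp), c0 + rng.normal(0, 1.5 / upp)) for _ in range(2)
            ]
            for rc in centers:
                rad = rng.uniform(1.5, 2.5) / upp
                rr, cc = draw_disk(rc, max(rad, 1.0), shape=shape)
                blob[rr, cc] = True
            pix = np.argwhere(blob)
            has_nucleus = j < n_with
            cell_masks.append({"pixels": pix, "has_nucleus": has_nucleus})
            if has_nucleus:
                cy, cx = pix.mean(axis=0)
                nuclei.append((cx * upp, cy * upp, "interstitial", -1))

    record = _render(spec, rng, label_img, ecm_mask, fibers, fiber_types, nuclei, cap_centers, cell_masks)
    truth = PhantomGroundTruth(
        fiber_polygons=[np.asarray(p.exterior.coords) for p in fibers],
        fiber_types=fiber_types,
        nucleus_centers=nuclei,
        capillary_centers=cap_centers,
        capillary_adjacent=cap_adjacent,
        specific_cell_masks=cell_masks,
        ecm_mask=ecm_mask,
        section_polygon=section,
    )
    return record, truth


def _render(spec, rng, label_img, ecm_mask, fibers, fiber_types, nuclei, cap_centers, cell_masks):
    upp = spec.um_per_px
    shape = ecm_mask.shape
    img = np.full((len(PHANTOM_CHANNELS), *shape), BACKGROUND, dtype=float)

    img[PHANTOM_CHANNELS["laminin"]][ecm_mask] = FOREGROUND

    # DNA: Gaussian spots, rendered by filtering a delta image once
    sigma_px = NUCLEUS_SIGMA_UM / upp
    deltas = np.zeros(shape)
    gain = NUCLEUS_AMPLITUDE * 2 * np.pi * sigma_px**2
    for x, y, _cls, _fid in nuclei:
        r, c = int(round(y / upp)), int(round(x / upp))
        if 0 <= r < shape[0] and 0 <= c < shape[1]:
            deltas[r, c] += gain
    img[PHANTOM_CHANNELS["dna"]] += ndi.gaussian_filter(deltas, sigma_px)

    for i, label in enumerate(fiber_types):
        for t in label.split("-"):
            img[PHANTOM_CHANNELS[f"type_{t}"]][label_img == i + 1] = FOREGROUND

    ch = img[PHANTOM_CHANNELS["endothelial"]]
    for x, y in cap_centers:
        rr, cc = draw_disk((y / upp, x / upp), max(CAPILLARY_RADIUS_UM / upp, 1.0), shape=shape)
        ch[rr, cc] = FOREGROUND

    ch = img[PHANTOM_CHANNELS["cell_marker"]]
    for blob in cell_masks:
        ch[tuple(blob["pixels"].T)] = FOREGROUND

    ch = img[PHANTOM_CHANNELS["myonuclei_marker"]]
    for x, y, cls, _fid in nuclei:
        if cls in ("central", "peripheral"):
            rr, cc = draw_disk((y / upp, x / upp), MYONUCLEI_SPOT_RADIUS_UM / upp, shape=shape)
            ch[rr, cc] = FOREGROUND

    # membrane-localized stain: bright ring just inside each fiber boundary
    ch = img[PHANTOM_CHANNELS["intensity_target"]]
    for i, poly in enumerate(fibers):
        inner = poly.buffer(-MEMBRANE_RING_UM)
        ring = (label_img == i + 1) & ~_poly_mask(inner, shape, upp)
        ch[ring] = FOREGROUND

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)
    pixels = np.clip(img, 0, FULL_SCALE).astype(np.uint16)

    roles = dict(PHANTOM_CHANNELS)
    roles["section_shape"] = PHANTOM_CHANNELS["laminin"]
    roles["cartography_base"] = PHANTOM_CHANNELS["laminin"]
    return ImageRecord(pixels=pixels, um_per_px=upp, channel_roles=roles, source_path="<phantom>")


def rasterize_truth(truth: PhantomGroundTruth, spec: PhantomSpec) -> np.ndarray:
    """Integer label image of the ground-truth fiber interiors.

    Pixel value ``k > 0`` marks the interior of fiber ``k - 1`` (list order);
    used as the segmentation oracle in tests.
    """
    shape = (spec.height_px, spec.width_px)
    label_img = np.zeros(shape, dtype=np.int32)
    for i, poly in enumerate(truth.fiber_polygons):
        poly = np.asarray(poly)
        rr, cc = draw_polygon(poly[:, 1] / spec.um_per_px, poly[:, 0] / spec.um_per_px, shape=shape)
        label_img[rr, cc] = i + 1
    return label_img


# ---------------------------------------------------------------------------
# parametric test shapes
# ---------------------------------------------------------------------------


def disc_polygon(area_um2: float, n_vertices: int = 256, center=(0.0, 0.0)) -> np.ndarray:
    """Regular ``n_vertices``-gon scaled so its polygon area is exactly
    ``area_um2``; a near-perfect disc for boundary sweeps."""
    ang = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    unit = np.stack([np.cos(ang), np.sin(ang)], axis=1)
    x, y = unit[:, 0], unit[:, 1]
    poly_area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    r = math.sqrt(area_um2 / poly_area)
    return unit * r + np.asarray(center)


def _poly_circularity(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    perim = float(np.hypot(*(np.roll(poly, -1, axis=0) - poly).T).sum())
    return min(4 * np.pi * area / perim**2, 1.0)


def ellipse_polygon(
    circularity: float,
    area_um2: float,
    n_vertices: int = 256,
    center=(0.0, 0.0),
    tol: float = 1e-9,
) -> np.ndarray:
    """Elliptical polygon with a prescribed circularity and area.

    The aspect ratio is found by bisection (polygon circularity decreases
    monotonically with elongation), then the shape is scaled to the exact
    target area.  Feasible targets are bounded above by the circularity of
    the regular ``n_vertices``-gon (≈1 for the default 256).
    """
    ang = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)

    def shape(q: float) -> np.ndarray:
        return np.stack([np.cos(ang), q * np.sin(ang)], axis=1)

    if circularity > _poly_circularity(shape(1.0)):
        raise ValueError("target circularity above the polygonal maximum")
    lo, hi = 1e-5, 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _poly_circularity(shape(mid)) < circularity:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * 1e-3:
            break
    # keep the upper bracket: the result never undershoots the target
    poly = shape(hi)
    x, y = poly[:, 0], poly[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return poly * math.sqrt(area_um2 / area) + np.asarray(center)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def write_phantom(record: ImageRecord, truth: PhantomGroundTruth, spec: PhantomSpec, out_dir, name="phantom"):
    """Write the phantom as OME-TIFF plus a JSON ground-truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img_path = out_dir / f"{name}.ome.tif"
    write_image(record, img_path)
    sidecar = {
        "spec": {k: (v if not isinstance(v, dict) else dict(v)) for k, v in vars(spec).items()},
        "fiber_types": truth.fiber_types,
        "fiber_polygons": [np.asarray(p).tolist() for p in truth.fiber_polygons],
        "nucleus_centers": [[x, y, cls, fid] for x, y, cls, fid in truth.nucleus_centers],
        "capillary_centers": [list(c) for c in truth.capillary_centers],
        "capillary_adjacent": [sorted(s) for s in truth.capillary_adjacent],
        "specific_cells": [
            {"pixels": b["pixels"].tolist(), "has_nucleus": bool(b["has_nucleus"])}
            for b in truth.specific_cell_masks
        ],
    }
    json_path = out_dir / f"{name}_truth.json"
    json_path.write_text(json.dumps(sidecar), encoding="utf-8")
    return str(img_path), str(json_path)
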