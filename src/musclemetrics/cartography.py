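"""Result cartographies: false-color maps of the section per analysis.

Kept fibers are filled with a class color (typing) or a continuous
viridis ramp (morphology/intensity); excluded fibers are filled black;
point objects (capillaries, cells, nuclei) are drawn as small symbols at
their gravity centers.  A legend box scaled to the image, a physical scale
bar (300 µm on whole sections, 100 µm on crops, off by default), and a
3-per-row titled montage complete the panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from matplotlib import colormaps
from PIL import Image, ImageDraw, ImageFont
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .fibers import FiberROI

FEATURES = (
    "fiber_morphology",
    "centro_myonuclei",
    "peri_myonuclei",
    "satellite_cells",
    "capillaries",
    "fiber_type",
    "fiber_intensity",
    "specific_cells",
    "ecm_signal",
)

SCALEBAR_WHOLE_UM = 300.0
SCALEBAR_CROP_UM = 100.0
SCALEBAR_POSITIONS = ("none", "lower_right", "lower_left", "upper_right", "upper_left")
MONTAGE_COLS = 3
LEGEND_WIDTH_FRACTION = 0.15
TITLE_HEIGHT_FRACTION = 0.03

#: fixed categorical palette for fiber types (RGB, 0-255)
TYPE_COLORS = {
    "I": (214, 39, 40),
    "IIA": (44, 160, 44),
    "IIB": (31, 119, 180),
    "IIX": (255, 127, 14),
    "undetermined": (128, 128, 128),
}
EXCLUDED_COLOR = (0, 0, 0)


@dataclass
class CartographySpec:
    feature: str
    base_channel: np.ndarray | None = None
    legend: bool = True
    scalebar_position: str = "none"
    is_crop: bool = False

    def __post_init__(self):
        if self.feature not in FEATURES:
            raise ValueError(f"unknown cartography feature {self.feature!r}")
        if self.scalebar_position not in SCALEBAR_POSITIONS:
            raise ValueError(f"unknown scale-bar position {self.scalebar_position!r}")


@dataclass
class Montage:
    image: np.ndarray
    grid: tuple[int, int]  # rows, cols
    panels: list = field(default_factory=list)


def _hybrid_color(label: str) -> tuple[int, int, int]:
    parts = label.split("-")
    cols = np.array([TYPE_COLORS.get(p, (128, 128, 128)) for p in parts], dtype=float)
    return tuple(int(v) for v in cols.mean(axis=0))


def class_color(label: str) -> tuple[int, int, int]:
    if label in TYPE_COLORS:
        return TYPE_COLORS[label]
    if "-" in label:
        return _hybrid_color(label)
    return (128, 128, 128)


def _continuous_colors(values: dict[int, float]) -> dict[int, tuple[int, int, int]]:
    cmap = colormaps["viridis"]
    finite = [v for v in values.values() if v is not None and np.isfinite(v)]
    lo = min(finite) if finite else 0.0
    hi = max(finite) if finite else 1.0
    span = hi - lo if hi > lo else 1.0
    out = {}
    for k, v in values.items():
        if v is None or not np.isfinite(v):
            out[k] = (80, 80, 80)
        else:
            r, g, b, _ = cmap((v - lo) / span)
            out[k] = (int(255 * r), int(255 * g), int(255 * b))
    return out


def render_map(
    spec: CartographySpec,
    image_shape: tuple[int, int],
    fibers: list[FiberROI] | None = None,
    kept_ids: set | None = None,
    values: dict[int, float] | None = None,
    class_labels: dict[int, str] | None = None,
    markers: list[tuple[float, float]] | None = None,
    overlay_mask: np.ndarray | None = None,
    um_per_px: float = 1.0,
) -> np.ndarray:
    """Render one cartography as an RGB uint8 array.

    ``values`` drives a continuous ramp, ``class_labels`` a categorical
    fill; fibers not in ``kept_ids`` are painted black.  ``markers`` are
    (row, col) pixel positions drawn as small discs; ``overlay_mask`` (for
    ECM/vessel surface features) is painted in a fixed accent color.
    """
    h, w = image_shape
    if spec.base_channel is not None:
        base = spec.base_channel.astype(float)
        base = (base - base.min()) / (np.ptp(base) + 1e-12)
        rgb = np.stack([(base * 120).astype(np.uint8)] * 3, axis=-1)
    else:
        rgb = np.zeros((h, w, 3), dtype=np.uint8)

    fibers = fibers or []
    kept = set(kept_ids) if kept_ids is not None else {f.id for f in fibers}
    colors: dict[int, tuple[int, int, int]] = {}
    if class_labels is not None:
        colors = {fid: class_color(lbl) for fid, lbl in class_labels.items()}
    elif values is not None:
        colors = _continuous_colors(values)
    for f in fibers:
        poly = np.asarray(f.polygon)
        rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=(h, w))
        color = colors.get(f.id, (60, 120, 60)) if f.id in kept else EXCLUDED_COLOR
        rgb[rr, cc] = color
    if overlay_mask is not None:
        rgb[overlay_mask] = (0, 200, 80)
    if markers:
        radius = max(2, int(round(2.0 / um_per_px)))
        for row, col in markers:
            rr, cc = draw_disk((row, col), radius, shape=(h, w))
            rgb[rr, cc] = (255, 60, 60)
    return rgb


def _font(size: int):
    try:
        return ImageFont.load_default(size=size)
    except TypeError:  # older Pillow
        return ImageFont.load_default()


def render_legend(
    spec: CartographySpec,
    present_classes: list[str],
    image_size: tuple[int, int],
) -> np.ndarray:
    """Legend box as an RGB array, proportional to the image size.

    Width is 15% of the image width; row height scales with image height.
    Only the classes (including hybrids) actually present appear.
    """
    h, w = image_size
    box_w = max(40, int(LEGEND_WIDTH_FRACTION * w))
    row_h = max(12, int(0.04 * h))
    box_h = row_h * (len(present_classes) + 1)
    img = Image.new("RGB", (box_w, box_h), (255, 255, 255))
    draw = ImageDraw.Draw(img)
    font = _font(max(8, int(0.6 * row_h)))
    draw.text((4, 2), spec.feature, fill=(0, 0, 0), font=font)
    for i, cls in enumerate(present_classes):
        y = row_h * (i + 1)
        draw.rectangle([4, y + 2, 4 + row_h - 4, y + row_h - 2], fill=class_color(cls))
        draw.text((row_h + 4, y + 2), cls, fill=(0, 0, 0), font=font)
    return np.asarray(img)


def draw_scale_bar(
    image: np.ndarray,
    um_per_px: float,
    position: str = "none",
    is_crop: bool = False,
) -> np.ndarray:
    """Overlay the fixed-length scale bar; ``position='none'`` is a no-op.

    Bar length is 300 µm on a whole section and 100 µm on a crop, so the
    pixel length is exactly ``length_um / um_per_px`` (rounded to a pixel).
    """
    if position not in SCALEBAR_POSITIONS:
        raise ValueError(f"unknown scale-bar position {position!r}")
    out = image.copy()
    if position == "none":
        return out
    if um_per_px <= 0:
        raise ValueError("calibration required for a scale bar")
    length_um = SCALEBAR_CROP_UM if is_crop else SCALEBAR_WHOLE_UM
    length_px = int(round(length_um / um_per_px))
    h, w = out.shape[:2]
    thickness = max(3, int(0.01 * h))
    margin = max(5, int(0.02 * min(h, w)))
    if length_px + 2 * margin > w:
        raise ValueError("image too small for the scale bar")
    row0 = margin if position.startswith("upper") else h - margin - thickness
    col0 = margin if position.endswith("left") else w - margin - length_px
    out[row0 : row0 + thickness, col0 : col0 + length_px] = 255
    return out


def make_montage(panels: list[tuple[str, np.ndarray]]) -> Montage:
    """Assemble titled panels into a grid of at most 3 per row."""
    if not panels:
        raise ValueError("montage needs at least one panel")
    ph = max(p.shape[0] for _, p in panels)
    pw = max(p.shape[1] for _, p in panels)
    title_h = max(14, int(TITLE_HEIGHT_FRACTION * ph))
    cell_h, cell_w = ph + title_h, pw
    n = len(panels)
    cols = min(MONTAGE_COLS, n)
    rows = math.ceil(n / MONTAGE_COLS)
    canvas = Image.new("RGB", (cols * cell_w, rows * cell_h), (20, 20, 20))
    font = _font(max(10, title_h - 4))
    for i, (title, panel) in enumerate(panels):
        r, c = divmod(i, MONTAGE_COLS)
        tile = Image.new("RGB", (cell_w, cell_h), (20, 20, 20))
        drawer = ImageDraw.Draw(tile)
        drawer.text((4, 1), title, fill=(255, 255, 255), font=font)
        tile.paste(Image.fromarray(panel.astype(np.uint8)), (0, title_h))
        canvas.paste(tile, (c * cell_w, r * cell_h))
    return Montage(image=np.asarray(canvas), grid=(rows, cols), panels=[t for t, _ in panels])
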