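"""Tissue-foreground detection, crop validation, and artifact exclusion.

The section mask is the reference surface every percentage in the result
tables is computed against.  Detection thresholds the section-shape channel
(any ECM or fiber marker) with Otsu after light Gaussian smoothing, closes
small gaps, drops debris-sized pieces, and then either fills holes (limb
sections) or keeps them (diaphragm sections, which are cut folded and whose
lumen must not count as tissue).  All pieces above the debris cutoff are
kept, so multi-piece sections contribute their full area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as sk_label
from skimage.morphology import closing, disk

from .imgio import ImageRecord

#: pieces smaller than this fraction of the canvas are treated as debris
MIN_PIECE_FRACTION = 0.005


class NoTissueError(ValueError):
    """Raised when the section-shape channel contains no detectable tissue."""


@dataclass
class SectionMask:
    mask: np.ndarray  # bool, True = tissue
    n_pieces: int
    total_area_um2: float
    is_crop: bool = False

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


def detect_section(
    record: ImageRecord,
    role: str = "section_shape",
    anatomy: str = "Limb",
    is_crop: bool = False,
) -> SectionMask:
    """Detect the tissue foreground on the section-shape channel.

    ``anatomy='Limb'`` fills holes per piece; ``'Diaphragm'`` keeps them so
    fiberless lumen does not inflate the surface estimate.
    """
    ch = record.channel(role).astype(float)
    sm = gaussian(ch, sigma=2, preserve_range=True)
    if np.unique(sm).size < 2:
        raise NoTissueError("no tissue detected: constant section-shape channel")
    mask = sm >= threshold_otsu(sm)
    mask = closing(mask, disk(5))

    min_px = max(1, int(MIN_PIECE_FRACTION * mask.size))
    lbl = sk_label(mask, connectivity=1)
    keep = np.zeros_like(mask)
    n_pieces = 0
    for k in range(1, lbl.max() + 1):
        piece = lbl == k
        if piece.sum() < min_px:
            continue
        if anatomy == "Limb":
            piece = ndi.binary_fill_holes(piece)
        keep |= piece
        n_pieces += 1
    if n_pieces == 0:
        raise NoTissueError("no tissue detected")
    area = float(keep.sum()) * record.um_per_px**2
    return SectionMask(mask=keep, n_pieces=n_pieces, total_area_um2=area, is_crop=is_crop)


def validate_crop(record: ImageRecord, role: str = "section_shape", min_background_pct: float = 25.0):
    """Check that a cropped field keeps enough empty background.

    Background pixels are those below 10% of the channel's 99th-percentile
    intensity.  Returns ``(ok, background_pct, message)``; an insufficient
    margin yields a warning, never an error — responsibility stays with the
    user.
    """
    ch = record.channel(role).astype(float)
    level = 0.10 * np.percentile(ch, 99)
    if level <= float(ch.min()):  # signal-free image: everything is background
        bg_pct = 100.0
    else:
        bg_pct = 100.0 * float(np.mean(ch < level))
    ok = bg_pct >= min_background_pct
    msg = (
        ""
        if ok
        else f"crop warning: only {bg_pct:.1f}% black background "
        f"(minimum {min_background_pct:.0f}% recommended)"
    )
    return ok, bg_pct, msg


def artifact_check(fiber_area_um2: float, section_area_um2: float, min_pct: float) -> bool:
    """True = keep the image; exclude when detected fibers cover strictly
    less than ``min_pct`` percent of the section surface."""
    if section_area_um2 <= 0:
        raise ValueError("section area must be positive")
    return 100.0 * fiber_area_um2 / section_area_um2 >= min_pct
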