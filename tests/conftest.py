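"""Shared fixtures: phantoms and derived analysis state.

Session-scoped phantoms keep the suite fast — generation and segmentation
run once and every test reads from the same frozen state.
"""

from __future__ import annotations

import numpy as np
import pytest

from musclemetrics import fibers as fib
from musclemetrics import section as sec
from musclemetrics.imgio import ImageRecord
from musclemetrics.phantom import (
    BACKGROUND,
    FOREGROUND,
    PhantomSpec,
    generate_phantom,
)


@pytest.fixture(scope="session")
def phantom_default():
    """Default mid-size phantom: 40 fibers, capillaries, cells, nuclei."""
    spec = PhantomSpec(seed=3)
    record, truth = generate_phantom(spec)
    return spec, record, truth


@pytest.fixture(scope="session")
def analyzed_default(phantom_default):
    """Section mask, fiber candidates, filter report and ROI bands of the
    default phantom (healthy mode)."""
    _spec, record, _truth = phantom_default
    smask = sec.detect_section(record)
    candidates = fib.segment_fibers(record, smask)
    report = fib.filter_fibers(candidates, "Healthy")
    kept = [f for f in candidates if f.id in set(report.kept_ids)]
    bands = [fib.derive_rois(f, smask.mask.shape, record.um_per_px) for f in kept]
    return smask, candidates, report, bands


@pytest.fixture(scope="session")
def truth_bands(phantom_default):
    """ROI bands derived from the ground-truth polygons (segmentation-free
    oracle for the nucleus / capillary classification tests)."""
    spec, record, truth = phantom_default
    shape = (spec.height_px, spec.width_px)
    fibers = [
        fib.fiber_from_polygon(i, np.asarray(p) / spec.um_per_px, spec.um_per_px)
        for i, p in enumerate(truth.fiber_polygons)
    ]
    bands = [fib.derive_rois(f, shape, spec.um_per_px) for f in fibers]
    return fibers, bands


@pytest.fixture(scope="session")
def phantom_ecm():
    """Wide-lattice phantom for the ECM-fraction recovery check: few large
    fibers so the inter-fiber band dominates rasterization effects."""
    spec = PhantomSpec(
        width_px=768,
        height_px=768,
        n_fibers=12,
        ecm_fraction_target=0.25,
        n_capillaries=0,
        n_specific_cells=0,
        peri_nuclei_per_fiber=2,
        seed=11,
    )
    record, truth = generate_phantom(spec)
    return spec, record, truth


def make_record(channels: dict[str, np.ndarray], um_per_px: float = 1.0) -> ImageRecord:
    """Build a minimal record from named 2-D planes (same shape)."""
    roles = {}
    planes = []
    for i, (role, plane) in enumerate(channels.items()):
        roles[role] = i
        planes.append(np.asarray(plane))
    return ImageRecord(
        pixels=np.stack(planes), um_per_px=um_per_px, channel_roles=roles
    )


def flat(shape, level=BACKGROUND):
    return np.full(shape, level, dtype=float)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def intensity_levels():
    return BACKGROUND, FOREGROUND
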