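"""Fiber morphometry, the healthy/damaged filter, ROI bands, segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi

from musclemetrics import fibers as fib
from musclemetrics.phantom import (
    PhantomSpec,
    disc_polygon,
    generate_phantom,
    rasterize_truth,
)
from musclemetrics import section as sec
from musclemetrics._primitives import polygon_mask

SQUARE10 = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)


class TestShapeMetrics:
    @pytest.mark.parametrize(
        "polygon,expected",
        [
            # (area, circularity, feret_min, feret_max)
            (SQUARE10, (100.0, np.pi / 4, 10.0, 10 * np.sqrt(2))),
            (
                np.array([[0, 0], [20, 0], [20, 10], [0, 10]], float),
                (200.0, 4 * np.pi * 200 / 60**2, 10.0, np.sqrt(500)),
            ),
        ],
    )
    def test_closed_form_polygons(self, polygon, expected):
        area, _p, circ, fmin, fmax = fib.shape_metrics(polygon, 1.0)
        exp_area, exp_circ, exp_fmin, exp_fmax = expected
        assert area == pytest.approx(exp_area)
        assert circ == pytest.approx(exp_circ, abs=1e-9)
        assert fmin == pytest.approx(exp_fmin)
        assert fmax == pytest.approx(exp_fmax)

    def test_regular_64gon_is_nearly_a_disc(self):
        ang = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        poly = 10 * np.stack([np.cos(ang), np.sin(ang)], axis=1)
        _a, _p, circ, fmin, fmax = fib.shape_metrics(poly, 1.0)
        assert circ >= 0.99
        assert fmin == pytest.approx(fmax, rel=0.01)

    @pytest.mark.parametrize("scale", [2.0, 0.5])
    def test_circularity_is_scale_invariant(self, scale):
        base = fib.shape_metrics(SQUARE10, 1.0)[2]
        scaled = fib.shape_metrics(SQUARE10 * scale, 1.0)[2]
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_calibration_scales_area_quadratically(self):
        a1 = fib.shape_metrics(SQUARE10, 1.0)[0]
        a2 = fib.shape_metrics(SQUARE10, 0.5)[0]
        assert a2 == pytest.approx(a1 / 4)

    def test_self_intersecting_polygon_rejected(self):
        bowtie = np.array([[0, 0], [10, 10], [10, 0], [0, 10]], float)
        with pytest.raises(ValueError, match="self-intersecting"):
            fib.shape_metrics(bowtie, 1.0)


def _fiber(i, area, circ=0.9):
    """Candidate with prescribed measures (polygon irrelevant to the filter)."""
    return fib.FiberROI(
        id=i,
        polygon=SQUARE10,
        area_um2=area,
        perimeter_um=1.0,
        circularity=circ,
        feret_min_um=1.0,
        feret_max_um=1.0,
        centroid=(0.0, 0.0),
    )


class TestFilterFibers:
    def test_uniform_population_kept_in_full(self):
        cands = [_fiber(i, 500.0) for i in range(4)]
        rep = fib.filter_fibers(cands, "Healthy")
        assert rep.csa_sd_um2 == 0.0
        assert rep.upper_bound_um2 == rep.csa_mean_um2  # SD = 0
        assert sorted(rep.kept_ids) == [0, 1, 2, 3]  # inclusive boundary

    def test_small_fiber_healthy_excluded_damaged_kept(self):
        cands = [_fiber(0, 60.0)] + [_fiber(i, 500.0) for i in range(1, 8)]
        assert 0 in fib.filter_fibers(cands, "Healthy").excluded_ids
        assert 0 in fib.filter_fibers(cands, "Damaged").kept_ids

    def test_giant_outlier_excluded_under_healthy(self):
        cands = [_fiber(i, 200.0) for i in range(20)] + [_fiber(20, 10_000.0)]
        rep = fib.filter_fibers(cands, "Healthy")
        assert 20 in rep.excluded_ids
        assert sorted(rep.kept_ids) == list(range(20))

    def test_low_circularity_excluded_in_both_modes(self):
        cands = [_fiber(0, 500.0, circ=0.3)] + [_fiber(i, 500.0) for i in range(1, 5)]
        for mode in ("Healthy", "Damaged"):
            assert 0 in fib.filter_fibers(cands, mode).excluded_ids

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(st.floats(10.0, 20_000.0), st.floats(0.05, 1.0)),
            min_size=1,
            max_size=60,
        )
    )
    def test_damaged_keeps_a_superset_of_healthy(self, measures):
        cands = [_fiber(i, a, c) for i, (a, c) in enumerate(measures)]
        healthy = set(fib.filter_fibers(cands, "Healthy").kept_ids)
        damaged = set(fib.filter_fibers(cands, "Damaged").kept_ids)
        assert healthy <= damaged

    def test_report_partitions_candidates(self):
        cands = [_fiber(i, 100.0 + 50 * i, 0.4 + 0.1 * (i % 7)) for i in range(30)]
        rep = fib.filter_fibers(cands, "Healthy")
        assert sorted(rep.kept_ids + rep.excluded_ids) == list(range(30))


@pytest.fixture(scope="module")
def disc_bands():
    # 40 µm diameter disc at 0.25 µm/px -> fine rasterization
    upp = 0.25
    poly_um = disc_polygon(np.pi * 20.0**2, center=(30.0, 30.0))
    fiber = fib.fiber_from_polygon(0, poly_um / upp, upp)
    bands = fib.derive_rois(fiber, (240, 240), upp)
    return fiber, bands, upp


class TestDeriveRois:
    def test_membrane_band_width_is_one_twentieth_of_min_feret(self, disc_bands):
        fiber, bands, upp = disc_bands
        r_um = 20.0
        area_mb = bands.roi_mb.sum() * upp**2
        width = r_um - np.sqrt(r_um**2 - area_mb / np.pi)  # annulus inversion
        assert width / fiber.feret_min_um == pytest.approx(1 / 20, rel=0.10)

    def test_band_area_matches_perimeter_times_width(self, disc_bands):
        fiber, bands, upp = disc_bands
        width = fiber.feret_min_um / 20
        area_mb = bands.roi_mb.sum() * upp**2
        assert area_mb == pytest.approx(fiber.perimeter_um * width, rel=0.15)

    def test_set_invariants(self, disc_bands):
        _fiber, b, _upp = disc_bands
        assert not (b.roi_mb & ~b.roi_f).any()  # mb inside fiber
        assert not (b.roi_cnf & ~b.roi_f).any()
        assert not (b.roi_cnf & b.roi_mb).any()
        assert not (b.roi_sc & b.roi_f).any()  # outer bands outside
        assert not (b.roi_cap & b.roi_f).any()

    def test_tiny_fiber_cnf_annihilates_quietly(self):
        poly = disc_polygon(np.pi * 1.5**2, center=(10.0, 10.0))
        fiber = fib.fiber_from_polygon(0, poly, 1.0)
        bands = fib.derive_rois(fiber, (20, 20), 1.0)
        assert bands.roi_cnf.sum() == 0
        assert bands.roi_f.sum() > 0


@pytest.fixture(scope="module")
def phantom25():
    spec = PhantomSpec(seed=21, n_fibers=25, n_capillaries=8, n_specific_cells=4)
    record, truth = generate_phantom(spec)
    smask = sec.detect_section(record)
    cands = fib.segment_fibers(record, smask)
    return spec, record, truth, smask, cands


class TestSegmentation:
    def test_candidate_count_matches_planted_fibers(self, phantom25):
        _spec, _record, _truth, _smask, cands = phantom25
        assert len(cands) == 25

    def test_each_candidate_overlaps_truth_with_jaccard_08(self, phantom25):
        spec, _record, truth, smask, cands = phantom25
        gt = rasterize_truth(truth, spec)
        for f in cands:
            m = polygon_mask(f.polygon, smask.mask.shape)
            labs = gt[m]
            labs = labs[labs > 0]
            assert labs.size, "candidate falls outside every true fiber"
            k = np.bincount(labs).argmax()
            g = gt == k
            assert (m & g).sum() / (m | g).sum() >= 0.8

    def test_csa_within_ten_percent_of_truth(self, phantom25):
        spec, _record, truth, _smask, cands = phantom25
        from shapely.geometry import Point, Polygon

        polys = [Polygon(p) for p in truth.fiber_polygons]
        for f in cands:
            owner = next(
                (pl for pl in polys if pl.contains(Point(*f.centroid))), None
            )
            assert owner is not None
            assert f.area_um2 == pytest.approx(owner.area, rel=0.10)

    def test_blank_laminin_channel_yields_no_usable_candidates(self, phantom25):
        from conftest import flat, make_record

        _spec, record, _t, smask, _c = phantom25
        blank = make_record({"laminin": flat(smask.mask.shape), "section_shape": flat(smask.mask.shape)})
        assert fib.segment_fibers(blank, smask) == []

    def test_pixelwise_measures_agree_with_polygon_measures(self, phantom25):
        _spec, _record, _truth, smask, cands = phantom25
        for f in cands[:10]:
            m = polygon_mask(f.polygon, smask.mask.shape)
            assert m.sum() == pytest.approx(f.area_um2, rel=0.05)
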