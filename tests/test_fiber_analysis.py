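"""Nuclei classes, capillary classification/adjacency, typing, intensity."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk

from conftest import flat, make_record
from musclemetrics import fiber_analysis as fa
from musclemetrics import fibers as fib
from musclemetrics import section_analysis as sa
from musclemetrics.phantom import BACKGROUND, FOREGROUND, NUCLEUS_SIGMA_UM
from musclemetrics.section import SectionMask, detect_section


def _full_section(shape, um_per_px=1.0):
    mask = np.ones(shape, bool)
    return SectionMask(mask=mask, n_pieces=1, total_area_um2=mask.sum() * um_per_px**2)


def _dna_with_spots(shape, centers_px, sigma_um=NUCLEUS_SIGMA_UM, um_per_px=1.0):
    deltas = np.zeros(shape)
    sigma = sigma_um / um_per_px
    gain = 0.5 * 65535 * 2 * np.pi * sigma**2
    for r, c in centers_px:
        deltas[r, c] = gain
    return BACKGROUND + ndi.gaussian_filter(deltas, sigma)


def _square_fiber(fid, origin, side, shape, um_per_px=1.0):
    x0, y0 = origin
    poly = np.array(
        [[x0, y0], [x0 + side, y0], [x0 + side, y0 + side], [x0, y0 + side]], float
    )
    fiber = fib.fiber_from_polygon(fid, poly, um_per_px)
    return fiber, fib.derive_rois(fiber, shape, um_per_px)


class TestDetectNuclei:
    def test_phantom_count_within_five_percent(self, phantom_default):
        _spec, record, truth = phantom_default
        smask = detect_section(record)
        res = fa.detect_nuclei(record, smask)
        planted = len(truth.nucleus_centers)
        assert abs(len(res.records) - planted) <= 0.05 * planted

    def test_touching_pair_six_um_apart_is_split(self):
        dna = _dna_with_spots((64, 64), [(32, 29), (32, 35)])
        rec = make_record({"dna": dna})
        res = fa.detect_nuclei(rec, _full_section((64, 64)))
        assert len(res.records) == 2

    def test_empty_channel_gives_no_nuclei(self):
        rec = make_record({"dna": flat((32, 32))})
        assert fa.detect_nuclei(rec, _full_section((32, 32))).records == []

    def test_missing_channel_is_an_error(self):
        rec = make_record({"laminin": flat((32, 32))})
        with pytest.raises(ValueError):
            fa.detect_nuclei(rec, _full_section((32, 32)))


class TestCentroNuclei:
    def test_central_nucleus_counted_membrane_nucleus_not(self):
        shape = (80, 80)
        _fiber, bands = _square_fiber(0, (10, 10), 60, shape)
        dna = _dna_with_spots(shape, [(40, 40), (40, 12)])  # center + membrane rim
        rec = make_record({"dna": dna})
        nuclei = fa.detect_nuclei(rec, _full_section(shape))
        assert len(nuclei.records) == 2
        counts = fa.count_centronuclei([bands], nuclei, 1.0)
        assert counts[0] == 1  # the rim nucleus sits in roi_mb, not roi_cnf

    def test_phantom_centronucleated_fibers_recovered(self, phantom_default, truth_bands):
        spec, record, truth = phantom_default
        _fibers, bands = truth_bands
        smask = detect_section(record)
        nuclei = fa.detect_nuclei(record, smask)
        counts = fa.count_centronuclei(bands, nuclei, spec.um_per_px)
        detected = {fid for fid, c in counts.items() if c >= 1}
        planted = {fid for _x, _y, cls, fid in truth.nucleus_centers if cls == "central"}
        assert detected == planted


class TestPeriMyonuclei:
    def _scene(self):
        shape = (80, 80)
        _fiber, bands = _square_fiber(0, (10, 10), 60, shape)
        # two rim nuclei (one marker+, one marker-) and one interstitial marker+
        dna = _dna_with_spots(shape, [(12, 30), (68, 40), (5, 70)])
        marker = flat(shape)
        for r, c in [(12, 30), (5, 70)]:
            rr, cc = draw_disk((r, c), 3, shape=shape)
            marker[rr, cc] = FOREGROUND
        rec = make_record({"dna": dna, "myonuclei_marker": marker})
        nuclei = fa.detect_nuclei(rec, _full_section(shape))
        return bands, nuclei, rec

    def test_colabel_and_location_rules(self):
        bands, nuclei, rec = self._scene()
        counts, details = fa.count_peri_myonuclei([bands], nuclei, rec)
        assert counts[0] == 1  # marker- rim nucleus and interstitial nucleus rejected
        assert len(details) == 1
        assert details[0]["nucleus_y_um"] == pytest.approx(12, abs=2)

    def test_phantom_peri_counts_close_to_truth(self, phantom_default, truth_bands):
        _spec, record, truth = phantom_default
        _fibers, bands = truth_bands
        smask = detect_section(record)
        nuclei = fa.detect_nuclei(record, smask)
        counts, _ = fa.count_peri_myonuclei(bands, nuclei, record)
        planted = sum(1 for _x, _y, cls, _f in truth.nucleus_centers if cls == "peripheral")
        assert sum(counts.values()) == pytest.approx(planted, rel=0.10)


class TestSatelliteCells:
    def _scene(self, with_dna=True):
        shape = (80, 80)
        _fiber, bands = _square_fiber(0, (20, 20), 40, shape)
        marker = flat(shape)
        rr, cc = draw_disk((40, 18), 2.5, shape=shape)  # just outside the left edge
        marker[rr, cc] = FOREGROUND
        centers = [(40, 18)] if with_dna else []
        dna = _dna_with_spots(shape, centers) if centers else flat(shape)
        rec = make_record({"dna": dna, "cell_marker": marker})
        nuclei = fa.detect_nuclei(rec, _full_section(shape))
        return bands, nuclei, rec

    def test_edge_cell_assigned_to_exactly_one_fiber(self):
        bands, nuclei, rec = self._scene()
        counts, details = fa.detect_satellite_cells([bands], nuclei, rec, _full_section((80, 80)))
        assert counts[0] == 1 and len(details) == 1

    def test_marker_without_dna_rejected(self):
        bands, nuclei, rec = self._scene(with_dna=False)
        counts, _ = fa.detect_satellite_cells([bands], nuclei, rec, _full_section((80, 80)))
        assert counts[0] == 0

    def test_no_markers_no_counts(self):
        shape = (64, 64)
        _fiber, bands = _square_fiber(0, (10, 10), 40, shape)
        rec = make_record({"dna": flat(shape), "cell_marker": flat(shape)})
        nuclei = fa.detect_nuclei(rec, _full_section(shape))
        counts, _ = fa.detect_satellite_cells([bands], nuclei, rec, _full_section(shape))
        assert sum(counts.values()) == 0


def _vessel(label, area, circ):
    return sa.VesselObject(
        label=label,
        centroid_um=(0.0, 0.0),
        area_um2=area,
        circularity=circ,
        feret_min_um=1.0,
        feret_max_um=1.0,
        intensity_mean=1.0,
    )


@pytest.mark.parametrize(
    "area,circ,is_capillary",
    [
        (50.0, 1.0, True),
        (120.0, 1.0, False),  # too large
        (40.0, 0.30, False),  # too elongated
        (100.0, 0.45, True),  # both bounds inclusive
        (100.01, 0.45, False),
        (100.0, 0.4499, False),
    ],
)
def test_capillary_classifier_bounds(area, circ, is_capillary):
    kept = fa.classify_capillaries([_vessel(1, area, circ)])
    assert (len(kept) == 1) is is_capillary


class TestSharingFactor:
    def _junction_scene(self):
        """Three square fibers meeting around (50, 50); 4th quadrant empty."""
        shape = (100, 100)
        scene = []
        for fid, origin in enumerate([(2, 2), (52, 2), (2, 52)]):
            scene.append(_square_fiber(fid, origin, 46, shape))
        bands = [b for _f, b in scene]
        vessel_labels = np.zeros(shape, np.int32)
        rr, cc = draw_disk((50, 50), 2, shape=shape)
        vessel_labels[rr, cc] = 1  # capillary at the triple junction
        rr, cc = draw_disk((80, 80), 2, shape=shape)  # far inside the empty quadrant
        vessel_labels[rr, cc] = 2
        caps = [
            fa.CapillaryRecord(1, (50.0, 50.0), 12.0, 1.0, 4.0, 4.0, 1.0),
            fa.CapillaryRecord(2, (80.0, 80.0), 12.0, 1.0, 4.0, 4.0, 1.0),
        ]
        return caps, vessel_labels, bands

    def test_triple_junction_capillary_has_sf_three(self):
        caps, labels, bands = self._junction_scene()
        adj = fa.capillary_fiber_adjacency(caps, labels, bands)
        sf = fa.sharing_factor(adj)
        assert sf[0] == 3

    def test_isolated_capillary_has_sf_zero(self):
        caps, labels, bands = self._junction_scene()
        adj = fa.capillary_fiber_adjacency(caps, labels, bands)
        assert fa.sharing_factor(adj)[1] == 0

    def test_double_counting_identity_on_phantom(self, phantom_default, analyzed_default):
        _spec, record, _truth = phantom_default
        smask, _cands, _report, bands = analyzed_default
        labels, vessels = sa.segment_vessels(record, smask)
        caps = fa.classify_capillaries(vessels)
        adj = fa.capillary_fiber_adjacency(caps, labels, bands)
        assert fa.sharing_factor(adj).sum() == fa.capillary_contacts(adj).sum()
        assert fa.sharing_factor(adj).sum() > 0

    def test_removing_a_capillary_decrements_only_adjacent_fibers(self):
        caps, labels, bands = self._junction_scene()
        adj = fa.capillary_fiber_adjacency(caps, labels, bands)
        reduced = fa.capillary_fiber_adjacency(caps[1:], labels, bands)
        delta = fa.capillary_contacts(adj) - fa.capillary_contacts(reduced)
        assert np.array_equal(delta, adj[0].astype(int))


class TestFiberTyping:
    def _typed_scene(self, bright_ids, channel_types=("I", "IIA"), dim=BACKGROUND):
        shape = (100, 100)
        scene = [
            _square_fiber(fid, (5 + 48 * (fid % 2), 5 + 48 * (fid // 2)), 40, shape)
            for fid in range(4)
        ]
        channels = {}
        for t in channel_types:
            ch = flat(shape, dim)
            for fid in bright_ids.get(t, []):
                f, _b = scene[fid]
                x0, y0 = f.polygon.min(axis=0).astype(int)
                ch[y0 : y0 + 40, x0 : x0 + 40] = FOREGROUND
            channels[f"type_{t}"] = ch
        rec = make_record(channels)
        return [b for _f, b in scene], rec

    def test_two_population_channels_classified(self):
        bands, rec = self._typed_scene({"I": [0, 1], "IIA": [2]})
        _thr, labels, _raw = fa.fiber_typing(bands, rec)
        assert labels[0] == "I" and labels[1] == "I"
        assert labels[2] == "IIA"
        assert labels[3] == "undetermined"

    def test_double_positive_fiber_gets_hybrid_label(self):
        bands, rec = self._typed_scene({"I": [0], "IIA": [0, 1]})
        _thr, labels, _raw = fa.fiber_typing(bands, rec)
        assert labels[0] == "I-IIA"

    def test_uniform_channel_with_zero_sd_marks_all_positive(self):
        bands, rec = self._typed_scene({"I": [0, 1, 2, 3]}, channel_types=("I",))
        thr, labels, _raw = fa.fiber_typing(bands, rec)
        assert thr.per_channel["I"]["sd"] == pytest.approx(0.0)
        assert all(lbl == "I" for lbl in labels.values())

    def test_threshold_rules_by_type(self):
        bands, rec = self._typed_scene(
            {"I": [0], "IIA": [1], "IIB": [2], "IIX": [3]},
            channel_types=("I", "IIA", "IIB", "IIX"),
        )
        thr, _labels, _raw = fa.fiber_typing(bands, rec)
        for t in ("I", "IIA"):
            d = thr.per_channel[t]
            assert d["threshold"] == pytest.approx(d["mean"] + d["sd"])
        for t in ("IIB", "IIX"):
            d = thr.per_channel[t]
            assert d["threshold"] == pytest.approx(d["mean"])

    def test_every_kept_fiber_gets_exactly_one_label(self, phantom_default, analyzed_default):
        _spec, record, _truth = phantom_default
        _smask, _cands, report, bands = analyzed_default
        _thr, labels, _raw = fa.fiber_typing(bands, record)
        assert set(labels) == set(report.kept_ids)
        assert all(isinstance(v, str) and v for v in labels.values())


class TestIntensityByRoi:
    def _scene(self):
        shape = (80, 80)
        fiber, bands = _square_fiber(0, (10, 10), 60, shape)
        ch = flat(shape)
        ch[10:70, 10:40] = FOREGROUND  # left half of the fiber positive
        rec = make_record({"intensity_target": ch})
        return fiber, bands, rec

    def test_fully_positive_roi_reports_hundred(self):
        shape = (120, 120)
        _fiber, bands = _square_fiber(0, (10, 10), 60, shape)
        ch = flat(shape)
        ch[8:73, 8:73] = FOREGROUND  # covers the fiber, background dominates
        rec = make_record({"intensity_target": ch})
        per_fiber, _ = fa.fiber_intensity_by_roi([bands], rec, _full_section(shape), threshold=100.0)
        assert per_fiber[0]["roi_f_pct_positive"] == pytest.approx(100.0)

    def test_half_positive_roi_reports_fifty(self):
        _fiber, bands, rec = self._scene()
        per_fiber, _ = fa.fiber_intensity_by_roi([bands], rec, _full_section((80, 80)), threshold=100.0)
        assert per_fiber[0]["roi_f_pct_positive"] == pytest.approx(50.0, abs=2.0)

    def test_pct_positive_monotone_in_threshold(self):
        _fiber, bands, rec = self._scene()
        sm = _full_section((80, 80))
        prev = None
        for thr in (10.0, 100.0, 1000.0, 40000.0):
            per_fiber, _ = fa.fiber_intensity_by_roi([bands], rec, sm, threshold=thr)
            val = per_fiber[0]["roi_f_pct_positive"]
            if prev is not None:
                assert val <= prev
            prev = val

    def test_membrane_stain_enriches_mb_over_cnf(self, phantom_default, analyzed_default):
        _spec, record, _truth = phantom_default
        smask, _cands, _report, bands = analyzed_default
        per_fiber, summary = fa.fiber_intensity_by_roi(bands, record, smask)
        mb = np.nanmean([d["roi_mb_pct_positive"] for d in per_fiber.values()])
        cnf = np.nanmean([d["roi_cnf_pct_positive"] for d in per_fiber.values()])
        assert mb > cnf
        assert summary["roi_mb_intensity_mean"] > summary["roi_cnf_intensity_mean"]

    def test_empty_roi_reports_missing(self):
        shape = (30, 30)
        from musclemetrics.phantom import disc_polygon

        poly = disc_polygon(np.pi * 1.5**2, center=(15.0, 15.0))
        fiber = fib.fiber_from_polygon(0, poly, 1.0)
        bands = fib.derive_rois(fiber, shape, 1.0)
        rec = make_record({"intensity_target": flat(shape)})
        per_fiber, _ = fa.fiber_intensity_by_roi([bands], rec, _full_section(shape), threshold=1.0)
        assert np.isnan(per_fiber[0]["roi_cnf_pct_positive"])
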