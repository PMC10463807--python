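# musclemetrics

Batch analysis of immunofluorescence-stained skeletal-muscle cross
sections, for muscle physiologists and histology core facilities.  Given
multi-channel TIFF/OME-TIFF slide scans (laminin or another boundary stain,
a DNA stain, myosin-heavy-chain isoform channels, an endothelial marker, an
arbitrary cell marker, …), the package segments the tissue section and the
individual myofibers and quantifies, per image and per fiber:

* **fiber morphometry** — cross-sectional area (CSA), perimeter,
  circularity `4πA/P²`, min/max Feret diameters;
* **nuclei** — centronucleated fibers (nucleus in the fiber core, a
  regeneration marker), peripheral myonuclei (marker⁺/DNA⁺ nuclei in the
  sub-sarcolemmal membrane band), satellite cells;
* **capillaries** — endothelial objects with area ≤ 100 µm² and
  circularity ≥ 0.45, their per-fiber *capillary contacts* and the
  *sharing factor* (number of fibers apposed to each capillary);
* **fiber typing** — MyHC I/IIA/IIB/IIX positivity with per-channel
  thresholds (mean + SD for I/IIA, mean for IIB/IIX over the per-fiber
  mean intensities), including hybrid fibers;
* **whole-section measures** — extracellular-matrix area (moment-preserving
  threshold), vascularization % and vessels/mm², arbitrary-marker
  "specific cells" with and without a nucleus;
* **intensity by ROI** — mean intensity and % positive pixels of any
  staining in five nested/surrounding regions of each fiber (whole fiber,
  core, membrane band of width minFeret/20, satellite band, capillary
  band);
* **cartographies** — false-color maps of any result with legend, fixed
  300 µm / 100 µm scale bars and a 3-per-row montage.

Fibers pass a pathophysiology filter before analysis: circularity in
[0.45, 1] and CSA within [100 µm², mean + 3·SD] for *healthy* muscle or
[50 µm², mean + 4·SD] for *damaged* muscle, where CSA is far more
heterogeneous.

A built-in phantom generator (`musclemetrics.phantom`) creates synthetic
sections — a Voronoi fiber mosaic, ECM lattice, nuclei of every class,
capillaries, marker blobs — with exhaustive ground truth, so the whole
pipeline is testable without real slides.

## Worked example

```python
import numpy as np
from musclemetrics.phantom import PhantomSpec, generate_phantom
from musclemetrics import section, fibers, section_analysis, fiber_analysis

spec = PhantomSpec(n_fibers=40, seed=3)          # synthetic limb section
record, truth = generate_phantom(spec)

smask = section.detect_section(record, anatomy="Limb")
candidates = fibers.segment_fibers(record, smask)
report = fibers.filter_fibers(candidates, mode="Healthy")
kept = [f for f in candidates if f.id in set(report.kept_ids)]
bands = [fibers.derive_rois(f, smask.mask.shape, record.um_per_px) for f in kept]

labels_img, vessels = section_analysis.segment_vessels(record, smask)
caps = fiber_analysis.classify_capillaries(vessels)
adj = fiber_analysis.capillary_fiber_adjacency(caps, labels_img, bands)
sf = fiber_analysis.sharing_factor(adj)

print(f"section area: {smask.total_area_um2:.0f} um^2 in {smask.n_pieces} piece(s)")
print(f"fibers kept: {len(kept)}/{len(candidates)}  "
      f"CSA mean {np.mean([f.area_um2 for f in kept]):.0f} um^2  "
      f"filter window [{report.lower_bound_um2:.0f}, {report.upper_bound_um2:.0f}]")
print(f"capillaries: {len(caps)}  mean sharing factor {sf.mean():.2f}")
ecm = section_analysis.detect_ecm(record, smask)
print(f"ECM: {ecm.ecm_area_um2:.0f} um^2 ({ecm.ecm_pct_of_section:.1f}% of section)")
```

prints

```
section area: 168256 um^2 in 1 piece(s)
fibers kept: 40/40  CSA mean 3727 um^2  filter window [100, 6659]
capillaries: 29  mean sharing factor 2.97
ECM: 3795 um^2 (2.3% of section)
```

All 40 planted fibers are recovered and kept (a healthy phantom has
homogeneous CSA, so the mean + 3·SD window excludes nothing); 29 of the 30
planted capillaries are detected, each shared by ~3 fibers, as expected
for objects sitting at the junctions of a polygonal mosaic; the ECM
estimate matches the thin endomysial lattice the generator drew.

## Command line

```sh
musclemetrics phantom --spec spec.yaml --out images/      # synthetic data
musclemetrics run --folder images/ --config config.yaml   # batch analysis
```

One batch = one folder of images sharing staining and configuration.  The
run writes, into the configured output directory: a timestamped
`*_BATCH_LOG.txt`, a `<folder>_GlobalResults_<analyses>.txt` table that is
atomically rewritten after **every** image (an interrupted run keeps all
completed rows), per-image detail tables (`FiberDetails`,
`CapillaryDetails`, `SpecificDetails_<marker>`, `SatCellDetails`,
`PeriMyoNucleiDetails`), a Fiji-compatible `*_xxROI.zip` polygon archive,
and the requested cartography PNGs.

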