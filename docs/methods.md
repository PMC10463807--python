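# Methods

This note documents the models and procedures implemented in
`musclemetrics`, the parameter choices that matter, and what the synthetic
phantom does and does not emulate.

## Section detection

The tissue foreground is detected on the *section shape* channel (any ECM
or fiber marker): Gaussian smoothing (σ = 2 px), Otsu threshold,
morphological closing (disk radius 5 px).  Every connected piece covering
at least 0.5% of the canvas is kept — multi-piece sections (e.g. a
quadriceps separated during cryosectioning) contribute their full area.
For limb sections holes are filled per piece; for diaphragm sections —
usually cut folded, enclosing fiberless lumen — holes are retained, so the
reported surface is the actual tissue surface.  The smoothing scale,
closing radius and 0.5% debris cutoff are this package's choices; the
upstream pretreatment chain of the original tool is not published.

Crop fields are sanity-checked: at least 25% of the image should be black
background (pixels below 10% of the 99th-percentile intensity — our
quantification of "black").  An insufficient margin produces a logged
warning, never an error: background estimation degrades gracefully and the
responsibility stays with the user.

An image is excluded from the results ("artifact") when its kept fibers
cover strictly less than a configurable percentage of the section surface.
The strict `<` follows from reading "less than" literally; the boundary
case keeps the image.

## Fiber segmentation and morphometry

Candidate fibers are the connected regions enclosed by the laminin
boundary network: morphological background flattening (gray opening,
51 px), Gaussian σ = 1, Otsu on the boundary channel, then connected
components of non-boundary pixels inside the section.  Components whose
convexity deficiency (1 − area/convex area) exceeds 0.2 are split by a
distance-transform watershed; peak labeling is scan-ordered, so the whole
chain is deterministic.  Each component is traced to a polygon
(sub-pixel contour, simplified at 0.75 px tolerance).

Shape measures are polygon-based: shoelace area, arc-length perimeter,
circularity `4πA/P²` clipped to 1, and min/max Feret diameters by rotating
calipers on the convex hull.  Polygon (rather than pixel-count) perimeter
avoids the systematic overestimate of digital perimeters; tests accept a
5% discrepancy against pixel-based measures.

### Pathophysiology filter

CSA mean and SD are computed over **all** candidates (population SD,
ddof = 0).  A fiber is kept iff its circularity lies in [0.45, 1] and its
CSA in [L, mean + k·SD], with (L, k) = (100 µm², 3) for healthy and
(50 µm², 4) for damaged muscle.  All bounds are inclusive: a perfectly
uniform population (SD = 0) is kept in full, and the damaged window always
contains the healthy one.  Excluded fibers are retained for cartography,
where they are painted black.

### Per-fiber regions

Five regions are derived from each kept fiber's outline using exact
Euclidean distance transforms:

| region    | definition                               | default |
|-----------|------------------------------------------|---------|
| `roi_f`   | fiber interior                           | —       |
| `roi_mb`  | interior within *w* of the boundary      | *w* = minFeret/20 |
| `roi_cnf` | interior deeper than max(2 µm, minFeret/10) | —    |
| `roi_sc`  | exterior band                            | 3 µm    |
| `roi_cap` | exterior band                            | 3 µm    |

The membrane-band fraction (1/20 of the min Feret diameter) is the defining
constant of `roi_mb`.  The `roi_cnf` margin is chosen at twice the membrane
band (so the two can never touch) with a 2 µm floor that keeps a peripheral
nucleus rim out of the core even in small fibers.  The outer band widths
are not quantified anywhere we could find; 3 µm — roughly half a capillary
diameter — is exposed as a knob (`sc_band_um`, `cap_band_um`).

## Section-level analyses

**ECM.**  The ECM channel inside the section is binarized with the
moment-preserving (Tsai) threshold and eroded once with a radius-1 cross
("low erosion"), then reported in µm² and as % of the section.  Our Tsai
implementation computes the below-class mass `p0` in closed form and maps
it to the gray level whose cumulative mass is nearest `p0` (first level on
ties).  The common "first cumulative > p0" convention degenerates on
exactly bimodal histograms (it returns the upper mode itself); the
nearest-mass rule places the cut strictly between modes and is invariant
to appended empty bins.  The single erosion biases the area low by ~1 px
per boundary; at lattice widths of ≳ 15 px this stays within a few percent.

**Vascularization.**  Endothelial background is the histogram mode of
in-section pixels; the residual is thresholded with the triangle method
(appropriate for its unimodal histogram) and labeled with **no** size or
shape criterion — arteries and veins count.  Outputs: % surface covered
and vessels per mm².

**Specific cells.**  Marker blobs are segmented the same way (no shape
prior — round and irregular cells alike).  A blob *has a nucleus* when it
overlaps a DNA spot by ≥ 1 px (a minimum-overlap-fraction knob exists,
default 0).  The total count includes nucleus-free blobs — out-of-focus
nuclei are common — but mean intensity and mean area are computed over
nucleus-bearing cells only, and detail rows carry the nucleus gravity
center only when one exists.

## Fiber-level analyses

**Nuclei.**  DNA spots are Otsu-thresholded on the background-subtracted
channel and split by a distance-transform watershed (markers ≥ 2 µm
apart).  Classification is by centroid membership: `roi_cnf` → central
(no colabel needed — central position suffices), `roi_mb` + myonuclei
marker positive → peripheral myonucleus.  Marker positivity is Otsu over
the nucleus-wise mean intensities, inclusive ≥ (a degenerate one-level
distribution counts everything positive).  A nucleus straddling bands goes
to the lowest fiber id — an arbitrary but fixed tie-break.

**Capillaries.**  Objects from the vessel segmentation with area ≤ 100 µm²
and circularity ≥ 0.45 (both inclusive).  Adjacency is one boolean
capillary × fiber matrix — mask ∩ `roi_cap` ≥ 1 px — whose row sums are
sharing factors and column sums capillary contacts, making
Σ SF = Σ contacts an identity rather than an approximation.

**Typing.**  Per MyHC channel, the mean and SD of per-fiber mean
intensities over `roi_f` are computed in a single pass over all kept
fibers; the positivity threshold is mean + SD for types I and IIA and the
mean for types IIB and IIX (which stain dimmer).  Comparisons are
inclusive.  Labels: the sole positive type, a hybrid label joining all
positive types in canonical order (e.g. `I-IIA`), or `undetermined`.  A
caveat follows from the mean-rule: a type channel containing no real
signal still marks roughly half the fibers positive, so only channels that
were actually stained should be mapped.  Raw per-channel intensities are
always written to FiberDetails so users can re-threshold manually.

**Intensity by ROI.**  One background level (histogram mode) and one
positivity threshold (triangle) per image; per fiber and per region, the
mean residual intensity and 100 × positive/total pixels.  Empty regions
(e.g. an annihilated core in a tiny fiber) report NaN and are excluded
from the per-image mean/SD.

## Cartography

Kept fibers are filled with a categorical palette (typing) or a viridis
ramp (continuous features); excluded fibers are black; point objects are
red symbols at their gravity centers.  The legend box is 15% of the image
width and lists only classes present in the section.  Scale bars are
physically fixed — 300 µm on whole sections, 100 µm on crops, none by
default — so their pixel length is exactly `length/µm·px⁻¹`.  Montages
wrap at 3 panels per row, each panel titled (title strip 3% of panel
height).

## The phantom generator

The generator emulates a transverse mouse-limb section: Poisson-disc seeds
(minimum spacing 8 µm — adult fibers are never thinner) tessellated by
Voronoi cells clipped to a disc, shrunk to leave an ECM lattice whose
width is calibrated by bisection to a target area fraction (default 8%,
typical healthy endomysium); DAPI-like Gaussian spots (σ = 2 µm, minimum
5 µm spacing) at central/peripheral/interstitial positions; 4 µm-diameter
capillaries at fiber junctions; irregular marker blobs in the
interstitium, 70% of them nucleus-bearing; MyHC channels bright per
assigned type (hybrids on two channels at equal intensity); a
membrane-localized stain ringing each fiber; 16-bit intensities
(background 5%, signal 60% of full scale) plus additive Gaussian noise
(SD 150).  Everything placed is recorded as ground truth, and generation
is bit-deterministic in (spec, seed).

What it does **not** emulate: optics (no PSF beyond the nuclear Gaussian),
staining gradients and vignetting, necrotic or split fibers, folds and
tears, autofluorescence, or anisotropic sectioning.  Passing tests
therefore demonstrate correctness of the measurement logic on
geometrically faithful inputs, not robustness to degraded real-world
staining — thresholds that are adaptive here (Otsu/triangle/Tsai) are the
components most sensitive to that gap.

## Problem sizes and numerical conventions

The test suite and the acceptance sweeps run on 256–768 px phantoms with
12–50 fibers, populations of ~2 000 synthetic fibers for filter sweeps,
and 0.01-step circularity grids; these sizes give sub-second operations
while keeping rasterization error well below every tolerance asserted.
Key conventions, fixed once: inclusive comparisons at every filter and
positivity boundary; population (ddof = 0) standard deviations;
scan-order tie-breaks in watershed marker labeling; smallest-id tie-break
for band membership; ROI vertices truncated to integers on export (the
ImageJ `.roi` format stores shorts).
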