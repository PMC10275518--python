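# Methods

## The corrected-hue statistic

A brain photographed after intra-arterial trypan-blue injection shows blue
parenchymal staining wherever the blood–brain barrier has opened. The
package quantifies this semiquantitatively from 8-bit RGB photographs: each
pixel's hexagonal HSV hue H ∈ [0, 360) is computed from its RGB triple, and
the piecewise *corrected hue*

    H' = 99 − H     for 0 ≤ H < 100
    H' = 459 − H    for 100 ≤ H < 360

is averaged over each hemisphere ROI. Raw hue is an angle: red tissue sits
near 0°/360° and blue stain near 230–240°, so an arithmetic mean of raw hue
is meaningless across the wrap. The corrected transform folds the red family
(including hues just below 360°, which map continuously onto the 99 − H
branch since 459 − 360 = 99) onto low values and the blue/green family onto
high values, producing a single linear scale that increases with blueness.
Means on that scale are ordinary arithmetic means; no circular statistics
are used, deliberately — the transform exists precisely so that a linear
mean is meaningful for the red-vs-blue contrast at hand.

The readout is the ratio of mean corrected hue, ipsilateral (treated) over
contralateral hemisphere. A ratio above 1.0 indicates stronger blue staining
on the treated side. Ratios are tabulated per treatment group over the
timepoints 30 min / 1 h / 2 h, and each group is annotated with its peak
(argmax) timepoint.

Choices the data format forces us to make explicit:

- **Achromatic pixels** (zero chroma) have undefined hue; they are excluded
  and counted. An optional `saturation_min` threshold (default 0 = off)
  additionally drops near-achromatic pale pixels, useful for unstained
  tissue in real photographs.
- **Spread** is the population standard deviation (divide by n), since the
  ROI is the full population of pixels, not a sample from it.
- The transform is **discontinuous at H = 100** (99 − 99.99… ≈ −1 vs.
  459 − 100 = 359) and values of H in (99, 100) yield small negative
  corrected hues. Both are kept exactly as defined; no smoothing.
- **Multi-animal aggregation** defaults to the arithmetic mean of per-animal
  ratios; dividing pixel-weighted pooled means is available as
  `aggregation="ratio_of_pooled_means"`. The choice is echoed into every
  run report.

ROIs come either from a vertical midline split of the tissue mask (the
midline at the tissue centroid column by default, the midline column
assigned to neither hemisphere; treated side is image-right unless flipped)
or from a two-polygon ROI file for real photographs, rasterized on pixel
centers and intersected with the tissue mask. The tissue mask keeps pixels
with max(R, G, B) above a brightness threshold (default 30), dropping dark
photographic background.

## MSI ion images and hemisphere ratios

Drug delivery is read out from spatially rastered centroid mass spectra
(DESI-style acquisition, m/z 50–700, 100 µm square pixels, positive mode).
For a target ion, the ion image holds per pixel the **sum** of centroid
intensities within a mass window interpreted as a **full width** — the
default 0.02 Da means target ± 0.01 Da, closed at both endpoints. Both
interpretations of "window" exist in vendor software; full width is the
recorded convention here, and half-width users can simply pass 0.04. Pixels
with no peak in the window read 0; grid positions never acquired, or lost
to a zero normalization denominator, are NaN ("missing") and are excluded
from all means — a missing pixel is never conflated with a zero intensity.

Target m/z values come from adduct arithmetic: nominal mode adds integer
deltas (+1 for [M+H]+, +23 for [M+Na]+) to the nominal neutral mass;
monoisotopic mode sums monoisotopic atomic masses over the elemental
formula and adds the adduct atom's mass under the hydrogen-atom convention
(no electron-mass correction). That convention reproduces the conventional
leucine-enkephalin lock mass 556.2771 from C28H37N5O7 + H, which is the
package's internal consistency anchor. Presets: temozolomide [M+Na]+ at
m/z 217, doxorubicin [M+H]+ at m/z 544.

Per-pixel normalization is optional: none (default — displayed panels in
such studies are typically raw), TIC (divide by the pixel's total ion
current), or lock-mass (divide by the intensity extracted at the lock m/z
with the same window rule). The delivery readout is the ratio of mean
extracted intensity, ipsilateral over contralateral; a zero contralateral
mean is reported as an infinite-ratio flag together with both means rather
than as an exception.

Datasets interchange as processed-mode imzML (1-based integer pixel
coordinates, float32 binary storage); the round trip is lossless at float32
precision for coordinates, m/z and intensities. The imzML scan settings
written by the library do not carry a physical pixel size, so the reader
takes it as an argument (default 100 µm).

## The synthetic phantoms

No photographs or MSI acquisitions are distributable, so every pipeline is
exercised on generators that plant a known signal and record it.

**Brain phantom.** Two mirror-image elliptical hemispheres (semi-axes
0.18 w × 0.38 h, centers at 0.28 w and 0.72 w, leaving a midline gap) on a
pure black background. Tissue starts at a pale pinkish base color
(200, 150, 140), raw hue ≈ 10°, corrected ≈ 89; a configurable fraction of
each hemisphere's pixels is linearly blended toward a trypan-blue-like
stain color (60, 70, 200), raw hue ≈ 236°, corrected ≈ 223. Per-channel
Gaussian noise (default SD 3) is added to tissue pixels only and clipped to
[0, 255]; the background stays exactly black so the brightness threshold
recovers the tissue mask exactly. The same noise field is applied to both
hemispheres in mirrored order, so an unstained phantom has *identical*
hemisphere pixel populations and a planted ratio of exactly 1. The recorded
ground truth is each hemisphere's mean corrected hue computed from the
final quantized pixels, so downstream recovery is exact to floating point.
With full blending the hemisphere mean is linear in the stained fraction f,
so `stain_fraction_for_ratio` inverts a target ipsi/contra ratio
analytically; noise and 8-bit quantization perturb realized ratios only at
the ~0.1% level. Background peaks in MS and photographic reality the
phantom does **not** model: lighting gradients, white balance, specular
highlights, vascular texture, anatomy. Passing tests therefore show the
*quantification* is correct and self-consistent, not that midline ROIs are
adequate for real photographs.

**MSI phantom.** A full rectangular grid (default 20 × 16, 100 µm pixels),
left half contralateral, right half ipsilateral (middle column unassigned
when the width is odd). Every pixel's centroid spectrum holds one drug peak
at the target m/z plus Gaussian mass error (default SD 0.003 Da, clipped to
the m/z range) with hemisphere-dependent intensity (defaults 100 ipsi / 10
contra), and uniform background peaks (default 50 per pixel, intensities
uniform on [0, 50]) drawn outside the drug m/z ± 1 Da — a documented
generator guarantee so that window-extraction tests are never contaminated
by construction. Spectra are centroided, not profile; the extraction
contract is defined on centroids. With SD 0.003 Da and a ±0.01 Da window,
~99.9% of drug peaks are captured; misses hit both hemispheres
symmetrically, so the planted intensity ratio is recovered well within 5%.

## Numerical and design choices

- Hue is computed by the standard hexagonal HSV formula (ties broken
  max=R > max=G > max=B); tests cross-check it against the standard
  library's `colorsys` on the full 8-bit lattice sampled by hypothesis.
- Window extraction uses binary search (`searchsorted`) on the sorted m/z
  axis; a naive linear scan serves as the test oracle, and the two agree
  exactly on randomized datasets.
- Interval endpoints are closed on both sides, so boundary ties are
  deterministically included.
- Seeds: every generator takes an explicit seed; the demo pipeline derives
  per-stage child seeds (< 2³¹) from the single top-level seed via
  `numpy.random.SeedSequence`, so stages rerun in isolation reproduce the
  full-run numbers. Identical config + seed gives bit-identical images,
  spectra, CSV and JSON outputs.
- Problem sizes: the shipped demo uses 160 × 120 px phantoms (≈ 5,500
  tissue pixels per hemisphere) and 20 × 16 MSI grids — large enough that
  recovered ratios sit two orders of magnitude inside the tested
  tolerances, while a full demo run completes in about a second.

## Known limitations

- The midline-split ROI is a geometric convenience; real coronal
  photographs may need the polygon route, and neither reproduces whatever
  manual delineation a given study used.
- Mean corrected hue is not a dye concentration; the statistic is
  semiquantitative by design and no spectrophotometric calibration is
  attempted.
- Profile-mode spectra, peak picking, and m/z axis recalibration against
  the lock mass are out of scope; the lock mass is used for normalization
  and as a mass-arithmetic anchor only.
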