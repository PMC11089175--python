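# Methods

## Problem and scope

The package computes a *relative* quantification of PpIX fluorescence from
single blue-light RGB frames. Nothing is radiometrically calibrated: the
arbitrary-unit (au) scale spans 0–255 per acquisition and supports
comparisons between regions of one scene, not absolute concentration
estimates or cross-device comparisons. Live video, illumination-angle
compensation, and spectroscopic PpIX estimation are out of scope; the
per-frame API is pure so a stream wrapper could be added later.

## Colorimetry backends

The extraction step has no single canonical formula in the field, so two
explicit, documented backends are shipped and selectable:

* **Excitation subtraction** (default):
  `au = clamp(gain · max(0, R − α · max(G, B)), 0, 255)`, α ≥ 0 (default 1),
  gain ≥ 0 (default 1). PpIX emits ~635 nm red under ~405 nm excitation, so
  red minus the scaled larger of green/blue removes both reflected
  excitation (high B) and white specular highlights (high G *and* B).
  Monotone in R at fixed G, B; zero for any red-free pixel.
* **HSV hue-band gate**: pixels whose hue lies in a configurable
  (wrap-around) band — default 320°–30°, the red/magenta range — with
  saturation ≥ 0.3 and value ≥ 0.1 contribute `255 · value`; all others 0.
  More robust on weakly pinkish backgrounds where channel subtraction loses
  signal.

The backends are alternative operationalizations; their numerical
equivalence is neither expected nor asserted. Both guarantee range
[0, 255] and blue rejection, and tests assert exactly those shared
properties. Saturated camera pixels receive no special treatment — an
inherited limitation of uncalibrated 8-bit capture.

All quantisation uses round-half-up (never banker's rounding) so integer
outputs are exactly reproducible; 16-bit input rescales as
`round_half_up(v · 255/65535)`, preserving both endpoints.

## Mask, intensity map, margins

Thresholding is inclusive (`au ≥ t`), making the saturated 255 case
unambiguous. Default threshold 30 au is a low-fluorescence floor against
background noise — a tunable, not a calibrated constant. Cleanup is
opening *then* closing with a disk (speckle removal before pinhole
sealing; radius 1 default, 0 disables) followed by removal of 8-connected
components below `min_area` (default 25 px); `min_area=0, morph_radius=0`
reproduces the bare per-pixel comparison exactly, which is the tested
equivalence. 8-connectivity is used everywhere so visually contiguous
zones never split on diagonals; component labels are assigned in
raster-scan order of each component's first pixel, independent of the
labelling backend.

The display scale is a gamma power law `255 · (au/255)^γ`, default
γ = 0.6 to lift the dim margin-zone signal; γ = 1 is linear. The
continuous scale is strictly increasing and endpoint-preserving for every
γ; integer rounding happens only at colormap lookup (a 256-entry LUT of a
named matplotlib map, default `inferno`). Region statistics are computed
on raw au values *before* the display scale, since au quantifies
fluorescence while the scale only serves display; means are reported to
one decimal (half-up).

Margins are marching-squares iso-contours of the 0/1 mask at level 0.5
with saddle cells resolved toward 8-connected foreground, giving sub-pixel
rings that run half a pixel outside foreground pixel centers. Conventions
fixed for serialization: vertices are (row, col) floats with pixel centers
at integers; rings are closed with ≥ 4 vertices; outer rings have positive
shoelace area over (col, row)-as-(x, y), holes negative; hole rings carry
the index of their enclosing outer ring. Even-odd filling of all rings at
pixel centers inverts the extraction exactly — the tested consistency
property. An optional outward dilation radius (default 0) places the
margin conservatively outside the fluorescent zone; boundary placement is
the default because no field standard dictates a safety distance.

Overlay blending is `out = a · layer + (1 − a) · original` (half-up), so
`a = 1` paints exact colormap colors and `a = 0` leaves only the margin
polylines; pixels away from mask and polylines are bit-identical to the
input. Stroke width is realized by dilating the drawn polyline with a disk
of radius ⌊w/2⌋, so effective width is 2⌊w/2⌋ + 1 pixels.

## Phantom generator

The generator emulates bench validation phantoms: a gelatin "brain" with
embedded agarose masses containing known PpIX concentrations, photographed
under white and blue light. Core emission per lesion is

    emission(c, d) = 255 · (1 − exp(−k_sat · c)) · exp(−μ · d)  [au]

with defaults k_sat = 0.5 (µg/mL)⁻¹ and μ = 0.6 mm⁻¹. The constants are
nominal, not measured gel coefficients: k_sat puts 5 µg/mL — the upper end
of intratumoral PpIX — near 92% of full scale so the tested concentration
series (0.5, 1.25, 5, 50, 100 µg/mL) spans the dynamic range with the top
two saturating; μ makes ~2 mm of gelatin attenuate a saturating mass below
a surface mass at half its concentration, reproducing the depth confound
that makes depth-uncorrected quantification misleading. Lesions are
rotated ellipses with a cubic-smoothstep edge falloff over the outer 5% of
the normalized radius (default `edge_softness` 0.05, narrow enough that
thresholded recovery of a surface mass keeps Jaccard ≥ 0.9 against the
geometric ground truth); overlaps resolve to the maximum emission per
pixel. Two background styles imitate translucent yellowish gelatin and the
opaque pinkish variant used to limit reflections; both keep the blue-light
background red channel below max(G, B) so background fluorescence reads
exactly 0 au under the default backend. Optional specular highlight blobs
(translucent style) stress-test blue rejection. Noise is additive Gaussian
per channel (default sd 3 au), clamped; all randomness derives from the
spec seed and identical specs render bit-identically.

What the generator does **not** emulate: scattering, spectral camera
response, illumination-angle falloff, motion blur, blood/CSF occlusion, or
tissue texture. Passing tests therefore demonstrate the correctness and
determinism of the processing chain and its qualitative behaviours
(saturation, depth confound, concentration ordering) — not clinical
performance on real surgical images.

## Problem sizes and numerical choices

Test phantoms are 64–320 px on a side with lesion radii 18–30 px — large
enough that component statistics and Jaccard scores are stable, small
enough that the full suite runs in seconds. Oracle-equivalence checks use
200 random 64×64 blob masks (Gaussian-smoothed noise thresholded at a
quantile), exercising many nontrivial topologies per run. Degenerate
inputs are defined, not errors: empty masks yield empty contour lists,
empty region lists, and fully transparent maps; an all-black frame yields
an empty report.

## Known limitations

* au values are camera- and scene-relative; no absolute calibration.
* Depth attenuation is reproduced, not corrected; quantification of buried
  tissue is systematically low by design of the physics, and the package
  makes that visible rather than attempting an inverse model.
* The subtraction backend underestimates fluorescence on strongly pinkish
  backgrounds (background red raises the subtracted baseline); the HSV
  backend is provided for such scenes.
* JPEG input is accepted but its chroma subsampling degrades colorimetry;
  PNG/TIFF are the supported capture formats.
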