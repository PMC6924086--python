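# Methods

This note records the models, conventions and numerical choices behind
`spinetrack`, and what the synthetic validation does and does not show.

## Coordinate and unit conventions

Images are float arrays indexed `[row, column]`; x is the column
(rightward), y the row (downward), both 0-based, so angles in degrees run
from +x toward +y (clockwise on screen). Brightness lives in [0, 255] as
real values; 8-bit quantization is an explicit, optional step
(`quantize_8bit`). Forces are Newton, lever arms metres, linear
displacements millimetres, angles radians — giving instant rigidities in
N/mm (compression), Nm/rad (angle variants) and Nm/mm (shift variants).

## Instant rigidity

Rigidity is computed per load step, not as a fitted slope:
R_c = F/Δl for compression, R_t = F·r/φ or F·r/d for torsion, and
R_f = F·l/α or F·l/d for bending, where d is the camera-measured shift of
the constant lever arm. Both the angle and the shift variants are
implemented; the variant is an explicit configuration choice because in
practice the cameras deliver d, not φ. Results carry their units and a
mode tag; mixing variants or modes in a comparison is rejected rather than
silently converted. A measurement sweep is repeated (10 repeats by
default); the summary is the mean and sample SD of the per-repeat mean.
Intact-vs-treated comparison reports 100 × treated/intact per mode, so the
intact specimen maps to exactly 100 %. Step forces may be averaged over
several gauge readings (n_avg), which suppresses gauge noise roughly as
1/√n_avg. Warm-up metadata (0.1 Hz cycling before measurement) is recorded
with a run but never computed on.

Lever arms r and l are rig-specific geometry with no meaningful default;
they are required configuration.

## Gauge calibration

The voltage-to-force map is the straight line y = a + bx fitted by the
closed-form normal-equation sums

    a = (Σx²Σy − ΣxΣxy) / (nΣx² − (Σx)²),
    b = (nΣxy − ΣxΣy) / (nΣx² − (Σx)²),

evaluated exactly as written (they are the package's core contract and are
cross-checked in the tests against an independent regression routine). The
error audit reports the maximum relative force error against known truth,
excluding true forces below a floor (default 5 % of the largest force):
a relative error diverges as F → 0, so a bound quoted for a calibration is
only meaningful above some fraction of full scale. Where the test suite
asserts the classical "error below 5 %" bound it uses gauge noise at the
level of the rig's measurement chain — a 200 N full-scale strain-gauge
bridge read by a 24-bit ADC with per-step averaging, modelled as Gaussian
force noise of SD 0.2 N. At substantially higher noise (e.g. SD 1 N) the
worst-case relative error at the 10 N floor scales up proportionally
(prediction SD ≈ σ·√(1/n + (x−x̄)²/Sxx) ≈ 0.36σ there) and the 5 % bound no
longer holds for the worst of many replicates; the audit reports whatever
the data give.

## Marker-disc detection

The chain is: Sobel gradient magnitude → inclusive band threshold →
morphological opening → 8-connected component centroids. Conventions:

* Convolution uses reflective border padding; morphology treats
  outside-frame pixels as 0. Erosion/dilation follow the set definitions
  over explicit offset sets (origin required), so arbitrary asymmetric
  elements work and the duality
  erode(m, B) = ¬dilate(¬m, B̌) holds on padded frames.
* The threshold band is inclusive at both ends; a band [v, v] selects
  exactly the pixels equal to v.
* Centroids are arithmetic means of member pixel coordinates, computed per
  8-connected component (a single global row/column average would fail as
  soon as more than one disc is visible). Integer translations of a mask
  translate every centroid exactly.
* Default pipeline parameters: automatic threshold at 0.28 of the maximum
  edge response, opening by a radius-1 digital disc (the 5-point cross),
  minimum component size 20 px. The structuring element is deliberately
  small: the gradient ring of a radius 4–8 px disc is only 2–3 px thick,
  and opening with a radius-2 disc erases it completely. For
  high-resolution footage with larger markers a larger element is
  appropriate (`struct_radius` in the configuration).
* Track assembly is greedy nearest-neighbour linking with a maximum
  per-frame jump (default 15 px); unmatched detections open new tracks and
  missed detections leave gaps rather than forcing merges.

On synthetic scenes (radius 4–8 px discs, contrast 150 brightness units,
sensor noise SD drawn from [0, 10], ~1 px camera PSF) the chain recovers
true centers to better than 0.5 px worst-case. Two limitations are worth
stating. First, at the extreme corner of low contrast *and* high noise
(contrast 50 at noise SD 10) the blurred gradient-ring peak (~110
brightness units) falls below the upper tail of the Sobel noise magnitude
(~130), so no threshold separates ring from background and the chain
cannot segment reliably; detection there needs either more contrast, less
noise, or spatial averaging before differentiation. Second, at constant
noise SD 10 the centroid error distribution has a tail that touches 0.5 px
(~0.2 % of discs), so individual worst cases near the boundary are
expected.

## Speckle-FFT displacement

A pseudo-speckle target is band-limited Gaussian texture: white noise
smoothed by a periodic Gaussian kernel (correlation length 2 px), rescaled
to brightness SD σ (default 50) about mid-grey and clipped to [0, 255].
The generation recipe behind the original rigs' σ = 50 targets is not
documented anywhere we know of; filtered noise is this package's stand-in
and reproduces the one stated property (the brightness SD) within the
clipping loss (~1.5 %).

Sub-pixel rigid shifts are realized spectrally (phase ramp) with periodic
boundaries — real cameras crop instead of wrapping, which is acceptable
for fixtures because the fringe method itself is spectral. The unpaired
Nyquist bin of an even-size image has no well-defined fractional phase and
is dropped on fractional shifts; this keeps outputs exactly real and makes
fractional shifts compose exactly (the one remaining edge case — a chain
of fractional shifts summing to an exact integer — differs from the direct
integer roll by the image's Nyquist energy only).

Measurement chain: the two frames are mean-subtracted and summed; the sum
is windowed (Hann, after subtracting the window-weighted mean so the DC
bin is exactly zero) and its power spectrum taken, with a 2-bin DC
neighbourhood suppressed. By the shift theorem the spectrum of the sum is
the texture spectrum times 2(1 + cos(**k**·**d**)): straight interference
strips with spacing N/|**d**| bins, normal to **d**. The strips are read
automatically by a second FFT of the log-power spectrum: a cosine of
period p bins appears as a peak pair at radius N/p — i.e. exactly at
±**d** in pixel units. Before this second FFT the mean log-power over each
radius annulus is subtracted: the texture's own spectral envelope is
smooth and isotropic and would otherwise swamp the cepstrum at small
radii, while the fringes are directional and survive untouched. The
dominant non-DC peak is refined by per-axis parabolic interpolation.

Fringe contrast is the peak's share of the total non-DC cepstral
magnitude; on 256² σ-50 targets genuine fringes score ≳ 1.2 × 10⁻³ and
unshifted pairs ≲ 2 × 10⁻⁴, so the detection threshold defaults to
5 × 10⁻⁴ (configurable). Shifts below 2 px leave no complete fringe in the
spectrum half-plane and report the no-fringe path (zero displacement).
Summing the frames destroys the sign of **d**; the sign is restored by
correlating frame 2 against frame 1 shifted by +**d** and −**d** and
keeping the better match (scores within 1 % leave the direction
unresolved, with a warning, as a 180°-ambiguous estimate).

On 256² σ-50 targets with true shifts of 3–32 px the full chain recovers
the displacement vector to ≤ 0.21 px and the direction to ≤ 0.8° (100/100
seeded trials), and agrees with an independent phase-correlation
registration to well under 0.5 px.

## Synthetic data: what it does and does not emulate

The generators emulate: texture statistics of the speckle targets (SD,
correlation length), rigid in-plane motion, anti-aliased circular markers
with a ~1 px camera PSF and additive Gaussian sensor noise, and linear
gauge responses with Gaussian noise. They do not emulate: perspective and
lens distortion, illumination gradients, occlusion, out-of-plane motion,
sensor nonlinearity, or hysteresis and viscoelasticity of real specimens.
Passing the synthetic suite therefore validates the *algorithms and their
numerics*, not the metrological performance of any physical rig; rig
acceptance still requires measurements of reference objects.

Validation problem sizes were chosen to exercise each claim at full
fidelity while keeping the whole suite interactive (seconds, one CPU):
256² speckle frames with 100-trial sweeps, 96² disc scenes with 50 seeded
scenes, 200 random masks for the morphology enumeration, and 20-replicate
gauge simulations.

## Degenerate inputs and tie-breaks

Zero displacement/angle in a rigidity step raises an undefined-rigidity
error rather than returning ±inf; an all-equal voltage design raises a
singular-design error; a featureless frame yields an empty detection list;
component ties in the centroid sort break by (y, x) of the center;
parabolic peak offsets are clipped to ±0.5 bin. JSON outputs are
pretty-printed with sorted keys and every output file carries the hash of
the configuration that produced it, so identical configurations produce
byte-identical outputs.
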