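# Methods

## Position encoding

The color map is modeled as a continuous field over a square frame of side
200 mm (top-left origin, x rightward, y downward, mm).  Each of the three
pigments (cyan, magenta, yellow) ramps linearly along an axis; the axes are
at 0°, 120° and 240° from +x.  The projection for a gradient at angle θ is

    p(x, y) = (pos − center) · (cos θ, sin θ) + side/2,

and the pigment value is `low + (high − low) · p / side`, with defaults
`low = 0x20`, `high = 0xD0`.  Referencing the projection to the map center
makes the mid-map pigment exactly `(low + high)/2` and keeps the usable
central 140 mm strictly inside the byte range; the continuous field is left
unclipped and unrounded (clipping/rounding happen only when rasterizing),
so linearity along gradient axes holds exactly.  Reflectance follows the
ideal subtractive complement `R = 255 − C` etc. — any channel-wise monotone
printer model would do; the complement is the simplest invertible choice.

Because the three axis unit vectors sum to zero, `C + M + Y` — hence
`R + G + B` — is constant over the map (405 counts at unit gain for the
defaults).  Sum-normalized chromaticity is therefore an affine injective
map of position, which is the property all decoding rests on.

Geometry constants: the pen rides in a 2-inch (50.8 mm) guide disc, so the
pen center can reach 200 − 50.8 = 149.2 mm of the frame; the software
usable span is the central 140 mm, decoded at 32 pixels/axis, i.e.
4.375 mm/pixel.

## Sensor simulator

The simulator reproduces the artifact classes the decoder must survive,
not the physics of any particular part:

* **Spot averaging** — mean reflectance over a disc of radius 1 mm
  (half the 2 mm fiber), via a fixed 37-point hexagonal quadrature.  The
  patch is centro-symmetric, so affine fields average exactly to the
  center value; a Monte-Carlo disc integral serves as the test oracle.
* **Gains** — counts per byte level, per channel (default 1.0).
* **Luminance drift** — a shared log-luminance random walk
  (σ = 0.002/sample): slow multiplicative wander, the canonical artifact
  that sum-normalization cancels.
* **Channel noise** — independent multiplicative Gaussian per sample,
  σ = 0.02 relative (default).
* **Lift-off** — a one-sample multiplicative collapse to 5% of the
  in-contact signal, satisfying the >50%-in-<250 ms detection premise.

All randomness flows from one seeded generator per stream (walk increment
first, then the three channel draws, per sample), so streams are
bit-reproducible.  Real per-channel gains and noise magnitudes of the
hardware are unpublished; these defaults are property-test conditions, not
hardware reproductions.  The simulator deliberately omits printed-map
nonlinearity, ink wear and specular effects — see Limitations.

## Calibration and forward interpolation

`calibration_grid` lays a grid_n × grid_n lattice (default 5×5) across the
usable span, endpoints on the boundary, row-major from the top edge.  Each
point is sampled `samples_per_point` times (default 30 ≈ 1 s at 30
samples/s); samples are normalized first, then averaged, then renormalized,
so brighter samples cannot outvote dimmer ones.  Whether normalization
precedes averaging, and which axis is fitted first, are config options
(`axis_order`), not silent guesses; for the default (affine) map both
orders agree to numerical tolerance.

Interpolation is separable ordinary-least-squares: per channel, a
quadratic through each grid row evaluated at all pixel-center x's, then a
quadratic down each resulting pixel column.  Coordinates are centered and
scaled before `lstsq` for conditioning; degree-≤2 separable fields are
reproduced to ≤1e−9.  Pixel i covers `[i·pitch, (i+1)·pitch)` of the span
(0-based, half-open) and is evaluated at its center.  Finally each pixel's
channels are renormalized to sum 1.

## Inverse lookup table

The LUT is built over normalized chromaticity — the quantity actually used
for positioning — quantized to B = 256 levels per channel
(`floor(c·(B−1) + 0.5)`), preserving the byte-space ±5% tolerance
semantics.  Construction:

1. **Seed**: `quantize(fwd[iy, ix]) → (ix, iy)`; collisions keep the
   lexicographically smallest (iy, ix) and are counted; >1% colliding
   pixels fails the build loudly.
2. **Project**: every unassigned triple whose Euclidean-nearest seed
   (ties: smaller distance, then smaller (iy, ix)) lies within
   `0.05·(B−1) ≈ 12.75` levels in *every* channel inherits that seed's
   pixel.  The envelope is per-channel (Chebyshev) because the tolerance
   is stated per channel; "nearest" is Euclidean because no metric is
   implied by a per-channel bound.
3. Everything else is off-map.

The production path vectorizes the search (candidate cubes around seeds,
deduplicated, exact integer-valued float32 distance argmin); tests compare
it entry-for-entry against a naive all-triples-vs-all-seeds scan on a
reduced instance (N=8, B=32).  Storage is a sparse dict; the file format
is a sorted text table, so rebuilds are bit-identical.

**A consequence worth knowing**: the frame's white background normalizes
to (1/3, 1/3, 1/3), which for the default symmetric gamut *equals* the
chromaticity of the map-center neutral gray.  A luminance-blind LUT
therefore cannot reject frame white by color; rejection of frame contact
falls to the redundant luminance-drop rule.  (A raw-byte-space LUT would
keep white ≥32 levels from the surface, at the cost of losing luminance
invariance everywhere else.)  Saturated chromaticities are rejected as the
envelope intends.

## Stroke decoding

Per sample: an all-zero count triple is invalid (treated as pen-up);
otherwise normalize and look up.  Lift-off uses two redundant cues:

* **Drop rule** — summed counts falling by more than `drop_fraction`
  (default 0.5) of any sub-interval-start value within `drop_window_s`
  (default 0.25 s), evaluated over a sliding window at every sample.
* **Off-map color** — an unassigned chromaticity (togglable via
  `require_offmap_confirmation`; the original system's exact conjunction
  is not documented, so the flag is exposed).

Because the simulated collapse is multiplicative, a lifted pen still reads
an on-map chromaticity; contact state therefore needs a re-entry rule:
after a drop-triggered lift, pen-down resumes once the summed counts
recover above `(1 − drop_fraction)` of the last in-contact level.  Every
rule is a ratio of sums, which makes the entire decoder exactly invariant
to scaling all counts by any constant — verified for ×0.25…×4.  A stream
that *begins* with a hovering pen is indistinguishable from contact (the
absolute level carries no information by design) and decodes as pen-down
until the first genuine lift.

Strokes collect consecutive pen-down samples; positions are pixel centers
in frame mm, smoothed by a causal rolling mean (default window 5, reset at
stroke boundaries; lag ≈ (window−1)/2 samples ≈ 67 ms at 30 Hz — the
decoder also reports its measured per-sample processing time).  A pen-up
dwell ≥ `completion_dwell_s` (default 1.0 s; the deployed value was
unspecified) completes the response, emits a trial-advance event (the
stand-in for the serial cue to the stimulus computer) and clears the
canvas.  Metrics per response: stroke count, per-stroke path length, mean
and peak finite-difference speed on the smoothed trace, lift-off count
(strokes − 1), total pen-down time, and hesitations — operationalized as
an in-stroke interval ≥0.3 s with all positions within one pixel pitch of
the interval start (the construct is named in the source protocol; the
rule is ours).

Letter rasters are drawn as stroke polylines (width 2) on a white canvas,
saved as PNG and JPEG; an optional per-stroke color palette makes stroke
order visible.

## Straightedge precision experiment

Five constant-y and five constant-x lines at fractions
{0.15, 0.3, 0.5, 0.7, 0.85} of the usable span (plus a seeded
uniform-within-pixel offset) are traversed at 35 mm/s — a careful
ruler-guided drag — under a chosen noise model.  Decoding is raw
per-sample lookup, deliberately unsmoothed.  Per traversal, the standard
deviation of the decoded perpendicular coordinate is computed about the
traversal's own mean, separately for samples in the central 50% of the
span and in the outer quadrants, pooled as RMS across traversals; RMS
error about the true line position is reported alongside.  With default
noise the central dispersion is ~2.7 mm — sub-pixel.

The center-versus-edge contrast deserves honesty: for an *ideal* affine
map, propagating the multiplicative noise analytically gives outer/central
dispersion ratios of only +1–2% per line, and the skewed Voronoi cells of
the seed lattice under the Euclidean chroma metric leak the
opposite-gradient cross-axis noise into the perpendicular coordinate,
partially cancelling even that.  Pooled over many seeds the outer
dispersion does exceed the central (ratio ≈ 1.01), but a single
10-traversal run detects the ordering only ~60% of the time.  A strong
edge degradation requires physical map/print nonlinearity, which this
ideal-map model intentionally omits.

## Numerical choices

* Byte rounding: half-up (`floor(v + 0.5)`), at raster and quantization.
* Quadratic fits: `lstsq` on centered/scaled coordinates; collinear
  values are fine (least squares is always defined).
* LUT distances: squared integer distances computed in float32 (< 2²⁴,
  hence exact); argmin's first-minimum implements the (iy, ix) tie-break.
* Empty degenerate inputs: empty scripts give empty streams; empty
  streams give empty response lists; a response must hold ≥1 stroke.
* Seeds: every stochastic entry point takes an explicit integer seed;
  artifact files embed seeds, parameters and the map-spec hash, and
  chained stages hard-fail on hash mismatch.

## Problem sizes used in tests

The suite runs the full default chain (5×5 calibration, N=32, B=256)
once as a shared fixture; exhaustive LUT audits use the reduced N=8,
B=32 instance; noise-propagation checks use 10⁴-sample streams and
20-seed averages.  These sizes were chosen to exercise every code path at
full default fidelity while keeping the suite fast.

## Limitations

* The map model is ideal-affine: no ink saturation, halftoning, ICC
  profiles or wear, so edge-of-map degradation seen with physical prints
  is only weakly reproduced (see above).
* The gradient byte sub-range [0x20, 0xD0] is a stand-in; the deployed
  map's exact range was never published.
* Frame-white aliasing of the center gray (above) is inherent to
  normalized-space lookup.
* No live GUI, serial I/O or stimulus-computer integration; trial
  sequencing is abstracted as events in the decoded output.
* Handwriting legibility is not scored — responses are rasters plus
  kinematic metrics, as the acquisition workflow leaves grading to
  humans.
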