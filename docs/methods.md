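# Methods

This note documents the models, conventions and numerical choices
behind `holoplankton`, in the order the pipeline runs.

## Wave-optics simulation and reconstruction

The camera is modelled as an in-line (Gabor) holographic scheme: a unit
plane wave travels from the source through a straight working volume of
length 338.4 mm to the sensor. (The physical instrument folds this path
with a mirror–prism system; folding changes nothing in the scalar-wave
description, so the equivalent straight path is used.) Particles are
opaque binary amplitude masks — classification uses silhouette geometry
only, so phase structure and partial transparency are not modelled. The
field is multiplied by (1 − mask) at each particle's plane, propagated
plane to plane, and squared at the sensor. Sensor noise is additive
Gaussian with relative σ = 0.01 by default, with optional Poisson shot
noise; every stochastic API takes a seed.

Propagation uses the angular-spectrum transfer function
`exp(2πi·d·sqrt((n/λ)² − f_r² − f_c²))` with evanescent components
zeroed. Two properties follow exactly: power conservation and
round-trip invertibility (`+d` then `−d` is the identity to machine
precision), because the kernel is unit-modulus on the propagating band.
A Matsushima-style band limit, which suppresses the wrap-around
replicas that appear beyond d ≈ N·p²/λ, is implemented but **off by
default**: band-limiting discards frequency content and therefore
breaks exact invertibility, while in a closed simulate→reconstruct loop
the wrap-around is reproduced and undone by the inverse kernel. For
reconstructing externally recorded holograms at long range,
`band_limit=True` is the better choice.

Reconstruction back-propagates the square root of the (background-
normalised) intensity. This carries the usual twin image of in-line
holography; no twin suppression is attempted beyond background removal
(divide by a Gaussian-blurred copy, σ = 1/20 of the sensor width, or
subtraction of a sequence mean).

Default optics: λ = 0.66 µm (red laser diode), 3.45 µm pixel pitch,
1024×1024 sensor. None of these are dictated by the instrument's
published specification; all are configurable. The entrance-pupil area
S0p is derived as exposure volume / working length = 0.5 L / 338.4 mm =
1477.5 mm² unless supplied.

### Scale caveat

The simulated sensor footprint (3.5 × 3.5 mm) is ~1/118 of the real
instrument's pupil cross-section. Simulated multi-particle scenes are
therefore far denser, per unit of image area, than the field situation
at the same volumetric concentration; overlapping silhouettes — which
are physically superposed along the optical axis and cannot be
separated from a single projection — are correspondingly over-
represented. Detection scores quoted below should be read with this in
mind.

## Scene synthesis

Each taxon gets a geometric body: filled ellipses (Copepoda, Copelata,
Cladocera, Other, Rotifera, Suspension), a thin flexed strip
(Chaetognatha, Phytoplankton chain), and a connected chain of
overlapping lobes (Marine snow). Antenna-bearing taxa receive two thin
anterior protrusions: length 0.32·H (0.45·H for bodies under 80 px,
so the protrusion stays resolvable), width ≤ H/20 and thinner than the
body core, angles limited so the whole mask fits the target rectangle.
After drawing, the mask is anisotropically rescaled (up to 4
iterations) until its measured minimum-area rectangle matches the
requested H within ~1 px and M within ~0.02 — the generator is
self-calibrating against the same measurement code used downstream.

Sampling cells (`TAXON_CELLS`) restrict each taxon's (H, M) draw to a
sub-range of its decision-tree cell: H is capped so silhouettes fit the
sensor footprint, and M is floored where the tree's nominal lower edge
(M → 0) is unrasterisable or would make antennae geometrically
impossible (e.g. Rotifera M ≥ 0.25). Positions are uniform in the
volume; frame particle counts in a cast are Poisson with mean
concentration × exposure volume — no clustering model. A configurable
cap (default 5% of the pupil) rejects scenes whose particles shade too
much of the frame.

What the generator does **not** emulate: real plankton texture and
transparency, swimming motion and blur, size–depth covariance,
aggregation. Passing closed-loop tests therefore demonstrates the
correctness of the measurement chain, not field-grade classification
accuracy.

## Particle extraction

1. **Candidates** — connected dark regions of the minimum-amplitude
   projection below mean − 2.5 σ. The area gate at this stage is 0.25×
   the area of a 0.1 mm disc: the sub-threshold dark core of a particle
   at the instrument's lower size bound underfills its silhouette, so
   gating at the full disc area would drop genuinely measurable
   particles. The definitive 0.1–28 mm size filter is applied to the
   measured H (with 10% grace below the floor for the same
   core-underfill bias).
2. **Focus and segmentation** — within each candidate window every
   slice is segmented with Otsu's threshold (holes filled; components
   labelled on a dilated copy so a body split from its antennae stays
   one component; touching silhouettes split by a watershed on the
   distance map, accepted only when a genuinely narrow neck separates
   two interior maxima). A component is accepted at the slice where its
   own sharpness profile peaks — the focus metric is normalised
   gradient energy (Tenengrad / mean²), chosen over amplitude variance
   because an opaque silhouette keeps high variance even far from
   focus, while its edges sharpen only at the true depth. Sub-slice
   depth comes from a parabola through the peak; ties break toward
   smaller z.
3. **Gates** — a component must contain a pixel at least 3 σ below the
   projection mean at its own depth (diffraction-ring arcs and halo
   fragments are much shallower: measured true-particle cores sit ≥ 4 σ
   deep, arcs at ~1.4 σ); duplicates within 0.55·H of an
   already-accepted sharper detection are dropped; border-truncated and
   out-of-size-range detections are excluded from metrics by default.
4. **Measurement** — H and M from the minimum-area rotated rectangle
   computed on boundary-pixel corners (an axis-aligned a×b block
   measures exactly a×b); S = pixel count × pitch²; compactness =
   area / boundary length (µm); antennae via morphological opening.

The antenna operator: the body is the opening of the mask with a disc
of radius min(0.25 × rectangle width, 1.1 × the 75th percentile of the
interior distance transform, 0.9 × the maximal inscribed radius) — the
percentile term keeps thin strip bodies from being erased wholesale.
Protrusions (mask minus body) count as antennae when they reach at
least 0.15·H beyond the body with reach/thickness ≥ 3, where reach is
the distance-from-body maximum and thickness twice the median interior
depth; these distance-based measures tolerate two antennae merging at a
common root. All constants are keyword arguments.

## Classification

The nine-row decision tree tests antennas, H against 200 µm, and M
intervals. Printed ranges touch without stating inclusion; the package
fixes: H = 200 µm belongs to the small-size branch; M intervals are
half-open [lo, hi) except intervals ending at 1, which are closed. Two
cells of the verbatim table are uncovered — (antennas, H ≤ 200,
M ∈ [0.9, 1]) and (no antennas, H > 200, M ∈ [0.9, 1]); the default
patched table routes both to "Other", and `validate_decision_table`
reports coverage gaps and overlaps for any user-edited tree (the tree
is editable as CSV). Classification is total and deterministic on
[0, 1] × (0, ∞) × {yes, no}.

## Metrics and profiling

Turbidity, ellipsoid volume and biomass are implemented exactly as in
the model section of the README; biomass includes every classified
particle (Marine snow and Suspension too) unless the caller filters the
table — the inclusion convention is the caller's choice, not hidden in
the code. Size statistics use the sample SD (n−1); with n < 2 the SD is
reported missing, never 0. Histograms use strictly half-open bins.
`summarize_with_uncertainty` returns mean, SD and a Student-t
confidence half-width; summaries are conventionally displayed as
mean ± SD, with the half-width available because "±SD at p = 0.05" is
not a well-defined interval.

Counts are non-overlapping blocks of N exposures (a sliding mode
exists, off by default); a trailing incomplete block is dropped with a
warning, so pooled particles + dropped remainder always equal the
stream total. Every exposure contributes volume whether or not it
contains particles. Hydrophysical data joins on nearest depth within
0.5 m (the probe's sensors are asynchronous); forward and backward
casts are kept apart because lifting the probe stirs the water it is
about to sample.

## Net-sample verification

An operator-classified net haul (organism, spp/m³) is mapped onto the
sensor's taxa by a shipped organism→taxon table and summed; the
agreement measure is round(100·|net − dhc|/net) with the net value as
reference (the traditional method is the benchmark). With the bundled
example pair this yields a holographic total of 1163.54 spp/m³ and
rounded differences of 23% (Cladocera) and 11% (Copepoda); the total
concentration computes to 7% by this formula. Taxa the sensor did not
detect at all (net > 0, dhc = 0) print 100% and are reported as such; a
zero net value makes the measure undefined and is flagged rather than
forced to a number.

## Verified behaviour at the shipped study conditions

All figures below are computed by the test suite and
`scripts/acceptance.py`, at these problem sizes: 500 closed-loop
particles; 20 detection scenes of 9 particles each (1024² frames,
z ∈ [30, 120] mm, 11-slice stacks); a 31-frame cast (0.3 m/s, 1 fps,
9 m, step profile 4000 spp/m³ above 4 m).

- Propagation round trip and power conservation: ≲ 1e−14.
- Single-disc oracle (0.6 mm at 50 mm): area within 10%, depth within
  a slice step.
- Detection recall 0.88–0.91 and precision 0.94–0.98 across seed
  families; residual losses are dominated by silhouettes overlapping in
  projection (see scale caveat).
- Closed-loop taxon recovery 96–98% across seeds; confusions sit at
  M-interval boundaries (rasterisation jitter ~±0.02) or the antenna
  flag of the smallest Rotifera.
- Cast recovery: every count within 3 Poisson SD of its expectation,
  zero false counts in the particle-free layer, step depth within one
  count spacing (1.5 m at these settings).

## Known limitations

- Same-depth laterally overlapping particles are reported as one
  detection; the desk-scale sensor makes this common at densities that
  would be unremarkable for the real pupil.
- The twin image is not suppressed; it slightly biases segmentation of
  very small particles toward under-measurement (hence the 10% grace
  at the size floor).
- Particle speed/trajectory estimation across frames is out of scope.
- Biomass beyond the ellipsoid model (taxon-specific length–weight
  regressions) is not implemented.
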