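# Methods

This note documents the models, defaults, and numerical choices behind
`ulm2d`, and what the synthetic validation does and does not establish
about real contrast-enhanced ultrasound (CEUS) data.

## Coordinate and data conventions

All physical quantities are micrometers and seconds. Images are row-major
with the origin at the top-left corner; pixel (i, j) is a square of side
`pixel_pitch` (reference 132 µm) whose center sits at
`((j + 0.5)·pitch, (i + 0.5)·pitch)` in (x, y). Ground-truth positions,
localizations, tracks and maps all live in this frame, so simulator
output and detector output are directly comparable without any registration.

## Synthetic vessel network and flow

The network generator builds a rectangular lattice spanning 2.2 × 1.1 cm
(12 × 7 nodes, spacings 2000 and 1833 µm — inside the 25 µm–2 mm segment
length range), assigns each segment a diameter drawn log-uniformly from
10–500 µm, and randomly prunes 25% of the segments subject to the graph
staying connected with every boundary node attached. Log-uniform
diameters keep microvessels represented despite the 50× range; the
lattice is a deliberately generic "grid of interconnecting vessels", not
an anatomical model.

Flow is laminar Poiseuille flow: segment conductance
`g = π r⁴ / (8 µ L)` with blood-like viscosity µ = 3.5 mPa·s by default.
Mass conservation at interior nodes yields a weighted graph Laplacian
system with Dirichlet pressures on the left (inlet) and right (outlet)
edges, solved densely (networks have ~10² nodes). Because the system is
linear in the pressure drop, the solution is rescaled post hoc so the
fastest segment's mean velocity equals a physiologic target (default
15 mm/s, inside the cm/s-scale arterial range the low-frame-rate gate
must accommodate); absolute pressures are otherwise irrelevant to the
pipeline. The solver refuses singular systems (a connected component
with no boundary node) naming the offending nodes, and asserts the
interior net-flow residual is below 1e-9 of the largest segment flow.

## Particle advection

Particles are dimensionless tracers of the segment *mean* velocity
`v = Q / (π r²)`: per frame interval a particle advances `v / frame_rate`
along its segment, crossing junctions by consuming time rather than
distance. At a junction the next segment is drawn with probability
proportional to outgoing volumetric flow, which preserves expected mass
transport. Each particle keeps a uniform lateral offset within the lumen
radius (redrawn per segment), so positions fill the projected vessel
cross-section while remaining inside the lumen by construction — the
containment invariant the tests verify at 100%.

The population is held constant (default 54 particles): a particle
reaching an outlet is replaced by a new identity injected at an inlet
with probability proportional to inlet flow. The initial population is
placed along flowing segments weighted by lumen volume — the uniform
steady-state concentration — so no wash-in transient is simulated. At
the reference 200-frame duration this gives 10,800 single-microbubble
placements, the documented order of magnitude (~10⁴) for such loops.
Per-frame merge labels are single-linkage clusters of particle centers at
385 µm (¾ of the 514 µm wavelength at 3 MHz), the separation below which
two echoes render as one event.

## Echo appearance model

Echoes are elliptical 2D Gaussians — an empirical appearance model, not
acoustics (no beamforming, attenuation, or nonlinear bubble dynamics).
What is calibrated is the *footprint*: the pixel count above half the
peak at 132 µm pitch. Target areas are drawn from a two-piece log-normal
pinned exactly to the reference quartiles (8/12/20 px), floored at the
5 px minimum; given a drawn area A and an aspect ratio k ~ U[1, 2.5], the
axis sigmas solve `A = 2π ln2 · σ_a σ_b / pitch²` exactly, so pixelation
is the only quantization (±1–2 px). Orientation is uniform; elongation
and orientation are described only qualitatively in the source data, so
these two distributions are modeling choices. A sampled appearance whose
pixel-centered footprint falls below 5 px from quantization is inflated
by 3% steps until it honors the floor.

Peak intensities are uniform in [60, 200] grayscale units. The noise
default follows the rule that the faintest sampled echo peak equals three
noise standard deviations, hence σ_n = 20. Note the rule is
scale-invariant: only the *shape* of the intensity distribution relative
to the 3σ floor matters for accuracy (see Limits below). Rendering
evaluates each Gaussian at pixel centers (exact sub-pixel placement),
sums contributions, adds i.i.d. zero-mean Gaussian noise — the standard
additive approximation for log-compressed speckle — and clips at zero.

### Single-microbubble mode

`SequenceConfig(single_mb_only=True)` renders, per frame, only particles
whose nearest same-frame neighbor is at least 1 mm away. This is the
configuration of the localization-accuracy experiment, which is defined
over *single* (well-separated) events: 1 mm exceeds twice the largest
appearance sigma in the reference size model, so every rendered echo is a
resolvable, unimodal blob. Without the separation floor, neighbor pairs
at 450–650 µm with σ_major up to ~460 µm render as provably unimodal
composite blobs that no seed detector can split, and one-to-one pairing
at 385 µm then charges one missed event per such pair — a property of the
scene, not of the algorithm under test.

## Detection

**Noise level.** Stored grayscale is clipped at zero, which folds the
lower noise tail onto 0 and breaks plain MAD estimates. The sequence
noise σ̂ is estimated from the upper quantile spread,
`(Q75 − median)/0.6745`, correct for Gaussian noise with or without the
clip and insensitive to the sparse bright echoes.

**Haar features.** Center-surround kernels: a positive disk core of unit
mass (radii 1.6/2.0/2.5 px, matched to the 8/12/20 px footprints) and a
negative annulus of unit mass out to twice the core radius, hence zero
response to any flat background. The feature image is the per-pixel
maximum response over scales, normalized to [0, 1] by the frame maximum;
thresholds are carried in the raw response domain, where the response of
a zero-mean kernel to white noise of sigma σ̂ has standard deviation
σ̂·‖k‖₂. The significance threshold is `z · σ̂ · max_s ‖k_s‖₂` with
z = 1.5 by default — low, by design: the minimum-size and intensity gates
downstream are the effective noise classifiers, and a higher z erodes the
significance footprint of floor-sized echoes below the 5-px gate. A
Monte-Carlo calibration (`calibrate_noise_threshold`) is provided when a
stated false-pixel rate is preferred over the z-rule.

**PPI.** Within each significant 8-connected component, a pixel's
particle probability is the fraction of significant pixels in a local
window at the *particle-area* scale (default 3 px ≈ √(min footprint)).
Earlier versions sized the window to the component's bounding box; that
collapses the PPI wherever two echoes bridge into one component and
silently deletes exactly the events that matter, so the particle-scale
window is used instead.

**Seeds.** Initial regions are components of PPI ≥ (1/e)·max PPI.
Candidate seeds are local maxima of the Gaussian-smoothed frame
(σ = 1 px, 3 px neighborhood by default; plateau ties broken at the
lexicographically smallest index). Maxima inside a region with PPI above
the threshold are kept; a region left without any maxima is seeded at its
brightest smoothed pixel, so no detected region is silently dropped.
The merged-mode preset (σ = 2 px, 7 px neighborhood, open size gate)
deliberately under-seeds so an overlapping echo yields one detection.

An adaptive non-local-means pre-filter is available before the Haar
stage, off by default: on the synthetic reference conditions it degrades
faint-echo detection more than it reduces noise.

## Segmentation and localization

The watershed relief is `max − smoothed` ("inverted Gaussian"): echoes
become basins, the background marker occupies every pixel outside the
initial regions, and flooding from it meets the seed's flood near the
background intensity level, so the basin recovers the echo's full
above-floor footprint. Each seed's basin is intersected with the initial
regions (keeping the connected part containing the seed), which pins the
segmented area to the detection floor. The gradient-magnitude relief is
retained purely as the comparison baseline: its watershed line forms on
the maximum-slope ring (radius ≈ σ of the echo), which shrinks regions —
small echoes then fall under the 5-px gate (missed events) and the
region boundary cuts through bright flank pixels whose inclusion jitter
degrades the centroid. Both effects are asserted, directionally, in the
acceptance suite.

Region filtering keeps `min_area ≤ area ≤ max_area` and mean intensity at
least the operator's estimate. Because the inverted-Gaussian area is the
full above-floor footprint — roughly twice the half-maximum calibration
area — an operator processing these loops opens the maximum-size gate
(the reference experiment uses 400 px) and flags events above the
single-event third quartile (20 px) as merged. Localization is the
intensity-weighted center of mass of the region pixels; zero total
intensity is a contract error.

## Tracking and maps

Events in consecutive frames link when each is the other's nearest
neighbor within a gate (default: 20 mm/s over one frame interval, i.e.
2 mm at 10 Hz — the fastest blood the method should follow). Unmatched
events begin or end tracks; a merged-flagged event may absorb several
predecessors or emit several successors, recorded as parent/child track
links while every event keeps one track identity. Mutual-nearest
association is deterministic and, at these densities, agrees with the
optimal assignment (a test oracle) essentially always.

Maps are rendered on a grid subdivided 3× per pixel: 44 µm subpixels,
comparable to the localization RMSE, which is the criterion that makes
subdivision meaningful. Tracks with fewer than two points carry no
displacement and are excluded. A density subpixel counts distinct
crossing tracks (Bresenham rasterization of the polyline; a track counts
once per subpixel); a velocity subpixel averages the local step speed of
the crossing tracks — local rather than track-mean speed, with the
alternative available by computing means upstream. FWHM is measured on a
linearly interpolated profile at 4 samples per subpixel, as the distance
between the half-maximum crossings around the global profile peak.

## Evaluation

Ground truth is merged-aware: in `merged` mode the events are merge-label
groups at their peak-intensity-weighted centers (what the localizer
estimates for an unresolved clump); in `single` mode they are the
singleton-labeled particles, and multi-particle clumps are not scored.
Pairing is per frame, one-to-one, greedy on globally increasing distance
within 385 µm — beyond that distance two echoes are distinct events by
the merge criterion itself. Reported statistics: RMSE over pairs,
missed% (ground truth without a pair), spurious% (detections without a
pair), min/max deviation.

## Accuracy limits under the reference noise rule

Under the generator's noise rule (faintest peak = 3σ_n) the faint stratum
carries an information-theoretic floor: the Cramér–Rao bound for
localizing a Gaussian spot of the reference sizes at peak 3σ_n in white
noise is ≈ 35 µm per axis (≈ 50 µm 2D), and mixing the strata at the
reference intensity distribution puts the population-optimal RMSE near
32 µm. The pipeline measures 34–54 µm across seeds (bright echoes ≈
22 µm, ≈ 1.3× their CRB), i.e. the centroid operates close to the
information limit; reported RMSE reflects the chosen noise conditions,
not estimator inefficiency. Missed events on the single-microbubble
reference run are 0.0–0.1% across seeds; the residual cases are
floor-sized (5 px) echoes whose segmented region occasionally lands under
the minimum-size gate — the method's own noise classifier.

## What the synthetic validation does not show

The simulator emulates echo geometry, flow-driven motion, and background
noise, but not: spatially varying PSF across depth (appearances are
position-independent), speckle correlation (noise is i.i.d.), tissue
motion (loops are static; the rigid registration stage is exercised on
separately constructed fixtures), attenuation or time-gain artifacts, or
out-of-plane bubble transit. Passing the synthetic suite therefore
validates the algorithmic chain and its bookkeeping, and bounds its
statistical accuracy under the stated conditions; it does not certify
performance on clinical loops, where the preprocessing stages
(artifact masking, registration) and the operator parameters carry more
of the burden.

## Reference problem sizes

Tests and the acceptance script use: 200-frame loops at 10 Hz on a
100 × 183 px canvas (the 1.1 × 2.2 cm field plus an 8-px margin so border
clipping does not contaminate accuracy statistics), 54-particle steady
population (~2,000–3,000 well-separated singles per 200-frame
single-microbubble run), 10,000 appearance draws for the size-distribution
check, and dense-oracle networks of ~10–20 nodes. The full suite runs in
well under a minute on one CPU.
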