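# Methods

## Input model and conventions

A segmentation is a rectangular binary raster containing exactly one
object, drawn either as a filled region or as a closed line possibly
thicker than one pixel. Foreground is strictly `value > 0` after collapsing
RGB to luminance, so `{0,1}` and `{0,255}` masks load identically without a
threshold parameter. Masks with more than one 8-connected foreground
component (after hole filling) are rejected: the tool fuses one object per
mask, and silently picking a component would hide annotation errors.

Coordinates are `(row, col)`, 0-based, origin at the top-left. Foreground
is 8-connected and background 4-connected — the standard dual pair, which
prevents diagonally "leaky" contours. Polar angles are measured
counterclockwise from the +col axis with the row axis pointing down, so
"up" in the image is θ = π/2.

## One-pixel boundary lines

Three line flavours are defined for a mask (selected by `line_mode`,
default `external`):

* **internal** — foreground pixels of the hole-filled mask that are
  4-adjacent to background. Filling the internal line recovers the region
  exactly, which makes it the right choice when bit-exact region identities
  matter.
* **external** — the ring of background pixels 4-adjacent to the filled
  region. It is disjoint from the region; an object touching the canvas
  border has no external ring and raises an error.
* **middle** — the topology-preserving skeleton of the original *unfilled*
  thick line, followed by spur pruning (iterative deletion of endpoint
  pixels) until only the closed loop remains. A filled blob has no defined
  thickness, so `middle` on one degrades to `internal` with a warning.

A contour is *closed* when background flood-fill from the border leaves at
least one unreached background pixel (it encloses an interior). The
one-pixel-wide contract is "no fully-foreground 2×2 block", and the
package's thinning primitive (`thin_line`) only deletes pixels inside such
blocks whose 8-neighborhood foreground forms a single circular arc — this
flattens genuine thickness while provably never breaking a clean 1-pixel
loop (corner pixels of staircase boundaries are not candidates, unlike
generic skeletonization, which shaves them).

## Fusion algorithms

*Largest* is the perimeter of the hole-filled union; *Smallest* the
perimeter of the area where the per-pixel count of (hole-filled) votes
equals N. An empty common area or a union that splits into several objects
is an error rather than a silent guess.

*Average Smallest And Largest* needs a line "between" the two. The band
`L \ interior(S)` (the annulus between the regions, including both
boundary rings) is skeletonized with the distance-transform medial axis and
spur-pruned. The medial axis of an annulus is the ring at the medial
radius, matching a distance-ridge oracle within ±1 px on nested-disk
fixtures; plain thinning-based skeletons of the same band sag up to ~1.3 px
inward and were rejected. The medial-axis tie-break order is seeded so the
operation is deterministic. When Smallest equals Largest the common
perimeter is returned directly.

The *Average Target* family walks every pixel of a target contour (the
Largest fusion, the Smallest fusion, or a chosen input) and groups it with
the nearest pixel (Euclidean; ties toward smaller row, then column) of each
other contour; the target pixel belongs to its own group. The group's
consensus is the midpoint for two points; the midpoint of the two mutually
farthest points when all members are exactly collinear (integer
cross-product test — members are grid pixels, so no tolerance is needed);
otherwise the arithmetic mean of the members. "Centroid of the polygon" is
deliberately the mean of the points: a handful of unordered pixels defines
no polygon orientation, so an area-weighted centroid would require an
ordering the data does not provide. Consensus points are rounded
half-away-from-zero and the resulting cloud is closed (below).

*Middle* ranks the masks by filled area and performs ⌊(N−1)/2⌋ removal
iterations, each dropping the current smallest- and largest-area member
(area ties drop the lowest rater index). Odd N leaves one survivor, whose
contour is returned bit-exactly; even N leaves two, fused by the configured
tiebreak (`average` = Average Smallest And Largest, `largest`, or
`smallest`). With N = 2 and the `average` tiebreak the output is
bit-identical to Average Smallest And Largest, as the two-input case
degenerates to the same band construction. Area ranking was chosen because
containment ordering is ill-defined for crossing contours; a consequence is
that permutation invariance holds exactly only when areas are distinct.

*STAPLE* treats the unknown truth as a per-pixel foreground probability
W and each rater j as a pair (sensitivity p_j, specificity q_j). The
reference is initialized by per-pixel majority vote; the M-step
re-estimates (p_j, q_j) against W, and the E-step updates W from the
prevalence prior π and the rater votes, in log space. π is the mean
foreground fraction of the inputs and is held fixed. Iteration stops when
max |ΔW| < tol (default 1e−6), when the thresholded reference stops
changing between iterations, or at max_iter (default 100); the final
region is W ≥ threshold (default 0.5), hole-filled. On clean simulations
the majority-vote initialization is already the EM fixed point, so
convergence in one iteration is the norm. The implementation agrees with
an independent ITK-based STAPLE on consensus regions (JI ≥ 0.99) and on
sensitivities to within 0.02 on the bernoulli-rater fixture.

## Closing sparse point clouds

The averaging algorithms emit unordered pixel clouds. Points are converted
to polar coordinates about a reference center — the centroid of the filled
union of the input set, which coincides with the largest region's centroid
for nested inputs and is always defined; standalone closing defaults to the
cloud centroid. Points are sorted by angle; angles colliding within 1e−9
rad are merged by averaging radii, keeping r(θ) single-valued. This polar
model is exact for star-shaped contours and an approximation otherwise
(documented, not an error).

* **linear** — consecutive points joined cyclically by straight chords.
  Each chord is rasterized by evaluating the segment interpolant
  f(x) = ((x₁−x)·y₀ + (x−x₀)·y₁)/(x₁−x₀) at every integer step of its
  major axis and rounding half-up. This pins the rasterization to a
  documented convention (generic Bresenham variants make different
  rounding-tie choices), so an independent re-implementation reproduces
  the output bit-exactly. The chord union *is* the result — no thinning —
  and every input pixel is preserved.
* **pchip** — monotone piecewise-cubic Hermite interpolation of r(θ),
  wrapped periodically by appending the first sample at θ+2π. Monotone
  runs of the samples produce monotone interpolated radii (no overshoot).
  The curve is sampled at Δθ ≤ 0.5/r_max (plus the sample angles
  themselves, so input pixels are reproduced exactly), rasterized, and
  thinned with the input pixels protected.
* **chan_vese / geodesic** — morphological active contours initialized at
  the filled convex hull of the points (iterations = 0 returns the hull
  boundary). The energy image is built from the cloud itself: Chan–Vese
  runs on a Gaussian-smoothed rough region obtained by morphological
  closing of the point raster with the smallest radius that produces an
  interior; the geodesic contour runs on g = d²/(d²+s²) of the distance
  transform (s = 3 px) with a shrinking balloon. Input pixels are *not*
  guaranteed preserved. Both reproduce a densely sampled circle with
  JI ≥ 0.97 on the 96×96 fixture.

Exactly collinear clouds cannot enclose area and raise a degenerate-
geometry error from every closer.

## Evaluation

The Jaccard index is computed on hole-filled regions: a fused contour is
compared as the region it encloses, because the index of two 1-pixel rings
is near zero regardless of how well they agree. `rank_algorithms` runs
every configuration on every case, stores per-case JI, ranks by descending
row mean (stable ties), excludes failed cells from the mean with a warning
rather than zero-filling them (zero-filling would silently punish erroring
configurations), and exports the table as CSV.

## Synthetic raters

The generator provides ground-truth shapes (disk, ellipse, random smooth
blob — all star-shaped about their centroid) that must fit the canvas with
a 2-pixel margin so external rings fit, and two rater models:

* **boundary** raters displace the boundary radius profile r(θ) by a
  truncated Fourier series (default 6 harmonics, no DC term, hence
  zero-mean) normalized so the maximum displacement equals the stated
  amplitude in pixels. Amplitude 0 returns the input unchanged. Defaults
  (5–6 raters, amplitude 2 px on a radius-20 disk) give individual-rater
  JI ≈ 0.93, a realistic level of annotator disagreement.
* **bernoulli** raters keep each true foreground pixel with probability p
  and each background pixel with probability q — exactly the generative
  model STAPLE assumes. The raw vote field is exposed for accuracy-recovery
  experiments; masks returned by `simulate_raters` are additionally cleaned
  (largest component, holes filled) to satisfy the single-object mask
  invariants. The cleanup repairs most sensitivity losses, so recovery of
  the nominal (p, q) must be measured on the raw fields.

Every generator operation is a pure function of (inputs, seed).

What the simulation does not emulate: systematic annotator bias (all
simulated raters are unbiased around the truth), outlier annotations,
correlated errors between raters, non-star-shaped objects, and intensity or
texture information. Passing tests on these fixtures demonstrates the
contracts of the algorithms, not their ranking on any particular real
dataset — on real data with biased or outlier raters the relative merits of
the algorithms can differ.

A consequence worth stating: with an *odd* number of raters the Middle
algorithm reduces to selecting the median-area annotation, so its expected
JI gain over a typical rater is zero (measured −0.0007 ± 0.0007 over 200
replicates of the 5-rater study); its averaging behaviour — and any
systematic gain — only engages through the tiebreak at even N. The
averaging-based consensus algorithms (Average Smallest And Largest, STAPLE)
show a clear positive gain (≈ +0.02 JI) on the same fixtures.

## Problem sizes

Default study sizes were chosen to keep every experiment comfortably
desk-scale while leaving discretization effects small relative to the
tolerances: 64×64 canvases with radius-20 truths for fusion studies
(boundary ≈ 126 px), 128×128 with radius 30 for STAPLE recovery
(≈ 16k pixels per vote field), 10–50 replicate seeds per property, and
16-sample circles for closing fidelity.

## Known limitations

* The polar closing model approximates non-star-shaped consensus clouds.
* Multi-object masks, multi-label fusion, probabilistic output maps and 3D
  stacks are out of scope; multipage TIFFs are rejected.
* Middle's area ranking is order-dependent under exact area ties.
* Active-contour closers depend on two fixed scale constants (adaptive
  closing radius search, s = 3 px edge scale); extremely sparse clouds may
  need more iterations or fail to converge, which is reported as an error.
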