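# Methods

This note records the model, the numerical choices, and the design
decisions behind lenstrace, including the places where the design was
genuinely open and what was chosen there.

## Contour model

A closed contour sampled at N points is the complex sequence
z(i) = x(i) + j·y(i) in image coordinates (x rightward = real axis,
y downward = imaginary axis, origin top-left). Its descriptors are the
unnormalized DFT coefficients c(k) = Σ z(i)·e^(−j2πki/N), so
c(0) = N·centroid and, for a circle of radius r, |c(1)| = N·r. The
inverse evaluates the truncated Fourier series with the +j sign; the
round trip with the full coefficient set is exact to floating precision
(asserted at 1e−9).

Conventions that were open and had to be fixed:

- **Truncation order.** "14 descriptors" does not say which. We keep the
  lowest absolute frequencies, symmetric about zero, favoring +k on ties:
  k = 0, ±1, …, ±6, +7. Lowest-|k| selection is the standard
  minimal-distortion truncation and reproduces coarse-to-fine
  reconstruction behavior.
- **Common sampling count.** All database shapes are resampled to N = 64
  arc-length-equidistant points before the transform, so every descriptor
  set lives on the same index set and morphing is well defined. 64 ≫ 14
  retains detail without cost.
- **Size semantics.** A hypothesis `size` is the first-harmonic radius
  |c(1)|/N in pixels (≈ lens half-width). Placement multiplies normalized
  coefficients by size·N and rewrites c(0) = N·centroid. Defining size as
  raw |c(1)| would make the IPD-relative sampling interval (below)
  correspond to sub-pixel lenses, so the radius convention is the only
  internally consistent one.
- **Normalization.** Translation invariance by dropping c(0); scale
  invariance by dividing by the scalar magnitude |c(1)| — not the complex
  value, so orientation and starting phase are preserved. No rotation or
  start-point normalization: rims are matched in image orientation.
- **Horizontal flip.** Implemented in descriptor space as
  c(k) → −conj(c(−k)) with c(0) preserved, which mirrors the point set
  about the vertical axis through the centroid (traversal order
  reverses, and the frequency index set is negated; flipping twice is an
  exact involution).

## Shape database

Left-rim shapes only; three classes. The built-in database is procedural
and deterministic (fixed internal seed): rounded rectangles
(aspect 0.55–0.75, corner radius 0.12–0.28), superellipses (aspect
0.60–0.85, exponent 1.9–2.4), and aviator-like asymmetric shapes (top
depth 0.45–0.52 of the half-width, bottom 0.35 deeper, nasal shear
±0.10–0.18 with fixed top/bottom exponents 2.6/2.0), 16 per class.

Two properties drove the parameter ranges, both load-bearing for the
search:

- **Class separability.** The winning class is the one whose refined fit
  scores best, so families that overlap (a near-zero-shear "asymmetric"
  shape is just a superellipse) directly produce class misidentification.
- **Within-class morph coverage.** Refinement never re-draws the shape
  pair; the 1-D morph through two random anchors must be able to
  approximate any family member. That requires few effective shape
  degrees of freedom per class (≈ 2 here). Early variants with ~5 free
  parameters in the asymmetric family left a 3–4 px shape-mismatch floor
  that no amount of position/size refinement could remove.

Three manually traced reference rims ship verbatim as a JSON fixture with
a documented index-mapping assumption (pairs printed high-to-low
frequency, c(0) last; orientation normalized on load by the k ↔ −k swap).
They are serialization/flip-test fixtures only: their recorded
coefficients carry enough high-frequency energy to self-intersect when
reconstructed under this package's conventions, which would violate the
database invariant that every same-class morph is a simple closed curve.

## Matching

Canny edges (smoothing σ = 1.4; hysteresis thresholds default to
Otsu-on-gradient-magnitude inside the ROI for the high threshold and half
that for the low — overridable) feed the exact Euclidean distance
transform. A rim is scored by the mean DT value under its 8-connected
rasterized boundary (64 reconstructed points joined by digital segments,
duplicate pixels counted once; pixels clipped at the field border read
the border value so the pixel count stays stable). Lower is better; the
combined score of a pair is the arithmetic mean of the two rims. The
acceptance direction is stated explicitly because a literal reading of
"best matching score" with a distance-based score is ambiguous: this
package minimizes everywhere.

Validation clauses, checked in order fifths → size → enclosure →
centroid → ROI (the order fixes which reason is reported when several
fail): lens vertical sides inside bands 1–3 (left) / 3–5 (right) of the
facial fifths anchored on the intercanthal gap; lens bounding box
strictly larger than the eye rectangle in both dimensions; eye center
strictly inside the rim polygon; lens centroid within 0.25·IPD of its
eye center (the "close to the eyes" rule needed a number; 0.25 matches
the sampling box); both contours inside the ROI.

## Search

Per class, 2000 hypotheses with all dimensions uniform: left centroid in
a ±0.25·IPD box around the left eye, right centroid x independently
around the right eye (y tied to the left centroid — frames are near
horizontal under the ≤ 10° tilt assumption), size in [0.35, 0.70]·IPD,
shape pair with replacement, β in [0, 1]. Validation runs vectorized
over the whole batch (clause-for-clause identical to the scalar path,
which a test asserts); only survivors are rasterized and scored.

Clustering is agglomerative on hypothesis bounding boxes (union of both
lens boxes): repeatedly merge the pair with the highest overlap fraction
(intersection over the smaller area) while it is ≥ α = 0.90; cluster
score is the mean of member scores and selection is best member of the
best cluster. Two caveats discovered during development and documented
here as limitations: with ~10³ valid hypotheses the enclosing-rectangle
merge rule chains clusters together (typically 1–3 clusters survive), so
in practice selection is close to picking the globally best valid
hypothesis, and false-positive suppression is carried mostly by the
validation clauses. The uniform 5-D sampling also means the best of 2000
samples typically still sits several pixels of mean edge distance from
the rims — the Monte Carlo stage *brackets*; it does not localize.

## Refinement

Because the sampling stage leaves 5–20 px errors with partial
compensation between position and size, the random walk must both escape
a curved, compensated valley and polish to sub-pixel accuracy. A
fixed-scale proposal does neither (a traced run with σ = 0.02·IPD
accepted 4 of 30 moves and stalled at 4.4 px mean edge distance), so the
proposal model anneals: per-dimension Gaussian scales start at 0.06·IPD
(position, size) and 0.20 (β) and decay geometrically to 5% of their
initial value over the walk. One iteration sweeps the four dimensions —
left centroid, right centroid x, size, β — in randomized order,
perturbing one at a time and accepting only strict score improvements;
β is clamped to [0, 1] and the shape pair is never re-drawn. 30
iterations, kept from the original heuristic. The walk is monotone by
construction and degenerates to the identity at zero sigma.

The pipeline runs search + refinement per class and returns the class
solution with the lowest combined score; a final mean edge distance
above 5 px (an addition — the original procedure has no reject path)
raises an extraction failure, as does finding no valid hypothesis at
all.

## Synthetic scenes and evaluation

Scenes are 800×600, background intensity 200, with: two dark elliptical
pupil blobs (intensity 30, 0.09·IPD × 0.055·IPD half-axes) at jittered
eye positions (IPD ≈ 200 px); lens interiors rendered as filled tinted
regions (intensity 150) whose boundaries are the exact 64-point truth
contours built from the same database/morph/place/flip chain the search
uses (truth size 0.35–0.42·IPD, centroid jitter ±0.05·IPD, rejection
sampling keeps the truth valid, inside the ROI, with a positive bridge);
optional eyebrow arcs (intensity 90 — strong edges, but above the
template detector's pupil threshold), nose line, specular blobs, and a
decoy superellipse 0.55·IPD below the eye line. Rim gaps are local
heavy-blur patches (σ = 7 blur blended in with a dilated, saturated
feather mask over 2–3 random arcs totaling the gap fraction): the blur
removes the edge response the way low-contrast rim segments do, while
the feather avoids phantom edges at the patch border. Gaussian intensity
noise (σ = 3) is added last. Generation is bit-deterministic in the
scene seed.

The fill-based rendering (rather than a stroked outline) is deliberate:
a thin stroke produces a double Canny chain at ±1 px and the truth
contour would sit *between* the chains, spoiling the render-then-score
self-consistency (truth rim score < 1 px) that anchors the evaluation.

Evaluation uses the truth-normalized area overlap
|detected ∩ truth| / |truth| on pixel-center rasterized interiors
(shapely), with a scene counting as a true positive when both lenses
reach γ = 0.95. This measure cannot penalize oversized detections, so
the benchmark also reports intersection-over-union as a symmetric
diagnostic. What passing these batteries shows is that the search and
refinement machinery recovers known parameters under partial contours,
clutter, and noise; it does not demonstrate robustness to skin texture,
shadows, hair, rimless frames, or perspective — none of which the
generator emulates.

## Problem sizes and runtime

Default problem sizes: 2000 hypotheses × 3 classes per image, 30
refinement sweeps, 64-point contours; about 3 s per 800×600 scene on one
CPU. The standard batteries are 50 clean, 50 cluttered, 20 decoy scenes;
typical results at these sizes are ~90% clean true positives at γ = 0.95
(≥ 96% class identification), ~70–95% under clutter depending on gap
placement, and 100% decoy rejection — the exact numbers for a given seed
are computed by `scripts/acceptance.py`, never hard-coded.

## Known limitations

- Eye localization ships without a trained cascade: the `cascade` mode
  requires a user-supplied classifier file; the built-in template
  detector is only valid for imagery where the pupils are the darkest
  compact blobs (true of the synthetic scenes).
- The cluster stage's chaining behavior (above) weakens the intended
  cluster-mean selection at large hypothesis counts.
- Mirror symmetry of the frame is a hard model assumption; strongly
  asymmetric frames (or > 10° head tilt) are out of scope.
- The γ-overlap criterion is asymmetric by design; report IoU alongside
  when comparing methods.
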