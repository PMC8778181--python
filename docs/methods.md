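# Methods

## Face-tree representation

A face is the ordered 68-landmark set of the standard convention (jaw 0–16,
brows 17–26, nose bridge 27–30, lower nose 31–35, eyes 36–47, outer mouth
48–59, inner mouth 60–67). The tree uses landmark 27 as the nose top and 30
as the nose tip; the nose axis (top → tip) defines both the unit length and
the zero orientation, which is what delivers similarity invariance. Primary
nodes are, in id order 1–8: the left-eye center (centroid of 36–41), the
right-eye center (centroid of 42–47) — both measured from the nose top —
and the mouth center (centroid of the outer contour 48–59) plus the five
lower-nose points 31–35, measured from the nose tip. Secondary nodes are
the contour points measured from their primary parent's endpoint: ids 9–19
are the left eye (6) and left brow (5), ids 20–30 the right eye and brow,
and ids 31–59 the outer mouth (12) and jaw (17).

Two layout choices deserve comment. First, the inner-mouth points are *not*
tree nodes: the secondary spans under the three non-leaf primaries must be
11 + 11 + 29 for the branch expansion to cover ids 9–59, and outer mouth +
jaw is the only contour combination that yields 29. Second, "left" means
image-left (landmarks 36–41). Every consumer of the tree — prototypes,
clustering, the synthetic generator — uses the same convention, so the
choice is unobservable downstream.

Degenerate inputs: fewer or more than 68 points, non-finite coordinates,
and a zero-length nose vector are rejected with typed errors rather than
propagated as NaNs.

## Lattice distance

Per node and coordinate the operands are intervals; the node distance under
v(x) = λx, θ(x) = 1 − x is evaluated in the valuation form
[v(θ(a∧c)) − v(θ(a∨c))] + [v(b∨e) − v(b∧e)], which reduces to
λ(|a − c| + |b − e|). Branch distances are computed leaves-to-root as
parent term + k_child · Σ children; the root term vanishes because both
trees are nose-normalized, and the root combiner is fixed at 1. The
whole-tree distance is k_r·D_r + k_φ·D_φ. For fixed nonnegative weights
this is a genuine (pseudo-)metric — the test suite checks non-negativity,
symmetry, identity and the triangle inequality on random triples, and the
hierarchical recursion against an independently written flat weighted-L1
closed form at 1e−9 relative error.

φ is treated as a *linear* quantity: interval endpoints are differenced
without wrap-around. Circular handling would break the linear interval
arithmetic the valuation form relies on; the cost is that two orientations
just either side of ±π look maximally distant. Nose-relative angles of
near-frontal faces live far from ±π, so in practice this affects only
extreme poses; it is a known limitation.

Batch operations (classification, cross-validation, k-means) use a
vectorized pairwise evaluation of the same closed form; a property test
pins it to the scalar branch recursion.

## Prototypes, classification, cross-validation

A pose prototype is the per-node min/max envelope of its training trees, so
envelope soundness (every training tree inside its prototype) holds by
construction and is asserted as a test. Classification is
nearest-prototype under the tree distance, ties broken to the lowest
prototype index in the canonical order (FrontLeft, FrontProper, FrontRight,
then poses 1–8); the three Front sub-classes merge to Front for reporting.
Cross-validation is stratified and seeded, and prototypes are re-induced on
each fold's training split only, to avoid leakage. Accuracy is scored on
the merged nine poses.

## GA metric optimization

The 126 weights are searched by a real-coded GA over genes in [0, 10]:
tournament selection (size 3), uniform crossover (rate 0.9), per-gene
Gaussian mutation (σ = 0.5, rate 1/126) clipped to bounds, one elite. The
all-ones chromosome (the plain unweighted metric) is always placed in
generation 0, so with elitism the result can never be worse than the
default metric. Fitness is the seeded cross-validated accuracy; fitness
values are cached by chromosome bytes, and the whole run is deterministic
given (data, config). The documented full scale is population 500 for 50
generations; the test suite exercises reduced scales (populations 10–50,
5–10 generations), which suffice to demonstrate elitism monotonicity,
determinism, bound preservation and planted-irrelevance recovery (a
pure-noise node's λ is driven below the informative nodes' λ, median over
five seeds).

## State induction

k-means runs with the lattice distance in the assignment step, initialized
at the 11 prototype midpoint trees, and merges the three Front clusters to
state 0. The centroid update is the per-coordinate arithmetic mean with φ
re-wrapped to [−π, π] — the classical k-means update, kept deliberately
even though the coordinate-wise *median* is the exact minimizer of the
weighted-L1 objective; the mean update is the canonical formulation of the
algorithm and converges in practice (the empirical objective is asserted
non-increasing in tests). Empty clusters keep their previous centroid;
assignment ties go to the lowest cluster index; iteration stops when
assignments repeat or after 300 iterations.

## Session analysis

Completeness and eligibility follow the frame contract: a frame is complete
iff it carries both robot-action values and landmarks, and attempts without
complete frames are ineligible. Events are indexed 1-based within each
attempt's complete-frame series; events whose k−1 or k+lag fall outside the
series are skipped, not clamped. Animation counts as active for any value
other than "None" (an override list is accepted for sensitivity analyses,
e.g. excluding "Stand"). Histograms with zero active frames report an
explicit empty flag and all-zero probabilities, never NaN.

Pattern mining tokenizes each state series into maximal runs and emits one
occurrence per window of exactly `min_distinct` (default 3) consecutive
runs with all symbols distinct and all run lengths ≤ `max_run` (default 3,
matching the 3 Hz intuition that up to three repeats are the same behavior
at different speed). Occurrences are *not* double-counted at sub-windows:
"8066" is one occurrence of class "806", not additionally an occurrence of
"806" itself. Modality profiles over a class count each spanned frame once
even when consecutive occurrences overlap, so all four modality totals
agree by construction. Windows never cross attempt boundaries, since
frames are only contiguous at 3 Hz within an attempt.

## Synthetic data

The pose generator rotates a fixed 3D template (anatomically plausible
68-point layout, inter-ocular distance 1.3 units, constants in
`face_template_3d`) by per-pose yaw/pitch presets (Front sub-classes at
yaw −12/0/+12°, the outer poses at ±35° yaw and/or ±25° pitch,
sign-symmetric), projects orthographically and adds Gaussian pixel jitter.
Noise presets emulate a 2×2 camera-distance × lighting design purely as
difficulty ordering: σ = 0.5%, 1%, 2%, 3% of the inter-ocular distance for
40cm/normal, 1m/normal, 40cm/dim, 1m/dim; nonzero presets also perturb the
pose angles (σ = 100× the jitter fraction, in degrees) and randomize scale
and position, none of which survive tree normalization. At noise "none"
generation is fully deterministic and all samples are identical. Training
uses 100 stills per pose sub-class at full scale; tests use 10–20 per class,
which preserve the same separability structure.

The session generator drives a sticky Markov chain over states 0–8
(stay-probability 0.8, remainder uniform — so the stationary law is
uniform); for 6 frames (2 s) after any action outset the transition row is
mixed with a point mass on state 0 with weight `boost` (default 0.6),
which is the planted cause→effect link. Robot actions follow independent
two-state on/off chains per modality (outset rate 0.02/frame, mean duration
9 frames ≈ 3 s). Landmarks for each frame are drawn from the pose generator
for the state's pose; a configurable fraction (default 0.15) of frames is
blanked to emulate failed face detection. Everything derives from one seed.

What the generator does *not* emulate: correlated landmark-detector error
(jitter is i.i.d. per landmark), perspective distortion, partial occlusion,
within-child idiosyncrasy or drift, and any coupling between robot actions
and detection failure. Passing tests therefore demonstrate correctness of
the representation, metric, classifiers and counting tools under the stated
generative assumptions — not field accuracy on clinical recordings.

## Numerical choices

- Angle wrapping uses ((x + π) mod 2π) − π everywhere.
- Tree-equality and oracle tolerances are 1e−9 (the pipeline is linear
  arithmetic; errors stay near machine precision).
- All ties (classification, clustering assignment, GA tournament) break to
  the lowest index, making every component deterministic under its seed.
- Metric weights must be finite and ≥ 0; GA genes live in [0, 10].

## Interfaces

The library is the primary interface; the `facelattice` CLI is a thin
dispatch layer over it (simulate / build-prototypes / classify / optimize /
cluster-states / analyze). Frame logs travel as the CSV dialect
`timestamp,animation,sound,leds,speaking,x0,y0,...,x67,y67` (blank landmark
cells = no detection, optional `state` column); metric parameters as the
flat 126-gene JSON chromosome; prototypes as labeled interval-tree JSON.
Every CLI run writes its resolved configuration (with a hash and the
package version) next to its outputs.
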