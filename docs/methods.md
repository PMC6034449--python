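# Methods

This note records the model behind `agrimorph`, the parameter choices that
matter, what the synthetic data generator does and does not emulate, and the
numerical conventions adopted where the design was genuinely open.

## The max-tree and its contract

A grey image f : E → [0, 255] is decomposed into its upper level sets
L_k = {f ≥ k}; the connected components (peak components) of all level sets,
nested by decreasing k, form the max-tree.  The implementation promises a
*canonical* tree: a component that is identical across consecutive levels is
stored once, at its highest level; every node owns at least one "proper"
pixel whose value equals the node level; the root is the unique component at
the global minimum; leaves are exactly the regional maxima.  Reconstructing
each pixel as the level of its owning node reproduces the input bit for bit
— this identity is asserted in the tests, as is node-by-node equality with a
brute-force enumeration of level-set components.

Parent/traverser computation is delegated to `skimage.morphology.max_tree`
(with a small union-find fallback for 1-pixel-thick images, which the
library rejects); everything above that — canonicalization into a node
table, attribute propagation, extinction values, branch selection — is this
package.  Default connectivity is 4 (8 available); nothing in the method
depends on the construction algorithm, only on the canonical contract.

The min-tree is the max-tree of 255 − f with levels reported on the
original scale; it is provided for completeness (dark-structure analysis)
and tested for structural duality, but the vegetation pipeline uses only the
max-tree, since plants are bright in NDVI.

## Attributes, propagated once

Area, coordinate sums up to second order, grey extrema and convex-hull
candidate vertices are propagated leaves-to-root, so each pixel is visited
once no matter how many nested regions are evaluated.  Moments use pixel
centers; the discrete A/6 correction enters in the feature formulas, not in
the stored sums.  Hulls are taken over the four corners of each pixel, so a
1-pixel-wide region has hull area ≥ 1 and solidity stays ≤ 1 by
construction.  Per-node hull propagation is available (`with_hull=True`)
and is verified against direct per-region hulls; the segmentation path
computes hulls only for accepted regions, from their explicit pixel sets —
both routes are asserted equal to an independent geometric oracle.

## Extinction values and markers

The grey-range extinction of a regional maximum is the contrast it retains
before merging into a branch carrying a higher maximum: leaf value minus
the level of the first ancestor whose subtree holds a better leaf.  "Better"
means higher value, ties resolved toward the lexicographically smallest
representative pixel — a deterministic choice the filtering definition
alone cannot make, since a filter flattens tied peaks into one plateau.
Exactly one leaf (the global winner) receives the full image range.  The
default marker threshold keeps leaves with extinction ≥ 10 grey levels;
the threshold is inclusive, reading "discard values smaller than 10"
literally.

## Growth-factor segmentation

Candidates along a marker branch are the canonical nodes from leaf to
root.  The growth of a candidate at level k compares it with the candidate
at the largest level ≤ k − Δ; when the span runs past the root level, the
root's area is used.  With this reading a strongly contrasted object that
merges directly into a much darker background registers its merge spike
even though the canonical tree skips the intermediate levels — the
alternative reading (smallest level ≥ k − Δ) assigns such an object zero
growth everywhere and the method collapses on clean two-level scenes.

Selection per branch: take B = argmax G (ties prefer the higher level — the
more contrasted core); then repeatedly scan candidates with
G_min < G(R) < G(B) in descending growth (ties by descending level), adopt
the first R with A(R) > K·A(B) if it is confirmed by l consecutive
candidates whose areas lie within ±e_A of A(R), and restart from the top
with the new B.  Both G_min bounds are strict; an unconfirmed R terminates
the adjustment (the scan does not move on to the next large candidate).
The loop terminates because each adopted B grows by a factor K ≥ 1.

Defaults: Δ = 30, G_min = 10, K = 15, e_A = 0.15, l = 6, marker threshold
10.  The area threshold T defaults to 0 (off) — no universal value exists,
since it encodes the minimal physical plant size for a given camera
geometry; the synthetic study uses T = 50 px.  Exact duplicates are
detected by node identity (two selections are the same region iff they
resolve to the same canonical node); nested non-identical regions are kept
deliberately, as they may capture sub-structures of overlapping vegetation.
Near-duplicate suppression is out of scope.

## Features and normalization

The five descriptors (solidity, eccentricity, circularity,
non-compactness, grey range) are defined in the README.  Circularity and
non-compactness are built as exact reciprocals, both 1 for an ideal disk,
with the 1/(6A) discrete correction making the single-pixel values
6/(2π) ≈ 0.955 and 2π/6 ≈ 1.047.  Eccentricity comes from the eigenvalues
of the second-moment matrix and is defined as 0 for a degenerate (single
pixel) region; a 1-px-wide line has eccentricity exactly 1 with
center-based moments.  Feature matrices are min–max normalized to [0, 1];
a constant column maps to 0.5; statistics are learned on training folds
only and transformed test values are clipped back to [0, 1].

## Classifier protocol

The SVM uses Platt-scaled probability outputs, so p_crop = 1 − p_weed and a
prediction is rejected when max(p_crop, p_weed) < c (nothing is rejected at
c = 0.5).  Grid: linear C ∈ {1, 10, 100, 1000}; RBF, the same C crossed
with γ ∈ {10⁻³, 10⁻⁴}; polynomial degree ∈ {2, 3, 4} with C = 1 (no cost
being prescribed for that kernel).  Each grid point is fitted on a
stratified 70% of the prepared training samples and scored by crop-F1 of
the *probability-based* decision on the remaining 30% — scoring the raw
decision function instead can select a near-constant kernel whose Platt
calibration has degenerated, which is exactly the model that then fails at
prediction time.  The first grid point wins ties, making selection
deterministic for a fixed seed.

Mixed regions (crop and weed in one segment) are duplicated into both
classes for training; at evaluation a mixed ground-truth region counts as
correct under either decision (a strict mode counts it wrong under both).
Rejected samples count as missed positives, never as false positives.
Cross-validation partitions *images*, not regions, into k = 10 folds, and
normalization statistics are fitted per fold on training regions only, so
no held-out information leaks through either the model or the scaling.

## Global-threshold baselines

Otsu maximizes the between-class variance ω₀ω₁(μ₀−μ₁)² over all 255
splits of the 8-bit histogram, ties resolved to the lowest threshold; a
constant image is rejected.  RATS computes T = Σwf / Σw with w the Sobel
gradient magnitude (√(gx²+gy²), replicate borders) where it exceeds ηλ,
λ = 3 by convention; when no gradient clears the noise level the threshold
is not well-defined and the implementation raises — the documented
low-content failure mode.  η has no universal default (it is tuned per
acquisition setup); the package default is 1.0 and the CLI exposes it.
Foreground is f > T.  Precision is defined as 0 for an empty prediction and
F1 as 0 when p + r = 0, so every metric is always defined.  Interpolated
precision at recall r is the maximum precision at any recall ≥ r (the
inclusive closure keeps the curve defined at its own support).

## Synthetic study conditions

The generator emulates the statistical regime the method assumes, not the
appearance of real fields.  Defaults, fixed once as the study conditions:
512×512 images; soil at grey level 70 with smoothed-noise texture of 9
grey levels peak-to-peak (σ = 6 px) and an illumination drift of 8 levels;
sparse speckle (0.2% of soil pixels) of prominence 2–8 levels; 10 plants
per field with contrast uniform in [40, 90] over local soil and target
core areas of 300–1500 px; compact multi-lobe rosettes for crop and thin
rotated ellipses (aspect 8–14) for weed, rendered with coverage-based
anti-aliased borders (ground truth = pixels with ≥ 50% coverage).  The
grey-level budget is deliberate: soil texture and speckle prominence sit
*below* the extinction threshold of 10, plant contrast sits well above it —
speckle maxima are numerous (hundreds per field) and are exactly what the
marker filter must remove.  Every plant top is flat at its local soil level
plus its contrast, guaranteeing a regional maximum inside each plant.  The
low-vegetation variant caps foreground at 0.5% of the image (4 small plants
near the center) and raises the illumination drift to 25 levels, emulating
a nearly empty bed under natural light — the regime in which a global
threshold splits the soil itself while the local method is unaffected.

What passing the synthetic suite shows: the tree machinery is exact (it
matches brute-force enumeration), the selection rule recovers contrasted
regions whose area is stable over tens of grey levels, performance is flat
in Δ when object edges are sharp, and five shape features suffice when the
class-conditional shape distributions differ.  What it does not show:
robustness to registration parallax, specular soil debris, overlapping
canopies with gradual NDVI transitions, or real weed/crop shape overlap —
on real data the reported F1 values are substantially lower and the Δ
sensitivity larger, and nothing here contradicts that.

## Numerical conventions and degenerate inputs

NDVI at NIR + VIS = 0 is defined as 0; quantization is linear with
round-half-up, so 0 → 128.  Loaded single-channel images are treated as
already-quantized NDVI.  8-bit processing throughout (the extinction scale
presumes grey levels 1–255).  Empty images, constant images for Otsu,
uniform images for RATS, non-leaf branch starts, empty feature matrices and
unknown labels all raise `ValueError` rather than returning sentinel
values.  All stochastic components (generator, fold assignment,
oversampling, SVM internals) are seeded; identical seeds give bit-identical
outputs.

## Problem sizes

The test suite and the acceptance script run the full pipeline on ten
512×512 fields (plus ten low-vegetation fields) and a 20-image classifier
study of ~150 regions; oracle equivalence checks use 10–16 px images where
exhaustive enumeration is exact.  These sizes were chosen so the entire
study re-runs from scratch in well under a minute on one core while still
exercising every code path at realistic marker counts (several hundred
maxima per field).
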