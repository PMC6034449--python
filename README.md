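# agrimorph

Attribute-morphology vegetation segmentation and crop/weed classification
for NDVI field imagery.

Precision-agriculture robots need to find every plant in an image of a field
and decide which plants are crop and which are weed before applying a
per-plant treatment.  The standard first step — picking one global grey
threshold on a vegetation-index image (Otsu, RATS) — breaks down under
uneven lighting, textured soil and low vegetation cover.  `agrimorph`
instead makes every decision *locally*, on a single hierarchical
representation of the image: the **max-tree**, the nesting hierarchy of the
connected components of all upper level sets L_k = {f ≥ k} of the NDVI
image f = (NIR − VIS)/(NIR + VIS), quantized to 8 bits.

The pipeline, end to end on one tree:

1. **Markers.**  The regional maxima (tree leaves) are ranked by their
   grey-range *extinction value* — the contrast a maximum keeps before its
   branch merges into a branch with a higher maximum.  Maxima with
   extinction < 10 grey levels (noise, soil texture) are discarded; on noisy
   imagery this removes ~98% of the raw maxima.
2. **Segmentation.**  Walking a marker's branch from leaf to root visits the
   regions obtained by thresholding around that maximum with a decreasing
   threshold.  At each region R_k the growth factor over a span of Δ grey
   levels,

       G(R_k) = (A(R_{k−Δ}) − A(R_k)) / A(R_k),

   spikes when the contrasted object merges into its background.  The
   region with the largest growth is selected, then adjusted to favour
   slightly larger, repeated regions (parameters G_min = 10, K = 15,
   e_A = 0.15, l = 6), optionally filtered by a minimal area T, and exact
   duplicates are removed.  No connected-component relabelling or noise
   post-processing is needed.
3. **Features.**  Each accepted region is described by five descriptors
   computed incrementally on the tree (no pixel is visited twice): solidity
   A/A_hull, ellipse eccentricity √(1 − b²/a²), moment-based circularity
   A²/(2π(μ₂₀+μ₀₂+A/6)), its exact reciprocal non-compactness
   2π((μ₂₀+μ₀₂)/A² + 1/(6A)), and the grey-level range f_max − f_min.
4. **Classification.**  A support vector machine with probability outputs
   (p_crop = 1 − p_weed) separates crop from weed regions; regions
   containing both classes are presented once as crop and once as weed, the
   minority class is oversampled to exact balance, predictions below a
   confidence c are rejected, and evaluation uses image-level 10-fold
   cross-validation with a kernel/parameter grid chosen on a 70/30
   validation split.

Otsu and RATS global-threshold baselines and precision/recall/F1 evaluation
with interpolated PR curves are included, together with a seeded synthetic
field generator (textured soil, illumination drift, speckle, compact
rosette crops vs thin elongated weeds) that provides per-pixel and
per-region ground truth for all tests.

## Worked example

```python
from agrimorph import (FieldSpec, generate_field, segment,
                       SegmentationParams, pixel_metrics)

sample = generate_field(FieldSpec(seed=3))          # 512x512, 10 plants
result = segment(sample.ndvi.values, SegmentationParams(area_threshold=50))
print(f"{result.n_leaves} maxima -> {result.n_markers} markers"
      f" -> {len(result)} regions")
m = pixel_metrics(result.to_mask(), sample.truth)
print(f"precision={m.precision:.3f} recall={m.recall:.3f} F1={m.f1:.3f}")
```

prints

```
663 maxima -> 11 markers -> 10 regions
precision=0.981 recall=0.995 F1=0.988
```

i.e. of 663 regional maxima in the noisy NDVI image, the extinction filter
keeps 11 markers; the growth-factor scan turns them into 10 regions (one
pair of markers converged on the same node), which cover the 10 generated
plants at pixel F1 0.988.  `result.to_dataframe()` lists each region's
marker position, level, area and growth; `result.to_label_image()` exports
a 16-bit label image in which nested regions overwrite outer ones.

The same workflow is available from the shell:

```sh
agrimorph synth --seed 3 --out fields/
agrimorph segment fields/field_000/ndvi.png --T 50 \
    --truth fields/field_000/truth.png --out seg/
agrimorph classify features.csv --k 10 --out clf/
agrimorph eval seg/ndvi_mask.png fields/field_000/truth.png
```

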