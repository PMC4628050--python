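# mammoseg

Segmentation of suspicious masses in digitized mammograms, with a complete
evaluation metric suite and a synthetic-phantom generator for ground-truth
testing.

Masses are among the primary radiological signs of breast cancer, and
delineating them automatically is hard: mammograms are low-contrast, the
bright pectoral muscle in mediolateral-oblique views mimics lesions, and
mass margins fade smoothly into fibroglandular tissue. `mammoseg`
implements a classical CAD-style pipeline:

1. **Fuzzy contrast enhancement.** The gray-level histogram is summarized
   by five parameters (α = min, γ = max/2, β₁ = (α+γ)/2, β₂ = (max+γ)/2,
   max) and every intensity *u* is mapped to a membership value *P* by a
   piecewise-quadratic S-type intensification that is 0 at α and max and 1
   at γ; defuzzification maps the plane back with
   g′ = round(α + P·(max − α)). Intensities near γ are stretched apart,
   extremes are compressed.
2. **Graph-based region merging with a dynamic threshold.** The image is a
   weighted graph (pixels as vertices, 4/8-neighbor edges, weight
   w = |I(vᵢ) − I(vⱼ)|). Edges are processed once in ascending order; two
   regions merge when the inter-region measure (the current, i.e. minimum,
   connecting weight) does not exceed the dynamic threshold
   DT(R₁,R₂) = min(Int(R₁) + k/|R₁|, Int(R₂) + k/|R₂|), where Int(R) is the
   largest edge weight accepted inside R. The merge scale *k* is derived
   from the edge-weight histogram by **Otsu's method** (maximize
   ω₀ω₁(μ₀−μ₁)²), so the threshold adapts to each image.
3. **ROI extraction and pectoral-muscle flagging.** The region containing a
   top corner is flagged as pectoral muscle when brighter than the global
   mean. The brightest interior region of plausible area seeds the mass
   ROI, which is delineated at half maximum over the dominant tissue level;
   candidates whose support floods into the borders (pectoral fragments,
   noise clumps) are rejected in favor of the next-brightest seed.
4. **Metrics.** PSNR/MSE, NSD/ENL, index of fuzziness, fuzzy entropy,
   target-to-background contrast (σ- and entropy-based), pixel confusion
   statistics (sensitivity, specificity, PPV, NPV, accuracy), ROC AUC,
   region-overlap acceptance (IoU ≥ k, default k = 0.75), asymmetric local
   refinement error |R(A,p)\R(B,p)|/|R(A,p)|, and boundary F-measure by
   minimum-cost bipartite edgel assignment.

Because clinical mammogram databases cannot be redistributed, the package
ships a seeded phantom generator (`mammoseg.synthetic_phantoms`) that
renders mammogram-like images — dark background, half-elliptical breast,
pectoral wedge, Gaussian-profile masses, additive noise — with exact
analytic ground truth (mass support at half amplitude, radius σ√(2 ln 2)).

## Worked example

```sh
mammoseg phantom --out phantoms --n 2 --seed 42 --noise 4
mammoseg segment phantoms/phantom_001/image.pgm \
    --labels labels.png --roi roi.png --report report.json
mammoseg evaluate --pred roi.png --truth phantoms/phantom_001/mass_mask.png \
    --image phantoms/phantom_001/image.pgm --out eval.json
```

The segment step prints `248 regions (k_scale=13.965); ROI -> roi.png`:
the Otsu-derived merge scale was ≈14 gray levels and the merge produced 248
regions, from which the ROI was extracted. `eval.json` then contains
(abridged):

```json
{
  "iou": 0.959,
  "dice": 0.979,
  "overlap_accepted": true,
  "sensitivity": 0.992,
  "specificity": 0.9998,
  "ppv": 0.967,
  "accuracy": 0.9997,
  "f_measure": 0.978
}
```

The extracted ROI overlaps the half-maximum ground-truth disc with IoU 0.96
(passing the k = 0.75 region-overlap acceptance), misses <1 % of mass
pixels (sensitivity), and its boundary matches the true boundary almost
edgel-for-edgel (F = 0.98).

The same operations are available as library calls
(`mammoseg.enhance`, `mammoseg.segment`,
`mammoseg.graph_segmentation.detect_mass`, `mammoseg.evaluate_masks`, …).

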