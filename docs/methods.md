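# Methods

## Fuzzy histogram enhancement

The enhancement operator works on the gray-level histogram's five summary
parameters, all real-valued (no premature rounding):

    alpha = min(I),  max = max(I),  gamma = max/2,
    beta1 = (alpha + gamma)/2,  beta2 = (max + gamma)/2.

Fuzzification maps u ∈ [alpha, max] to a membership P through four
piecewise-quadratic rules (an S-type intensification), evaluated in rule
order over half-open domains so that degenerate orderings (gamma ≤ alpha
whenever min > max/2) simply leave the lower domains empty:

    [alpha, beta1):  P = 2((u − alpha)/(gamma − alpha))²
    [beta1, gamma):  P = 1 − 2((u − gamma)/(gamma − alpha))²
    [gamma, beta2):  P = 1 − 2((u − gamma)/(max − gamma))²
    [beta2, max]:    P = 2((u − max)/(max − gamma))²      (corrected, default)
                     P = 2((u − gamma)/(max − gamma))², clamped  (literal)

In the default *corrected* mode the transform is continuous on
[alpha, max], equals 0 at both endpoints and 1 at gamma, and is unimodal;
adjacent branches agree exactly at beta1, gamma and beta2 (both give 0.5 at
the betas). The *literal* mode keeps the upper branch in its published
form, which reaches 2 at u = max and is clamped to [0, 1]; it is retained
for comparison but breaks the membership-range contract, which is why it is
not the default. The fuzzy-modification step is the identity on the plane —
the intensification already lives in the rules — with the function boundary
kept as a hook for alternative operators.

Defuzzification is the affine map g′ = round(alpha + P·(max − alpha)),
rounding half away from zero: the simplest monotone map back onto the
original dynamic range. Constant images (no dynamic range) are returned
unchanged with a warning.

Note the transform is *not* a brightness-preserving stretch: intensities
near gamma = max/2 map toward max while both extremes map toward alpha.
On phantom suites the index of fuzziness and the fuzzy entropy of the
enhanced image's membership plane are lower than the original's (the
acceptance script computes both), i.e. the enhanced histogram is crisper.

## Otsu thresholding

`otsu_threshold` maximizes the between-class variance
sigma_b²(t) = ω₀ω₁(μ₀ − μ₁)² over all splits {level ≤ t} / {level > t} with
two non-empty classes, exactly and deterministically (ties broken at the
smallest maximizing t). It serves twice:

- on gray-level histograms, as the conventional image thresholder (used to
  separate background from breast tissue during ROI refinement);
- on the segmentation graph's edge-weight distribution (256 equal-width
  bins over [min, max]; the returned scale is the threshold bin's center),
  where it supplies the default merge scale `k_scale`. This is what makes
  the merge threshold "dynamic": the scale separating within-region from
  between-region dissimilarities is estimated per image rather than fixed.

## Graph-based region merging

One vertex per pixel (row-major), one edge per neighbor pair; connectivity
defaults to 8. The default edge weight is |I(vi) − I(vj)| — dissimilarity
in the intensity feature. A `spatial_literal` mode weighting edges by the
Euclidean distance between pixel coordinates exists for completeness; under
it every weight is 1 or √2 and the partition cannot depend on content, so
it is never the default.

Edges are processed once in ascending (weight, i, j) order — fully
deterministic. For the two regions joined by the current edge,

    IRM(R1, R2) = w_current                      (minimum connecting weight,
                                                  by the ascending order)
    DT(R1, R2)  = min(Int(R1) + k/|R1|, Int(R2) + k/|R2|)

and the regions merge when IRM ≤ DT. Int(R) — the region's internal
measure — is the largest edge weight accepted during its merge history, so
DT adapts both to region homogeneity and (through k/|R|) to region size.
The partition is maintained in a union-find forest (union by size, path
halving) carrying per-region size, Int and intensity moments. A post-pass
over the same edge order merges any region smaller than `min_size`
(default max(16, 0.01 % of pixels)) into its lowest-connecting-weight
neighbor, suppressing speckle. Labels are renumbered by each region's first
row-major pixel, making results bit-reproducible.

Limit behavior is exact and tested: k = 0 in intensity mode yields the
connected components of constant intensity; k → ∞ yields a single region;
the region count is non-increasing in k. A naive replay oracle
(dictionary-of-pixel-sets over the same sorted edge list) validates the
union-find partition on random images.

## Pectoral flagging and ROI extraction

The pectoral muscle appears as a bright wedge at a top corner in
mediolateral-oblique views. The region containing the designated corner
pixel (side `left`, `right`, or `auto` = brighter corner) is flagged when
its mean intensity exceeds the global mean; otherwise no flag.

ROI candidates are regions that (a) have between `min_area` (12 px) and
`max_area_frac` (25 %) of the image's pixels, (b) do not touch the image
border — breast silhouette, background and pectoral wedge all do — and
(c) are neither the pectoral region nor 8-adjacent to it (bright slivers
along the pectoral margin are the classic false positive). Candidates are
ranked by mean intensity, brightest first.

Ascending-minimum-edge merging systematically under-segments smooth
masses: on a Gaussian-profile mass the merge cascade stalls once the
quantization-level rings on the slope grow larger than the merge scale, so
the winning region is a bright *cap* centered on the mass, not its full
extent. The cap is therefore treated as a seed, and the mass support is
delineated at half maximum: threshold = bg + (peak − bg)/2, where peak is
the seed's maximum on a σ = 1 px smoothed image and bg is the dominant
tissue level (mode of the smoothed histogram above the image's Otsu
threshold — in a mammogram, the fibroglandular plateau). The connected
component containing the seed is kept and holes are filled. A candidate is
rejected — and the next-brightest tried, up to 10 — when its half-maximum
component reaches the image border or the refinement window border (3× the
seed extent): a contained focal mass fits well inside both, whereas
pectoral fragments and faint noise clumps flood outward. With
`refine=False` the raw seed region is returned instead; note the refined
mask is a level set and need not be a union of merge regions.

`detect_mass` composes the pipeline: edge weights are computed on a
Gaussian-smoothed copy (σ = 0.8 px; minimum-edge merging is notoriously
fragile under pixel noise, and light pre-smoothing is the standard remedy),
while region statistics, flagging and refinement use the original
intensities. `segment` itself never smooths, so its limit guarantees hold
exactly as stated.

## Evaluation metrics

Conventions fixed for reproducibility: population (biased) standard
deviations; base-2 entropies; `inf` sentinels for degenerate denominators
(PSNR of identical images, ENL of constant regions); NaN with a warning for
undefined confusion statistics.

- MSE/PSNR: psnr = 10·log10(max_level²/mse).
- NSD/ENL over a homogeneous region (default: 5 % border strip as
  background proxy): std and (mean/std)².
- Index of fuzziness (2/N)Σ min(P, 1−P) and normalized fuzzy entropy
  (1/(N ln 2))Σ S(P); both 0 iff crisp, 1 iff all P = 0.5.
- Target-to-background contrast |μT − μB|/(σT + σB + ε) and
  |HT − HB|/(HT + HB + ε), ε = 1e−12, capped at 1e12.
- Region overlap acceptance: IoU ≥ k, boundary inclusive, default k = 0.75.
- Local refinement error E(A,B,p) = |R(A,p)\R(B,p)|/|R(A,p)|, asymmetric
  (zero under refinement); the mean over pixels is computed from the
  label-pair contingency table.
- Boundary agreement: 8-connected inner border pixels, bipartite
  assignment with Euclidean costs gated at d_max = 2 px, solved exactly
  (Hungarian) on the admissible sub-problem; precision = matched/|A|,
  recall = matched/|B|, F = 2PR/(P+R).
- ROC AUC via the rank (Mann–Whitney) formula, ties counted ½ —
  identical to the trapezoidal empirical ROC area.

## Synthetic phantoms

A phantom emulates the salient structure of a digitized MLO mammogram:
background (level 20), half-elliptical breast silhouette anchored to the
chest-wall side (level 100; vertical semi-axis 0.65·H so the silhouette
spans the whole chest-wall edge and the wedge owns the top corner),
pectoral wedge (level 180, right triangle covering 35 % of the top width),
plus Gaussian masses I += A·exp(−d²/2σ²) and additive Gaussian noise,
rounded and clipped to [0, max_level]. Defaults for the single-mass
recovery suites: σ ∈ [5, 9] px, A ∈ [70, 110], sizes 96–160 px — masses
conspicuous enough for a screening-style phantom yet spanning a 2× range of
scale and contrast. Ground truth is analytic: the mass mask is the union of
half-amplitude discs (radius σ√(2 ln 2)), the FWHM convention for a
Gaussian lesion.

What the phantoms do **not** model: textured fibroglandular tissue,
spiculated or ill-defined margins, overlapping structures, vessel/duct
clutter, scanner artifacts. Passing the recovery suites therefore
demonstrates correctness of the pipeline's mechanics (merging, scale
selection, flagging, delineation, metrics) under controlled conditions, not
clinical-grade performance on real mammograms.

## Problem sizes and determinism

Test and acceptance runs use phantoms of 96–160 px square and 20-phantom
suites, 500-histogram and 200-image oracle sweeps — sizes chosen so the
full validation runs in well under a minute on one core while every check
remains exact. All randomness flows through explicit seeds
(`numpy.random.default_rng`); identical inputs give bit-identical outputs,
including region labels and JSON reports.

## Known limitations

- The ROI extractor assumes a single dominant tissue plateau when
  estimating background; strongly bimodal parenchyma would bias the
  half-maximum threshold.
- Candidate ranking by mean intensity presumes masses are the brightest
  focal structures; calcification clusters would compete.
- `spatial_literal` edge weights are content-blind by construction and
  provided only for comparison.
- The literal fuzzification branch exceeds 1 before clamping; analyses
  needing a true membership plane should use the corrected mode.
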