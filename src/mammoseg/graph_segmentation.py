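"""Graph-based region-merging segmentation with a dynamic threshold.

The image is mapped onto a weighted undirected graph: one vertex per pixel
(row-major rank), one edge per neighboring pixel pair under 4- or
8-connectivity.  The default edge weight is the intensity dissimilarity
``|I(vi) - I(vj)|``; a ``spatial_literal`` mode weighting by the Euclidean
distance between pixel *coordinates* is kept for completeness (under it all
weights are 1 or sqrt(2) and the partition cannot depend on image content).

Edges are processed once in ascending weight order (ties broken by vertex
indices, fully deterministic).  Two regions R1, R2 joined by the current
edge are merged when the inter-region measure does not exceed the dynamic
threshold:

    IRM(R1, R2) = w_current            (the minimum connecting weight,
                                        since edges arrive in ascending order)
    DT(R1, R2)  = min(Int(R1) + k/|R1|, Int(R2) + k/|R2|)

where ``Int(R)`` is the region's internal measure — the largest edge weight
accepted during its merge history — and ``k`` (``k_scale``) sets how strongly
small regions are encouraged to grow.  When ``k_scale`` is not given it is
derived from the edge-weight distribution itself by Otsu's method
(:func:`mammoseg.otsu.otsu_weight_scale`), which is what makes the threshold
"dynamic": the scale adapts to each image's dissimilarity statistics.

A post-pass merges any region smaller than ``min_size`` into its
lowest-connecting-weight neighbor.  ROI extraction then selects, among
interior regions of plausible area, the one with the highest mean intensity;
the pectoral muscle (bright wedge at a top corner) is flagged separately so
it cannot masquerade as the mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import scipy.ndimage as ndi

from .image_io import BinaryMask, GrayImage
from .fuzzy_enhancement import DegenerateHistogramError
from .otsu import otsu_image_threshold, otsu_weight_scale

__all__ = [
    "WeightMode",
    "PixelGraph",
    "RegionForest",
    "SegmentationResult",
    "edge_weight",
    "build_graph",
    "sort_edges",
    "merge_criterion",
    "segment",
    "extract_roi",
    "flag_pectoral",
    "detect_mass",
]


class WeightMode(str, Enum):
    INTENSITY = "intensity"
    SPATIAL_LITERAL = "spatial_literal"


@dataclass(frozen=True)
class PixelGraph:
    """Edge list over row-major pixel vertices; i < j for every edge."""

    n_vertices: int
    edges_i: np.ndarray
    edges_j: np.ndarray
    weights: np.ndarray
    connectivity: int
    weight_mode: WeightMode
    shape: tuple[int, int]

    @property
    def n_edges(self) -> int:
        return int(self.edges_i.size)


class RegionForest:
    """Union-find partition of pixels with per-region merge statistics.

    Tracks for every region root: pixel count, internal measure ``Int``
    (largest accepted edge weight in the region's merge history) and the
    intensity sum / sum-of-squares needed for region means and variances.
    Union by size with path halving.
    """

    def __init__(self, intensities: np.ndarray):
        n = intensities.size
        self.parent = np.arange(n, dtype=np.int64)
        self.size = np.ones(n, dtype=np.int64)
        self.internal = np.zeros(n, dtype=float)
        self.i_sum = intensities.astype(float).copy()
        self.i_sq = (intensities.astype(float) ** 2).copy()

    def find(self, x: int) -> int:
        parent = self.parent
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return int(x)

    def union(self, ra: int, rb: int, w: float) -> int:
        """Merge the two roots; new Int = max(Int_a, Int_b, w). Returns new root."""
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]
        self.internal[ra] = max(self.internal[ra], self.internal[rb], w)
        self.i_sum[ra] += self.i_sum[rb]
        self.i_sq[ra] += self.i_sq[rb]
        return ra

    def n_regions(self) -> int:
        return int(np.sum(self.parent == np.arange(self.parent.size)))


@dataclass(frozen=True)
class SegmentationResult:
    """Label image plus region table, ROI mask and pectoral flag.

    Labels are contiguous 0-based ids, renumbered deterministically by each
    region's minimum (row-major) pixel index.
    """

    labels: np.ndarray
    region_sizes: np.ndarray
    region_means: np.ndarray
    region_bboxes: np.ndarray  # (n_regions, 4): min_row, min_col, max_row, max_col
    k_scale: float
    roi_mask: BinaryMask | None = None
    pectoral_label: int | None = None

    @property
    def n_regions(self) -> int:
        return int(self.region_sizes.size)


def edge_weight(
    vi: tuple[int, int],
    vj: tuple[int, int],
    img: GrayImage,
    mode: WeightMode | str = WeightMode.INTENSITY,
) -> float:
    """Dissimilarity weight of the edge between two neighboring pixels."""
    mode = WeightMode(mode)
    dr, dc = abs(vi[0] - vj[0]), abs(vi[1] - vj[1])
    if (dr, dc) == (0, 0) or dr > 1 or dc > 1:
        raise ValueError(f"{vi} and {vj} are not distinct neighbors")
    if mode is WeightMode.SPATIAL_LITERAL:
        return float(np.sqrt(dr * dr + dc * dc))
    return float(abs(int(img.pixels[vi]) - int(img.pixels[vj])))


def build_graph(
    img: GrayImage,
    connectivity: int = 8,
    mode: WeightMode | str = WeightMode.INTENSITY,
) -> PixelGraph:
    """Construct the pixel-adjacency graph with one edge per neighbor pair."""
    mode = WeightMode(mode)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    h, w = img.shape
    idx = np.arange(h * w, dtype=np.int64).reshape(h, w)
    px = img.pixels.astype(np.int64)

    segs_i: list[np.ndarray] = []
    segs_j: list[np.ndarray] = []
    segs_w: list[np.ndarray] = []

    def add(a_idx, b_idx, a_px, b_px, dist):
        i = a_idx.ravel()
        j = b_idx.ravel()
        if i.size == 0:
            return
        if mode is WeightMode.SPATIAL_LITERAL:
            wt = np.full(i.size, dist, dtype=float)
        else:
            wt = np.abs(a_px.ravel() - b_px.ravel()).astype(float)
        # orient edges so i < j (true by construction: b is below/right of a)
        segs_i.append(i)
        segs_j.append(j)
        segs_w.append(wt)

    add(idx[:, :-1], idx[:, 1:], px[:, :-1], px[:, 1:], 1.0)          # horizontal
    add(idx[:-1, :], idx[1:, :], px[:-1, :], px[1:, :], 1.0)          # vertical
    if connectivity == 8:
        add(idx[:-1, :-1], idx[1:, 1:], px[:-1, :-1], px[1:, 1:], np.sqrt(2.0))  # diag ↘
        add(idx[:-1, 1:], idx[1:, :-1], px[:-1, 1:], px[1:, :-1], np.sqrt(2.0))  # diag ↙
    if segs_i:
        ei = np.concatenate(segs_i)
        ej = np.concatenate(segs_j)
        ew = np.concatenate(segs_w)
    else:
        ei = ej = np.empty(0, dtype=np.int64)
        ew = np.empty(0, dtype=float)
    return PixelGraph(h * w, ei, ej, ew, connectivity, mode, (h, w))


def sort_edges(g: PixelGraph) -> np.ndarray:
    """Indices that order edges by (weight, i, j) ascending — deterministic."""
    return np.lexsort((g.edges_j, g.edges_i, g.weights))


def merge_criterion(
    int_r1: float,
    size_r1: int,
    int_r2: float,
    size_r2: int,
    w_current: float,
    k_scale: float,
) -> bool:
    """IRM(R1,R2) <= DT(R1,R2) with IRM = w_current and
    DT = min(Int(R1) + k/|R1|, Int(R2) + k/|R2|)."""
    dt = min(int_r1 + k_scale / size_r1, int_r2 + k_scale / size_r2)
    return w_current <= dt


def default_min_size(n_pixels: int) -> int:
    """Speckle-suppression floor: max(16, 0.01% of the pixel count)."""
    return max(16, int(round(n_pixels * 1e-4)))


def segment(
    img: GrayImage,
    connectivity: int = 8,
    mode: WeightMode | str = WeightMode.INTENSITY,
    k_scale: float | None = None,
    min_size: int | None = None,
) -> SegmentationResult:
    """Segment an image by single-pass ascending-edge region merging.

    Parameters
    ----------
    img
        Input image (typically contrast-enhanced first).
    connectivity
        4 or 8 (default 8).
    mode
        Edge-weight mode; ``intensity`` (default) or ``spatial_literal``.
    k_scale
        Merge scale ``k``; if None it is set dynamically by Otsu's method on
        the edge-weight histogram.
    min_size
        Post-pass floor on region size; defaults to
        :func:`default_min_size`.  Pass 1 to disable the post-pass.
    """
    g = build_graph(img, connectivity, mode)
    h, w = img.shape
    n = h * w
    if min_size is None:
        min_size = default_min_size(n)
    if k_scale is None:
        if g.n_edges == 0:
            k_scale = 0.0
        else:
            k_scale = otsu_weight_scale(g.weights)

    forest = RegionForest(img.pixels.ravel())
    order = sort_edges(g)
    ei, ej, ew = g.edges_i, g.edges_j, g.weights
    find, union = forest.find, forest.union
    internal, size = forest.internal, forest.size

    for e in order:
        a, b = find(int(ei[e])), find(int(ej[e]))
        if a == b:
            continue
        wt = float(ew[e])
        if wt <= min(internal[a] + k_scale / size[a], internal[b] + k_scale / size[b]):
            union(a, b, wt)

    if min_size > 1:
        # each undersized region absorbs along its lowest-weight connecting edge
        for e in order:
            a, b = find(int(ei[e])), find(int(ej[e]))
            if a != b and (size[a] < min_size or size[b] < min_size):
                union(a, b, float(ew[e]))

    roots = np.array([find(i) for i in range(n)], dtype=np.int64)
    uniq, labels_flat = np.unique(roots, return_inverse=True)
    # np.unique sorts roots; root ids are not ordered by first pixel, so renumber
    first_pix = np.full(uniq.size, n, dtype=np.int64)
    np.minimum.at(first_pix, labels_flat, np.arange(n))
    rank = np.argsort(first_pix, kind="stable")
    remap = np.empty(uniq.size, dtype=np.int64)
    remap[rank] = np.arange(uniq.size)
    labels_flat = remap[labels_flat]
    labels = labels_flat.reshape(h, w)

    n_regions = uniq.size
    sizes = np.bincount(labels_flat, minlength=n_regions)
    sums = np.bincount(labels_flat, weights=img.pixels.ravel().astype(float), minlength=n_regions)
    means = sums / sizes
    rows = np.repeat(np.arange(h), w)
    cols = np.tile(np.arange(w), h)
    bboxes = np.zeros((n_regions, 4), dtype=np.int64)
    for k_axis, coord in ((0, rows), (1, cols)):
        mn = np.full(n_regions, n, dtype=np.int64)
        mx = np.full(n_regions, -1, dtype=np.int64)
        np.minimum.at(mn, labels_flat, coord)
        np.maximum.at(mx, labels_flat, coord)
        bboxes[:, k_axis] = mn
        bboxes[:, 2 + k_axis] = mx

    return SegmentationResult(
        labels=labels,
        region_sizes=sizes,
        region_means=means,
        region_bboxes=bboxes,
        k_scale=float(k_scale),
    )


def _border_labels(labels: np.ndarray) -> np.ndarray:
    return np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )


def flag_pectoral(
    seg: SegmentationResult, img: GrayImage, side: str = "auto"
) -> int | None:
    """Region containing the designated top corner, if brighter than average.

    ``side='auto'`` picks whichever top corner's region has the higher mean
    intensity.  Returns None when the corner region is not brighter than the
    global mean (no pectoral wedge visible).
    """
    h, w = img.shape
    global_mean = float(img.pixels.mean())
    corners = {"left": (0, 0), "right": (0, w - 1)}
    if side in corners:
        cands = [seg.labels[corners[side]]]
    elif side == "auto":
        cands = sorted(
            {int(seg.labels[c]) for c in corners.values()},
            key=lambda lab: -seg.region_means[lab],
        )[:1]
    else:
        raise ValueError("side must be 'left', 'right' or 'auto'")
    lab = int(cands[0])
    if seg.region_means[lab] > global_mean:
        return lab
    return None


def _candidate_regions(
    seg: SegmentationResult,
    img: GrayImage,
    min_area: int,
    max_area_frac: float,
) -> list[int]:
    """Interior regions of plausible area, brightest first.

    Excluded: regions touching the image border (breast silhouette,
    background and pectoral wedge all do), the flagged pectoral region, and
    regions 8-adjacent to it — bright slivers along the pectoral margin are
    the classic false positive in mass detection.
    """
    h, w = img.shape
    total = h * w
    excluded = set(_border_labels(seg.labels).tolist())
    if seg.pectoral_label is not None:
        pect = int(seg.pectoral_label)
        excluded.add(pect)
        grown = ndi.binary_dilation(seg.labels == pect, np.ones((3, 3), bool))
        excluded |= set(np.unique(seg.labels[grown]).tolist())
    cands = [
        lab
        for lab in range(seg.n_regions)
        if lab not in excluded and min_area <= seg.region_sizes[lab] <= max_area_frac * total
    ]
    cands.sort(key=lambda lab: (-seg.region_means[lab], lab))
    return cands


def _tissue_background_level(img: GrayImage, sm: np.ndarray) -> float | None:
    """Dominant tissue gray level: histogram mode above the image's Otsu split."""
    try:
        t = otsu_image_threshold(img)
    except DegenerateHistogramError:
        return None
    tissue = sm[img.pixels > t]
    if tissue.size == 0:
        return None
    vals = np.round(tissue).astype(np.int64)
    return float(np.bincount(vals - vals.min()).argmax() + vals.min())


def _halfmax_refine(
    img: GrayImage, sm: np.ndarray, bg: float, seed_mask: np.ndarray
) -> np.ndarray | None:
    """Delineate a mass around a seed region at half maximum over background.

    The seed region produced by ascending-edge merging is reliably centered
    on the mass but captures only its brightest cap (merging stalls on the
    smooth intensity slope).  The full extent is recovered by thresholding a
    smoothed neighborhood at background + (peak - background)/2 — the
    half-maximum convention for the support of a focal bright lesion — with
    the peak taken inside the seed.  Only the connected component containing
    the seed is kept, holes filled.

    Returns None when the seed cannot be a contained focal mass: no contrast
    over background, or the half-maximum component runs into the image or
    window border (a real mass's support fits well inside the window, which
    is padded to 3x the seed extent).
    """
    px = img.pixels
    h, w = px.shape
    rr, cc = np.nonzero(seed_mask)
    r0, r1, c0, c1 = rr.min(), rr.max(), cc.min(), cc.max()
    pad = 3 * max(r1 - r0 + 1, c1 - c0 + 1) + 8
    win_r = slice(max(0, r0 - pad), min(h, r1 + 1 + pad))
    win_c = slice(max(0, c0 - pad), min(w, c1 + 1 + pad))
    patch = sm[win_r, win_c]
    seed_patch = seed_mask[win_r, win_c]

    peak = float(patch[seed_patch].max())
    if peak <= bg:
        return None
    thresh = bg + 0.5 * (peak - bg)

    fg_labels, _ = ndi.label(patch >= thresh)
    seed_components = np.unique(fg_labels[seed_patch])
    seed_components = seed_components[seed_components > 0]
    if seed_components.size == 0:
        return None
    keep = ndi.binary_fill_holes(np.isin(fg_labels, seed_components))
    edge = (
        keep[0, :].any()
        or keep[-1, :].any()
        or keep[:, 0].any()
        or keep[:, -1].any()
    )
    if edge:
        return None
    out = np.zeros((h, w), dtype=bool)
    out[win_r, win_c] = keep
    return out


def extract_roi(
    seg: SegmentationResult,
    img: GrayImage,
    min_area: int = 12,
    max_area_frac: float = 0.25,
    refine: bool = True,
    smooth_sigma: float = 1.0,
    max_candidates: int = 10,
) -> BinaryMask:
    """Extract the suspected-mass ROI.

    Candidate seed regions are segmentation regions with
    ``min_area <= size <= max_area_frac * total`` pixels that neither touch
    the image border nor belong to (or abut) the flagged pectoral region,
    ranked by mean intensity — masses are the brightest focal structures.
    With ``refine=True`` (default) each candidate in turn is expanded to its
    half-maximum support via :func:`_halfmax_refine`; the first candidate
    whose support is a contained focal blob wins.  Candidates whose support
    floods into the border (pectoral fragments, faint noise clumps) are
    rejected and the next-brightest is tried, up to ``max_candidates``.
    With ``refine=False`` the brightest candidate's raw region mask is
    returned.  When no candidate survives, an empty mask is returned with a
    warning.
    """
    h, w = img.shape
    cands = _candidate_regions(seg, img, min_area, max_area_frac)
    if not cands:
        warnings.warn("no ROI candidate region; returning empty mask")
        return BinaryMask(np.zeros((h, w), dtype=bool))
    if not refine:
        return BinaryMask(seg.labels == cands[0])

    sm = (
        ndi.gaussian_filter(img.pixels.astype(float), smooth_sigma)
        if smooth_sigma > 0
        else img.pixels.astype(float)
    )
    bg = _tissue_background_level(img, sm)
    if bg is not None:
        for lab in cands[:max_candidates]:
            refined = _halfmax_refine(img, sm, bg, seg.labels == lab)
            if refined is not None:
                return BinaryMask(refined)
    warnings.warn("no ROI candidate region; returning empty mask")
    return BinaryMask(np.zeros((h, w), dtype=bool))


def detect_mass(
    img: GrayImage,
    connectivity: int = 8,
    mode: WeightMode | str = WeightMode.INTENSITY,
    k_scale: float | None = None,
    min_size: int | None = None,
    smooth_sigma: float = 0.8,
    pectoral_side: str = "auto",
    refine: bool = True,
) -> SegmentationResult:
    """Full detection pipeline: smooth, segment, flag pectoral, extract ROI.

    Edge weights are computed on a Gaussian-smoothed copy of the image
    (``smooth_sigma``, in pixels; 0 disables) — minimum-edge region merging
    is fragile under pixel noise, and light pre-smoothing is the standard
    remedy.  Region statistics, pectoral flagging and ROI refinement all use
    the original intensities.  Returns the segmentation with
    ``pectoral_label`` and ``roi_mask`` populated.
    """
    if smooth_sigma > 0:
        sm = np.round(ndi.gaussian_filter(img.pixels.astype(float), smooth_sigma))
        work = GrayImage(
            np.clip(sm, 0, img.max_level).astype(np.int64),
            max_level=img.max_level,
            source=img.source,
        )
    else:
        work = img
    seg = segment(work, connectivity=connectivity, mode=mode, k_scale=k_scale, min_size=min_size)
    # region means for seeding/flagging must reflect the original intensities
    n_regions = seg.n_regions
    flat = seg.labels.ravel()
    sums = np.bincount(flat, weights=img.pixels.ravel().astype(float), minlength=n_regions)
    seg = replace(seg, region_means=sums / seg.region_sizes)
    pect = flag_pectoral(seg, img, side=pectoral_side)
    seg = replace(seg, pectoral_label=pect)
    roi = extract_roi(seg, img, refine=refine)
    return replace(seg, roi_mask=roi)
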