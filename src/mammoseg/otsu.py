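"""Otsu's between-class-variance threshold.

Used in two roles: as a standalone image thresholder and — histogrammed over
the segmentation graph's edge weights — as the source of the dynamic merge
scale ``k_scale`` for region merging.  The threshold ``t`` maximizes

    sigma_b^2(t) = w0(t) * w1(t) * (mu0(t) - mu1(t))^2

over splits {level <= t} / {level > t} with both classes non-empty; ties are
broken at the smallest maximizing ``t`` so results are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fuzzy_enhancement import DegenerateHistogramError
from .image_io import GrayImage

__all__ = [
    "Histogram",
    "histogram_of",
    "otsu_threshold",
    "otsu_image_threshold",
    "otsu_weight_scale",
    "between_class_variance",
]


@dataclass(frozen=True)
class Histogram:
    """Counts indexed by gray level 0..max_level."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 1 or c.size < 1:
            raise ValueError("counts must be a 1-D vector")
        if (c < 0).any() or c.sum() == 0:
            raise ValueError("counts must be non-negative with positive total")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def histogram_of(img: GrayImage) -> Histogram:
    """Gray-level histogram of an image over 0..max_level."""
    return Histogram(np.bincount(img.pixels.ravel(), minlength=img.max_level + 1))


def between_class_variance(h: Histogram) -> np.ndarray:
    """sigma_b^2 for every candidate threshold t = 0..L-1 (NaN where a class is empty)."""
    c = h.counts.astype(float)
    total = c.sum()
    p = c / total
    omega0 = np.cumsum(p)
    omega1 = 1.0 - omega0
    levels = np.arange(c.size, dtype=float)
    mu_cum = np.cumsum(p * levels)
    mu_total = mu_cum[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / omega0
        mu1 = (mu_total - mu_cum) / omega1
        sigma_b = omega0 * omega1 * (mu0 - mu1) ** 2
    sigma_b[(omega0 <= 0) | (omega1 <= 0)] = np.nan
    return sigma_b


def otsu_threshold(h: Histogram) -> int:
    """Smallest level t maximizing the between-class variance.

    Raises :class:`DegenerateHistogramError` if fewer than two levels carry
    mass (no valid split exists).
    """
    if np.count_nonzero(h.counts) < 2:
        raise DegenerateHistogramError("histogram has a single occupied level")
    sigma_b = between_class_variance(h)
    best = np.nanmax(sigma_b)
    return int(np.flatnonzero(sigma_b == best)[0])


def otsu_image_threshold(img: GrayImage) -> int:
    """Otsu threshold of an image's gray-level histogram."""
    return otsu_threshold(histogram_of(img))


def otsu_weight_scale(weights: np.ndarray, bins: int = 256) -> float:
    """Dynamic merge scale from the edge-weight distribution.

    The weights are histogrammed into ``bins`` equal-width bins over
    [min, max] and Otsu's threshold is taken on that histogram; the returned
    scale is the center of the threshold bin.  Degenerate input (all weights
    equal) returns that weight with a warning.
    """
    w = np.asarray(weights, dtype=float).ravel()
    if w.size == 0:
        raise ValueError("no edge weights")
    lo, hi = float(w.min()), float(w.max())
    if lo == hi:
        warnings.warn("all edge weights equal; merge scale degenerates to that weight")
        return lo
    counts, edges = np.histogram(w, bins=bins, range=(lo, hi))
    t = otsu_threshold(Histogram(counts))
    return float((edges[t] + edges[t + 1]) / 2.0)
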