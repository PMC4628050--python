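"""Fuzzy histogram-based contrast enhancement.

The gray-level histogram is characterized by five parameters
(alpha, beta1, gamma, beta2, max) derived from the observed dynamic range:

    alpha = min,  gamma = max / 2,
    beta1 = (alpha + gamma) / 2,  beta2 = (max + gamma) / 2.

Fuzzification maps each intensity ``u`` to a membership value ``P`` through
a piecewise quadratic (S-type intensification) transform that is 0 at the
range endpoints and 1 at ``gamma``; intensities near ``gamma`` are pushed
up, intensities below ``beta1`` or above ``beta2`` are pushed down.
Defuzzification maps the membership plane back onto the original dynamic
range with the affine rule ``g' = round(alpha + P * (max - alpha))``.

Two fuzzification variants are provided.  In ``corrected`` mode (default)
the upper branch is ``P = 2*((u - max)/(max - gamma))**2``, which makes the
transform continuous on [alpha, max] with P(alpha) = P(max) = 0 and
P(gamma) = 1.  ``literal`` mode keeps the upper branch as
``P = 2*((u - gamma)/(max - gamma))**2`` — which reaches 2 at ``u = max``
and is therefore clamped to [0, 1] — for fidelity to the published rule set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .image_io import GrayImage

__all__ = [
    "FuzzyMode",
    "FuzzyParams",
    "FuzzyPlane",
    "DegenerateHistogramError",
    "compute_params",
    "fuzzify",
    "fuzzify_image",
    "defuzzify",
    "enhance",
]


class FuzzyMode(str, Enum):
    CORRECTED = "corrected"
    LITERAL = "literal"


class DegenerateHistogramError(ValueError):
    """Raised when an image has a single gray level (no dynamic range)."""


@dataclass(frozen=True)
class FuzzyParams:
    """The five histogram parameters, kept as exact reals (no rounding)."""

    alpha: float
    beta1: float
    gamma: float
    beta2: float
    max: float


@dataclass(frozen=True)
class FuzzyPlane:
    """Image-shaped grid of membership values P."""

    values: np.ndarray
    mode: FuzzyMode = FuzzyMode.CORRECTED


def compute_params(img: GrayImage) -> FuzzyParams:
    """Derive (alpha, beta1, gamma, beta2, max) from the image's gray range."""
    lo = float(img.pixels.min())
    hi = float(img.pixels.max())
    if lo == hi:
        raise DegenerateHistogramError(
            "constant image: histogram has a single level, enhancement is undefined"
        )
    gamma = hi / 2.0
    return FuzzyParams(
        alpha=lo,
        beta1=(lo + gamma) / 2.0,
        gamma=gamma,
        beta2=(hi + gamma) / 2.0,
        max=hi,
    )


def _fuzzify_array(
    u: np.ndarray, p: FuzzyParams, mode: FuzzyMode
) -> np.ndarray:
    """Vectorized piecewise transform; rule domains evaluated as stated.

    When min > max/2 the ordering degenerates (gamma <= alpha) and the lower
    rule domains are empty; the first matching branch in rule order wins, and
    coverage of [alpha, max] is guaranteed by the half-open domain chain.
    """
    a, b1, g, b2, mx = p.alpha, p.beta1, p.gamma, p.beta2, p.max
    # guarded denominators: empty domains never evaluate, but numpy computes all branches
    d_low = g - a if g != a else 1.0
    d_high = mx - g if mx != g else 1.0

    r1 = 2.0 * ((u - a) / d_low) ** 2
    r2 = 1.0 - 2.0 * ((u - g) / d_low) ** 2
    r3 = 1.0 - 2.0 * ((u - g) / d_high) ** 2
    if mode is FuzzyMode.CORRECTED:
        r4 = 2.0 * ((u - mx) / d_high) ** 2
    else:
        r4 = 2.0 * ((u - g) / d_high) ** 2
    out = np.select(
        [
            (a <= u) & (u < b1),
            (b1 <= u) & (u < g),
            (g <= u) & (u < b2),
            (b2 <= u) & (u <= mx),  # closed at max so the range is covered
        ],
        [r1, r2, r3, r4],
        default=np.nan,
    )
    return np.clip(out, 0.0, 1.0)


def fuzzify(
    u: float, p: FuzzyParams, mode: FuzzyMode | str = FuzzyMode.CORRECTED
) -> float:
    """Membership value P for a single intensity ``u`` in [alpha, max]."""
    if not (p.alpha <= u <= p.max):
        raise ValueError(f"intensity {u} outside fuzzification domain [{p.alpha}, {p.max}]")
    return float(_fuzzify_array(np.asarray(float(u)), p, FuzzyMode(mode)))


def fuzzify_image(
    img: GrayImage, p: FuzzyParams, mode: FuzzyMode | str = FuzzyMode.CORRECTED
) -> FuzzyPlane:
    """Element-wise fuzzification of an image."""
    mode = FuzzyMode(mode)
    u = img.pixels.astype(float)
    if u.min() < p.alpha or u.max() > p.max:
        raise ValueError("image intensities outside fuzzification domain")
    return FuzzyPlane(_fuzzify_array(u, p, mode), mode=mode)


def defuzzify(plane: FuzzyPlane, p: FuzzyParams) -> GrayImage:
    """Map memberships back to gray levels: g' = round(alpha + P*(max - alpha)).

    Rounding is half-away-from-zero (all quantities are non-negative here).
    The output is monotone non-decreasing in P and spans [alpha, max].
    """
    vals = np.clip(plane.values, 0.0, 1.0)
    g = np.floor(p.alpha + vals * (p.max - p.alpha) + 0.5).astype(np.int64)
    max_level = int(max(255, np.ceil(p.max)))
    return GrayImage(g, max_level=max_level)


def enhance(
    img: GrayImage, mode: FuzzyMode | str = FuzzyMode.CORRECTED
) -> GrayImage:
    """Full enhancement: compute_params -> fuzzify -> defuzzify.

    Deterministic and pointwise: each output pixel depends only on its input
    value and the global histogram parameters.  A constant image is returned
    unchanged with a warning (the transform is undefined without dynamic
    range).
    """
    try:
        p = compute_params(img)
    except DegenerateHistogramError:
        warnings.warn("constant image: enhancement skipped")
        return img
    plane = fuzzify_image(img, p, mode)
    out = defuzzify(plane, p)
    return GrayImage(out.pixels, max_level=img.max_level, source=img.source)
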