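"""Seeded mammogram-like phantoms with exact analytic ground truth.

A phantom emulates the salient structure of a digitized mediolateral-oblique
mammogram: a dark background, a bright half-elliptical breast silhouette
anchored to the chest-wall side of the frame, a brighter pectoral-muscle
wedge in one top corner, zero or more Gaussian-profile masses inside the
breast, and additive Gaussian noise.  Geometry is analytic, so every mask
(breast, pectoral, mass) is exact rather than estimated: the mass ground
truth is the union of half-amplitude (FWHM) discs, radius sigma*sqrt(2*ln 2)
around each mass center.

Identical spec + seed always produces a bit-identical phantom.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .image_io import BinaryMask, GrayImage

__all__ = ["MassSpec", "PhantomSpec", "Phantom", "generate", "suite"]

HALF_MAX_FACTOR = float(np.sqrt(2.0 * np.log(2.0)))  # FWHM radius in units of sigma


@dataclass(frozen=True)
class MassSpec:
    """One Gaussian-profile mass: center (row, col), spread and peak height."""

    row: float
    col: float
    sigma: float
    amplitude: float


@dataclass(frozen=True)
class PhantomSpec:
    height: int = 128
    width: int = 128
    max_level: int = 255
    background_level: int = 20
    breast_level: int = 100
    pectoral_level: int = 180
    pectoral_side: str = "left"  # 'left' or 'right'
    pectoral_frac: float = 0.35  # fraction of width covered by the wedge at the top row
    masses: tuple[MassSpec, ...] = ()
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.background_level < self.breast_level < self.pectoral_level <= self.max_level):
            raise ValueError("levels must satisfy 0 <= background < breast < pectoral <= max_level")
        if self.pectoral_side not in ("left", "right"):
            raise ValueError("pectoral_side must be 'left' or 'right'")
        if any(m.amplitude <= 0 or m.sigma <= 0 for m in self.masses):
            raise ValueError("mass amplitude and sigma must be positive")


@dataclass(frozen=True)
class Phantom:
    image: GrayImage
    mass_mask: BinaryMask
    pectoral_mask: BinaryMask
    breast_mask: BinaryMask
    spec: PhantomSpec = field(compare=False)


def _geometry(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Breast and pectoral masks from the analytic geometry."""
    h, w = spec.height, spec.width
    r = np.arange(h)[:, None]
    c = np.arange(w)[None, :]
    # half-ellipse anchored to the chest-wall side (same side as the pectoral
    # wedge); the vertical semi-axis exceeds h/2 so the silhouette spans the
    # whole chest-wall edge and the wedge owns the top corner pixel, as in a
    # mediolateral-oblique view
    a = 0.65 * h  # vertical semi-axis
    b = 0.85 * w  # horizontal semi-axis
    if spec.pectoral_side == "left":
        x = c.astype(float)
    else:
        x = (w - 1 - c).astype(float)
    breast = (((r - (h - 1) / 2.0) / a) ** 2 + (x / b) ** 2) <= 1.0
    # right-triangle wedge at the top corner of the chest-wall side
    wedge_cols = spec.pectoral_frac * w
    wedge_rows = 0.45 * h
    pect = (x / wedge_cols + r / wedge_rows) < 1.0
    pect &= breast
    return breast, pect


def mass_ground_truth(spec: PhantomSpec) -> np.ndarray:
    """Union of FWHM discs: pixels where each Gaussian is >= half amplitude."""
    h, w = spec.height, spec.width
    rr = np.arange(h)[:, None]
    cc = np.arange(w)[None, :]
    mask = np.zeros((h, w), dtype=bool)
    for m in spec.masses:
        d2 = (rr - m.row) ** 2 + (cc - m.col) ** 2
        mask |= d2 <= 2.0 * m.sigma**2 * np.log(2.0)
    return mask


def generate(spec: PhantomSpec) -> Phantom:
    """Render a phantom and its exact ground-truth masks."""
    breast, pect = _geometry(spec)
    mass_mask = mass_ground_truth(spec)
    if not (mass_mask <= breast).all():
        raise ValueError("every mass must lie inside the breast silhouette")
    if (mass_mask & pect).any():
        raise ValueError("masses must not overlap the pectoral wedge")

    img = np.full((spec.height, spec.width), float(spec.background_level))
    img[breast] = spec.breast_level
    img[pect] = spec.pectoral_level

    rr = np.arange(spec.height)[:, None]
    cc = np.arange(spec.width)[None, :]
    for m in spec.masses:
        d2 = (rr - m.row) ** 2 + (cc - m.col) ** 2
        img += m.amplitude * np.exp(-d2 / (2.0 * m.sigma**2))

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img += rng.normal(0.0, spec.noise_sigma, img.shape)

    img = np.clip(np.floor(img + 0.5), 0, spec.max_level).astype(np.int64)
    return Phantom(
        image=GrayImage(img, max_level=spec.max_level, source=f"phantom(seed={spec.seed})"),
        mass_mask=BinaryMask(mass_mask),
        pectoral_mask=BinaryMask(pect),
        breast_mask=BinaryMask(breast),
        spec=spec,
    )


def random_single_mass_spec(
    rng: np.random.Generator,
    noise_sigma: float = 0.0,
    seed: int = 0,
    size: int = 128,
) -> PhantomSpec:
    """A single-mass phantom with randomized mass placement and strength.

    The mass is kept inside the breast, clear of the pectoral wedge and the
    border; amplitude and spread span the range of conspicuous masses.
    """
    sigma = float(rng.uniform(5.0, 9.0))
    amplitude = float(rng.uniform(70.0, 110.0))
    side = "left" if rng.integers(2) == 0 else "right"
    row = float(rng.uniform(0.55 * size, 0.8 * size))
    col_frac = float(rng.uniform(0.25, 0.55))
    col = col_frac * size if side == "left" else (1 - col_frac) * size
    return PhantomSpec(
        height=size,
        width=size,
        pectoral_side=side,
        masses=(MassSpec(row, col, sigma, amplitude),),
        noise_sigma=noise_sigma,
        seed=seed,
    )


def suite(n: int, master_seed: int, noise_sigma: float | None = None) -> list[Phantom]:
    """Deterministic suite of ``n`` varied phantoms.

    Sizes, mass counts (0-3), mass geometry and noise levels vary with the
    sub-seed ``master_seed + index``; at least one phantom is mass-free so
    negative cases are always represented.  Same master seed, same suite.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    phantoms = []
    for i in range(n):
        sub_seed = master_seed + i
        rng = np.random.default_rng(sub_seed)
        size = int(rng.choice([96, 128, 160]))
        n_masses = 0 if i == 0 else int(rng.integers(0, 4))
        noise = float(rng.uniform(0.0, 6.0)) if noise_sigma is None else noise_sigma
        spec = random_single_mass_spec(rng, noise_sigma=noise, seed=sub_seed, size=size)
        masses: list[MassSpec] = list(spec.masses[:1]) if n_masses >= 1 else []
        # extra masses, spread vertically so discs stay disjoint and in-breast
        for k in range(1, n_masses):
            sigma = float(rng.uniform(4.0, 7.0))
            amplitude = float(rng.uniform(60.0, 100.0))
            row = float(rng.uniform(0.5 * size, 0.85 * size))
            col_frac = float(rng.uniform(0.25, 0.5))
            col = col_frac * size if spec.pectoral_side == "left" else (1 - col_frac) * size
            cand = MassSpec(row, col, sigma, amplitude)
            # FWHM discs (radius ~1.18 sigma) stay disjoint with margin
            if all(
                (cand.row - m.row) ** 2 + (cand.col - m.col) ** 2
                > (1.5 * (cand.sigma + m.sigma) + 4.0) ** 2
                for m in masses
            ):
                masses.append(cand)
        spec = replace(spec, masses=tuple(masses), noise_sigma=noise)
        phantoms.append(generate(spec))
    return phantoms
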