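"""Deterministic generator of blood-smear-like test images.

Thresholding methods only ever see the per-channel histogram, so the
generator targets *histogram* realism rather than cell morphology: a
bright background, dark round cells (cytoplasm) with darker stained
nuclei, and Gaussian pixel noise produce a genuinely multimodal
histogram with unequal mode masses — the regime the segmentation
pipeline is designed for.  Alongside the image the generator returns
the ground truth a test can score against: the three per-channel mode
means and the exhaustive-search Otsu-optimal threshold pair of the
realized histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .objectives import exhaustive_otsu, normalized_histogram

__all__ = ["CellImageSpec", "CellImageTruth", "generate_cell_image"]


def _as_rgb(level) -> np.ndarray:
    arr = np.asarray(level, dtype=float).reshape(-1)
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.size != 3:
        raise ValueError("levels must be scalars or length-3 RGB triples")
    if np.any(arr < 0) or np.any(arr > 255):
        raise ValueError("levels must lie in [0, 255]")
    return arr


@dataclass(frozen=True)
class CellImageSpec:
    """Scene description.  Mode levels may be scalars (equal across RGB
    channels) or per-channel triples; they must be separated by at least
    3 * noise_sigma so the histogram stays multimodal."""

    width: int = 256
    height: int = 256
    n_cells: int = 12
    radius_range: tuple[int, int] = (12, 20)
    background_level: float | Sequence[float] = 220.0
    cytoplasm_level: float | Sequence[float] = 130.0
    nucleus_level: float | Sequence[float] = 40.0
    noise_sigma: float = 8.0
    nucleus_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ValueError("image dimensions must be at least 64 pixels")
        if self.n_cells < 0:
            raise ValueError("n_cells must be nonnegative")
        if not 0 < self.radius_range[0] <= self.radius_range[1]:
            raise ValueError("invalid radius range")
        if not 0.0 <= self.nucleus_fraction <= 1.0:
            raise ValueError("nucleus_fraction must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        levels = np.stack(
            [_as_rgb(self.nucleus_level), _as_rgb(self.cytoplasm_level),
             _as_rgb(self.background_level)]
        )
        gaps = np.diff(np.sort(levels, axis=0), axis=0)
        if np.any(gaps < 3.0 * self.noise_sigma):
            raise ValueError(
                "mode levels must be separated by at least 3 * noise_sigma"
            )

    @property
    def levels_rgb(self) -> np.ndarray:
        """(3 modes, 3 channels): nucleus, cytoplasm, background rows."""
        return np.stack(
            [_as_rgb(self.nucleus_level), _as_rgb(self.cytoplasm_level),
             _as_rgb(self.background_level)]
        )


@dataclass(frozen=True)
class CellImageTruth:
    """Per-channel mode means and the histogram's exhaustive-Otsu optimum.

    Because the modes are well separated, the histogram has empty
    stretches and the Otsu optimum is a plateau of exactly tied
    threshold pairs; ``otsu_plateaus`` carries the full argmax set per
    channel (``otsu_thresholds`` is its first member)."""

    mode_levels: np.ndarray          # (3 modes, 3 channels)
    otsu_thresholds: list[np.ndarray]  # per channel, 2 thresholds each
    otsu_values: list[float]
    otsu_plateaus: list[np.ndarray]  # per channel, (n_ties, 2)
    cell_centers: np.ndarray
    cell_radii: np.ndarray


def _place_cells(
    spec: CellImageSpec, rng: np.random.Generator, max_tries: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    for _ in range(spec.n_cells):
        placed = False
        for _try in range(max_tries):
            r = float(rng.uniform(*spec.radius_range))
            cx = float(rng.uniform(r, spec.width - r))
            cy = float(rng.uniform(r, spec.height - r))
            if all(
                (cx - x) ** 2 + (cy - y) ** 2 > (r + rr + 2.0) ** 2
                for (x, y), rr in zip(centers, radii)
            ):
                centers.append((cx, cy))
                radii.append(r)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place {spec.n_cells} non-overlapping cells "
                f"in {spec.width}x{spec.height} after {max_tries} tries each"
            )
    return np.asarray(centers, dtype=float).reshape(-1, 2), np.asarray(radii)


def generate_cell_image(spec: CellImageSpec) -> tuple[np.ndarray, CellImageTruth]:
    """Render the scene and derive its ground truth.

    Returns an (H, W, 3) uint8 image and a :class:`CellImageTruth` whose
    thresholds are the brute-force Otsu optima (2 thresholds) of each
    realized channel histogram.  Deterministic for equal spec (the seed
    is part of the spec).
    """
    rng = np.random.default_rng(spec.seed)
    centers, radii = _place_cells(spec, rng)

    yy, xx = np.mgrid[0:spec.height, 0:spec.width].astype(float)
    mode_index = np.full((spec.height, spec.width), 2, dtype=int)  # background
    for (cx, cy), r in zip(centers, radii):
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        mode_index[d2 <= r**2] = 1                                   # cytoplasm
        nr = r * np.sqrt(spec.nucleus_fraction)
        mode_index[d2 <= nr**2] = 0                                  # nucleus

    levels = spec.levels_rgb  # (3 modes, 3 channels)
    clean = levels[mode_index]  # (H, W, 3)
    noisy = clean + rng.normal(0.0, spec.noise_sigma, size=clean.shape)
    image = np.clip(np.round(noisy), 0, 255).astype(np.uint8)

    otsu_ths, otsu_vals, otsu_plateaus = [], [], []
    for c in range(3):
        th, val, ties = exhaustive_otsu(
            normalized_histogram(image[..., c]), 2, return_ties=True
        )
        otsu_ths.append(th.values.copy())
        otsu_vals.append(val)
        otsu_plateaus.append(ties)

    truth = CellImageTruth(
        mode_levels=levels,
        otsu_thresholds=otsu_ths,
        otsu_values=otsu_vals,
        otsu_plateaus=otsu_plateaus,
        cell_centers=centers,
        cell_radii=radii,
    )
    return image, truth
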