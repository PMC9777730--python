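"""Conventional circular-ROI stiffness comparators (SWEavg, SWEmax, Q-box).

Each valid pixel inside the ROI is decoded to kPa individually and the
statistics are taken over the decoded values; void pixels are excluded.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colormap import StiffnessColormap, decode_pixels
from .histograms import Elastogram


class EmptyRoiError(ValueError):
    """ROI contains no valid (chromatic) pixel — it lies entirely in void."""


@dataclass(frozen=True)
class CircularROI:
    center: tuple[float, float]  # (row, col), 0-based
    radius: float  # pixels
    kind: str = "target"  # target | reference

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.kind not in ("target", "reference"):
            raise ValueError("kind must be 'target' or 'reference'")


@dataclass(frozen=True)
class SweRoiStats:
    mean_kpa: float
    min_kpa: float
    max_kpa: float
    sd_kpa: float
    n_pixels: int


def circular_mask(roi: CircularROI, shape: tuple[int, int]) -> np.ndarray:
    """Center-of-pixel circle membership, clipped to the image bounds."""
    h, w = int(shape[0]), int(shape[1])
    if h < 1 or w < 1:
        raise ValueError("shape must be positive")
    rr, cc = np.ogrid[:h, :w]
    cr, cl = roi.center
    mask = (rr - cr) ** 2 + (cc - cl) ** 2 <= roi.radius**2
    if not mask.any():
        raise ValueError("ROI does not intersect the image")
    return mask


def roi_stats(
    img: Elastogram, roi: CircularROI, cmap: StiffnessColormap
) -> SweRoiStats:
    """Decode every valid ROI pixel to kPa and aggregate.

    SD is the sample (n-1) standard deviation; 0 for a single pixel.
    """
    mask = circular_mask(roi, img.pixels.shape[:2]) & img.valid_mask
    n = int(mask.sum())
    if n == 0:
        raise EmptyRoiError("ROI lies entirely in signal void / achromatic area")
    kpa = decode_pixels(img.pixels[mask], cmap)
    sd = float(np.std(kpa, ddof=1)) if n > 1 else 0.0
    return SweRoiStats(
        mean_kpa=float(np.mean(kpa)),
        min_kpa=float(np.min(kpa)),
        max_kpa=float(np.max(kpa)),
        sd_kpa=sd,
        n_pixels=n,
    )


def qbox_ratio(target: SweRoiStats, reference: SweRoiStats) -> float:
    """Target mean stiffness over reference (fat-pad) mean stiffness.

    NaN when the reference mean is zero (undefined-value signal).
    """
    if reference.mean_kpa == 0:
        return float("nan")
    return target.mean_kpa / reference.mean_kpa
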