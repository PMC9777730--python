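"""Stiffness <-> pseudocolor lookup for shear-wave elastography heatmaps.

The vendor renders per-pixel tissue stiffness on a fixed 0-180 kPa scale,
mapping soft tissue to cool colors and stiff tissue to warm colors.  This
module models that rendering as an invertible lookup table (LUT) and
classifies pixels as chromatic (valid stiffness signal) or achromatic
(grayscale overlays and black signal voids, which carry no stiffness
information and are excluded from every downstream statistic).
"""
from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

DEFAULT_KPA_RANGE = (0.0, 180.0)
DEFAULT_N_LEVELS = 256
DEFAULT_ACHROMATIC_THRESHOLD = 20

# Waypoints are traversed left (coolest) to right (warmest) with equal
# spacing in stiffness.  Every variant must keep red non-decreasing and
# blue non-increasing so that inversion is well-posed.
_RAMP_WAYPOINTS: dict[str, list[tuple[int, int, int]]] = {
    "linear-bgr": [(0, 0, 255), (0, 255, 0), (255, 0, 0)],
    "jet-like": [
        (0, 0, 255),
        (0, 255, 255),
        (0, 255, 0),
        (255, 255, 0),
        (255, 0, 0),
    ],
}


class PixelClass(enum.Enum):
    """Validity class of a rendered pixel."""

    CHROMATIC = "chromatic"
    ACHROMATIC = "achromatic"


class AchromaticPixelError(ValueError):
    """Raised when a grayscale/void pixel is passed to the color decoder."""


@dataclass(frozen=True)
class StiffnessColormap:
    """Ordered color ramp over a stiffness interval.

    Level ``i`` encodes stiffness ``kpa_min + i * step`` where
    ``step = (kpa_max - kpa_min) / (L - 1)``.
    """

    levels: np.ndarray
    kpa_min: float = DEFAULT_KPA_RANGE[0]
    kpa_max: float = DEFAULT_KPA_RANGE[1]
    name: str = "linear-bgr"

    def __post_init__(self) -> None:
        lev = np.asarray(self.levels, dtype=np.int64)
        if lev.ndim != 2 or lev.shape[1] != 3 or lev.shape[0] < 2:
            raise ValueError("levels must be an (L, 3) array with L >= 2")
        if lev.min() < 0 or lev.max() > 255:
            raise ValueError("color components must be in 0..255")
        if not np.isfinite(self.kpa_min) or not np.isfinite(self.kpa_max):
            raise ValueError("stiffness range must be finite")
        if not self.kpa_min < self.kpa_max:
            raise ValueError("kpa_min must be < kpa_max")
        if np.any(np.diff(lev[:, 0]) < 0):
            raise ValueError("red component must be non-decreasing (warm ordering)")
        if np.any(np.diff(lev[:, 2]) > 0):
            raise ValueError("blue component must be non-increasing (cool ordering)")
        object.__setattr__(self, "levels", lev)

    @property
    def n_levels(self) -> int:
        return int(self.levels.shape[0])

    @property
    def step_kpa(self) -> float:
        """Stiffness quantization step between adjacent levels."""
        return (self.kpa_max - self.kpa_min) / (self.n_levels - 1)

    @property
    def stiffness_values(self) -> np.ndarray:
        return self.kpa_min + np.arange(self.n_levels) * self.step_kpa

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kpa_min": self.kpa_min,
            "kpa_max": self.kpa_max,
            "levels": self.levels.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StiffnessColormap":
        return cls(
            levels=np.asarray(d["levels"], dtype=np.int64),
            kpa_min=float(d["kpa_min"]),
            kpa_max=float(d["kpa_max"]),
            name=str(d.get("name", "custom")),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "StiffnessColormap":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_colormap(
    n_levels: int = DEFAULT_N_LEVELS,
    kpa_range: tuple[float, float] = DEFAULT_KPA_RANGE,
    variant: str = "linear-bgr",
) -> StiffnessColormap:
    """Build a cool-to-warm stiffness colormap.

    The default ``linear-bgr`` variant traverses blue -> green -> red
    linearly, the stated working assumption for the vendor scale.  A
    ``jet-like`` variant with cyan/yellow waypoints is available to probe
    sensitivity to the (unpublished) vendor LUT.
    """
    if int(n_levels) != n_levels or n_levels < 2:
        raise ValueError("n_levels must be an integer >= 2")
    kpa_min, kpa_max = float(kpa_range[0]), float(kpa_range[1])
    if not kpa_min < kpa_max:
        raise ValueError("kpa_range must be ordered (min, max)")
    try:
        waypoints = np.asarray(_RAMP_WAYPOINTS[variant], dtype=float)
    except KeyError:
        raise ValueError(
            f"unknown variant {variant!r}; choose from {sorted(_RAMP_WAYPOINTS)}"
        ) from None
    t = np.linspace(0.0, 1.0, int(n_levels))
    tw = np.linspace(0.0, 1.0, len(waypoints))
    levels = np.column_stack(
        [np.rint(np.interp(t, tw, waypoints[:, c])) for c in range(3)]
    ).astype(np.int64)
    return StiffnessColormap(levels=levels, kpa_min=kpa_min, kpa_max=kpa_max, name=variant)


def _level_index(kpa: np.ndarray | float, cmap: StiffnessColormap) -> np.ndarray:
    frac = (np.asarray(kpa, dtype=float) - cmap.kpa_min) / (cmap.kpa_max - cmap.kpa_min)
    frac = np.clip(frac, 0.0, 1.0)
    return np.rint(frac * (cmap.n_levels - 1)).astype(np.intp)


def stiffness_to_color(kpa: float, cmap: StiffnessColormap) -> tuple[int, int, int]:
    """Map a stiffness value to the nearest LUT color (out-of-range clamps)."""
    if not np.isfinite(kpa):
        raise ValueError("stiffness must be finite")
    r, g, b = cmap.levels[int(_level_index(kpa, cmap))]
    return int(r), int(g), int(b)


def encode_field(field: np.ndarray, cmap: StiffnessColormap) -> np.ndarray:
    """Vectorized ``stiffness_to_color`` over an H x W stiffness array."""
    field = np.asarray(field, dtype=float)
    if not np.all(np.isfinite(field)):
        raise ValueError("stiffness field must be finite")
    idx = _level_index(field, cmap)
    return cmap.levels[idx].astype(np.uint8)


def classify_pixel(
    rgb: Sequence[int], saturation_threshold: int = DEFAULT_ACHROMATIC_THRESHOLD
) -> PixelClass:
    """Achromatic iff max(R,G,B) - min(R,G,B) <= threshold."""
    r, g, b = (int(v) for v in rgb)
    for v in (r, g, b):
        if not 0 <= v <= 255:
            raise ValueError("color components must be in 0..255")
    spread = max(r, g, b) - min(r, g, b)
    return PixelClass.ACHROMATIC if spread <= saturation_threshold else PixelClass.CHROMATIC


def chromatic_mask(
    pixels: np.ndarray, saturation_threshold: int = DEFAULT_ACHROMATIC_THRESHOLD
) -> np.ndarray:
    """Boolean mask of chromatic pixels for an H x W x 3 array."""
    px = np.asarray(pixels, dtype=np.int64)
    spread = px.max(axis=-1) - px.min(axis=-1)
    return spread > saturation_threshold


def color_to_stiffness(
    rgb: Sequence[int],
    cmap: StiffnessColormap,
    saturation_threshold: int = DEFAULT_ACHROMATIC_THRESHOLD,
) -> float:
    """Invert the LUT by nearest-neighbor search in RGB space.

    Ties are broken toward the lower stiffness level.  Achromatic input is
    a caller error: void pixels must be masked out before decoding.
    """
    if classify_pixel(rgb, saturation_threshold) is PixelClass.ACHROMATIC:
        raise AchromaticPixelError(f"pixel {tuple(rgb)} is achromatic; mask it out")
    p = np.asarray(rgb, dtype=np.int64)
    d2 = ((cmap.levels - p) ** 2).sum(axis=1)
    return float(cmap.stiffness_values[int(np.argmin(d2))])


def decode_pixels(pixels: np.ndarray, cmap: StiffnessColormap) -> np.ndarray:
    """Decode an (N, 3) array of chromatic pixels to stiffness values.

    Nearest neighbor in RGB Euclidean distance; ``argmin`` returns the first
    (= lowest stiffness) level on ties. Chunked to bound memory.
    """
    px = np.asarray(pixels, dtype=np.int64).reshape(-1, 3)
    out = np.empty(px.shape[0], dtype=float)
    sv = cmap.stiffness_values
    lev = cmap.levels
    chunk = 8192
    for start in range(0, px.shape[0], chunk):
        block = px[start : start + chunk]
        d2 = ((block[:, None, :] - lev[None, :, :]) ** 2).sum(axis=2)
        out[start : start + chunk] = sv[np.argmin(d2, axis=1)]
    return out
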