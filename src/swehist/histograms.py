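"""Per-channel 250-bin histograms and bin-range descriptors for elastograms.

Channels are reported in warm/intermediate/cool order (R, G, B), the
stiff-to-soft reading order of the vendor colormap. Histograms count
chromatic pixels only; achromatic pixels (voids, grayscale overlays) never
contribute.

Bin convention: 250 equal-width, half-open bins over [0, 256), reported
with 1-based indices. Bin k covers intensity [(k-1)*256/250, k*256/250).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .colormap import DEFAULT_ACHROMATIC_THRESHOLD, chromatic_mask

N_BINS = 250
BIN_WIDTH = 256.0 / N_BINS
CHANNELS = ("warm", "intermediate", "cool")  # R, G, B
LABELS = ("benign", "malignant", "unknown")


def channel_index(channel: str) -> int:
    try:
        return CHANNELS.index(channel)
    except ValueError:
        raise ValueError(f"channel must be one of {CHANNELS}, got {channel!r}") from None


@dataclass
class Elastogram:
    """RGB elastogram crop with its chromatic-pixel validity mask."""

    pixels: np.ndarray  # (H, W, 3) uint8
    valid_mask: np.ndarray  # (H, W) bool
    source_id: str = ""
    label: str = "unknown"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("pixels must be a nonempty (H, W, 3) array")
        mask = np.asarray(self.valid_mask, dtype=bool)
        if mask.shape != px.shape[:2]:
            raise ValueError("valid_mask shape must match pixels")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        self.pixels = px.astype(np.uint8)
        self.valid_mask = mask

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())


def load_elastogram(
    path: str | Path,
    threshold: int = DEFAULT_ACHROMATIC_THRESHOLD,
    crop: tuple[int, int, int, int] | None = None,
    source_id: str | None = None,
    label: str = "unknown",
) -> Elastogram:
    """Read a PNG/JPEG elastogram crop and compute its validity mask.

    ``crop`` is (x0, y0, x1, y1) in 0-based, half-open pixel coordinates
    (x = column, y = row).
    """
    try:
        arr = iio.imread(Path(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary by plugin
        raise IOError(f"cannot decode image {path}: {exc}") from exc
    if arr.ndim == 2:  # grayscale: promote so the classifier rejects it
        arr = np.stack([arr] * 3, axis=-1)
    arr = arr[:, :, :3]
    if crop is not None:
        x0, y0, x1, y1 = (int(v) for v in crop)
        h, w = arr.shape[:2]
        if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
            raise ValueError(f"crop {crop} outside image bounds {(w, h)}")
        arr = arr[y0:y1, x0:x1]
    return Elastogram(
        pixels=arr,
        valid_mask=chromatic_mask(arr, threshold),
        source_id=source_id if source_id is not None else Path(path).stem,
        label=label,
    )


@dataclass
class ChannelHistogramSet:
    """3 x 250 per-channel counts over valid pixels, plus normalized form."""

    counts: np.ndarray  # (3, 250) int64
    normalized: np.ndarray  # (3, 250) float
    n_valid_pixels: int

    def channel_counts(self, channel: str) -> np.ndarray:
        return self.counts[channel_index(channel)]

    def channel_normalized(self, channel: str) -> np.ndarray:
        return self.normalized[channel_index(channel)]


def intensity_bin(value: int | np.ndarray) -> np.ndarray:
    """1-based bin index of an 8-bit intensity: floor(v * 250 / 256) + 1."""
    v = np.asarray(value, dtype=np.int64)
    return (v * N_BINS) // 256 + 1


def extract_histograms(img: Elastogram) -> ChannelHistogramSet:
    """Count valid pixels of each channel into the 250-bin grid."""
    valid = img.pixels[img.valid_mask].astype(np.int64)  # (n, 3)
    n = valid.shape[0]
    counts = np.zeros((3, N_BINS), dtype=np.int64)
    if n:
        idx0 = (valid * N_BINS) // 256  # 0-based bin indices
        for c in range(3):
            counts[c] = np.bincount(idx0[:, c], minlength=N_BINS)
    normalized = counts / n if n else np.zeros((3, N_BINS), dtype=float)
    return ChannelHistogramSet(counts=counts, normalized=normalized.astype(float), n_valid_pixels=n)


@dataclass(frozen=True)
class BinRanges:
    """Inclusive 1-based bin index ranges partitioning 1..250.

    Bins in ``noise_low`` and ``noise_high`` are rejected as noise; the
    ``low`` and ``high`` ranges carry the intensity-band AUC descriptors.
    """

    noise_low: tuple[int, int] = (1, 14)
    low: tuple[int, int] = (15, 100)
    high: tuple[int, int] = (101, 200)
    noise_high: tuple[int, int] = (201, 250)

    def __post_init__(self) -> None:
        ranges = [self.noise_low, self.low, self.high, self.noise_high]
        covered: list[int] = []
        for lo, hi in ranges:
            if not (1 <= lo <= hi <= N_BINS):
                raise ValueError(f"range ({lo}, {hi}) outside 1..{N_BINS}")
            covered.extend(range(lo, hi + 1))
        if sorted(covered) != list(range(1, N_BINS + 1)):
            raise ValueError("bin ranges must be disjoint and cover 1..250")


DEFAULT_BIN_RANGES = BinRanges()


def bin_range_auc(
    hist: ChannelHistogramSet, channel: str, bin_range: tuple[int, int]
) -> float:
    """Normalized-histogram mass over an inclusive 1-based bin range."""
    lo, hi = int(bin_range[0]), int(bin_range[1])
    if not (1 <= lo <= hi <= N_BINS):
        raise ValueError(f"bin range ({lo}, {hi}) outside 1..{N_BINS}")
    return float(hist.normalized[channel_index(channel), lo - 1 : hi].sum())


def histogram_skewness(hist: ChannelHistogramSet, channel: str) -> float:
    """Fisher-Pearson skewness of bin-center intensities, count-weighted.

    Bias-uncorrected third standardized central moment. Returns NaN when
    the channel has zero variance or fewer than two valid pixels (the
    undefined-value signal; callers report it as missing, never as 0).
    """
    if hist.n_valid_pixels < 2:
        return float("nan")
    w = hist.normalized[channel_index(channel)]
    centers = (np.arange(N_BINS) + 0.5) * BIN_WIDTH
    mu = float(np.sum(w * centers))
    var = float(np.sum(w * (centers - mu) ** 2))
    if var <= 0.0:
        return float("nan")
    return float(np.sum(w * (centers - mu) ** 3) / var**1.5)


@dataclass
class FeatureVector:
    """Per-image descriptors: bin-range AUCs and skewness per channel."""

    source_id: str
    label: str
    n_valid_pixels: int
    auc_low: dict[str, float]
    auc_high: dict[str, float]
    skewness: dict[str, float]

    def to_row(self) -> dict:
        row: dict = {
            "source_id": self.source_id,
            "label": self.label,
            "n_valid_pixels": self.n_valid_pixels,
        }
        for ch in CHANNELS:
            row[f"auc_low_{ch}"] = self.auc_low[ch]
            row[f"auc_high_{ch}"] = self.auc_high[ch]
        for ch in CHANNELS:
            row[f"skew_{ch}"] = self.skewness[ch]
        return row


FEATURE_COLUMNS = (
    ["source_id", "label", "n_valid_pixels"]
    + [f"auc_{band}_{ch}" for ch in CHANNELS for band in ("low", "high")]
    + [f"skew_{ch}" for ch in CHANNELS]
)


def compute_features(
    img: Elastogram,
    ranges: BinRanges = DEFAULT_BIN_RANGES,
    renormalize_signal: bool = False,
) -> FeatureVector:
    """Assemble the per-image descriptor record.

    With ``renormalize_signal=True`` the noise bins are rejected before
    normalization, so AUCs are fractions of the signal-band mass instead
    of fractions of all valid pixels (default).
    """
    hist = extract_histograms(img)
    auc_low: dict[str, float] = {}
    auc_high: dict[str, float] = {}
    skew: dict[str, float] = {}
    for ch in CHANNELS:
        lo = bin_range_auc(hist, ch, ranges.low)
        hi = bin_range_auc(hist, ch, ranges.high)
        if renormalize_signal:
            signal = lo + hi
            lo = lo / signal if signal > 0 else 0.0
            hi = hi / signal if signal > 0 else 0.0
        auc_low[ch] = lo
        auc_high[ch] = hi
        skew[ch] = histogram_skewness(hist, ch)
    return FeatureVector(
        source_id=img.source_id,
        label=img.label,
        n_valid_pixels=hist.n_valid_pixels,
        auc_low=auc_low,
        auc_high=auc_high,
        skewness=skew,
    )


def cohort_mean_histogram(
    hists: Sequence[ChannelHistogramSet], channel: str
) -> np.ndarray:
    """Bin-wise mean of per-image normalized histograms for one channel."""
    if len(hists) == 0:
        raise ValueError("need at least one histogram")
    if any(h.n_valid_pixels == 0 for h in hists):
        raise ValueError("cohort mean requires nonempty images")
    c = channel_index(channel)
    return np.mean([h.normalized[c] for h in hists], axis=0)


def features_to_frame(features: Iterable[FeatureVector]) -> pd.DataFrame:
    df = pd.DataFrame([f.to_row() for f in features])
    return df[list(FEATURE_COLUMNS)]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Cohort manifest CSV: source_id, path, label, optional x0,y0,x1,y1."""
    df = pd.read_csv(path, dtype={"source_id": str, "path": str, "label": str})
    missing = {"source_id", "path", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df
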