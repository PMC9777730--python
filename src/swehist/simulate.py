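"""Seeded synthetic elastogram cohorts.

Stands in for the clinical image set: each image is a rendered stiffness
field with a two-component soft/intermediate background mixture, a central
lesion disc, an optional stiff peritumoral rim, and random black signal
voids. Determinism is guaranteed by deriving one child seed per image from
(cohort seed, image index), so partial regeneration is stable.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .colormap import (
    DEFAULT_ACHROMATIC_THRESHOLD,
    StiffnessColormap,
    build_colormap,
    chromatic_mask,
    encode_field,
)
from .histograms import Elastogram

# Background mixture components; defaults land in the cool and intermediate
# bands of the 0-180 kPa ramp. Config knobs, not tissue claims.
SOFT_MEAN_KPA = 15.0
SOFT_GAMMA_SHAPE = 9.0
INTERMEDIATE_MEAN_KPA = 45.0
INTERMEDIATE_GAMMA_SHAPE = 4.0


@dataclass(frozen=True)
class LesionParams:
    """Stiffness structure of one synthetic image."""

    mean_kpa: float = 60.0
    sd_kpa: float = 15.0
    radius_px: float = 24.0
    rim_width_px: float = 0.0  # 0 disables the stiff rim
    rim_kpa: float = 150.0
    soft_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.mean_kpa < 0 or self.sd_kpa < 0:
            raise ValueError("stiffness parameters must be >= 0")
        if self.radius_px < 0 or self.rim_width_px < 0:
            raise ValueError("radii must be >= 0")
        if not 0.0 <= self.soft_fraction <= 1.0:
            raise ValueError("soft_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    n_benign: int = 32
    n_malignant: int = 64
    image_shape: tuple[int, int] = (256, 256)
    benign: LesionParams = field(
        default_factory=lambda: LesionParams(
            mean_kpa=40.0, sd_kpa=12.0, radius_px=24.0, soft_fraction=0.6
        )
    )
    malignant: LesionParams = field(
        default_factory=lambda: LesionParams(
            mean_kpa=110.0,
            sd_kpa=25.0,
            radius_px=24.0,
            rim_width_px=4.0,
            rim_kpa=150.0,
            soft_fraction=0.2,
        )
    )
    void_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_benign < 1 or self.n_malignant < 1:
            raise ValueError("cohort counts must be >= 1")
        if not 0.0 <= self.void_fraction < 1.0:
            raise ValueError("void_fraction must lie in [0, 1)")
        h, w = self.image_shape
        if h < 1 or w < 1:
            raise ValueError("image_shape must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_shape"] = list(self.image_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "benign" in d:
            d["benign"] = LesionParams(**d["benign"])
        if "malignant" in d:
            d["malignant"] = LesionParams(**d["malignant"])
        if "image_shape" in d:
            d["image_shape"] = tuple(int(v) for v in d["image_shape"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_stiffness_field(
    params: LesionParams, shape: tuple[int, int], rng_seed
) -> np.ndarray:
    """Draw one H x W stiffness field (kPa), deterministic given the seed.

    Background pixels come from a soft gamma component (mean ~15 kPa) with
    probability ``soft_fraction`` and an intermediate gamma component
    (mean ~45 kPa) otherwise; a centered disc gets truncated-gaussian
    lesion stiffness and an optional annulus gets rim stiffness.
    """
    h, w = int(shape[0]), int(shape[1])
    if h < 1 or w < 1:
        raise ValueError("shape must be positive")
    rng = _rng(rng_seed)
    soft = rng.gamma(SOFT_GAMMA_SHAPE, SOFT_MEAN_KPA / SOFT_GAMMA_SHAPE, size=(h, w))
    inter = rng.gamma(
        INTERMEDIATE_GAMMA_SHAPE,
        INTERMEDIATE_MEAN_KPA / INTERMEDIATE_GAMMA_SHAPE,
        size=(h, w),
    )
    field_kpa = np.where(rng.random((h, w)) < params.soft_fraction, soft, inter)

    rr, cc = np.ogrid[:h, :w]
    dist2 = (rr - (h - 1) / 2.0) ** 2 + (cc - (w - 1) / 2.0) ** 2
    if params.radius_px > 0:
        lesion = dist2 <= params.radius_px**2
        field_kpa[lesion] = rng.normal(params.mean_kpa, params.sd_kpa, int(lesion.sum()))
        if params.rim_width_px > 0:
            rim = (dist2 > params.radius_px**2) & (
                dist2 <= (params.radius_px + params.rim_width_px) ** 2
            )
            field_kpa[rim] = rng.normal(params.rim_kpa, params.sd_kpa, int(rim.sum()))
    return np.clip(field_kpa, 0.0, None)


def render_elastogram(
    field: np.ndarray,
    cmap: StiffnessColormap,
    void_fraction: float = 0.0,
    rng_seed=None,
    source_id: str = "",
    label: str = "unknown",
    threshold: int = DEFAULT_ACHROMATIC_THRESHOLD,
) -> Elastogram:
    """Render a stiffness field through the colormap, punching black voids."""
    field = np.asarray(field, dtype=float)
    if not np.all(np.isfinite(field)) or field.min() < 0:
        raise ValueError("field must be finite and >= 0")
    if not 0.0 <= void_fraction < 1.0:
        raise ValueError("void_fraction must lie in [0, 1)")
    pixels = encode_field(field, cmap)
    if void_fraction > 0.0:
        rng = _rng(rng_seed)
        void = rng.random(field.shape) < void_fraction
        pixels[void] = 0
    return Elastogram(
        pixels=pixels,
        valid_mask=chromatic_mask(pixels, threshold),
        source_id=source_id,
        label=label,
    )


def _child_seed(seed: int, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(seed, spawn_key=(index,))


def simulate_image(
    params: LesionParams,
    shape: tuple[int, int],
    cmap: StiffnessColormap,
    void_fraction: float,
    seed: int,
    index: int,
    source_id: str,
    label: str,
) -> Elastogram:
    """One cohort image from its (cohort seed, index) child seed."""
    field_rng, void_rng = (
        np.random.default_rng(s) for s in _child_seed(seed, index).spawn(2)
    )
    field = simulate_stiffness_field(params, shape, field_rng)
    return render_elastogram(
        field, cmap, void_fraction, void_rng, source_id=source_id, label=label
    )


def simulate_cohort(
    spec: CohortSpec,
    out_dir: str | Path | None = None,
    cmap: StiffnessColormap | None = None,
) -> tuple[list[Elastogram], pd.DataFrame]:
    """Generate the full labeled cohort (benign images first).

    Returns the images plus the ground-truth parameter table. When
    ``out_dir`` is given, also writes ``images/<source_id>.png``, a
    ``manifest.csv`` (source_id, path, label) consumable by the histogram
    pipeline, and a ``truth.csv`` with the per-image generating parameters.
    """
    if cmap is None:
        cmap = build_colormap()
    images: list[Elastogram] = []
    rows: list[dict] = []
    plan = [("benign", spec.benign, spec.n_benign), ("malignant", spec.malignant, spec.n_malignant)]
    index = 0
    for label, params, count in plan:
        for i in range(count):
            source_id = f"{label}_{i:03d}"
            img = simulate_image(
                params,
                spec.image_shape,
                cmap,
                spec.void_fraction,
                spec.seed,
                index,
                source_id,
                label,
            )
            images.append(img)
            row = {"source_id": source_id, "label": label, "seed_index": index}
            row.update(asdict(params))
            rows.append(row)
            index += 1
    truth = pd.DataFrame(rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        img_dir = out_dir / "images"
        img_dir.mkdir(parents=True, exist_ok=True)
        manifest_rows = []
        for img in images:
            rel = f"images/{img.source_id}.png"
            try:
                iio.imwrite(out_dir / rel, img.pixels, extension=".png")
            except OSError as exc:
                raise IOError(f"failed to write {out_dir / rel}: {exc}") from exc
            manifest_rows.append(
                {"source_id": img.source_id, "path": rel, "label": img.label}
            )
        pd.DataFrame(manifest_rows).to_csv(out_dir / "manifest.csv", index=False)
        truth.to_csv(out_dir / "truth.csv", index=False)
    return images, truth
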