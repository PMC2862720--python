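"""Synthetic IHC micrographs and paired ordinal ratings with known truth.

Real DAB-stained fields contain three color populations: brown stained
cell regions (SP), blue hematoxylin-counterstained unstained cell regions
(NSP), and pale background (BG). The generator renders cells as disks on
a background, samples each region's pixels from a Gaussian mixture color
model, adds i.i.d. Gaussian pixel noise, and records the exact label mask
— so the downstream segmentation and quantification pipeline can be
scored against ground truth without any external images.

The rating generator produces paired 4-level ordinal scores (two scoring
methods over the same cases) with controllable marginals and agreement,
serving as input for the concordance statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ConfigurationError
from .gmm import BG, NSP, SP, GaussianComponent, MixtureModel


def _mixture(weights, means, var) -> MixtureModel:
    comps = [
        GaussianComponent(w, np.array(m, dtype=float), var * np.eye(3))
        for w, m in zip(weights, means)
    ]
    return MixtureModel(comps)


def default_sp_model() -> MixtureModel:
    """DAB brown, two shades (darker core staining vs lighter rim)."""
    return _mixture([0.6, 0.4], [(140, 90, 60), (110, 70, 45)], 60.0)


def default_nsp_model() -> MixtureModel:
    """Hematoxylin blue, pale and dense nuclear shades."""
    return _mixture([0.5, 0.5], [(120, 120, 180), (90, 95, 150)], 60.0)


def default_bg_model() -> MixtureModel:
    """Near-white background with a faint pinkish cast."""
    return _mixture([0.7, 0.3], [(235, 230, 235), (245, 243, 240)], 25.0)


@dataclass
class ImageGenConfig:
    width_px: int = 96
    height_px: int = 96
    n_cells: int = 40
    nucleus_radius_px: tuple[float, float] = (5.0, 9.0)
    fraction_stained: float = 0.3
    sp_color_model: MixtureModel = field(default_factory=default_sp_model)
    nsp_color_model: MixtureModel = field(default_factory=default_nsp_model)
    bg_color_model: MixtureModel = field(default_factory=default_bg_model)
    pixel_noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ConfigurationError("image dimensions must be positive")
        if self.n_cells < 0:
            raise ConfigurationError("n_cells must be non-negative")
        lo, hi = self.nucleus_radius_px
        if not (0 < lo <= hi):
            raise ConfigurationError("nucleus radius range must be positive and ordered")
        if not 0.0 <= self.fraction_stained <= 1.0:
            raise ConfigurationError("fraction_stained must lie in [0, 1]")
        if self.pixel_noise_sd < 0:
            raise ConfigurationError("pixel_noise_sd must be non-negative")
        for model in (self.sp_color_model, self.nsp_color_model, self.bg_color_model):
            if np.any(model.means < 0) or np.any(model.means > 255):
                raise ConfigurationError("color-model means must lie in [0, 255]^3")


@dataclass
class FieldTruth:
    staining_ratio: float
    staining_intensity: float
    expression_level: float
    n_cells_placed: int


@dataclass
class LabeledImage:
    rgb: np.ndarray       # H x W x 3 uint8
    labels: np.ndarray    # H x W int, codes 0=BG 1=NSP 2=SP
    truth: FieldTruth


def generate_gmm_sample(model: MixtureModel, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` i.i.d. RGB vectors from a Gaussian mixture."""
    if n < 1:
        raise ConfigurationError("sample size must be >= 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(model.n_components, size=n, p=model.weights)
    out = np.empty((n, model.dim))
    means, covs = model.means, model.covs
    for j in range(model.n_components):
        idx = np.flatnonzero(comp == j)
        if idx.size:
            out[idx] = rng.multivariate_normal(means[j], covs[j], size=idx.size)
    return out


def _fill_region(rgb, mask, model, rng):
    idx = np.flatnonzero(mask.ravel())
    if idx.size == 0:
        return
    comp = rng.choice(model.n_components, size=idx.size, p=model.weights)
    colors = np.empty((idx.size, 3))
    for j in range(model.n_components):
        sel = np.flatnonzero(comp == j)
        if sel.size:
            colors[sel] = rng.multivariate_normal(model.means[j], model.covs[j], size=sel.size)
    rgb.reshape(-1, 3)[idx] = colors


def generate_ihc_field(config: ImageGenConfig) -> LabeledImage:
    """Render one synthetic IHC field with an exact SP/NSP/BG label mask.

    Cells are possibly-overlapping disks; the stained subset (rounded
    ``fraction_stained`` of the cells) is drawn last so overlaps resolve
    deterministically in favor of SP. The recorded truth uses the label
    mask itself: staining ratio |SP| / (|SP| + |NSP|), and staining
    intensity as mean darkness (1 - luminance/255) over true SP pixels of
    the rendered image.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.height_px, config.width_px
    labels = np.full((h, w), BG, dtype=np.int64)

    yy, xx = np.mgrid[0:h, 0:w]
    n_stained = int(round(config.fraction_stained * config.n_cells))
    centers = rng.uniform([0, 0], [h, w], size=(config.n_cells, 2))
    radii = rng.uniform(*config.nucleus_radius_px, size=config.n_cells)
    stained = np.zeros(config.n_cells, dtype=bool)
    if config.n_cells:
        stained[rng.permutation(config.n_cells)[:n_stained]] = True

    # NSP disks first, SP last: SP wins any overlap, keeping truth exact.
    for order, code in ((~stained, NSP), (stained, SP)):
        for i in np.flatnonzero(order):
            cy, cx = centers[i]
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radii[i] ** 2
            labels[disk] = code

    rgb = np.empty((h, w, 3), dtype=float)
    _fill_region(rgb, labels == BG, config.bg_color_model, rng)
    _fill_region(rgb, labels == NSP, config.nsp_color_model, rng)
    _fill_region(rgb, labels == SP, config.sp_color_model, rng)
    if config.pixel_noise_sd > 0:
        rgb += rng.normal(0.0, config.pixel_noise_sd, size=rgb.shape)
    rgb = np.clip(np.round(rgb), 0, 255).astype(np.uint8)

    n_sp = int((labels == SP).sum())
    n_nsp = int((labels == NSP).sum())
    cell_px = n_sp + n_nsp
    ratio = n_sp / cell_px if cell_px else 0.0
    if n_sp:
        lum = rgb[labels == SP].mean(axis=1)
        intensity = float(np.mean(1.0 - lum / 255.0))
    else:
        intensity = 0.0
    truth = FieldTruth(
        staining_ratio=float(ratio),
        staining_intensity=intensity,
        expression_level=float(ratio) * intensity,
        n_cells_placed=config.n_cells,
    )
    return LabeledImage(rgb=rgb, labels=labels, truth=truth)


def training_pixels(fields: list[LabeledImage]) -> dict[str, np.ndarray]:
    """Pool per-class pixel samples across labeled fields for EM training."""
    out = {}
    for name, code in (("sp", SP), ("nsp", NSP), ("bg", BG)):
        chunks = [f.rgb[f.labels == code].astype(float) for f in fields]
        pooled = np.concatenate([c for c in chunks if len(c)]) if any(
            len(c) for c in chunks
        ) else np.empty((0, 3))
        out[name] = pooled
    return out


# ---------------------------------------------------------------------
# Paired ordinal ratings
# ---------------------------------------------------------------------

def _independent_kernel(marginals: np.ndarray) -> np.ndarray:
    return np.tile(marginals, (4, 1))


@dataclass
class RatingGenConfig:
    n_cases: int = 105
    marginals: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1)
    agreement: float = 0.9
    confusion_kernel: np.ndarray | None = None  # rows: method-A category
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ConfigurationError("n_cases must be positive")
        m = np.asarray(self.marginals, dtype=float)
        if m.shape != (4,) or np.any(m < 0) or abs(m.sum() - 1.0) > 1e-9:
            raise ConfigurationError("marginals must be a probability vector over 4 categories")
        if not 0.0 <= self.agreement <= 1.0:
            raise ConfigurationError("agreement must lie in [0, 1]")
        if self.confusion_kernel is None:
            self.confusion_kernel = _independent_kernel(m)
        k = np.asarray(self.confusion_kernel, dtype=float)
        if k.shape != (4, 4) or np.any(k < 0) or not np.allclose(k.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError("confusion kernel must be 4x4 row-stochastic")
        self.confusion_kernel = k


@dataclass
class PairedRatings:
    case_ids: list[str]
    method_a: np.ndarray  # ordinal codes 0..3
    method_b: np.ndarray

    @property
    def n(self) -> int:
        return len(self.case_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"case_id": self.case_ids, "method_a": self.method_a, "method_b": self.method_b}
        )


def generate_paired_ratings(config: RatingGenConfig) -> PairedRatings:
    """Two aligned 4-level ordinal score vectors over the same cases.

    Method A draws from ``marginals``; method B copies A with probability
    ``agreement``, otherwise draws from the confusion-kernel row for A's
    category (default kernel: independent redraw from the marginals).
    """
    rng = np.random.default_rng(config.seed)
    m = np.asarray(config.marginals, dtype=float)
    a = rng.choice(4, size=config.n_cases, p=m)
    copy = rng.random(config.n_cases) < config.agreement
    b = np.empty_like(a)
    b[copy] = a[copy]
    for i in np.flatnonzero(~copy):
        b[i] = rng.choice(4, p=config.confusion_kernel[a[i]])
    ids = [f"case_{i + 1:03d}" for i in range(config.n_cases)]
    return PairedRatings(case_ids=ids, method_a=a, method_b=b)


# ---------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------

def save_field(field: LabeledImage, stem: str | Path) -> dict[str, str]:
    """Write <stem>.png (RGB), <stem>_mask.png (codes 0/1/2) and <stem>.json."""
    stem = Path(stem)
    img_path = stem.with_suffix(".png")
    mask_path = stem.parent / f"{stem.name}_mask.png"
    meta_path = stem.with_suffix(".json")
    Image.fromarray(field.rgb).save(img_path)
    Image.fromarray(field.labels.astype(np.uint8), mode="L").save(mask_path)
    meta = {
        "image": img_path.name,
        "mask": mask_path.name,
        "mask_codes": {"bg": BG, "nsp": NSP, "sp": SP},
        "truth": {
            "staining_ratio": field.truth.staining_ratio,
            "staining_intensity": field.truth.staining_intensity,
            "expression_level": field.truth.expression_level,
        },
    }
    meta_path.write_text(json.dumps(meta, indent=2))
    return {"image": str(img_path), "mask": str(mask_path), "meta": str(meta_path)}


def load_field(meta_path: str | Path) -> LabeledImage:
    meta_path = Path(meta_path)
    meta = json.loads(meta_path.read_text())
    rgb = np.asarray(Image.open(meta_path.parent / meta["image"]))
    labels = np.asarray(Image.open(meta_path.parent / meta["mask"])).astype(np.int64)
    t = meta["truth"]
    truth = FieldTruth(
        staining_ratio=t["staining_ratio"],
        staining_intensity=t["staining_intensity"],
        expression_level=t["expression_level"],
        n_cells_placed=-1,
    )
    return LabeledImage(rgb=rgb, labels=labels, truth=truth)


def save_ratings(ratings: PairedRatings, path: str | Path) -> None:
    ratings.to_frame().to_csv(path, index=False)
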