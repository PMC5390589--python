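"""Seeded generator of two-class tongue-like images.

The clinical dataset the evaluation protocol was designed around is
private, so this module fabricates a texture-discriminable stand-in with
the same ~85:15 class imbalance (48 normal vs 267 abnormal by default):
an elliptical bright "tongue body" on a dark background, carrying a
smooth Gaussian-correlated texture.  Abnormal images additionally receive
high-frequency "coating" spots whose density scales with the class
contrast parameter; at contrast 0 the two class-conditional distributions
coincide exactly.  The appearance model is deliberately schematic — it
exists to plant learnable texture, not to mimic clinical photographs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image as PILImage
from scipy import ndimage

from .preprocess import Image


@dataclass
class SynthConfig:
    """Generator configuration; identical seed implies identical dataset.

    contrast scales the density of class-1 coating spots (0 = classes
    indistinguishable); smooth_scale is the Gaussian correlation length of
    the base texture in pixels; noise_level the std of additive pixel noise.
    """

    n_normal: int = 48
    n_abnormal: int = 267
    height: int = 32
    width: int = 32
    seed: int = 0
    contrast: float = 1.0
    spot_density: float = 0.25  # expected spots per foreground pixel at contrast 1
    smooth_scale: float = 3.0
    noise_level: float = 2.0

    def __post_init__(self) -> None:
        if self.n_normal < 0 or self.n_abnormal < 0:
            raise ValueError("class counts must be >= 0")
        if self.height < 1 or self.width < 1:
            raise ValueError(f"invalid image size {(self.height, self.width)}")
        if self.contrast < 0:
            raise ValueError("contrast must be >= 0")


def _ellipse_mask(h: int, w: int) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    return ((yy - cy) / (0.45 * h)) ** 2 + ((xx - cx) / (0.38 * w)) ** 2 <= 1.0


def generate_image(class_label: int, seed: int, cfg: SynthConfig | None = None) -> Image:
    """One synthetic tongue-like image for the given class.

    Class 0: elliptical foreground with smooth correlated texture only.
    Class 1: the same, plus bright high-frequency coating spots with
    expected count contrast * spot_density * foreground area.
    """
    cfg = cfg or SynthConfig()
    if class_label not in (0, 1):
        raise ValueError(f"class_label must be 0 or 1, got {class_label}")
    h, w = cfg.height, cfg.width
    rng = np.random.default_rng(seed)
    mask = _ellipse_mask(h, w)

    base = ndimage.gaussian_filter(rng.standard_normal((h, w)), cfg.smooth_scale)
    base *= 30.0 / max(base.std(), 1e-12)
    img = np.where(mask, 150.0 + base, 25.0)

    n_spots = rng.poisson(class_label * cfg.contrast * cfg.spot_density * mask.sum())
    if n_spots:
        fg = np.argwhere(mask)
        centers = fg[rng.integers(0, len(fg), size=n_spots)]
        spots = np.zeros((h, w))
        spots[centers[:, 0], centers[:, 1]] = 90.0
        img += ndimage.gaussian_filter(spots, 0.6) * mask

    img += rng.normal(0.0, cfg.noise_level, size=(h, w))
    return Image(np.clip(img, 0.0, 255.0), source=f"synth:class{class_label}:seed{seed}")


def generate_dataset(cfg: SynthConfig | None = None) -> tuple[list[Image], np.ndarray]:
    """n_normal + n_abnormal labeled images, deterministic per cfg.seed.

    Labels are emitted normal-first (all 0s, then all 1s); per-image seeds
    are spawned from cfg.seed so each image is independently reproducible.
    """
    cfg = cfg or SynthConfig()
    total = cfg.n_normal + cfg.n_abnormal
    if total == 0:
        raise ValueError("at least one image must be requested")
    seed_rng = np.random.default_rng(cfg.seed)
    child_seeds = seed_rng.integers(0, 2**31 - 1, size=total)
    labels = np.concatenate(
        [np.zeros(cfg.n_normal, dtype=int), np.ones(cfg.n_abnormal, dtype=int)]
    )
    imgs = [generate_image(int(lbl), int(s), cfg) for lbl, s in zip(labels, child_seeds)]
    return imgs, labels


def write_dataset(imgs: list[Image], labels: np.ndarray, out_dir: str | Path) -> Path:
    """Write PNGs plus a two-column labels CSV (image id, label); returns the CSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "labels.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", "label"])
        for i, (img, lbl) in enumerate(zip(imgs, labels)):
            name = f"img_{i:04d}.png"
            arr = np.clip(np.round(img.pixels), 0, 255).astype(np.uint8)
            PILImage.fromarray(arr, mode="L").save(out_dir / name)
            writer.writerow([name, int(lbl)])
    return csv_path
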