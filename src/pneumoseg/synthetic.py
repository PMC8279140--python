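"""Deterministic chest-phantom corpora for exercising the full pipeline.

The generator emulates the *shape* of the pneumothorax segmentation task,
not radiographic appearance: elliptical lung fields on a body oval, and
thin crescent-shaped foreground lesions hugging the lung boundary (a
pneumothorax presents as a lucent crescent between lung edge and chest
wall).  Lesions occupy roughly 0.5-8% of pixels and about 22% of images
are positive by default, mirroring the class balance of the challenge
corpus.  Matched probability maps with controllable blur and noise stand
in for network outputs when testing thresholding and ensembling.

Identical configs produce byte-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .imaging import write_dicom, write_mask_png
from .rle import encode_rle

__all__ = [
    "PhantomConfig",
    "PhantomRecord",
    "generate_corpus",
    "generate_probability_maps",
    "write_corpus",
]


@dataclass
class PhantomConfig:
    image_size: int = 256
    n_images: int = 16
    positive_fraction: float = 0.22
    lesion_area_range: tuple[float, float] = (0.005, 0.08)
    max_lesions: int = 3
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.lesion_area_range
        if not (0 < lo <= hi <= 1):
            raise ValueError(f"lesion_area_range must be within (0, 1], got {self.lesion_area_range}")
        if not 0 <= self.positive_fraction <= 1:
            raise ValueError("positive_fraction must be in [0, 1]")
        if lo * self.image_size**2 < 3:
            raise ValueError(
                f"lesion area fraction {lo} is infeasible at {self.image_size}px "
                "(fewer than 3 foreground pixels)"
            )


@dataclass
class PhantomRecord:
    image_id: str
    image: np.ndarray  # (H, W) uint8
    mask: np.ndarray  # (H, W) uint8 in {0, 1}
    rle_strings: list[str] = field(default_factory=list)  # one per lesion; empty if negative


def _lung_fields(n: int) -> tuple[np.ndarray, list[tuple[float, float, float, float]]]:
    """Binary lung-field map and the two lung ellipses (cy, cx, ry, rx)."""
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    lungs = np.zeros((n, n), dtype=bool)
    params = []
    for cx_frac in (0.32, 0.68):
        cy, cx = 0.52 * n, cx_frac * n
        ry, rx = 0.30 * n, 0.13 * n
        lungs |= ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        params.append((cy, cx, ry, rx))
    return lungs, params


def _crescent(n: int, ellipse, theta: float, area_px: float, rng) -> np.ndarray:
    """Thin crescent: a disk minus an overlapping disk, centred on the lung edge."""
    cy, cx, ry, rx = ellipse
    py, px = cy + ry * np.sin(theta), cx + rx * np.cos(theta)
    # crescent area with offset 0.6r between equal disks is ~1.18 r^2
    r = max(2.0, np.sqrt(area_px / 1.18))
    phi = rng.uniform(0, 2 * np.pi)
    oy, ox = 0.6 * r * np.sin(phi), 0.6 * r * np.cos(phi)
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    disk1 = (yy - py) ** 2 + (xx - px) ** 2 <= r**2
    disk2 = (yy - py - oy) ** 2 + (xx - px - ox) ** 2 <= r**2
    return disk1 & ~disk2


def generate_corpus(cfg: PhantomConfig) -> list[PhantomRecord]:
    """Generate phantom radiographs with masks and per-lesion RLE strings."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.image_size
    lungs, ellipses = _lung_fields(n)
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    body = ((yy - 0.55 * n) / (0.42 * n)) ** 2 + ((xx - 0.5 * n) / (0.38 * n)) ** 2 <= 1.0

    n_pos = int(round(cfg.positive_fraction * cfg.n_images))
    positive = np.zeros(cfg.n_images, dtype=bool)
    positive[rng.choice(cfg.n_images, size=n_pos, replace=False)] = True

    records = []
    for i in range(cfg.n_images):
        base = np.full((n, n), 30.0)
        base[body] = 120.0
        base[lungs] = 70.0
        mask = np.zeros((n, n), dtype=np.uint8)
        rles: list[str] = []
        if positive[i]:
            for _ in range(int(rng.integers(1, cfg.max_lesions + 1))):
                area = rng.uniform(*cfg.lesion_area_range) * n * n
                for _attempt in range(8):
                    comp = _crescent(n, ellipses[int(rng.integers(2))], rng.uniform(0, 2 * np.pi), area, rng)
                    comp &= ~(mask > 0)
                    if comp.sum() >= 3:
                        mask[comp] = 1
                        rles.append(encode_rle(comp))
                        break
            if not rles:  # guarantee every positive image has foreground
                comp = _crescent(n, ellipses[0], 0.0, cfg.lesion_area_range[1] * n * n, rng)
                mask[comp] = 1
                rles.append(encode_rle(comp))
        base[mask > 0] += 25.0
        img = base + rng.normal(0.0, cfg.noise_sd, size=(n, n))
        records.append(
            PhantomRecord(
                image_id=f"phantom_{cfg.seed:03d}_{i:04d}",
                image=np.clip(img, 0, 255).astype(np.uint8),
                mask=mask,
                rle_strings=rles,
            )
        )
    return records


def generate_probability_maps(
    masks, blur_sd: float = 1.5, noise_sd: float = 0.1, seed: int = 0, n_models: int = 1
) -> list[list[np.ndarray]]:
    """Surrogate network outputs: clipped(blurred mask + Gaussian noise).

    Returns one list of maps per simulated model (independent noise draws,
    shared seed stream).  With ``blur_sd = noise_sd = 0`` binarizing at 0.5
    reproduces the mask exactly; raising ``noise_sd`` strictly degrades the
    expected IoU of the thresholded map.
    """
    rng = np.random.default_rng(seed)
    out: list[list[np.ndarray]] = []
    for _ in range(n_models):
        maps = []
        for mask in masks:
            m = np.asarray(mask, dtype=np.float64)
            if blur_sd > 0:
                m = gaussian_filter(m, blur_sd)
            if noise_sd > 0:
                m = m + rng.normal(0.0, noise_sd, size=m.shape)
            maps.append(np.clip(m, 0.0, 1.0))
        out.append(maps)
    return out


def write_corpus(records: list[PhantomRecord], out_dir, *, file_format: str = "dicom") -> Path:
    """Write a corpus in the dataset's on-disk layout.

    ``<out>/images/<id>.dcm`` (or ``.png``), ``<out>/masks/<id>.png`` and a
    ``train-rle.csv`` with one ``ImageId,EncodedPixels`` row per RLE string
    ("-1" for negatives).
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        if file_format == "dicom":
            write_dicom(out_dir / "images" / f"{rec.image_id}.dcm", rec.image, rec.image_id)
        else:
            from PIL import Image

            Image.fromarray(rec.image, mode="L").save(out_dir / "images" / f"{rec.image_id}.png")
        write_mask_png(out_dir / "masks" / f"{rec.image_id}.png", rec.mask)
        for rle in rec.rle_strings or ["-1"]:
            rows.append({"ImageId": rec.image_id, "EncodedPixels": rle})
    csv_path = out_dir / "train-rle.csv"
    pd.DataFrame(rows, columns=["ImageId", "EncodedPixels"]).to_csv(csv_path, index=False)
    return csv_path
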