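"""Training-time augmentation for image+mask pairs.

The menu: horizontal flip; shift-scale-rotate (rotations up to 20 deg);
one of elastic transform / optical distortion / grid distortion; one of
random contrast / brightness / gamma; plus random crop (resized back) for
the ResNet50-UNet configuration only.  Geometric transforms warp image and
mask identically (bilinear vs nearest so masks stay binary); intensity
transforms touch the image alone.  All randomness is drawn from a caller-
supplied generator *before* anything is applied, so a fixed generator
state reproduces the augmentation bitwise and the warp is independent of
the pixel content.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .imaging import ModelInput

__all__ = ["AugmentationConfig", "augment_pair", "build_train_augmentation", "sample_params", "apply_params"]


@dataclass
class AugmentationConfig:
    horizontal_flip_p: float = 0.5
    shift_scale_rotate_p: float = 0.5
    max_rotation_deg: float = 20.0
    shift_limit: float = 0.0625
    scale_limit: float = 0.1
    distortion_group_p: float = 0.5
    intensity_group_p: float = 0.5
    random_crop_enabled: bool = False
    random_crop_area_range: tuple[float, float] = (0.81, 1.0)
    seed: int = 0
    # moderate distortion magnitudes, all overridable
    elastic_alpha: float = 15.0
    elastic_sigma: float = 5.0
    optical_limit: float = 0.05
    grid_steps: int = 5
    grid_limit: float = 0.3

    def __post_init__(self):
        for name in ("horizontal_flip_p", "shift_scale_rotate_p", "distortion_group_p", "intensity_group_p"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.max_rotation_deg < 0:
            raise ValueError("max_rotation_deg must be non-negative")
        lo, hi = self.random_crop_area_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("random_crop_area_range must be within (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def build_train_augmentation(model_name: str) -> AugmentationConfig:
    """Per-model training augmentation; random crop only for ResNet50-UNet."""
    known = {
        "resnet50_unet", "densenet169_unet", "se_resnext50_unet", "efficientnetb4_unet",
        "se_resnext101_unet", "efficientnetb3_unet", "tiny_unet",
    }
    if model_name not in known:
        raise ValueError(f"unknown model {model_name!r}; choose from {sorted(known)}")
    return AugmentationConfig(random_crop_enabled=model_name == "resnet50_unet")


def sample_params(cfg: AugmentationConfig, rng: np.random.Generator) -> dict:
    """Draw every random decision for one augmentation application."""
    u = rng.random(4)
    params: dict = {"flip": bool(u[0] < cfg.horizontal_flip_p)}
    if u[1] < cfg.shift_scale_rotate_p:
        params["ssr"] = {
            "angle": float(rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg)),
            "shift": tuple(rng.uniform(-cfg.shift_limit, cfg.shift_limit, 2)),
            "scale": float(1.0 + rng.uniform(-cfg.scale_limit, cfg.scale_limit)),
        }
    if u[2] < cfg.distortion_group_p:
        kind = ("elastic", "optical", "grid")[int(rng.integers(3))]
        if kind == "elastic":
            params["distortion"] = {"kind": kind, "seed": int(rng.integers(2**31))}
        elif kind == "optical":
            params["distortion"] = {"kind": kind, "k": float(rng.uniform(-cfg.optical_limit, cfg.optical_limit))}
        else:
            params["distortion"] = {
                "kind": kind,
                "sx": rng.uniform(-cfg.grid_limit, cfg.grid_limit, cfg.grid_steps),
                "sy": rng.uniform(-cfg.grid_limit, cfg.grid_limit, cfg.grid_steps),
            }
    if u[3] < cfg.intensity_group_p:
        kind = ("contrast", "brightness", "gamma")[int(rng.integers(3))]
        value = {
            "contrast": float(1.0 + rng.uniform(-0.2, 0.2)),
            "brightness": float(rng.uniform(-0.2, 0.2)),
            "gamma": float(rng.uniform(0.8, 1.25)),
        }[kind]
        params["intensity"] = {"kind": kind, "value": value}
    if cfg.random_crop_enabled:
        area = rng.uniform(*cfg.random_crop_area_range)
        params["crop"] = {"area": float(area), "u": tuple(rng.random(2))}
    return params


def _warp_coords(cfg: AugmentationConfig, params: dict, shape: tuple[int, int]) -> np.ndarray | None:
    """Source-coordinate field (2, H, W) for the composed geometric warp."""
    h, w = shape
    coords = None

    def ident():
        return np.mgrid[0:h, 0:w].astype(np.float64)

    if "ssr" in params:
        p = params["ssr"]
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        th = np.deg2rad(p["angle"])
        yy, xx = ident()
        # inverse map: rotate by -th, scale by 1/s, undo shift
        ys = yy - cy - p["shift"][0] * h
        xs = xx - cx - p["shift"][1] * w
        cos_t, sin_t = np.cos(th), np.sin(th)
        coords = np.stack([
            (cos_t * ys - sin_t * xs) / p["scale"] + cy,
            (sin_t * ys + cos_t * xs) / p["scale"] + cx,
        ])
    if "distortion" in params:
        d = params["distortion"]
        base = coords if coords is not None else ident()
        if d["kind"] == "elastic":
            r = np.random.default_rng(d["seed"])
            dy = gaussian_filter(r.uniform(-1, 1, (h, w)), cfg.elastic_sigma) * cfg.elastic_alpha
            dx = gaussian_filter(r.uniform(-1, 1, (h, w)), cfg.elastic_sigma) * cfg.elastic_alpha
            coords = np.stack([base[0] + dy, base[1] + dx])
        elif d["kind"] == "optical":
            cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
            yn, xn = (base[0] - cy) / cy, (base[1] - cx) / cx
            factor = 1.0 + d["k"] * (yn**2 + xn**2)
            coords = np.stack([cy + yn * factor * cy, cx + xn * factor * cx])
        else:  # grid: piecewise-linear monotone stretch of each axis
            def axis_map(n, scales):
                steps = np.full(len(scales), n / len(scales)) * (1.0 + scales)
                knots_src = np.concatenate(([0.0], np.cumsum(steps)))
                knots_src *= (n - 1) / knots_src[-1]
                knots_dst = np.linspace(0, n - 1, len(scales) + 1)
                return np.interp(np.arange(n), knots_dst, knots_src)

            my = axis_map(h, np.asarray(d["sy"]))
            mx = axis_map(w, np.asarray(d["sx"]))
            src_y = np.interp(base[0].ravel(), np.arange(h), my).reshape(h, w)
            src_x = np.interp(base[1].ravel(), np.arange(w), mx).reshape(h, w)
            coords = np.stack([src_y, src_x])
    return coords


def _apply_geometric(plane: np.ndarray, coords: np.ndarray | None, order: int) -> np.ndarray:
    if coords is None:
        return plane
    return map_coordinates(plane.astype(np.float64), coords, order=order, mode="reflect")


def _crop_resize(plane: np.ndarray, crop: dict, order: int) -> np.ndarray:
    from skimage.transform import resize

    h, w = plane.shape
    side = np.sqrt(crop["area"])
    ch, cw = max(1, int(round(h * side))), max(1, int(round(w * side)))
    oy = int(round(crop["u"][0] * (h - ch)))
    ox = int(round(crop["u"][1] * (w - cw)))
    piece = plane[oy : oy + ch, ox : ox + cw]
    return resize(piece.astype(np.float64), (h, w), order=order, mode="edge",
                  anti_aliasing=False, preserve_range=True)


def apply_params(sample: ModelInput, cfg: AugmentationConfig, params: dict) -> ModelInput:
    img = sample.tensor[:, :, 0].astype(np.float64)
    mask = sample.mask.copy() if sample.mask is not None else None
    if params.get("flip"):
        img = img[:, ::-1]
        mask = mask[:, ::-1] if mask is not None else None
    coords = _warp_coords(cfg, params, img.shape)
    if coords is not None:
        img = _apply_geometric(img, coords, order=1)
        if mask is not None:
            mask = _apply_geometric(mask.astype(np.float64), coords, order=0)
    if "crop" in params:
        img = _crop_resize(img, params["crop"], order=1)
        if mask is not None:
            mask = _crop_resize(mask.astype(np.float64), params["crop"], order=0)
    if "intensity" in params:
        kind, v = params["intensity"]["kind"], params["intensity"]["value"]
        if kind == "contrast":
            img = (img - img.mean()) * v + img.mean()
        elif kind == "brightness":
            img = img + v
        else:
            img = np.clip(img, 0, 1) ** v
        img = np.clip(img, 0.0, 1.0)
    tensor = np.repeat(np.ascontiguousarray(img)[:, :, None], 3, axis=2).astype(np.float32)
    out_mask = None if mask is None else (np.ascontiguousarray(mask) > 0.5).astype(np.uint8)
    return ModelInput(tensor=tensor, mask=out_mask)


def augment_pair(sample: ModelInput, cfg: AugmentationConfig, rng: np.random.Generator) -> ModelInput:
    """Randomly augment one image(+mask) sample; deterministic in ``rng`` state."""
    if sample.mask is not None and sample.mask.shape != sample.tensor.shape[:2]:
        raise ValueError(
            f"mask shape {sample.mask.shape} does not match image {sample.tensor.shape[:2]}"
        )
    return apply_params(sample, cfg, sample_params(cfg, rng))
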