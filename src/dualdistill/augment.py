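"""Probability-combined image augmentation and occlusion operators.

Two families of operators expand a training set:

* a *transformation* policy in which each sub-strategy — rotation (+/-30
  deg), horizontal flip, random crop (up to 20% of the side), and
  brightness / contrast / saturation / hue jitter (+/-10%) — fires
  independently on every image with probability 10%, so several can combine
  on one image; and
* a *cropping* (occlusion) dispatcher that applies at most one of cutout
  (15%), random erasing (10%), or hide-and-seek (5%) per image, masking a
  region of 10-20% of the image area to imitate partially occluded subjects.

``expand_dataset`` composes both to grow a dataset by an integer factor
(default 10, e.g. 1,000 -> 10,000 images), keeping the original image as one
of its variants and preserving per-class balance exactly.

All operators preserve image shape and the [0, 1] pixel range and are
deterministic given a seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from skimage import transform as sktransform

from .data import LabeledImage

__all__ = [
    "AugmentConfig",
    "SUB_STRATEGIES",
    "OCCLUSION_BRANCHES",
    "apply_transform_policy",
    "cutout",
    "random_erase",
    "hide_and_seek",
    "select_occlusion",
    "apply_occlusion",
    "expand_dataset",
]

#: transformation-class sub-strategies, each fired independently
SUB_STRATEGIES = (
    "rotate",
    "hflip",
    "crop",
    "brightness",
    "contrast",
    "saturation",
    "hue",
)

#: cropping-class branches of the single categorical occlusion draw
OCCLUSION_BRANCHES = ("cutout", "random_erase", "hide_and_seek", "none")


@dataclasses.dataclass(frozen=True)
class AugmentConfig:
    """Probabilities and parameter ranges of the augmentation stack."""

    p_sub_strategy: float = 0.10
    rotation_range: float = 30.0  # degrees, symmetric
    p_hflip: float = 0.50  # flip probability once the flip sub-strategy fires
    max_crop_frac: float = 0.20
    jitter_range: float = 0.10  # +/- fraction for brightness/contrast/saturation/hue
    p_cutout: float = 0.15
    p_random_erase: float = 0.10
    p_hide_and_seek: float = 0.05
    occlusion_area_range: tuple[float, float] = (0.10, 0.20)
    hide_grid: int = 4
    p_hide_patch: float = 0.25
    expansion_factor: int = 10

    def __post_init__(self) -> None:
        probs = (
            self.p_sub_strategy,
            self.p_hflip,
            self.p_cutout,
            self.p_random_erase,
            self.p_hide_and_seek,
            self.p_hide_patch,
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError(f"probabilities must lie in [0, 1]: {probs}")
        if self.p_cutout + self.p_random_erase + self.p_hide_and_seek > 1.0:
            raise ValueError("occlusion branch probabilities must sum to <= 1")
        lo, hi = self.occlusion_area_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError(
                f"occlusion_area_range must satisfy 0 <= lo <= hi < 1, got {self.occlusion_area_range}"
            )
        if self.expansion_factor < 1:
            raise ValueError(
                f"expansion_factor must be >= 1, got {self.expansion_factor}"
            )
        if self.hide_grid < 1:
            raise ValueError(f"hide_grid must be >= 1, got {self.hide_grid}")


def _check_image(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=np.float64)
    if arr.size == 0 or arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected non-empty HxWx3 image, got shape {arr.shape}")
    return arr


def apply_transform_policy(
    img: np.ndarray,
    cfg: AugmentConfig | None = None,
    rng: np.random.Generator | None = None,
    fired: list[str] | None = None,
) -> np.ndarray:
    """Apply the independent-Bernoulli transformation policy to one image.

    Each sub-strategy in :data:`SUB_STRATEGIES` fires with probability
    ``cfg.p_sub_strategy``; the flip sub-strategy, once fired, mirrors the
    image with probability ``cfg.p_hflip``. Output shape equals input shape
    (rotations use edge padding, crops are resized back). If ``fired`` is a
    list, the names of the sub-strategies that fired are appended to it.
    """
    cfg = cfg or AugmentConfig()
    rng = rng or np.random.default_rng()
    out = _check_image(img)
    h, w = out.shape[:2]

    for name in SUB_STRATEGIES:
        if rng.random() >= cfg.p_sub_strategy:
            continue
        if fired is not None:
            fired.append(name)
        if name == "rotate":
            if cfg.rotation_range > 0:
                angle = rng.uniform(-cfg.rotation_range, cfg.rotation_range)
                out = sktransform.rotate(out, angle, mode="edge", order=1)
        elif name == "hflip":
            if rng.random() < cfg.p_hflip:
                out = out[:, ::-1, :]
        elif name == "crop":
            if cfg.max_crop_frac > 0:
                f = rng.uniform(0.0, cfg.max_crop_frac)
                ch, cw = max(1, round(h * (1 - f))), max(1, round(w * (1 - f)))
                if (ch, cw) != (h, w):
                    top = rng.integers(0, h - ch + 1)
                    left = rng.integers(0, w - cw + 1)
                    window = out[top : top + ch, left : left + cw]
                    out = sktransform.resize(
                        window, (h, w), order=1, anti_aliasing=False
                    )
        elif name == "brightness":
            f = 1.0 + rng.uniform(-cfg.jitter_range, cfg.jitter_range)
            if f != 1.0:
                out = out * f
        elif name == "contrast":
            f = 1.0 + rng.uniform(-cfg.jitter_range, cfg.jitter_range)
            if f != 1.0:
                mean = out.mean()
                out = mean + (out - mean) * f
        elif name == "saturation":
            f = 1.0 + rng.uniform(-cfg.jitter_range, cfg.jitter_range)
            if f != 1.0:
                gray = out.mean(axis=2, keepdims=True)
                out = gray + (out - gray) * f
        elif name == "hue":
            # rotate RGB channels toward each other by a small mixing angle
            shift = rng.uniform(-cfg.jitter_range, cfg.jitter_range)
            if shift != 0.0:
                out = (1.0 - abs(shift)) * out + abs(shift) * np.roll(
                    out, 1 if shift >= 0 else -1, axis=2
                )
        out = np.clip(out, 0.0, 1.0)
    return out


def _draw_area(
    shape: tuple[int, ...], cfg: AugmentConfig, rng: np.random.Generator
) -> float:
    lo, hi = cfg.occlusion_area_range
    return rng.uniform(lo, hi)


def cutout(
    img: np.ndarray,
    cfg: AugmentConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Zero out one axis-aligned square covering 10-20% of the image area."""
    cfg = cfg or AugmentConfig()
    rng = rng or np.random.default_rng()
    out = _check_image(img).copy()
    h, w = out.shape[:2]
    frac = _draw_area(out.shape, cfg, rng)
    side = round(math.sqrt(frac * h * w))
    if side == 0:
        return out
    if side > min(h, w):
        raise ValueError(
            f"occlusion area {frac:.2f} infeasible for a {h}x{w} image"
        )
    top = rng.integers(0, h - side + 1)
    left = rng.integers(0, w - side + 1)
    out[top : top + side, left : left + side, :] = 0.0
    return out


def random_erase(
    img: np.ndarray,
    cfg: AugmentConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Fill one random-aspect rectangle (10-20% of area) with uniform noise.

    The aspect ratio is drawn log-uniformly in [1/3, 3]; integer rounding is
    retried so the realised area fraction stays inside the configured range.
    """
    cfg = cfg or AugmentConfig()
    rng = rng or np.random.default_rng()
    out = _check_image(img).copy()
    h, w = out.shape[:2]
    lo, hi = cfg.occlusion_area_range
    if hi == 0.0:
        return out

    eh = ew = 0
    for _ in range(64):
        area = _draw_area(out.shape, cfg, rng) * h * w
        ratio = math.exp(rng.uniform(math.log(1 / 3), math.log(3.0)))
        cand_h = max(1, round(math.sqrt(area * ratio)))
        cand_w = max(1, round(math.sqrt(area / ratio)))
        if cand_h <= h and cand_w <= w and lo <= cand_h * cand_w / (h * w) <= hi:
            eh, ew = cand_h, cand_w
            break
    if eh == 0:  # fall back to an exact square, as in cutout
        eh = ew = round(math.sqrt(_draw_area(out.shape, cfg, rng) * h * w))
        if eh > min(h, w):
            raise ValueError(f"occlusion area infeasible for a {h}x{w} image")
    if eh == 0:
        return out
    top = rng.integers(0, h - eh + 1)
    left = rng.integers(0, w - ew + 1)
    out[top : top + eh, left : left + ew, :] = rng.uniform(size=(eh, ew, 3))
    return out


def hide_and_seek(
    img: np.ndarray,
    grid: int = 4,
    p_hide: float = 0.25,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Zero each patch of a grid x grid partition independently with p_hide."""
    if grid < 1:
        raise ValueError(f"grid must be >= 1, got {grid}")
    rng = rng or np.random.default_rng()
    out = _check_image(img).copy()
    h, w = out.shape[:2]
    rows = np.linspace(0, h, grid + 1).round().astype(int)
    cols = np.linspace(0, w, grid + 1).round().astype(int)
    hide = rng.random((grid, grid)) < p_hide
    for i in range(grid):
        for j in range(grid):
            if hide[i, j]:
                out[rows[i] : rows[i + 1], cols[j] : cols[j + 1], :] = 0.0
    return out


def select_occlusion(cfg: AugmentConfig, rng: np.random.Generator) -> str:
    """One categorical draw over the mutually exclusive occlusion branches."""
    u = rng.random()
    if u < cfg.p_cutout:
        return "cutout"
    if u < cfg.p_cutout + cfg.p_random_erase:
        return "random_erase"
    if u < cfg.p_cutout + cfg.p_random_erase + cfg.p_hide_and_seek:
        return "hide_and_seek"
    return "none"


def apply_occlusion(
    img: np.ndarray, branch: str, cfg: AugmentConfig, rng: np.random.Generator
) -> np.ndarray:
    if branch == "cutout":
        return cutout(img, cfg, rng)
    if branch == "random_erase":
        return random_erase(img, cfg, rng)
    if branch == "hide_and_seek":
        return hide_and_seek(img, cfg.hide_grid, cfg.p_hide_patch, rng)
    if branch == "none":
        return img
    raise ValueError(f"unknown occlusion branch {branch!r}")


def expand_dataset(
    images: list[LabeledImage],
    cfg: AugmentConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[LabeledImage]:
    """Grow a dataset by ``cfg.expansion_factor``.

    Each source image contributes itself plus ``factor - 1`` augmented
    variants; every variant passes the transformation policy and then at
    most one occlusion operator chosen by :func:`select_occlusion`. Labels
    and per-class balance are preserved exactly.
    """
    if not images:
        raise ValueError("input dataset is empty")
    cfg = cfg or AugmentConfig()
    rng = rng or np.random.default_rng()
    out: list[LabeledImage] = []
    for item in images:
        out.append(item)
        for k in range(1, cfg.expansion_factor):
            aug = apply_transform_policy(item.image, cfg, rng)
            branch = select_occlusion(cfg, rng)
            aug = apply_occlusion(aug, branch, cfg, rng)
            out.append(LabeledImage(aug, item.label, f"{item.id}-aug{k}"))
    return out
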