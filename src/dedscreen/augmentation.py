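"""Seeded geometric augmentation streamed per epoch.

Augmentation here never enlarges the stored dataset: each training epoch
sees exactly one transformed variant of every input image (flip, mirror,
small rotation, crop-and-resize), drawn from a seeded stream so that runs
are reproducible.  Labels are untouched by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from dedscreen._util import round_half_up


@dataclass(frozen=True)
class AugmentConfig:
    """Which transforms are allowed and how strong they may be.

    ``rotation_range`` is the maximum absolute rotation in degrees;
    ``crop_fraction`` the linear fraction of each dimension kept by a random
    crop (1.0 disables cropping).  "Mirror" is the horizontal flip.
    """

    allow_horizontal_flip: bool = True
    allow_vertical_flip: bool = False
    rotation_range: float = 15.0
    crop_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rotation_range < 0:
            raise ValueError("rotation_range must be >= 0")
        if not (0 < self.crop_fraction <= 1):
            raise ValueError("crop_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class TransformDescriptor:
    """A fully determined geometric transform (no randomness left)."""

    hflip: bool = False
    vflip: bool = False
    angle: float = 0.0
    crop: tuple[int, int, int, int] | None = None  # (row0, col0, height, width)


def sample_transform(cfg: AugmentConfig, rng: np.random.Generator,
                     shape: tuple[int, int]) -> TransformDescriptor:
    h, w = shape
    hflip = bool(cfg.allow_horizontal_flip and rng.random() < 0.5)
    vflip = bool(cfg.allow_vertical_flip and rng.random() < 0.5)
    angle = float(rng.uniform(-cfg.rotation_range, cfg.rotation_range)) \
        if cfg.rotation_range > 0 else 0.0
    crop = None
    if cfg.crop_fraction < 1.0:
        ch = max(1, int(round(cfg.crop_fraction * h)))
        cw = max(1, int(round(cfg.crop_fraction * w)))
        r0 = int(rng.integers(0, h - ch + 1))
        c0 = int(rng.integers(0, w - cw + 1))
        crop = (r0, c0, ch, cw)
    return TransformDescriptor(hflip=hflip, vflip=vflip, angle=angle, crop=crop)


def apply_transform(img: np.ndarray, t: TransformDescriptor) -> np.ndarray:
    """Apply a descriptor deterministically; output keeps the input shape.

    Flips are exact; rotations by multiples of 90 degrees are exact pixel
    permutations; other angles use bilinear resampling with edge
    replication; crops are resized back bilinearly to the original size.
    """
    out = np.asarray(img)
    h, w = out.shape[:2]
    if t.hflip:
        out = out[:, ::-1]
    if t.vflip:
        out = out[::-1, :]
    angle = t.angle % 360.0
    if angle:
        # exact pixel permutation where it preserves the shape
        if angle % 90 == 0 and (h == w or angle == 180.0):
            out = np.rot90(out, k=int(angle // 90))
        else:
            rotated = ndimage.rotate(out.astype(np.float64), angle, axes=(1, 0),
                                     reshape=False, order=1, mode="nearest")
            out = np.clip(round_half_up(rotated), 0, 255).astype(img.dtype)
    if t.crop is not None:
        r0, c0, ch, cw = t.crop
        patch = out[r0 : r0 + ch, c0 : c0 + cw]
        restored = resize(patch.astype(np.float64), (h, w) + patch.shape[2:],
                          order=1, preserve_range=True, anti_aliasing=False)
        out = np.clip(round_half_up(restored), 0, 255).astype(img.dtype)
    return np.ascontiguousarray(out)


class Augmenter:
    """Callable transform stream: ``augmenter(images)`` returns one epoch.

    Two augmenters built from equal configs (same seed) produce byte-equal
    streams; the output count always equals the input count.
    """

    def __init__(self, cfg: AugmentConfig):
        self.cfg = cfg
        self._rng = np.random.default_rng(cfg.seed)

    def __call__(self, images: list[np.ndarray]) -> list[np.ndarray]:
        return [
            apply_transform(img, sample_transform(self.cfg, self._rng, img.shape[:2]))
            for img in images
        ]

    def epochs(self, images: list[np.ndarray], n_epochs: int):
        """Yield ``n_epochs`` freshly transformed copies of the input list."""
        for _ in range(n_epochs):
            yield self(images)


def make_augmenter(cfg: AugmentConfig) -> Augmenter:
    return Augmenter(cfg)
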