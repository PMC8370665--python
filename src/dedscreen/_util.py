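"""Shared numeric helpers."""

from __future__ import annotations

import numpy as np


def round_half_up(x: np.ndarray | float) -> np.ndarray | float:
    """Round to nearest integer with halves going up (0.5 -> 1).

    numpy's ``round`` uses banker's rounding; every enhancement stage in this
    package instead rounds half up so that integer outputs are reproducible
    across platforms and match hand-computed examples.
    """
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


def as_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D gray image, got shape {img.shape}")
    return img


def as_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {img.shape}")
    return img


def as_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"expected a 2-D binary mask, got shape {mask.shape}")
    if mask.dtype != bool:
        vals = np.unique(mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask must be strictly binary")
        mask = mask.astype(bool)
    return mask
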