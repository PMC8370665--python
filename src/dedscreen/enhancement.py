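"""Fundus image enhancement operators.

The stages here are the classical quality pipeline applied to retinal fundus
photographs before segmentation and classification:

* green-channel extraction — the green channel of an RGB fundus image shows
  the strongest contrast between the vessel network and the background;
* contrast-limited adaptive histogram equalization (CLAHE) — tile-wise
  histogram equalization with a clip limit, stitched with bilinear
  interpolation;
* additive illumination correction against a local-mean estimate, which
  flattens the slowly varying background shading typical of fundus cameras;
* global min-max contrast stretching for low-contrast images;
* median filtering for impulse-noise removal.

All operators are deterministic and preserve image dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from dedscreen._util import as_gray, as_rgb, round_half_up


class DegenerateImageError(ValueError):
    """Raised when an operator receives an image it is undefined on
    (e.g. contrast stretching of a constant image)."""


# --------------------------------------------------------------------------
# Parameter containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ClaheConfig:
    """CLAHE tiling and clipping parameters.

    ``tile_rows`` x ``tile_cols`` is the pixel size of one contextual region
    (tile); ``gray_levels`` is the number of histogram bins; ``clip_factor``
    is the dimensionless multiple of the average bin occupancy at which each
    tile histogram is clipped.
    """

    tile_rows: int = 16
    tile_cols: int = 16
    gray_levels: int = 256
    clip_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.tile_rows < 2 or self.tile_cols < 2:
            raise ValueError("tile dimensions must be >= 2 pixels")
        if self.gray_levels < 2:
            raise ValueError("gray_levels must be >= 2")
        if self.clip_factor < 1:
            raise ValueError("clip_factor must be >= 1")


@dataclass(frozen=True)
class ClipLimitResult:
    """Average bin occupancy and the actual clip limit derived from it."""

    n_avg: float
    n_cl: float


@dataclass(frozen=True)
class IlluminationParams:
    """Additive illumination-correction parameters.

    ``desired_mean`` is the target intensity (``None`` = use the image's own
    global mean); ``window_side`` is the odd side of the square window over
    which the local mean is estimated.
    """

    desired_mean: float | None = None
    window_side: int = 31

    def __post_init__(self) -> None:
        if self.window_side < 3 or self.window_side % 2 == 0:
            raise ValueError("window_side must be odd and >= 3")


@dataclass(frozen=True)
class ContrastStretchParams:
    gray_levels: int = 256


@dataclass(frozen=True)
class MedianFilterParams:
    window: tuple[int, int] = (3, 3)

    def __post_init__(self) -> None:
        r, c = self.window
        if r < 1 or c < 1 or r % 2 == 0 or c % 2 == 0:
            raise ValueError("median window dimensions must be odd and >= 1")


# --------------------------------------------------------------------------
# Operators
# --------------------------------------------------------------------------


def extract_green(img: np.ndarray) -> np.ndarray:
    """Return the green channel of an RGB fundus image as a gray image."""
    return as_rgb(img)[:, :, 1].copy()


def clahe_clip_limit(cfg: ClaheConfig) -> ClipLimitResult:
    """Average pixels per gray level in one tile and the actual clip limit.

    n_avg = (tile_cols * tile_rows) / gray_levels, n_cl = clip_factor * n_avg.
    """
    n_avg = (cfg.tile_cols * cfg.tile_rows) / cfg.gray_levels
    return ClipLimitResult(n_avg=n_avg, n_cl=cfg.clip_factor * n_avg)


def clahe_tile_lut(hist: np.ndarray, clip_limit: float, gray_levels: int) -> np.ndarray:
    """Equalization lookup table for one tile from its clipped histogram.

    Counts above ``clip_limit`` are truncated and the excess mass is
    redistributed uniformly across all bins in a single pass; the mapping is
    the cumulative distribution of the clipped histogram scaled to
    [0, gray_levels - 1], rounded half up.  The result is non-decreasing.
    """
    hist = np.asarray(hist, dtype=np.float64)
    excess = np.maximum(hist - clip_limit, 0.0).sum()
    clipped = np.minimum(hist, clip_limit) + excess / hist.size
    cdf = np.cumsum(clipped)
    total = cdf[-1]
    if total == 0:
        return np.zeros_like(hist, dtype=np.int64)
    lut = round_half_up(cdf / total * (gray_levels - 1)).astype(np.int64)
    return lut


def clahe(img: np.ndarray, cfg: ClaheConfig | None = None, *, interpolate: bool = True) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    The image is padded by edge replication to a whole number of
    ``tile_rows`` x ``tile_cols`` tiles; each tile's histogram is clipped at
    the configured limit and equalized; per-pixel output blends the mappings
    of the four surrounding tiles bilinearly (``interpolate=False`` applies
    each tile's own mapping directly, which is useful for testing against a
    per-tile oracle but produces visible tile seams).
    """
    cfg = cfg or ClaheConfig()
    img = as_gray(img)
    h, w = img.shape
    th, tw = cfg.tile_rows, cfg.tile_cols
    if th > h or tw > w:
        raise ValueError("tile larger than image")
    levels = cfg.gray_levels
    if img.max() >= levels:
        raise ValueError("image has gray values outside [0, gray_levels)")

    n_ty = -(-h // th)
    n_tx = -(-w // tw)
    padded = np.pad(img, ((0, n_ty * th - h), (0, n_tx * tw - w)), mode="edge")

    clip = clahe_clip_limit(cfg).n_cl
    tiles = padded.reshape(n_ty, th, n_tx, tw).transpose(0, 2, 1, 3)
    luts = np.empty((n_ty, n_tx, levels), dtype=np.int64)
    for i in range(n_ty):
        for j in range(n_tx):
            hist = np.bincount(tiles[i, j].ravel(), minlength=levels)
            luts[i, j] = clahe_tile_lut(hist, clip, levels)

    rows = np.arange(h)
    cols = np.arange(w)
    if not interpolate:
        ty = np.minimum(rows // th, n_ty - 1)
        tx = np.minimum(cols // tw, n_tx - 1)
        out = luts[ty[:, None], tx[None, :], img]
        return out.astype(img.dtype)

    # Bilinear blend between the four tile mappings surrounding each pixel,
    # anchored at tile centers; pixels beyond the outer centers clamp.
    fy = (rows + 0.5) / th - 0.5
    fx = (cols + 0.5) / tw - 0.5
    y0 = np.clip(np.floor(fy).astype(int), 0, n_ty - 1)
    x0 = np.clip(np.floor(fx).astype(int), 0, n_tx - 1)
    y1 = np.minimum(y0 + 1, n_ty - 1)
    x1 = np.minimum(x0 + 1, n_tx - 1)
    wy = np.clip(fy - y0, 0.0, 1.0)[:, None]
    wx = np.clip(fx - x0, 0.0, 1.0)[None, :]

    m00 = luts[y0[:, None], x0[None, :], img]
    m01 = luts[y0[:, None], x1[None, :], img]
    m10 = luts[y1[:, None], x0[None, :], img]
    m11 = luts[y1[:, None], x1[None, :], img]
    out = (
        (1 - wy) * ((1 - wx) * m00 + wx * m01)
        + wy * ((1 - wx) * m10 + wx * m11)
    )
    return round_half_up(out).astype(img.dtype)


def correct_illumination(img: np.ndarray, params: IlluminationParams | None = None) -> np.ndarray:
    """Additive illumination correction: p' = p + mu_D - mu_L.

    ``mu_L`` is the local mean over the configured square window (borders by
    edge replication); ``mu_D`` is the desired mean.  Output is clamped to
    [0, 255] and rounded half up.
    """
    params = params or IlluminationParams()
    img = as_gray(img).astype(np.float64)
    mu_d = float(img.mean()) if params.desired_mean is None else float(params.desired_mean)
    mu_l = ndimage.uniform_filter(img, size=params.window_side, mode="nearest")
    out = img + mu_d - mu_l
    return np.clip(round_half_up(out), 0, 255).astype(np.uint8)


def stretch_contrast(img: np.ndarray, params: ContrastStretchParams | None = None) -> np.ndarray:
    """Min-max contrast stretch onto the full [0, gray_levels - 1] range.

    The minimum input value maps to 0 and the maximum to gray_levels - 1;
    the mapping is affine and monotone.  A constant image has no defined
    stretch and raises :class:`DegenerateImageError`.
    """
    params = params or ContrastStretchParams()
    img = as_gray(img).astype(np.float64)
    lo, hi = img.min(), img.max()
    if hi == lo:
        raise DegenerateImageError("cannot stretch a constant image")
    out = (img - lo) / (hi - lo) * (params.gray_levels - 1)
    return round_half_up(out).astype(np.uint8 if params.gray_levels <= 256 else np.int64)


def median_filter(img: np.ndarray, params: MedianFilterParams | None = None) -> np.ndarray:
    """Sliding-window median filter with edge-replication borders."""
    params = params or MedianFilterParams()
    img = as_gray(img)
    wr, wc = params.window
    padded = np.pad(img, ((wr // 2, wr // 2), (wc // 2, wc // 2)), mode="edge")
    windows = np.lib.stride_tricks.sliding_window_view(padded, (wr, wc))
    return np.median(windows, axis=(2, 3)).astype(img.dtype)
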