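"""Synthetic retinal fundus images with pixel-level ground truth.

Real screening datasets (Messidor-class fundus photographs) cannot be
redistributed with a library, so this module emulates their structure at toy
scale: an orange-red background with uneven illumination, a bright roughly
circular optic disc, a dark branching vessel network radiating from the
disc rim, and per-class lesions —

* ``normal`` — no lesions;
* ``mild_dr`` — a few 1-3 px dark microaneurysm dots near vessels, the
  earliest diabetic-retinopathy sign;
* ``mild_dme`` — bright compact exudate blobs away from the disc, the
  macular-edema sign;
* ``mild_gl`` — an enlarged optic disc with an enlarged pale cup, the
  glaucoma sign.

Every image comes with a :class:`GroundTruth` carrying the disc geometry and
exact vessel / exudate / microaneurysm masks, so segmentation accuracy can
be scored without any annotation.  Generation is fully deterministic given
``(config, label)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.draw import disk as draw_disk, line as draw_line

from dedscreen._util import round_half_up

LABELS = ("normal", "mild_dr", "mild_dme", "mild_gl")

_BACKGROUND = np.array([190.0, 140.0, 70.0])
_VESSEL = np.array([130.0, 55.0, 35.0])
_DISC = np.array([250.0, 225.0, 170.0])


class ConfigurationError(ValueError):
    """Invalid generator configuration (degenerate ranges, bad label)."""


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults describe a 128 px toy fundus."""

    image_side: int = 128
    disc_radius_range: tuple[int, int] = (10, 16)
    vessel_branches: int = 4
    vessel_width_range: tuple[int, int] = (1, 3)
    exudate_count_range: tuple[int, int] = (2, 4)
    microaneurysm_count_range: tuple[int, int] = (3, 8)
    illumination_gradient_amplitude: float = 18.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_side < 64:
            raise ConfigurationError("image_side must be >= 64")
        for name in ("disc_radius_range", "vessel_width_range",
                     "exudate_count_range", "microaneurysm_count_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ConfigurationError(f"{name} must be a non-empty non-negative range")
        if self.disc_radius_range[0] < 3:
            raise ConfigurationError("disc radii below 3 px are degenerate")
        if self.vessel_branches < 1:
            raise ConfigurationError("need at least one vessel branch")
        if self.noise_sd < 0 or self.illumination_gradient_amplitude < 0:
            raise ConfigurationError("noise and illumination amplitudes must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Pixel-exact annotation accompanying a generated image."""

    disc_center: tuple[int, int]
    disc_radius: int
    vessel_mask: np.ndarray
    exudate_mask: np.ndarray
    microaneurysm_mask: np.ndarray
    label: str


def _stamp(mask: np.ndarray, r: int, c: int, radius: float) -> None:
    rr, cc = draw_disk((r, c), max(radius, 0.5) + 0.5, shape=mask.shape)
    mask[rr, cc] = True


def _draw_vessels(canvas: np.ndarray, cfg: SynthConfig, rng: np.random.Generator,
                  disc_center: tuple[int, int], disc_radius: int) -> np.ndarray:
    """Random-walk branching polylines radiating from the disc rim."""
    side = cfg.image_side
    mask = np.zeros((side, side), dtype=bool)
    w_lo, w_hi = cfg.vessel_width_range
    base_angle = rng.uniform(0, 2 * np.pi)

    def walk(r: float, c: float, angle: float, width: float, steps: int, depth: int) -> None:
        for _ in range(steps):
            angle += rng.normal(0.0, 0.22)
            r2 = r + 3.0 * np.sin(angle)
            c2 = c + 3.0 * np.cos(angle)
            if not (1 <= r2 < side - 1 and 1 <= c2 < side - 1):
                return
            rr, cc = draw_line(int(round(r)), int(round(c)), int(round(r2)), int(round(c2)))
            for pr, pc in zip(rr, cc):
                _stamp(mask, pr, pc, width / 2.0)
            r, c = r2, c2
            width = max(w_lo, width - 0.04 * (w_hi - w_lo + 1))
            if depth < 2 and rng.random() < 0.06:
                walk(r, c, angle + rng.choice((-1, 1)) * rng.uniform(0.5, 0.9),
                     max(w_lo, width * 0.7), steps // 2, depth + 1)

    for k in range(cfg.vessel_branches):
        angle = base_angle + 2 * np.pi * k / cfg.vessel_branches + rng.normal(0, 0.2)
        r0 = disc_center[0] + disc_radius * np.sin(angle)
        c0 = disc_center[1] + disc_radius * np.cos(angle)
        walk(r0, c0, angle, float(w_hi), steps=rng.integers(25, 45), depth=0)

    canvas[mask] = _VESSEL + rng.normal(0, 3.0, size=3)
    return mask


def generate_fundus(config: SynthConfig, label: str,
                    rng: np.random.Generator | None = None) -> tuple[np.ndarray, GroundTruth]:
    """Generate one labeled fundus image and its ground truth.

    Identical ``(config, label)`` yields byte-identical output; an explicit
    ``rng`` overrides the config seed (used by :func:`generate_dataset`).
    """
    if label not in LABELS:
        raise ConfigurationError(f"unknown label {label!r}; expected one of {LABELS}")
    if label == "mild_dme" and config.exudate_count_range[0] < 1:
        raise ConfigurationError("mild_dme requires exudate_count_range lower bound >= 1")
    if label == "mild_dr" and config.microaneurysm_count_range[0] < 1:
        raise ConfigurationError("mild_dr requires microaneurysm_count_range lower bound >= 1")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    side = config.image_side
    canvas = np.tile(_BACKGROUND, (side, side, 1))

    # Optic disc geometry: fully inside the image with a safety margin;
    # glaucoma uses the top of the radius range and an enlarged cup.
    r_lo, r_hi = config.disc_radius_range
    disc_radius = int(r_hi if label == "mild_gl" else rng.integers(r_lo, r_hi + 1))
    margin = disc_radius + 6
    disc_center = (int(rng.integers(margin, side - margin)),
                   int(rng.integers(margin, side - margin)))

    vessel_mask = _draw_vessels(canvas, config, rng, disc_center, disc_radius)

    # Disc drawn over the vessels: branches visibly emerge from its rim.
    disc_fill = np.zeros((side, side), dtype=bool)
    rr, cc = draw_disk(disc_center, disc_radius + 0.5, shape=(side, side))
    disc_fill[rr, cc] = True
    canvas[disc_fill] = _DISC
    cup_frac = 0.7 if label == "mild_gl" else 0.35
    rr, cc = draw_disk(disc_center, disc_radius * cup_frac, shape=(side, side))
    canvas[rr, cc] = _DISC + np.array([4.0, 12.0, 25.0])
    vessel_mask &= ~disc_fill

    exudate_mask = np.zeros((side, side), dtype=bool)
    if label == "mild_dme":
        lo, hi = config.exudate_count_range
        n_blobs = int(rng.integers(lo, hi + 1))
        vessel_dist = ndimage.distance_transform_edt(~vessel_mask)
        placed: list[tuple[int, int, int]] = []
        attempts = 0
        while len(placed) < n_blobs and attempts < 2000:
            attempts += 1
            br = int(rng.integers(3, 7))
            pr = int(rng.integers(br + 2, side - br - 2))
            pc = int(rng.integers(br + 2, side - br - 2))
            if np.hypot(pr - disc_center[0], pc - disc_center[1]) < disc_radius + br + 6:
                continue
            if vessel_dist[pr, pc] < br + 3:
                continue
            if any(np.hypot(pr - qr, pc - qc) < br + qb + 6 for qr, qc, qb in placed):
                continue
            placed.append((pr, pc, br))
        if len(placed) < n_blobs:
            raise ConfigurationError(
                "could not place the requested exudate count; image too crowded")
        yy, xx = np.mgrid[0:side, 0:side]
        for pr, pc, br in placed:
            d2 = (yy - pr) ** 2 + (xx - pc) ** 2
            profile = np.exp(-d2 / (2 * (br / 1.6) ** 2))
            bump = profile[:, :, None] * np.array([55.0, 95.0, 30.0])[None, None, :]
            inside = d2 <= br**2
            canvas[inside] += bump[inside]
            exudate_mask |= inside

    microaneurysm_mask = np.zeros((side, side), dtype=bool)
    if label == "mild_dr":
        lo, hi = config.microaneurysm_count_range
        n_dots = int(rng.integers(lo, hi + 1))
        candidates = np.argwhere(vessel_mask)
        placed_dots: list[tuple[int, int]] = []
        attempts = 0
        while len(placed_dots) < n_dots and attempts < 2000:
            attempts += 1
            vr, vc = candidates[rng.integers(len(candidates))]
            ang = rng.uniform(0, 2 * np.pi)
            off = rng.uniform(2, 5)
            pr, pc = int(round(vr + off * np.sin(ang))), int(round(vc + off * np.cos(ang)))
            if not (2 <= pr < side - 2 and 2 <= pc < side - 2):
                continue
            if disc_fill[pr, pc] or vessel_mask[pr, pc]:
                continue
            dot = np.zeros((side, side), dtype=bool)
            _stamp(dot, pr, pc, rng.integers(0, 2))  # 1-3 px dots
            dot &= ~(vessel_mask | disc_fill)
            if not dot.any():
                continue
            canvas[dot] = _VESSEL + np.array([10.0, 10.0, 5.0])
            microaneurysm_mask |= dot
            placed_dots.append((pr, pc))

    # Uneven illumination: a linear ramp in a random direction.
    theta = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:side, 0:side]
    proj = (yy - side / 2) * np.sin(theta) + (xx - side / 2) * np.cos(theta)
    ramp = config.illumination_gradient_amplitude * proj / (side / 2)
    canvas += ramp[:, :, None]

    canvas += rng.normal(0.0, config.noise_sd, size=canvas.shape)
    img = np.clip(round_half_up(canvas), 0, 255).astype(np.uint8)

    gt = GroundTruth(
        disc_center=disc_center,
        disc_radius=disc_radius,
        vessel_mask=vessel_mask,
        exudate_mask=exudate_mask,
        microaneurysm_mask=microaneurysm_mask,
        label=label,
    )
    return img, gt


def generate_dataset(
    config: SynthConfig,
    n_per_class: int,
    classes: tuple[str, ...] | list[str] = LABELS,
) -> list[tuple[np.ndarray, GroundTruth]]:
    """Generate exactly ``n_per_class`` images for each requested class.

    The per-image streams are derived from ``config.seed`` so the whole
    dataset (images, masks and label order) is reproducible.
    """
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    if not classes:
        raise ConfigurationError("class list must be non-empty")
    for c in classes:
        if c not in LABELS:
            raise ConfigurationError(f"unknown label {c!r}")
    master = np.random.default_rng(config.seed)
    items: list[tuple[np.ndarray, GroundTruth]] = []
    for label in classes:
        for _ in range(n_per_class):
            sub = np.random.default_rng(master.integers(0, 2**31 - 1))
            items.append(generate_fundus(config, label, rng=sub))
    return items


def save_dataset(items: list[tuple[np.ndarray, GroundTruth]], outdir: str | Path,
                 seed: int | None = None) -> Path:
    """Write images, 0/255 mask PNGs, and a manifest CSV; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label", "disc_center_row",
                         "disc_center_col", "disc_radius"])
        for i, (img, gt) in enumerate(items):
            stem = f"img_{i:04d}"
            iio.imwrite(outdir / f"{stem}.png", img)
            for kind, mask in (("vessels", gt.vessel_mask),
                               ("exudates", gt.exudate_mask),
                               ("microaneurysms", gt.microaneurysm_mask)):
                iio.imwrite(outdir / f"{stem}_{kind}.png",
                            (mask.astype(np.uint8) * 255))
            writer.writerow([f"{stem}.png", gt.label, gt.disc_center[0],
                             gt.disc_center[1], gt.disc_radius])
    return manifest
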