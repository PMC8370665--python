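"""Binary morphology on masks: erosion, dilation, opening, closing.

Set conventions: a mask ``A`` is the set of True pixels; a structuring
element ``B`` is a small pattern with a designated origin.  Erosion keeps the
pixels where the translated element fits entirely inside the foreground;
dilation marks every pixel whose reflected element touches the foreground.
Cells outside the image count as background for erosion and contribute
nothing to dilation, so the usual duality

    dilate(A, B) == ~erode(~A, reflect(B))

holds exactly under this padding convention (tested exhaustively).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dedscreen._util import as_mask


@dataclass(frozen=True)
class StructuringElement:
    """A binary pattern with an origin, used to probe masks."""

    pattern: np.ndarray
    origin: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        pat = np.asarray(self.pattern, dtype=bool)
        if pat.ndim != 2 or not pat.any():
            raise ValueError("structuring element must be 2-D with at least one active cell")
        object.__setattr__(self, "pattern", pat)
        origin = self.origin
        if origin is None:
            origin = (pat.shape[0] // 2, pat.shape[1] // 2)
        if not (0 <= origin[0] < pat.shape[0] and 0 <= origin[1] < pat.shape[1]):
            raise ValueError("origin must lie inside the pattern")
        object.__setattr__(self, "origin", tuple(origin))

    @classmethod
    def square(cls, side: int = 3) -> "StructuringElement":
        return cls(np.ones((side, side), dtype=bool))

    @classmethod
    def disk(cls, radius: int) -> "StructuringElement":
        r = np.arange(-radius, radius + 1)
        pat = (r[:, None] ** 2 + r[None, :] ** 2) <= radius**2
        return cls(pat)

    def reflect(self) -> "StructuringElement":
        """Point reflection through the origin."""
        h, w = self.pattern.shape
        return StructuringElement(
            self.pattern[::-1, ::-1],
            (h - 1 - self.origin[0], w - 1 - self.origin[1]),
        )

    @property
    def offsets(self) -> np.ndarray:
        """(k, 2) array of active-cell displacements relative to the origin."""
        cells = np.argwhere(self.pattern)
        return cells - np.asarray(self.origin)


def _shift(mask: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Translate a mask by (dr, dc), filling exposed cells with background."""
    out = np.zeros_like(mask)
    h, w = mask.shape
    sr0, sr1 = max(0, -dr), min(h, h - dr)
    sc0, sc1 = max(0, -dc), min(w, w - dc)
    if sr0 < sr1 and sc0 < sc1:
        out[sr0 + dr : sr1 + dr, sc0 + dc : sc1 + dc] = mask[sr0:sr1, sc0:sc1]
    return out


def erode(mask: np.ndarray, se: StructuringElement | None = None) -> np.ndarray:
    """A ⊖ B: pixels where every active SE cell lands on foreground."""
    mask = as_mask(mask)
    se = se or StructuringElement.square(3)
    out = np.ones_like(mask)
    for dr, dc in se.offsets:
        out &= _shift(mask, -dr, -dc)
    return out


def dilate(mask: np.ndarray, se: StructuringElement | None = None) -> np.ndarray:
    """A ⊕ B: pixels reachable from the foreground by an SE displacement."""
    mask = as_mask(mask)
    se = se or StructuringElement.square(3)
    out = np.zeros_like(mask)
    for dr, dc in se.offsets:
        out |= _shift(mask, dr, dc)
    return out


def closing(mask: np.ndarray, se: StructuringElement | None = None) -> np.ndarray:
    """Dilation followed by erosion; fills gaps smaller than the element."""
    se = se or StructuringElement.square(3)
    return erode(dilate(mask, se), se)


def opening(mask: np.ndarray, se: StructuringElement | None = None) -> np.ndarray:
    """Erosion followed by dilation; removes objects smaller than the element."""
    se = se or StructuringElement.square(3)
    return dilate(erode(mask, se), se)
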