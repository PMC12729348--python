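"""Tracing-to-mask conversion and crop/pad canvas geometry.

A *tracing* is an ordered polygon of (x, y) pixel vertices around the nerve
boundary (0-based, x rightward, y downward, implicitly closed). Masks are
produced by a nonzero-winding fill over pixel centers; a center lying
exactly on the polygon boundary counts as foreground, so an axis-aligned
square with corners (10,10)–(19,19) fills exactly 10x10 pixels.

The canvas transform reproduces the standard ingestion geometry: center-crop
the acquisition to a fixed size, then pad symmetrically to a square network
input (1024x690 -> 1024x1024 at full scale), recording the pad offsets so
mask coordinates remain invertible. The fill is implemented here directly —
library rasterizers disagree with a pixel-center point-in-polygon test at
boundary-adjacent pixels, and downstream area accounting needs the rule to
be exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Tracing",
    "CanvasSpec",
    "rasterize_polygon",
    "fill_tracing",
    "crop_then_pad",
    "unpad",
    "binarize",
    "read_tracing_csv",
    "write_tracing_csv",
]


@dataclass(frozen=True)
class Tracing:
    """Closed polygon boundary in pixel coordinates (x rightward, y down)."""

    vertices: np.ndarray  # (M, 2) float, columns (x, y)

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
            raise ValueError("tracing needs >= 3 (x, y) vertices")
        object.__setattr__(self, "vertices", v)

    def shoelace_area(self) -> float:
        """Unsigned polygon area in squared pixels."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * abs(float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


@dataclass(frozen=True)
class CanvasSpec:
    """Center-crop then symmetric-pad geometry with recorded offsets."""

    crop_height: int
    crop_width: int
    pad_height: int
    pad_width: int
    pad_value: float = 0.0

    def __post_init__(self):
        if self.pad_height < self.crop_height or self.pad_width < self.crop_width:
            raise ValueError("pad dims must be >= crop dims")

    @property
    def pad_offsets(self) -> tuple[int, int]:
        """(top, left) placement of the crop inside the padded canvas."""
        return (
            (self.pad_height - self.crop_height) // 2,
            (self.pad_width - self.crop_width) // 2,
        )

    def scaled(self, factor: float) -> "CanvasSpec":
        """Uniformly scaled canvas for desk-scale runs (dims rounded)."""
        return CanvasSpec(
            crop_height=int(round(self.crop_height * factor)),
            crop_width=int(round(self.crop_width * factor)),
            pad_height=int(round(self.pad_height * factor)),
            pad_width=int(round(self.pad_width * factor)),
            pad_value=self.pad_value,
        )


#: Full-scale ingestion geometry: 1024x690 crop padded to 1024x1024.
DEFAULT_CANVAS = CanvasSpec(crop_height=1024, crop_width=690,
                            pad_height=1024, pad_width=1024)


def rasterize_polygon(vertices: np.ndarray, height: int, width: int) -> np.ndarray:
    """Boolean mask of pixel centers inside a polygon (nonzero winding).

    Pixel (row r, col c) has its center at (x=c, y=r). Centers exactly on
    the boundary are foreground. Vectorized winding-number computation over
    the polygon's bounding box.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
        raise ValueError("polygon needs >= 3 vertices")
    mask = np.zeros((height, width), dtype=bool)
    x0 = max(int(np.floor(v[:, 0].min())), 0)
    x1 = min(int(np.ceil(v[:, 0].max())), width - 1)
    y0 = max(int(np.floor(v[:, 1].min())), 0)
    y1 = min(int(np.ceil(v[:, 1].max())), height - 1)
    if x0 > x1 or y0 > y1:
        return mask
    xs = np.arange(x0, x1 + 1, dtype=float)
    ys = np.arange(y0, y1 + 1, dtype=float)
    px, py = np.meshgrid(xs, ys)  # (ny, nx)
    wn = np.zeros(px.shape, dtype=np.int32)
    on_edge = np.zeros(px.shape, dtype=bool)
    a = v
    b = np.roll(v, -1, axis=0)
    for (ax, ay), (bx, by) in zip(a, b):
        # signed area of triangle (a, b, p): >0 when p is left of a->b
        cross = (bx - ax) * (py - ay) - (px - ax) * (by - ay)
        if ay <= by:
            wn += ((py >= ay) & (py < by) & (cross > 0)).astype(np.int32)
        if by <= ay:
            wn -= ((py >= by) & (py < ay) & (cross < 0)).astype(np.int32)
        # boundary: collinear and within the segment's bounding box
        seg_len2 = (bx - ax) ** 2 + (by - ay) ** 2
        if seg_len2 > 0:
            t = ((px - ax) * (bx - ax) + (py - ay) * (by - ay)) / seg_len2
            d2 = (px - (ax + t * (bx - ax))) ** 2 + (py - (ay + t * (by - ay))) ** 2
            on_edge |= (t >= 0) & (t <= 1) & (d2 < 1e-18)
    mask[y0 : y1 + 1, x0 : x1 + 1] = (wn != 0) | on_edge
    return mask


def fill_tracing(tracing: Tracing, height: int, width: int) -> np.ndarray:
    """Fill a boundary tracing into a binary mask on a height x width canvas."""
    v = tracing.vertices
    if (v[:, 0] < 0).any() or (v[:, 0] > width - 1).any() \
            or (v[:, 1] < 0).any() or (v[:, 1] > height - 1).any():
        raise ValueError("tracing vertex outside image bounds")
    return rasterize_polygon(v, height, width)


def crop_then_pad(image: np.ndarray, canvas: CanvasSpec,
                  is_mask: bool = False) -> np.ndarray:
    """Center-crop then symmetrically zero-pad to the canvas size.

    Odd crop/pad remainders put the extra pixel at the bottom/right. Masks
    are padded with background regardless of ``pad_value``.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    ch, cw = canvas.crop_height, canvas.crop_width
    if h < ch or w < cw:
        raise ValueError(f"source {h}x{w} smaller than crop {ch}x{cw}")
    top, left = (h - ch) // 2, (w - cw) // 2
    cropped = image[top : top + ch, left : left + cw]
    ptop, pleft = canvas.pad_offsets
    fill = False if is_mask else canvas.pad_value
    out = np.full((canvas.pad_height, canvas.pad_width), fill, dtype=image.dtype)
    out[ptop : ptop + ch, pleft : pleft + cw] = cropped
    return out


def unpad(image: np.ndarray, canvas: CanvasSpec) -> np.ndarray:
    """Recover the cropped region using the recorded pad offsets."""
    top, left = canvas.pad_offsets
    return np.asarray(image)[
        top : top + canvas.crop_height, left : left + canvas.crop_width
    ]


def binarize(raster: np.ndarray) -> np.ndarray:
    """Robust mask ingestion: 8-bit raster -> boolean, foreground iff > 127."""
    raster = np.asarray(raster)
    if raster.min() < 0 or raster.max() > 255:
        raise ValueError("mask raster values must lie in [0, 255]")
    return raster > 127


def read_tracing_csv(path: str | Path) -> Tracing:
    frame = pd.read_csv(path)
    return Tracing(vertices=frame[["x", "y"]].to_numpy(dtype=float))


def write_tracing_csv(tracing: Tracing, path: str | Path) -> None:
    pd.DataFrame(tracing.vertices, columns=["x", "y"]).to_csv(path, index=False)
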