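"""Intensity-based dataset augmentation: CLAHE, gamma, speckle.

The expansion protocol keeps each original image and adds one variant per
parameter setting — three CLAHE settings, four gamma values, three speckle
levels — for an 11x expansion at the defaults. Augmentations are applied
independently to the original frame, never composed, and emulate acquisition
variability (gain/exposure/speckle differences across probes and depths)
rather than anatomy, so masks pass through bit-identical.

All operations act on float images in [0, 1] and return values in [0, 1].
CLAHE is delegated to scikit-image's ``equalize_adapthist`` (clip limit as
a normalized fraction of the tile pixel count, 256 bins); the speckle
convention is multiplicative, out = in + in·n with n ~ Normal(0, v).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.exposure import equalize_adapthist

__all__ = [
    "AugmentationSpec",
    "apply_gamma",
    "apply_clahe",
    "apply_speckle",
    "expand_dataset",
    "AugmentedPair",
]

_DEFAULT_CLAHE = ((0.01, (8, 8)), (0.02, (8, 8)), (0.03, (16, 16)))
_DEFAULT_GAMMA = (0.70, 0.80, 1.20, 1.30)
_DEFAULT_SPECKLE = (0.10, 0.20, 0.30)


@dataclass(frozen=True)
class AugmentationSpec:
    """The enumerated parameter sets defining the per-image expansion."""

    clahe_settings: tuple = _DEFAULT_CLAHE
    gamma_values: tuple = _DEFAULT_GAMMA
    speckle_levels: tuple = _DEFAULT_SPECKLE
    include_original: bool = True

    @property
    def expansion_factor(self) -> int:
        return (
            int(self.include_original)
            + len(self.clahe_settings)
            + len(self.gamma_values)
            + len(self.speckle_levels)
        )

    def for_image_size(self, height: int, width: int) -> "AugmentationSpec":
        """Clamp CLAHE tile grids so tiles keep >= 16 px on small canvases.

        The variant count (and hence the expansion factor) is preserved;
        only the grid granularity is reduced where the full-scale grid
        would produce degenerate tiles (tiles so small that the integer
        clip counts of the three settings coincide).
        """
        max_rows, max_cols = max(height // 16, 1), max(width // 16, 1)
        clamped = tuple(
            (clip, (min(g[0], max_rows), min(g[1], max_cols)))
            for clip, g in self.clahe_settings
        )
        return AugmentationSpec(
            clahe_settings=clamped, gamma_values=self.gamma_values,
            speckle_levels=self.speckle_levels,
            include_original=self.include_original,
        )


def apply_gamma(image: np.ndarray, gamma: float) -> np.ndarray:
    """Power-law mapping out = in**gamma on [0, 1] intensities.

    gamma < 1 brightens, gamma > 1 darkens; endpoints are fixed.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    image = np.asarray(image, dtype=np.float32)
    if image.min() < 0 or image.max() > 1:
        raise ValueError("intensities must lie in [0, 1]")
    return np.power(image, np.float32(gamma))


def apply_clahe(image: np.ndarray, clip_limit: float,
                tile_grid: tuple[int, int]) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    ``clip_limit`` is the normalized clipping fraction of each tile's
    histogram; ``tile_grid`` = (rows, cols) of contextual tiles. Tiles
    smaller than 8 px on a side are rejected as a degenerate grid.
    """
    image = np.asarray(image, dtype=np.float64)
    if not 0 < clip_limit <= 1:
        raise ValueError("clip_limit must lie in (0, 1]")
    rows, cols = tile_grid
    h, w = image.shape
    if rows < 1 or cols < 1 or h // rows < 8 or w // cols < 8:
        raise ValueError(f"tile grid {tile_grid} too fine for {h}x{w} image")
    if image.max() == image.min():
        return image.astype(np.float32)  # degenerate one-bin histogram
    out = equalize_adapthist(
        image, kernel_size=(h // rows, w // cols), clip_limit=clip_limit, nbins=256
    )
    return out.astype(np.float32)


def apply_speckle(image: np.ndarray, variance: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Multiplicative speckle: out = clip(in + in·n, 0, 1), n ~ N(0, v)."""
    if variance < 0:
        raise ValueError("speckle variance must be >= 0")
    image = np.asarray(image, dtype=np.float32)
    if variance == 0:
        return image.copy()
    noise = rng.normal(0.0, np.sqrt(variance), size=image.shape).astype(np.float32)
    return np.clip(image + image * noise, 0.0, 1.0)


@dataclass(frozen=True)
class AugmentedPair:
    """An image–mask pair with augmentation provenance."""

    image: np.ndarray
    mask: np.ndarray
    source_id: str
    kind: str  # "original" | "clahe" | "gamma" | "speckle"
    params: dict = field(default_factory=dict)

    @property
    def pair_id(self) -> str:
        if self.kind == "original":
            return self.source_id
        tag = "-".join(f"{k}{v}" for k, v in self.params.items())
        return f"{self.source_id}_{self.kind}_{tag}"


def expand_dataset(pairs, spec: AugmentationSpec | None = None,
                   rng: np.random.Generator | None = None) -> list[AugmentedPair]:
    """Expand image–mask pairs by the enumerated augmentation protocol.

    ``pairs`` is an iterable of ``(image, mask, source_id)`` triples (or
    objects with ``.image``, ``.mask`` and ``.sample_id``). Each input
    yields the original (if configured) plus one output per CLAHE, gamma
    and speckle setting; masks are copied bit-exactly and never
    intensity-transformed. The output count is exactly
    ``len(pairs) * spec.expansion_factor``.
    """
    spec = spec or AugmentationSpec()
    rng = rng or np.random.default_rng(0)
    out: list[AugmentedPair] = []
    for item in pairs:
        if isinstance(item, tuple):
            image, mask, source_id = item
        else:
            image, mask, source_id = item.image, item.mask, item.sample_id
        if spec.include_original:
            out.append(AugmentedPair(image=image, mask=mask, source_id=source_id,
                                     kind="original"))
        for clip, grid in spec.clahe_settings:
            out.append(AugmentedPair(
                image=apply_clahe(image, clip, grid), mask=mask,
                source_id=source_id, kind="clahe",
                params={"clip": clip, "grid": f"{grid[0]}x{grid[1]}"}))
        for g in spec.gamma_values:
            out.append(AugmentedPair(
                image=apply_gamma(image, g), mask=mask,
                source_id=source_id, kind="gamma", params={"gamma": g}))
        for v in spec.speckle_levels:
            out.append(AugmentedPair(
                image=apply_speckle(image, v, rng), mask=mask,
                source_id=source_id, kind="speckle", params={"var": v}))
    return out
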